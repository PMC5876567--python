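"""Pairwise shared-segment detection and the case/case sharing permutation test.

Two animals share a segment where their genotypes are IBS-compatible — no
opposite homozygotes — over a long stretch of the LD-pruned autosomal panel.
Shared segments between relatives are enriched for identity by descent; if a
disease haplotype segregates among affected animals, case/case pairs share
segments around it more often than expected under random labels.  The test
statistic at each marker position is the number of case/case pairs whose
shared segment overlaps that position; its null distribution comes from
permuting case/control labels over animals (segments themselves are
label-free and are not recomputed).  Per-position empirical p-values use the
add-one rule, and a within-chromosome max-statistic correction gives a
chromosome-level p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from susgwas._windows import eligible_runs, window_eligible
from susgwas.genotype_io import MISSING, PHENO_CASE, PHENO_CONTROL, GenotypeData

logger = logging.getLogger(__name__)


@dataclass
class SharingParams:
    """Windowed IBS-compatibility scan parameters (mirror the ROH scan)."""

    window_snps: int = 50
    window_opp_hom_max: int = 1
    window_miss_max: int = 1
    min_snps: int = 100
    min_length_kb: float = 1000.0
    hit_fraction: float = 0.05


@dataclass
class SharedSegment:
    """A shared (IBS-compatible) run for one unordered sample pair."""

    iid1: str
    iid2: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0

    @property
    def pair(self) -> frozenset:
        return frozenset((self.iid1, self.iid2))


@dataclass
class SharingStatistic:
    """Observed per-position sharing counts by pair class."""

    grid: pd.DataFrame                       # chrom, bp per evaluation position
    case_case: np.ndarray
    case_control: np.ndarray
    control_control: np.ndarray
    pair_ids: list[tuple[str, str]] = field(repr=False, default_factory=list)
    coverage: np.ndarray | None = field(repr=False, default=None)  # pairs x positions


@dataclass
class PermutationResult:
    """Empirical p-values of the case/case sharing statistic."""

    grid: pd.DataFrame
    observed: np.ndarray
    pvalues: np.ndarray
    null_mean: np.ndarray
    null_q95: np.ndarray
    chrom_min_p: pd.DataFrame                # chrom, max_count, p
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.copy()
        df["case_case_count"] = self.observed
        df["null_mean"] = self.null_mean
        df["null_q95"] = self.null_q95
        df["p"] = self.pvalues
        chrom_p = dict(zip(self.chrom_min_p["chrom"], self.chrom_min_p["p"]))
        df["chrom_min_p"] = df["chrom"].map(chrom_p)
        return df


# ---------------------------------------------------------------------------

def detect_shared_segments(
    data: GenotypeData,
    params: SharingParams | None = None,
) -> list[SharedSegment]:
    """IBS-compatible shared segments for every unordered sample pair.

    Run on the LD-pruned autosomal panel.  A window of consecutive SNPs is
    compatible when it holds at most one opposite-homozygote marker and one
    marker missing in either sample; eligibility and run filters mirror the
    ROH scan.  Chromosomes with fewer SNPs than ``min_snps`` are skipped
    with a log entry.
    """
    p = params or SharingParams()
    auto = data.autosomal()
    ids = auto.sample_ids
    n = auto.n_samples
    chroms = auto.markers["chrom"].to_numpy()
    bp = auto.markers["bp"].to_numpy()

    segments: list[SharedSegment] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < p.min_snps:
            logger.info(
                "chromosome %s has %d SNPs (< min_snps=%d); skipped for sharing",
                chrom, len(idx), p.min_snps,
            )
            continue
        cbp = bp[idx]
        calls = auto.calls[:, idx]
        hom0 = calls == 0
        hom2 = calls == 2
        miss = calls == MISSING
        for i in range(n):
            for j in range(i + 1, n):
                opp = (hom0[i] & hom2[j]) | (hom2[i] & hom0[j])
                either_miss = miss[i] | miss[j]
                eligible = window_eligible(
                    opp, either_miss, p.window_snps, p.window_opp_hom_max,
                    p.window_miss_max, p.hit_fraction,
                )
                for a, b in eligible_runs(eligible, cbp, p.min_snps, p.min_length_kb):
                    segments.append(
                        SharedSegment(
                            ids[i], ids[j], str(chrom), int(cbp[a]), int(cbp[b]),
                            b - a + 1,
                        )
                    )
    return segments


def segments_table(segments: list[SharedSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.iid1, s.iid2, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_kb)
            for s in segments
        ],
        columns=["iid1", "iid2", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"],
    )


# ---------------------------------------------------------------------------

def _pair_coverage(
    segments: list[SharedSegment],
    pairs: list[tuple[str, str]],
    grid: pd.DataFrame,
) -> np.ndarray:
    """Boolean pairs x positions matrix: pair's segment overlaps position."""
    pair_index = {frozenset(p): k for k, p in enumerate(pairs)}
    cov = np.zeros((len(pairs), len(grid)), dtype=bool)
    chrom_arr = grid["chrom"].to_numpy()
    bp_arr = grid["bp"].to_numpy()
    for s in segments:
        k = pair_index.get(s.pair)
        if k is None:
            continue
        hit = (chrom_arr == s.chrom) & (bp_arr >= s.start_bp) & (bp_arr <= s.end_bp)
        cov[k, hit] = True
    return cov


def case_pair_sharing_statistic(
    segments: list[SharedSegment],
    phenotypes: pd.Series | dict,
    grid: pd.DataFrame,
) -> SharingStatistic:
    """Per-position counts of sharing pairs, split by pair phenotype class.

    ``phenotypes`` maps sample id -> PLINK phenotype code; every sample must
    be labelled case or control.  ``grid`` is a DataFrame with columns
    (chrom, bp) of evaluation positions, normally the pruned-panel markers.
    """
    pheno = dict(phenotypes)
    for iid, ph in pheno.items():
        if ph not in (PHENO_CASE, PHENO_CONTROL):
            raise ValueError(f"sample {iid} is not labelled case or control")
    ids = sorted(pheno)
    pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    cov = _pair_coverage(segments, pairs, grid)
    is_case = np.array([pheno[i] == PHENO_CASE for i in ids])
    idx = {iid: k for k, iid in enumerate(ids)}
    a = np.array([idx[p[0]] for p in pairs])
    b = np.array([idx[p[1]] for p in pairs])
    cc = is_case[a] & is_case[b]
    uu = ~is_case[a] & ~is_case[b]
    cu = ~(cc | uu)
    return SharingStatistic(
        grid=grid.reset_index(drop=True),
        case_case=cov[cc].sum(axis=0).astype(np.int64),
        case_control=cov[cu].sum(axis=0).astype(np.int64),
        control_control=cov[uu].sum(axis=0).astype(np.int64),
        pair_ids=pairs,
        coverage=cov,
    )


def permutation_pvalues(
    segments: list[SharedSegment],
    phenotypes: pd.Series | dict,
    grid: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Case/case sharing permutation test.

    Case/control labels are permuted uniformly over samples with group
    sizes held fixed; segments are label-free and reused.  Per position,
    empirical p = (1 + #{permuted count >= observed}) / (1 + n_perm); per
    chromosome, the same rule on the within-chromosome maximum count
    (max-statistic multiplicity correction).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    stat = case_pair_sharing_statistic(segments, phenotypes, grid)
    pheno = dict(phenotypes)
    ids = sorted(pheno)
    n = len(ids)
    n_cases = sum(1 for i in ids if pheno[i] == PHENO_CASE)
    observed = stat.case_case
    cov = stat.coverage.astype(np.float32)
    idx = {iid: k for k, iid in enumerate(ids)}
    a = np.array([idx[p[0]] for p in stat.pair_ids])
    b = np.array([idx[p[1]] for p in stat.pair_ids])

    rng = np.random.default_rng(seed)
    n_pos = cov.shape[1]
    chrom_arr = stat.grid["chrom"].to_numpy()
    chrom_list = list(pd.unique(chrom_arr))
    chrom_cols = {c: np.flatnonzero(chrom_arr == c) for c in chrom_list}
    obs_max = {c: observed[cols].max() if len(cols) else 0 for c, cols in chrom_cols.items()}

    ge_count = np.zeros(n_pos, dtype=np.int64)
    null_sum = np.zeros(n_pos, dtype=np.float64)
    chrom_ge = {c: 0 for c in chrom_list}
    all_max: dict[str, list] = {c: [] for c in chrom_list}
    batch = 256
    done = 0
    q95_samples = []
    while done < n_permutations:
        nb = min(batch, n_permutations - done)
        mask = np.zeros((nb, n), dtype=np.float32)
        for r in range(nb):
            mask[r, rng.choice(n, size=n_cases, replace=False)] = 1.0
        pair_cc = mask[:, a] * mask[:, b]          # nb x pairs
        counts = pair_cc @ cov                     # nb x positions
        ge_count += (counts >= observed[None, :] - 1e-9).sum(axis=0)
        null_sum += counts.sum(axis=0)
        if len(q95_samples) < 8:                   # cap memory for the q95 summary
            q95_samples.append(counts)
        for c, cols in chrom_cols.items():
            if len(cols) == 0:
                continue
            cmax = counts[:, cols].max(axis=1)
            chrom_ge[c] += int((cmax >= obs_max[c] - 1e-9).sum())
        done += nb

    pvalues = (1.0 + ge_count) / (1.0 + n_permutations)
    null_mean = null_sum / n_permutations
    if q95_samples:
        null_q95 = np.percentile(np.vstack(q95_samples), 95, axis=0)
    else:
        null_q95 = np.zeros(n_pos)
    chrom_min_p = pd.DataFrame(
        {
            "chrom": chrom_list,
            "max_count": [obs_max[c] for c in chrom_list],
            "p": [(1.0 + chrom_ge[c]) / (1.0 + n_permutations) for c in chrom_list],
        }
    )
    return PermutationResult(
        grid=stat.grid,
        observed=observed,
        pvalues=pvalues,
        null_mean=null_mean,
        null_q95=null_q95,
        chrom_min_p=chrom_min_p,
        n_permutations=n_permutations,
        seed=seed,
    )


def marker_grid(data: GenotypeData) -> pd.DataFrame:
    """Evaluation grid (chrom, bp) from a dataset's autosomal markers."""
    auto = data.autosomal()
    return auto.markers[["chrom", "bp"]].reset_index(drop=True)
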