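"""Marker and sample quality control and LD pruning.

Filters mirror standard array-QC practice for a small case/control herd:
markers are dropped for low call rate (> 10% missing), low minor allele
frequency (< 1%) or departure from Hardy-Weinberg equilibrium (exact test,
p < 9.5e-7), samples for > 10% missingness; call-rate and MAF failures are
tabulated jointly (callrate-only / MAF-only / both) so the attrition audit
reports the same three categories a herd report would.  For analyses that
assume quasi-independent markers (MDS, relatedness, segment sharing) a
greedy windowed LD pruning (r^2 threshold) is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import lgamma, exp

import numpy as np
import pandas as pd

from susgwas.genotype_io import MISSING, GenotypeData, is_autosome


class EmptyPanelError(ValueError):
    """All markers (or all samples) were removed by QC."""


@dataclass
class QcThresholds:
    """QC cut-offs; all proportions/probabilities in [0, 1]."""

    maf_min: float = 0.01
    marker_missing_max: float = 0.10
    sample_missing_max: float = 0.10
    hwe_p_min: float = 9.5e-7
    ld_r2_max: float = 0.2

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_missing_max", "sample_missing_max",
                     "hwe_p_min", "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Attrition bookkeeping for one QC run.

    The marker categories partition the removed markers, so
    ``n_markers_out = n_markers_in - n_fail_callrate_only - n_fail_maf_only
    - n_fail_both - n_fail_hwe`` always holds (``surviving_markers`` is
    computed from that identity).
    """

    n_markers_in: int
    n_fail_callrate_only: int
    n_fail_maf_only: int
    n_fail_both: int
    n_fail_hwe: int
    n_samples_in: int
    n_samples_removed: int
    removed_markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )
    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["iid", "reason"])
    )

    @property
    def n_markers_out(self) -> int:
        return (
            self.n_markers_in
            - self.n_fail_callrate_only
            - self.n_fail_maf_only
            - self.n_fail_both
            - self.n_fail_hwe
        )

    @property
    def n_markers_out_pre_hwe(self) -> int:
        """Survivors of the call-rate/MAF stage, before the HWE filter."""
        return (
            self.n_markers_in
            - self.n_fail_callrate_only
            - self.n_fail_maf_only
            - self.n_fail_both
        )

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_removed

    def summary(self) -> str:
        return (
            f"samples: {self.n_samples_in} in, {self.n_samples_removed} removed, "
            f"{self.n_samples_out} kept\n"
            f"markers: {self.n_markers_in} in; "
            f"{self.n_fail_callrate_only} failed call rate only, "
            f"{self.n_fail_maf_only} failed MAF only, "
            f"{self.n_fail_both} failed both "
            f"({self.n_markers_out_pre_hwe} remained); "
            f"{self.n_fail_hwe} failed HWE; {self.n_markers_out} kept"
        )

    def to_tsv(self, path) -> None:
        frames = []
        if len(self.removed_samples):
            df = self.removed_samples.copy()
            df.insert(0, "kind", "sample")
            df = df.rename(columns={"iid": "id"})
            frames.append(df)
        if len(self.removed_markers):
            df = self.removed_markers.copy()
            df.insert(0, "kind", "marker")
            df = df.rename(columns={"snp": "id"})
            frames.append(df)
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["kind", "id", "reason"])
        )
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def _hwe_exact_cached(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    # conditional (Levene-Haldane) distribution of the heterozygote count
    # given n and the minor-allele count; two-sided p sums all outcomes at
    # most as probable as the observed one.
    log_const = (
        lgamma(n + 1)
        + lgamma(n_minor + 1)
        + lgamma(2 * n - n_minor + 1)
        - lgamma(2 * n + 1)
    )
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    logps = []
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        lp = (
            log_const
            + h * np.log(2.0)
            - lgamma(h + 1)
            - lgamma(hom_minor + 1)
            - lgamma(hom_major + 1)
        )
        logps.append((int(h), lp))
    mx = max(lp for _, lp in logps)
    probs = {h: exp(lp - mx) for h, lp in logps}
    total = sum(probs.values())
    p_obs = probs[n_het]
    # small relative slack so ties are included despite rounding
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    The p-value conditions on the observed allele counts (Levene-Haldane):
    it sums, over all heterozygote counts compatible with the allele counts,
    the probabilities no larger than the observed configuration's.
    Monomorphic input returns 1.

    Parameters are counts of minor-allele homozygotes, heterozygotes and
    major-allele homozygotes.
    """
    for c in (n_hom_minor, n_het, n_hom_major):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("at least one individual required")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    return _hwe_exact_cached(n_het, n_hom_minor, n_hom_major)


# ---------------------------------------------------------------------------
# marker / sample filters
# ---------------------------------------------------------------------------

def filter_markers(
    data: GenotypeData, thresholds: QcThresholds | None = None
) -> tuple[GenotypeData, QcReport]:
    """Apply sample then marker QC; returns the filtered panel and its report.

    Order: samples failing the missingness cut are removed first; marker
    statistics are then computed on the surviving samples.  Call-rate and
    MAF failures are tabulated jointly; the HWE exact test is applied only
    to markers passing both.  Finally a1 is re-set to the minor allele on
    the surviving samples.
    """
    thr = thresholds or QcThresholds()
    if data.n_markers == 0 or data.n_samples == 0:
        raise EmptyPanelError("input panel is empty")

    smiss = data.sample_missing_rate()
    bad_samples = np.flatnonzero(smiss > thr.sample_missing_max)
    removed_samples = pd.DataFrame(
        {
            "iid": data.samples["iid"].iloc[bad_samples].to_numpy(),
            "reason": ["callrate"] * len(bad_samples),
        }
    )
    keep_samples = np.setdiff1d(np.arange(data.n_samples), bad_samples)
    if len(keep_samples) == 0:
        raise EmptyPanelError("all samples removed by missingness filter")
    work = data.subset(sample_idx=keep_samples)

    miss = work.marker_missing_rate()
    maf = work.minor_allele_freqs()
    fail_callrate = miss > thr.marker_missing_max
    fail_maf = np.isnan(maf) | (maf < thr.maf_min)

    both = fail_callrate & fail_maf
    cr_only = fail_callrate & ~fail_maf
    maf_only = fail_maf & ~fail_callrate
    survivors1 = np.flatnonzero(~(fail_callrate | fail_maf))

    fail_hwe = np.zeros(work.n_markers, dtype=bool)
    for j in survivors1:
        col = work.calls[:, j]
        obs = col[col != MISSING]
        n_hom1 = int((obs == 2).sum())
        n_het = int((obs == 1).sum())
        n_hom2 = int((obs == 0).sum())
        if hwe_exact_test(n_hom1, n_het, n_hom2) < thr.hwe_p_min:
            fail_hwe[j] = True

    reasons = []
    snp = work.markers["snp"].to_numpy()
    for j in np.flatnonzero(cr_only):
        reasons.append((snp[j], "callrate"))
    for j in np.flatnonzero(maf_only):
        reasons.append((snp[j], "maf"))
    for j in np.flatnonzero(both):
        reasons.append((snp[j], "callrate+maf"))
    for j in np.flatnonzero(fail_hwe):
        reasons.append((snp[j], "hwe"))
    removed_markers = pd.DataFrame(reasons, columns=["snp", "reason"])

    keep = np.flatnonzero(~(fail_callrate | fail_maf | fail_hwe))
    report = QcReport(
        n_markers_in=data.n_markers,
        n_fail_callrate_only=int(cr_only.sum()),
        n_fail_maf_only=int(maf_only.sum()),
        n_fail_both=int(both.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
        n_samples_in=data.n_samples,
        n_samples_removed=len(bad_samples),
        removed_markers=removed_markers,
        removed_samples=removed_samples,
    )
    if len(keep) == 0:
        raise EmptyPanelError("all markers removed by QC:\n" + report.summary())
    out = work.subset(marker_idx=keep).set_minor_allele_first()
    return out, report


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """Squared Pearson correlation of two allele-count vectors.

    Computed on pairwise-complete (both non-missing) samples.  Returns NaN
    when either marker has zero variance among those samples — callers
    treat that as "prune one of the pair".
    """
    x = np.asarray(calls_i, dtype=float)
    y = np.asarray(calls_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("call vectors must have the same length")
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return np.nan
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """r^2 matrix over markers (columns) with pairwise-complete missing handling."""
    g = calls.astype(float)
    mask = g != MISSING
    g = np.where(mask, g, 0.0)
    m = mask.astype(float)
    n = m.T @ m                      # pairwise-complete counts
    sx = g.T @ m                     # sum of x over joint support
    sy = m.T @ g
    sxy = g.T @ g
    sxx = (g * g).T @ m
    syy = m.T @ (g * g)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sy / n)
        vx = sxx / n - (sx / n) ** 2
        vy = syy / n - (sy / n) ** 2
        r2 = cov * cov / (vx * vy)
    return r2


def ld_prune(
    data: GenotypeData,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy windowed LD pruning on the autosomes; returns kept marker ids.

    Within each sliding window, while any kept pair has r^2 >= ``r2_max``
    (or undefined r^2 from a zero-variance marker), the member of the
    offending pair with lower MAF is dropped (tie: the later bp position).
    X-chromosome markers never enter and are not returned.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    auto = data.autosomal()
    n = auto.n_markers
    if n == 0:
        return []
    maf = auto.minor_allele_freqs()
    kept = np.ones(n, dtype=bool)
    chroms = auto.markers["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        r2 = _pairwise_r2(auto.calls[:, idx])
        local_of = {g: k for k, g in enumerate(idx)}
        # windows slide over the *currently kept* markers; passes repeat
        # until stable so no surviving pair within a window of the pruned
        # panel violates the threshold (this also makes pruning idempotent)
        changed = True
        while changed:
            changed = False
            live = idx[kept[idx]]
            for start in range(0, max(1, len(live) - 1), step_snps):
                win = [g for g in live[start : start + window_snps] if kept[g]]
                while True:
                    worst = None
                    for a in range(len(win)):
                        if not kept[win[a]]:
                            continue
                        for b in range(a + 1, len(win)):
                            if not kept[win[b]]:
                                continue
                            v = r2[local_of[win[a]], local_of[win[b]]]
                            if np.isnan(v) or v >= r2_max:
                                worst = (win[a], win[b])
                                break
                        if worst:
                            break
                    if worst is None:
                        break
                    gi, gj = worst
                    # drop lower MAF; tie -> later bp (gj has the larger bp)
                    drop = gi if maf[gi] < maf[gj] else gj
                    # undefined/zero-variance markers always go first
                    if np.isnan(maf[gi]) or maf[gi] == 0:
                        drop = gi
                    elif np.isnan(maf[gj]) or maf[gj] == 0:
                        drop = gj
                    kept[drop] = False
                    changed = True
                if start + window_snps >= len(live):
                    break
    snp = auto.markers["snp"].to_numpy()
    return [snp[j] for j in np.flatnonzero(kept)]


# ---------------------------------------------------------------------------
# sample heterozygosity
# ---------------------------------------------------------------------------

def sample_het_check(data: GenotypeData, sd_multiplier: float = 3.0) -> pd.DataFrame:
    """Per-sample inbreeding-style F with excess-heterozygosity flags.

    F = 1 - observed het / expected het, where the expectation comes from
    panel allele frequencies (2*p*q summed over the sample's non-missing
    markers).  Samples with F more than ``sd_multiplier`` standard
    deviations *below* the mean (heterozygosity excess, a contamination
    signature) are flagged.  Returns a DataFrame (iid, obs_het, exp_het,
    F, flagged).
    """
    if data.n_samples < 5:
        raise ValueError("need at least 5 samples for the heterozygosity check")
    freqs = data.minor_allele_freqs()
    het_exp_marker = 2.0 * freqs * (1.0 - freqs)
    obs_mask = data.calls != MISSING
    het_obs = ((data.calls == 1) & obs_mask).sum(axis=1).astype(float)
    het_exp = np.where(np.isnan(het_exp_marker), 0.0, het_exp_marker)[None, :]
    het_exp = (het_exp * obs_mask).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(het_exp > 0, 1.0 - het_obs / het_exp, 0.0)
    sd = f.std()
    if sd > 0:
        flagged = f < f.mean() - sd_multiplier * sd
    else:
        flagged = np.zeros(len(f), dtype=bool)
    return pd.DataFrame(
        {
            "iid": data.samples["iid"].to_numpy(),
            "obs_het": het_obs,
            "exp_het": het_exp,
            "F": f,
            "flagged": flagged,
        }
    )
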