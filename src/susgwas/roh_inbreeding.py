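"""Runs of homozygosity, the FROH genomic inbreeding coefficient, and the
case/control inbreeding comparison.

A run of homozygosity (ROH) is a contiguous autosomal stretch of homozygous
genotypes; long runs indicate both chromosomes descend from a recent common
ancestor.  Detection uses the sliding-window scheme of standard array
tooling: windows of 50 SNPs tolerating one heterozygote and one missing
call, a 5% clean-window hit fraction per SNP, and final runs of at least
100 SNPs spanning at least 1,000 kb.  FROH is total ROH length over total
autosomal genome length (the Sus scrofa build-10.2 value 2,808,525 kb by
default), and group differences are assessed with a Welch two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from susgwas._windows import eligible_runs, window_eligible
from susgwas.genotype_io import MISSING, GenotypeData, is_autosome

logger = logging.getLogger(__name__)

#: total swine autosomal genome length in kb (Sscrofa10.2)
SWINE_GENOME_KB: float = 2_808_525.0


@dataclass
class RohParams:
    """Sliding-window ROH detection parameters (counts in SNPs, length in kb)."""

    window_snps: int = 50
    window_het_max: int = 1
    window_miss_max: int = 1
    min_snps: int = 100
    min_length_kb: float = 1000.0
    hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps) <= 0 or self.min_length_kb <= 0:
            raise ValueError("ROH parameters must be positive")
        if self.min_snps < self.window_snps:
            raise ValueError("min_snps must be >= window_snps")


@dataclass
class RohSegment:
    """One homozygous run: 1-based closed interval on one chromosome."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass
class FrohResult:
    """Per-sample genomic inbreeding: FROH = sum of ROH lengths / L."""

    sample_id: str
    n_segments: int
    total_roh_kb: float
    genome_length_kb: float

    @property
    def froh(self) -> float:
        return self.total_roh_kb / self.genome_length_kb


def detect_roh(
    data: GenotypeData,
    params: RohParams | None = None,
    sample_ids: list[str] | None = None,
) -> list[RohSegment]:
    """Detect ROH for every (or the given) sample on the autosomes.

    Chromosomes with fewer SNPs than one window are skipped with a log
    entry.  The heterozygote/missing tolerance applies inside scanning
    windows only; final runs are maximal stretches of window-eligible SNPs.
    """
    p = params or RohParams()
    auto = data.autosomal()
    ids = auto.sample_ids
    wanted = set(sample_ids) if sample_ids is not None else None
    chroms = auto.markers["chrom"].to_numpy()
    bp = auto.markers["bp"].to_numpy()

    segments: list[RohSegment] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < p.window_snps:
            logger.info(
                "chromosome %s has %d SNPs (< window of %d); skipped for ROH",
                chrom, len(idx), p.window_snps,
            )
            continue
        cbp = bp[idx]
        calls = auto.calls[:, idx]
        for i, iid in enumerate(ids):
            if wanted is not None and iid not in wanted:
                continue
            row = calls[i]
            het = row == 1
            miss = row == MISSING
            eligible = window_eligible(
                het, miss, p.window_snps, p.window_het_max, p.window_miss_max,
                p.hit_fraction,
            )
            for a, b in eligible_runs(eligible, cbp, p.min_snps, p.min_length_kb):
                segments.append(
                    RohSegment(iid, str(chrom), int(cbp[a]), int(cbp[b]), b - a + 1)
                )
    return segments


def compute_froh(
    segments: list[RohSegment],
    sample_id: str,
    genome_length_kb: float = SWINE_GENOME_KB,
) -> FrohResult:
    """FROH for one sample from its detected segments."""
    if genome_length_kb <= 0:
        raise ValueError("genome_length_kb must be positive")
    own = [s for s in segments if s.sample_id == sample_id]
    total = float(sum(s.length_kb for s in own))
    return FrohResult(sample_id, len(own), total, genome_length_kb)


def froh_table(
    segments: list[RohSegment],
    sample_ids: list[str],
    genome_length_kb: float = SWINE_GENOME_KB,
) -> pd.DataFrame:
    """Per-sample FROH summary (iid, n_segments, total_roh_kb, froh)."""
    rows = []
    for iid in sample_ids:
        r = compute_froh(segments, iid, genome_length_kb)
        rows.append((iid, r.n_segments, r.total_roh_kb, r.froh))
    return pd.DataFrame(rows, columns=["iid", "n_segments", "total_roh_kb", "froh"])


def segments_table(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_kb)
            for s in segments
        ],
        columns=["iid", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"],
    )


def froh_group_test(
    froh_cases: np.ndarray, froh_controls: np.ndarray
) -> tuple[float, float, float, float]:
    """Welch two-sample t-test of mean FROH, cases vs controls.

    Returns (mean_case, mean_control, t, two-sided p).  Degenerate
    zero-variance groups get a tiny variance floor so a finite statistic is
    still reported (identical groups return p = 1).
    """
    a = np.asarray(froh_cases, dtype=float)
    b = np.asarray(froh_controls, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return float(a.mean()), float(b.mean()), 0.0, 1.0
        eps = max(abs(a.mean()), abs(b.mean()), 1e-12) * 1e-8
        a = a + np.linspace(-eps, eps, len(a))
        b = b + np.linspace(-eps, eps, len(b))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(np.mean(froh_cases)), float(np.mean(froh_controls)), float(t), float(p)
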