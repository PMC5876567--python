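"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible — nested loops, exact
fractions, direct enumeration — and shares no code with the package paths
it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1


# -- Hardy-Weinberg exact test ---------------------------------------------

def hwe_exact_enumeration(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact HWE p by full enumeration with exact rationals."""
    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    probs = {}
    denom = comb(2 * n, n_minor)
    for het in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        if hom_major < 0:
            continue
        # multinomial count of genotype configurations x 2^het phasings
        num = (
            Fraction(
                comb(n, het) * comb(n - het, hom_minor) * (2**het), denom
            )
        )
        probs[het] = num
    total = sum(probs.values())
    p_obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= p_obs) / total
    return float(p)


# -- 2x2 chi-square ---------------------------------------------------------

def chi2_2x2_closed_form(a, b, c, d) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


# -- IBS distance -----------------------------------------------------------

def ibs_distance_loops(calls: np.ndarray) -> np.ndarray:
    n, m = calls.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            tot = 0
            ibs = 0
            for k in range(m):
                gi, gj = calls[i, k], calls[j, k]
                if gi == MISSING or gj == MISSING:
                    continue
                tot += 1
                ibs += 2 - abs(int(gi) - int(gj))
            out[i, j] = 1.0 - (ibs / tot) / 2.0
    return out


# -- windowed run detection (ROH and pairwise sharing) ----------------------

def roh_segments_loops(
    calls_row: np.ndarray,
    bp: np.ndarray,
    window: int,
    het_max: int,
    miss_max: int,
    min_snps: int,
    min_kb: float,
    hit_fraction: float,
) -> list[tuple[int, int]]:
    """ROH runs for one sample on one chromosome, index pairs inclusive."""
    viol = [1 if g == 1 else 0 for g in calls_row]
    miss = [1 if g == MISSING else 0 for g in calls_row]
    return _windowed_runs_loops(
        viol, miss, bp, window, het_max, miss_max, min_snps, min_kb, hit_fraction
    )


def shared_segments_loops(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    bp: np.ndarray,
    window: int,
    opp_max: int,
    miss_max: int,
    min_snps: int,
    min_kb: float,
    hit_fraction: float,
) -> list[tuple[int, int]]:
    viol = []
    miss = []
    for ga, gb in zip(calls_a, calls_b):
        opp = (ga == 0 and gb == 2) or (ga == 2 and gb == 0)
        viol.append(1 if opp else 0)
        miss.append(1 if (ga == MISSING or gb == MISSING) else 0)
    return _windowed_runs_loops(
        viol, miss, bp, window, opp_max, miss_max, min_snps, min_kb, hit_fraction
    )


def _windowed_runs_loops(
    viol, miss, bp, window, viol_max, miss_max, min_snps, min_kb, hit_fraction
):
    n = len(viol)
    if n < window:
        return []
    clean = []
    for start in range(n - window + 1):
        v = sum(viol[start : start + window])
        m = sum(miss[start : start + window])
        clean.append(v <= viol_max and m <= miss_max)
    eligible = []
    for i in range(n):
        overlapping = [
            clean[j] for j in range(max(0, i - window + 1), min(i, n - window) + 1)
        ]
        rate = sum(overlapping) / len(overlapping)
        eligible.append(rate >= hit_fraction - 1e-12)
    runs = []
    i = 0
    while i < n:
        if eligible[i]:
            j = i
            while j + 1 < n and eligible[j + 1]:
                j += 1
            if (j - i + 1) >= min_snps and (bp[j] - bp[i]) / 1000.0 >= min_kb:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


# -- per-position pair sharing counts ---------------------------------------

def sharing_counts_loops(segments, case_ids, control_ids, grid):
    """Per-position case/case sharing counts by naive overlap scan.

    ``segments`` is an iterable of (iid1, iid2, chrom, start_bp, end_bp).
    """
    cases = set(case_ids)
    counts = []
    for chrom, bp in grid:
        c = 0
        seen_pairs = set()
        for iid1, iid2, s_chrom, s_start, s_end in segments:
            if s_chrom != chrom or not (s_start <= bp <= s_end):
                continue
            pair = frozenset((iid1, iid2))
            if pair in seen_pairs:
                continue
            if iid1 in cases and iid2 in cases:
                c += 1
                seen_pairs.add(pair)
        counts.append(c)
    return counts
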