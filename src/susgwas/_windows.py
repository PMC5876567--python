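"""Sliding-window scan shared by ROH detection and pairwise segment sharing.

Both analyses mark a SNP as run-eligible when at least a fraction of the
fixed-size windows overlapping it are "clean" (few violations, few missing
calls), then emit maximal runs of eligible SNPs passing count and physical
length filters.  Only the definition of a violation differs between the two
callers (heterozygote vs opposite-homozygote pair).
"""

from __future__ import annotations

import numpy as np


def window_eligible(
    viol: np.ndarray,
    miss: np.ndarray,
    window_snps: int,
    viol_max: int,
    miss_max: int,
    hit_fraction: float,
) -> np.ndarray:
    """Boolean eligibility per SNP from the windowed clean-fraction rule.

    A window of ``window_snps`` consecutive SNPs is clean when it holds at
    most ``viol_max`` violations and ``miss_max`` missing calls.  A SNP is
    eligible when the fraction of windows overlapping it that are clean is
    at least ``hit_fraction``.  Returns all-False when the chromosome is
    shorter than one window.
    """
    viol = np.asarray(viol, dtype=np.int64)
    miss = np.asarray(miss, dtype=np.int64)
    n = len(viol)
    w = window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    cv = np.concatenate([[0], np.cumsum(viol)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    vsum = cv[w:] - cv[:-w]          # per-window violation counts
    msum = cm[w:] - cm[:-w]
    clean = ((vsum <= viol_max) & (msum <= miss_max)).astype(np.int64)
    cc = np.concatenate([[0], np.cumsum(clean)])
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)    # first window index overlapping SNP i
    hi = np.minimum(i, n - w)        # last
    n_win = hi - lo + 1
    n_clean = cc[hi + 1] - cc[lo]
    return n_clean >= hit_fraction * n_win - 1e-12


def eligible_runs(
    eligible: np.ndarray,
    bp: np.ndarray,
    min_snps: int,
    min_length_kb: float,
) -> list[tuple[int, int]]:
    """Maximal runs of eligible SNPs passing the count and kb-span filters.

    Returns (start_index, end_index) pairs, both inclusive; the physical
    span is (bp[end] - bp[start]) / 1000 kb.
    """
    eligible = np.asarray(eligible, dtype=bool)
    bp = np.asarray(bp, dtype=np.int64)
    out: list[tuple[int, int]] = []
    n = len(eligible)
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        n_snps = j - i + 1
        length_kb = (bp[j] - bp[i]) / 1000.0
        if n_snps >= min_snps and length_kb >= min_length_kb:
            out.append((i, j))
        i = j + 1
    return out
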