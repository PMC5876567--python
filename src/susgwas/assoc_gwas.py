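"""Case/control association: allelic chi-square with odds ratios, genomic
inflation and QQ data, EM haplotype frequencies with haplotype tests, and
per-marker logistic effect estimates.

The per-marker test is the classic 1-df Pearson chi-square on the 2x2
minor/major allele-count table, without continuity correction; the odds
ratio uses the Haldane-Anscombe +0.5 correction when any cell is zero, so
even haplotypes absent from one group get a reportable direction.  Panel
calibration is summarised by the genomic inflation factor
lambda_GC = median(chi2) / median(chi2_1df).  Markers on the same chromosome
can be combined into unphased haplotypes whose frequencies are estimated by
an EM algorithm fitted per group; each haplotype is then tested against all
others on expected allele counts, alongside an omnibus test over all
haplotypes.  Marker effects on the log-odds scale come from single-predictor
logistic regression (Newton-Raphson, Wald test), with explicit separation
flagging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from susgwas.genotype_io import MISSING, GenotypeData

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN: float = float(stats.chi2.ppf(0.5, 1))

#: genome-wide significance threshold used throughout the herd screen
ASSOC_P_THRESHOLD: float = 5e-5


@dataclass
class AssocResult:
    """Allelic 2x2 test for one marker (counts are allele counts)."""

    marker_id: str
    case_minor: int
    case_major: int
    control_minor: int
    control_major: int
    chi2: float
    p: float
    odds_ratio: float


@dataclass
class InflationResult:
    lambda_gc: float
    n_markers: int


@dataclass
class HaplotypeResult:
    """One haplotype's case/control frequencies and 2x2 test."""

    marker_ids: tuple
    haplotype: str
    freq_cases: float
    freq_controls: float
    chi2: float | None
    p: float | None
    odds_ratio: float | None
    tested: bool


@dataclass
class HaplotypeAssoc:
    """Per-haplotype results plus the omnibus (h-1 df) test."""

    results: list[HaplotypeResult]
    omnibus_chi2: float
    omnibus_df: int
    omnibus_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "markers": "-".join(r.marker_ids),
                    "haplotype": r.haplotype,
                    "pct_case": 100.0 * r.freq_cases,
                    "pct_control": 100.0 * r.freq_controls,
                    "chi2": r.chi2,
                    "p": r.p,
                    "odds_ratio": r.odds_ratio,
                    "tested": r.tested,
                }
                for r in self.results
            ]
        )


@dataclass
class LogisticEffect:
    beta: float
    se: float
    p: float | None
    converged: bool
    separation: bool


# ---------------------------------------------------------------------------
# single-marker tests
# ---------------------------------------------------------------------------

def chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square of a 2x2 table [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> float:
    """Cross-product OR with Haldane-Anscombe +0.5 on all cells iff any is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def allelic_test(
    case_calls: np.ndarray, control_calls: np.ndarray, marker_id: str = ""
) -> AssocResult:
    """1-df allelic chi-square and odds ratio for one marker.

    Calls are minor-allele counts; missing calls are excluded.  The table is
    minor/major x case/control on allele (chromosome) counts.
    """
    cc = np.asarray(case_calls)
    uu = np.asarray(control_calls)
    cc = cc[cc != MISSING]
    uu = uu[uu != MISSING]
    if len(cc) == 0 or len(uu) == 0:
        group = "case" if len(cc) == 0 else "control"
        raise ValueError(f"marker {marker_id or '?'}: all calls missing in {group} group")
    a = int(cc.sum())                   # case minor
    b = int(2 * len(cc) - a)            # case major
    c = int(uu.sum())                   # control minor
    d = int(2 * len(uu) - c)
    chi2 = chi2_2x2(a, b, c, d)
    p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return AssocResult(marker_id, a, b, c, d, float(chi2), p, odds_ratio_2x2(a, b, c, d))


def gwas_scan(data: GenotypeData) -> pd.DataFrame:
    """Allelic test at every marker; returns a plot-ready association table.

    Monomorphic markers and markers entirely missing in one group are
    reported with NaN statistics rather than dropped, so marker bookkeeping
    stays transparent.
    """
    cases = data.calls[data.case_mask()]
    controls = data.calls[data.control_mask()]
    if cases.shape[0] == 0 or controls.shape[0] == 0:
        raise ValueError("both cases and controls are required for the GWAS scan")
    rows = []
    markers = data.markers
    for j in range(data.n_markers):
        mid = markers["snp"].iloc[j]
        col_c = cases[:, j]
        col_u = controls[:, j]
        obs_all = np.concatenate([col_c[col_c != MISSING], col_u[col_u != MISSING]])
        # monomorphic = every observed chromosome carries the same allele
        polymorphic = len(obs_all) > 0 and not ((obs_all == 0).all() or (obs_all == 2).all())
        try:
            if not polymorphic:
                raise ValueError("monomorphic")
            r = allelic_test(col_c, col_u, mid)
            rows.append(
                (mid, markers["chrom"].iloc[j], markers["bp"].iloc[j],
                 r.case_minor, r.case_major, r.control_minor, r.control_major,
                 r.chi2, r.p, r.odds_ratio)
            )
        except ValueError:
            rows.append(
                (mid, markers["chrom"].iloc[j], markers["bp"].iloc[j],
                 np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["snp", "chrom", "bp", "case_minor", "case_major",
                 "control_minor", "control_major", "chi2", "p", "odds_ratio"],
    )


def genomic_inflation(chi2_values: np.ndarray) -> InflationResult:
    """lambda_GC = median(chi2) / median of the 1-df chi-square null."""
    x = np.asarray(chi2_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no finite chi-square statistics")
    return InflationResult(float(np.median(x) / CHI2_1DF_MEDIAN), len(x))


def qq_points(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot (observed ascending)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    n = len(p)
    if n == 0:
        raise ValueError("no p-values")
    if (p <= 0).any():
        p = np.where(p <= 0, 1.0 / (2 * n), p)
    p = np.sort(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p)}
    )


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def _enumerate_haplotypes(n_markers: int) -> list[tuple[int, ...]]:
    return list(itertools.product((0, 1), repeat=n_markers))


def em_haplotype_freqs(
    calls: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[dict[tuple[int, ...], float], bool, list[float]]:
    """EM estimate of haplotype frequencies from unphased genotypes.

    ``calls`` is individuals x markers (2 or 3 markers) of minor-allele
    counts; individuals missing any of the markers are excluded.  Haplotypes
    are tuples over {0 = major, 1 = minor}.  Starting from uniform
    frequencies, the E-step distributes each multilocus genotype over its
    compatible ordered haplotype pairs in proportion to current frequency
    products; the M-step re-estimates frequencies; iteration stops when the
    largest frequency change drops below ``tol``.

    Returns (frequencies, converged, log-likelihood trace).
    """
    g = np.asarray(calls)
    if g.ndim != 2 or not 2 <= g.shape[1] <= 3:
        raise ValueError("calls must be individuals x (2 or 3) markers")
    g = g[(g != MISSING).all(axis=1)]
    m = g.shape[1]
    haps = _enumerate_haplotypes(m)
    hap_idx = {h: i for i, h in enumerate(haps)}
    nh = len(haps)
    if len(g) == 0:
        return {h: 1.0 / nh for h in haps}, True, []

    # pre-compute compatible (h1, h2) pairs per distinct genotype
    geno_counts: dict[tuple[int, ...], int] = {}
    for row in map(tuple, g):
        geno_counts[row] = geno_counts.get(row, 0) + 1
    compat: dict[tuple[int, ...], list[tuple[int, int]]] = {}
    for geno in geno_counts:
        pairs = []
        for h1 in haps:
            h2 = tuple(geno[k] - h1[k] for k in range(m))
            if all(v in (0, 1) for v in h2):
                pairs.append((hap_idx[h1], hap_idx[h2]))
        compat[geno] = pairs

    freq = np.full(nh, 1.0 / nh)
    loglik_trace: list[float] = []
    converged = False
    n_ind = sum(geno_counts.values())
    for _ in range(max_iter):
        new = np.zeros(nh)
        ll = 0.0
        for geno, count in geno_counts.items():
            pairs = compat[geno]
            w = np.array([freq[i] * freq[j] for i, j in pairs])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1.0
                ll += count * np.log(1e-300)
            else:
                w = w / tot
                ll += count * np.log(tot)
            for (i, j), wk in zip(pairs, w):
                new[i] += count * wk
                new[j] += count * wk
        new = new / (2.0 * n_ind)
        loglik_trace.append(float(ll))
        if np.max(np.abs(new - freq)) < tol:
            freq = new
            converged = True
            break
        freq = new
    return {h: float(freq[hap_idx[h]]) for h in haps}, converged, loglik_trace


def _hap_string(hap: tuple[int, ...], markers: pd.DataFrame, marker_ids) -> str:
    """Render a 0/1 haplotype as allele letters using marker a1/a2 codes."""
    letters = []
    for k, mid in enumerate(marker_ids):
        row = markers[markers["snp"] == mid].iloc[0]
        letters.append(str(row["a1"]) if hap[k] == 1 else str(row["a2"]))
    return "".join(letters)


def haplotype_assoc(
    data: GenotypeData,
    marker_ids: list[str],
    min_expected: float = 1.0,
) -> HaplotypeAssoc:
    """Haplotype association for 2-3 markers via per-group EM frequencies.

    Expected haplotype counts are 2n x frequency per group.  Each haplotype
    is tested this-vs-rest on a 2x2 chi-square (1 df) with Haldane-corrected
    OR; haplotypes with expected count below ``min_expected`` in both groups
    are reported descriptively, untested.  The omnibus test is an (h-1)-df
    chi-square over all haplotype expected counts.
    """
    if not 2 <= len(marker_ids) <= 3:
        raise ValueError("haplotype tests take 2 or 3 markers")
    cols = [data.marker_ids.index(m) for m in marker_ids]
    case_calls = data.calls[data.case_mask()][:, cols]
    control_calls = data.calls[data.control_mask()][:, cols]
    f_case, _, _ = em_haplotype_freqs(case_calls)
    f_ctrl, _, _ = em_haplotype_freqs(control_calls)
    n_case = int((case_calls != MISSING).all(axis=1).sum())
    n_ctrl = int((control_calls != MISSING).all(axis=1).sum())

    haps = sorted(f_case, key=lambda h: -(f_case[h] + f_ctrl[h]))
    results = []
    exp_case = {h: 2 * n_case * f_case[h] for h in haps}
    exp_ctrl = {h: 2 * n_ctrl * f_ctrl[h] for h in haps}
    for h in haps:
        a = exp_case[h]
        b = 2 * n_case - a
        c = exp_ctrl[h]
        d = 2 * n_ctrl - c
        tested = not (a < min_expected and c < min_expected)
        if tested:
            chi2 = chi2_2x2(a, b, c, d)
            p = float(stats.chi2.sf(chi2, 1))
            orr = odds_ratio_2x2(a, b, c, d)
        else:
            chi2 = p = orr = None
        results.append(
            HaplotypeResult(
                tuple(marker_ids),
                _hap_string(h, data.markers, marker_ids),
                f_case[h],
                f_ctrl[h],
                chi2,
                p,
                orr,
                tested,
            )
        )

    # omnibus over haplotypes with any appreciable expected count
    used = [h for h in haps if exp_case[h] + exp_ctrl[h] >= min_expected]
    table = np.array([[exp_case[h] for h in used], [exp_ctrl[h] for h in used]])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] >= 2 and table.sum() > 0:
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
        omnibus_chi2 = float(contrib.sum())
        omnibus_df = table.shape[1] - 1
        omnibus_p = float(stats.chi2.sf(omnibus_chi2, omnibus_df))
    else:
        omnibus_chi2, omnibus_df, omnibus_p = 0.0, 0, 1.0
    return HaplotypeAssoc(results, omnibus_chi2, omnibus_df, omnibus_p)


# ---------------------------------------------------------------------------
# logistic effects
# ---------------------------------------------------------------------------

def logistic_effect(
    calls: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> LogisticEffect:
    """Single-predictor logistic regression of case status on allele dose.

    ``labels`` are 1 for case, 0 for control; missing calls are dropped.
    Fitted by Newton-Raphson with an intercept; the Wald z-test gives the
    p-value.  Complete or quasi-complete separation (diverging slope or a
    vanishing information matrix) is flagged and no p-value is emitted.
    """
    x = np.asarray(calls, dtype=float)
    y = np.asarray(labels, dtype=float)
    ok = x != MISSING
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if x.min() == x.max():
        raise ValueError("marker is monomorphic among analysed samples")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    separation = False
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        if w.max() < 1e-10 or abs(beta[1]) > 15:
            separation = True
            break
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not separation and abs(beta[1]) > 15:
        separation = True
    if separation:
        return LogisticEffect(float(beta[1]), np.inf, None, False, True)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticEffect(float(beta[1]), se, p, converged, False)
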