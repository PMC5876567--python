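"""Pairwise IBS/IBD relatedness, classical MDS and genetic-background outliers.

Relatedness is estimated on an LD-pruned autosomal panel: an IBS allele-sharing
distance feeds a classical (Torgerson) multidimensional scaling used to spot
animals of divergent genetic background, and a method-of-moments IBD estimator
returns the usual (Z0, Z1, Z2, PI_HAT) per pair.  The study this tooling
serves removed background outliers by eye from the MDS plot; here the rule is
made deterministic (robust distance from the centroid of the first two MDS
dimensions) with a configuration override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from susgwas.genotype_io import MISSING, GenotypeData


@dataclass
class IbdEstimate:
    """Method-of-moments IBD state proportions for one sample pair."""

    iid1: str
    iid2: str
    z0: float
    z1: float
    z2: float

    @property
    def pi_hat(self) -> float:
        return self.z1 / 2.0 + self.z2


@dataclass
class MdsProjection:
    """Classical-MDS coordinates (samples x k) with their eigenvalues."""

    sample_ids: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"C{i+1}" for i in range(self.coords.shape[1])]
        )
        df.insert(0, "iid", self.sample_ids)
        return df


# ---------------------------------------------------------------------------

def _ibs_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair counts of IBS 0/1/2 and of jointly non-missing markers.

    Returns (n_ibs0, n_ibs1, n_ibs2, n_obs), each an n x n symmetric matrix.
    IBS at a marker is 2 - |g_i - g_j| for allele counts g.
    """
    n, _ = calls.shape
    obs = (calls != MISSING).astype(np.float64)
    n_obs = obs @ obs.T
    # indicators per genotype class
    ind = [((calls == k) & (calls != MISSING)).astype(np.float64) for k in (0, 1, 2)]
    # |gi-gj| == 2 exactly for opposite homozygotes
    n_ibs0 = (ind[0] @ ind[2].T) + (ind[2] @ ind[0].T)
    # |gi-gj| == 1: het vs either homozygote
    n_ibs1 = (ind[1] @ (ind[0] + ind[2]).T) + ((ind[0] + ind[2]) @ ind[1].T)
    n_ibs2 = n_obs - n_ibs0 - n_ibs1
    return n_ibs0, n_ibs1, n_ibs2, n_obs


def ibs_distance_matrix(data: GenotypeData) -> pd.DataFrame:
    """Symmetric IBS allele-sharing distance: 1 - mean(IBS)/2 per pair.

    Computed over pairwise-complete markers.  Raises if any pair has no
    jointly observed marker.
    """
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples")
    n_ibs0, n_ibs1, n_ibs2, n_obs = _ibs_counts(data.calls)
    ids = data.sample_ids
    iu = np.triu_indices(data.n_samples, k=1)
    zero = np.flatnonzero(n_obs[iu] == 0)
    if len(zero):
        k = zero[0]
        raise ValueError(
            f"samples {ids[iu[0][k]]} and {ids[iu[1][k]]} share no observed markers"
        )
    mean_ibs = (n_ibs1 + 2.0 * n_ibs2) / n_obs
    dist = 1.0 - mean_ibs / 2.0
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=ids, columns=ids)


# ---------------------------------------------------------------------------

def ibd_pi_hat(
    data: GenotypeData, allele_freqs: np.ndarray | None = None
) -> pd.DataFrame:
    """Method-of-moments IBD estimates (Z0, Z1, Z2, PI_HAT) for every pair.

    Expected IBS-state counts under each IBD state are accumulated from
    per-marker minor-allele frequencies (estimated on the panel when not
    supplied); the moment equations are solved in order Z0, Z1, Z2, then
    each Z is clipped to [0, 1] and the triple renormalised.  Monomorphic
    markers carry no IBD information and are excluded.

    Returns a DataFrame (iid1, iid2, z0, z1, z2, pi_hat), one row per
    unordered pair in sample order.
    """
    freqs = data.minor_allele_freqs() if allele_freqs is None else np.asarray(allele_freqs, float)
    poly = ~np.isnan(freqs) & (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers available for IBD estimation")
    sub = data.subset(marker_idx=np.flatnonzero(poly))
    p = freqs[poly]
    q = 1.0 - p

    # per-marker IBS-state probabilities under IBD 0 / 1 / 2
    e0_ibd0 = 2.0 * p**2 * q**2
    e1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e2_ibd1 = 1.0 - e1_ibd1

    calls = sub.calls
    obs = calls != MISSING
    n_ibs0, n_ibs1, n_ibs2, n_obs = _ibs_counts(calls)

    # expected counts restricted to each pair's jointly observed markers
    obs_f = obs.astype(np.float64)
    E0_0 = obs_f @ (e0_ibd0[:, None] * obs_f.T)
    E1_0 = obs_f @ (e1_ibd0[:, None] * obs_f.T)
    E2_0 = obs_f @ (e2_ibd0[:, None] * obs_f.T)
    E1_1 = obs_f @ (e1_ibd1[:, None] * obs_f.T)
    E2_1 = obs_f @ (e2_ibd1[:, None] * obs_f.T)

    ids = sub.sample_ids
    rows = []
    n = sub.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            m = n_obs[i, j]
            if m == 0:
                raise ValueError(f"samples {ids[i]} and {ids[j]} share no observed markers")
            z0 = n_ibs0[i, j] / E0_0[i, j] if E0_0[i, j] > 0 else 0.0
            z1 = (n_ibs1[i, j] - z0 * E1_0[i, j]) / E1_1[i, j] if E1_1[i, j] > 0 else 0.0
            z2 = (n_ibs2[i, j] - z0 * E2_0[i, j] - z1 * E2_1[i, j]) / m
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            s = z.sum()
            if s > 0:
                z = z / s
            pi = z[1] / 2.0 + z[2]
            rows.append((ids[i], ids[j], z[0], z[1], z[2], pi))
    return pd.DataFrame(rows, columns=["iid1", "iid2", "z0", "z1", "z2", "pi_hat"])


# ---------------------------------------------------------------------------

def classical_mds(dist, k: int = 2) -> MdsProjection:
    """Classical (Torgerson) scaling of a symmetric zero-diagonal distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top-k coordinates scaled by sqrt(eigenvalue).  If fewer than k positive
    eigenvalues exist, k is reduced (with a warning via the returned
    eigenvalue vector length).  Sign convention: within each dimension the
    largest-magnitude loading is made positive.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(1e-12, 1e-12 * abs(w[0])) if n else w > 0
    k_eff = min(k, int(pos.sum()))
    if k_eff == 0:
        coords = np.zeros((n, k))
        return MdsProjection(ids, coords, np.zeros(k))
    coords = v[:, :k_eff] * np.sqrt(w[:k_eff])
    for c in range(k_eff):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    if k_eff < k:
        coords = np.hstack([coords, np.zeros((n, k - k_eff))])
    return MdsProjection(ids, coords, w[:k_eff])


def flag_background_outliers(
    projection: MdsProjection,
    sd_multiplier: float = 4.0,
    override: list[str] | None = None,
) -> list[str]:
    """Samples divergent from the herd on MDS dimensions 1-2.

    Each of the first two dimensions is reduced to a robust z-score,
    |x - median| / (1.4826 * MAD); a sample is flagged when it exceeds
    ``sd_multiplier`` on either axis.  Per-axis scoring keeps the rule
    sensitive to a divergent group on one axis even when the herd's own
    family structure spreads the other axis.  The default threshold of 4
    essentially never fires under a single normal cluster while
    breed-level divergence scores well above 6.  Passing ``override``
    short-circuits the rule and returns that list verbatim.
    """
    if override is not None:
        return list(override)
    coords = projection.coords
    if coords.shape[1] < 2:
        raise ValueError("projection must have at least 2 dimensions")
    flagged = np.zeros(coords.shape[0], dtype=bool)
    for dim in (0, 1):
        x = coords[:, dim]
        med = np.median(x)
        spread = 1.4826 * np.median(np.abs(x - med))
        if spread <= 0:
            continue
        flagged |= np.abs(x - med) > sd_multiplier * spread
    return [projection.sample_ids[i] for i in np.flatnonzero(flagged)]
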