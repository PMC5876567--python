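import numpy as np
import pytest

from susgwas.genotype_io import MISSING
from susgwas.relatedness import (
    classical_mds,
    flag_background_outliers,
    ibd_pi_hat,
    ibs_distance_matrix,
)

from _oracles import ibs_distance_loops
from conftest import make_dataset


class TestIbsDistance:
    def test_identical_samples_distance_zero(self, rng):
        row = rng.integers(0, 3, 50).astype(np.int8)
        data = make_dataset(np.vstack([row, row]))
        assert ibs_distance_matrix(data).iloc[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        data = make_dataset([[0] * 20, [2] * 20])
        assert ibs_distance_matrix(data).iloc[0, 1] == 1.0

    def test_matches_naive_double_loop(self, rng):
        calls = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        data = make_dataset(calls)
        got = ibs_distance_matrix(data).to_numpy()
        want = ibs_distance_loops(calls)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_no_overlap_pair_is_an_error(self):
        calls = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="S1.*S2"):
            ibs_distance_matrix(make_dataset(calls))


class TestIbdPiHat:
    def test_duplicate_sample_pi_hat_one(self, rng):
        maf = rng.uniform(0.2, 0.5, 500)
        base = (
            (rng.random((4, 500)) < maf).astype(np.int8)
            + (rng.random((4, 500)) < maf).astype(np.int8)
        )
        calls = np.vstack([base, base[:1]])      # S5 duplicates S1
        res = ibd_pi_hat(make_dataset(calls))
        row = res[(res.iid1 == "S1") & (res.iid2 == "S5")].iloc[0]
        assert row.pi_hat == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_founders_mean_near_zero(self, rng):
        maf = rng.uniform(0.05, 0.5, 5000)
        calls = (
            (rng.random((40, 5000)) < maf).astype(np.int8)
            + (rng.random((40, 5000)) < maf).astype(np.int8)
        )
        res = ibd_pi_hat(make_dataset(calls))
        assert abs(res["pi_hat"].mean()) < 0.02

    def test_parent_offspring_near_half(self, rng):
        m = 5000
        maf = rng.uniform(0.2, 0.5, m)
        # two parents, child takes one allele from each parent per marker
        p1 = np.column_stack([(rng.random(m) < maf), (rng.random(m) < maf)]).astype(np.int8)
        p2 = np.column_stack([(rng.random(m) < maf), (rng.random(m) < maf)]).astype(np.int8)
        child = p1[np.arange(m), rng.integers(0, 2, m)] + p2[np.arange(m), rng.integers(0, 2, m)]
        others = (
            (rng.random((10, m)) < maf).astype(np.int8)
            + (rng.random((10, m)) < maf).astype(np.int8)
        )
        calls = np.vstack([p1.sum(axis=1), child, others])
        res = ibd_pi_hat(make_dataset(calls))
        row = res[(res.iid1 == "S1") & (res.iid2 == "S2")].iloc[0]
        assert row.pi_hat == pytest.approx(0.5, abs=0.05)

    def test_symmetric_in_sample_order(self, rng):
        calls = rng.integers(0, 3, size=(6, 800)).astype(np.int8)
        data = make_dataset(calls)
        res = ibd_pi_hat(data)
        flipped = ibd_pi_hat(data.subset(sample_idx=list(range(6))[::-1]))
        merged = res.merge(
            flipped.rename(columns={"iid1": "iid2", "iid2": "iid1"}),
            on=["iid1", "iid2"],
            suffixes=("", "_r"),
        )
        np.testing.assert_allclose(merged["pi_hat"], merged["pi_hat_r"], atol=1e-9)


class TestClassicalMds:
    def test_identical_samples_all_zero(self):
        d = np.zeros((4, 4))
        proj = classical_mds(d, k=2)
        np.testing.assert_allclose(proj.coords, 0.0, atol=1e-9)

    def test_3_4_5_triangle_reproduced(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        proj = classical_mds(d, k=2)
        emb = proj.coords
        for i in range(3):
            for j in range(3):
                got = np.linalg.norm(emb[i] - emb[j])
                assert got == pytest.approx(d[i, j], abs=1e-9)

    def test_two_populations_separate_on_dim1(self, rng):
        from sklearn.metrics import silhouette_score

        maf_a = rng.uniform(0.05, 0.5, 800)
        shift = rng.uniform(-0.3, 0.3, 800)
        maf_b = np.clip(maf_a + shift, 0.02, 0.98)
        pop_a = ((rng.random((15, 800)) < maf_a) + (rng.random((15, 800)) < maf_a)).astype(np.int8)
        pop_b = ((rng.random((15, 800)) < maf_b) + (rng.random((15, 800)) < maf_b)).astype(np.int8)
        data = make_dataset(np.vstack([pop_a, pop_b]))
        proj = classical_mds(ibs_distance_matrix(data), k=2)
        labels = [0] * 15 + [1] * 15
        assert silhouette_score(proj.coords[:, :1], labels) > 0.5


class TestOutlierFlags:
    def test_homogeneous_cluster_no_flags(self, rng):
        from susgwas.relatedness import MdsProjection

        coords = rng.normal(size=(40, 2))
        proj = MdsProjection([f"S{i}" for i in range(40)], coords, np.ones(2))
        assert flag_background_outliers(proj) == []

    def test_divergent_sample_flagged(self, rng):
        from susgwas.relatedness import MdsProjection

        coords = rng.normal(scale=0.1, size=(30, 2))
        coords[7] = [5.0, 5.0]
        proj = MdsProjection([f"S{i}" for i in range(30)], coords, np.ones(2))
        assert flag_background_outliers(proj) == ["S7"]

    def test_override_short_circuits(self, rng):
        from susgwas.relatedness import MdsProjection

        proj = MdsProjection(["a", "b"], rng.normal(size=(2, 2)), np.ones(2))
        assert flag_background_outliers(proj, override=["b"]) == ["b"]


def test_mds_flags_divergent_background_group():
    """A breed-divergent group mixed into a herd is flagged on MDS dims 1-2."""
    from susgwas.synthetic_data import SimConfig, simulate_population

    cfg = SimConfig(
        n_autosomes=2, markers_per_autosome=400, x_markers=0, n_founders=28,
        generation_sizes=(32,), risk=None, missing_rate=0.0, seed=5,
    )
    herd, _ = simulate_population(cfg)
    rng = np.random.default_rng(105)
    maf = np.clip(herd.minor_allele_freqs(), 0.02, 0.98)
    # breed-level divergence: systematic +-0.35 frequency shifts
    maf_out = np.clip(maf + rng.choice([-0.35, 0.35], herd.n_markers), 0.02, 0.98)
    out_calls = (
        (rng.random((8, herd.n_markers)) < maf_out)
        + (rng.random((8, herd.n_markers)) < maf_out)
    ).astype(np.int8)
    data = make_dataset(np.vstack([herd.calls, out_calls]))
    proj = classical_mds(ibs_distance_matrix(data), k=2)
    flagged = set(flag_background_outliers(proj))
    outsider_ids = {f"S{i+1}" for i in range(32, 40)}
    assert flagged >= outsider_ids


def test_removing_unrelated_animals_raises_mean_pi_hat():
    """Mean PI_HAT of the retained pairs rises once animals unrelated to the
    herd are excluded (the cross pairs dilute the herd average)."""
    from susgwas.synthetic_data import SimConfig, simulate_population

    cfg = SimConfig(
        n_autosomes=2, markers_per_autosome=400, x_markers=0, n_founders=10,
        generation_sizes=(20, 24), risk=None, missing_rate=0.0, seed=3,
    )
    herd, _ = simulate_population(cfg)
    rng = np.random.default_rng(203)
    outs = []
    for _ in range(8):          # each outsider from its own background
        mo = rng.uniform(0.05, 0.5, herd.n_markers)
        outs.append(
            (rng.random(herd.n_markers) < mo).astype(np.int8)
            + (rng.random(herd.n_markers) < mo).astype(np.int8)
        )
    data = make_dataset(np.vstack([herd.calls, np.array(outs, dtype=np.int8)]))
    outsiders = {f"S{i+1}" for i in range(24, 32)}
    ibd = ibd_pi_hat(data)
    all_mean = ibd["pi_hat"].mean()
    kept = ibd[~(ibd.iid1.isin(outsiders) | ibd.iid2.isin(outsiders))]
    assert kept["pi_hat"].mean() > all_mean
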