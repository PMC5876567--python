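import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from susgwas.assoc_gwas import (
    allelic_test,
    chi2_2x2,
    em_haplotype_freqs,
    genomic_inflation,
    gwas_scan,
    haplotype_assoc,
    logistic_effect,
    qq_points,
)
from susgwas.genotype_io import MISSING, PHENO_CASE, PHENO_CONTROL

from _oracles import chi2_2x2_closed_form
from conftest import make_dataset


def calls_from_counts(n_minor, n_major_allele_pairs):
    """Genotype vector with the given minor/major *allele* counts (n even)."""
    # build as many hets/homs as needed; only allele totals matter
    calls = []
    minor = n_minor
    total = (n_minor + n_major_allele_pairs) // 2
    for _ in range(total):
        if minor >= 2:
            calls.append(2)
            minor -= 2
        elif minor == 1:
            calls.append(1)
            minor -= 1
        else:
            calls.append(0)
    return np.array(calls, dtype=np.int8)


class TestAllelicTest:
    def test_textbook_table_chi2_20_or_9(self):
        # case alleles 30 minor / 10 major; control 10 / 30
        cases = calls_from_counts(30, 10)
        controls = calls_from_counts(10, 30)
        r = allelic_test(cases, controls, "m")
        assert r.chi2 == pytest.approx(20.0)
        assert r.odds_ratio == pytest.approx(9.0)
        assert r.p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_equal_frequencies_null(self):
        cases = np.array([0, 1, 2, 1], dtype=np.int8)
        r = allelic_test(cases, cases.copy(), "m")
        assert r.chi2 == 0.0
        assert r.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_or_uses_haldane_correction(self):
        cases = np.array([0, 0, 0, 0], dtype=np.int8)
        controls = np.array([1, 1, 0, 0], dtype=np.int8)
        r = allelic_test(cases, controls, "m")
        assert 0 < r.odds_ratio < 1          # protective direction, finite

    def test_all_missing_group_is_error(self):
        with pytest.raises(ValueError, match="control"):
            allelic_test(np.array([1, 2]), np.array([MISSING, MISSING]), "mk")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_chi2_matches_closed_form_and_scipy(self, cells):
        a, b, c, d = cells
        got = chi2_2x2(a, b, c, d)
        assert got == pytest.approx(chi2_2x2_closed_form(a, b, c, d), rel=1e-12)
        if min(a + b, c + d, a + c, b + d) > 0:
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)[0]
            assert got == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_null_panel_type_i_error(self, null_panel):
        scan = gwas_scan(null_panel).dropna(subset=["p"])
        rate = (scan["p"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.015)


class TestGenomicInflation:
    def test_null_median_gives_lambda_one(self):
        res = genomic_inflation(np.full(100, 0.4549))
        assert res.lambda_gc == pytest.approx(1.0, abs=1e-3)

    def test_scale_equivariance(self, rng):
        x = stats.chi2.rvs(1, size=500, random_state=1)
        l1 = genomic_inflation(x).lambda_gc
        l2 = genomic_inflation(2 * x).lambda_gc
        assert l2 == pytest.approx(2 * l1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))

    def test_null_panel_lambda_near_one(self, null_panel):
        scan = gwas_scan(null_panel).dropna(subset=["chi2"])
        lam = genomic_inflation(scan["chi2"].to_numpy()).lambda_gc
        assert lam == pytest.approx(1.0, abs=0.1)


class TestQqPoints:
    def test_single_p_expected_value(self):
        df = qq_points(np.array([0.2]))
        assert df["expected"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_observed_sorted_and_zero_clamped(self):
        df = qq_points(np.array([0.5, 0.0, 0.01]))
        # p sorted ascending -> -log10(p) non-increasing, all finite
        assert (np.diff(df["observed"]) <= 1e-12).all()
        assert np.isfinite(df["observed"]).all()

    def test_null_scan_hugs_diagonal(self, null_panel):
        scan = gwas_scan(null_panel).dropna(subset=["p"])
        df = qq_points(scan["p"].to_numpy())
        body = df[df["expected"] < 2]        # away from the extreme tail
        assert (body["observed"] - body["expected"]).abs().max() < 0.35


class TestEmHaplotypes:
    def test_doubly_homozygous_equals_direct_counting(self):
        # 6 individuals: 3 of AB/AB (calls 2,2), 3 of ab/ab (0,0)
        calls = np.array([[2, 2]] * 3 + [[0, 0]] * 3)
        freqs, converged, _ = em_haplotype_freqs(calls)
        assert converged
        assert freqs[(1, 1)] == pytest.approx(0.5, abs=1e-9)
        assert freqs[(0, 0)] == pytest.approx(0.5, abs=1e-9)

    def test_matches_grid_search_likelihood_oracle(self):
        # AB/AB, ab/ab homozygotes plus double heterozygotes
        calls = np.array([[2, 2]] * 4 + [[0, 0]] * 2 + [[1, 1]] * 4)
        freqs, _, _ = em_haplotype_freqs(calls)

        def loglik(f_ab, f_AB):
            # remaining mass split evenly over Ab and aB
            rest = max(0.0, 1 - f_ab - f_AB) / 2
            f = {(1, 1): f_AB, (0, 0): f_ab, (1, 0): rest, (0, 1): rest}
            ll = 0.0
            for row in calls:
                tot = 0.0
                for h1 in f:
                    h2 = (row[0] - h1[0], row[1] - h1[1])
                    if h2 in f:
                        tot += f[h1] * f[h2]
                ll += np.log(max(tot, 1e-300))
            return ll

        grid = np.arange(0.0, 1.001, 0.001)
        best = max(
            ((a, b) for a in grid for b in grid if a + b <= 1.0),
            key=lambda ab: loglik(*ab),
        )
        assert freqs[(0, 0)] == pytest.approx(best[0], abs=2e-3)
        assert freqs[(1, 1)] == pytest.approx(best[1], abs=2e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_frequencies_sum_to_one_and_loglik_monotone(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(rng.integers(2, 25), rng.integers(2, 4)))
        freqs, _, trace = em_haplotype_freqs(calls)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()


class TestHaplotypeAssoc:
    def _dataset(self, case_rows, control_rows):
        calls = np.array(case_rows + control_rows, dtype=np.int8)
        pheno = [PHENO_CASE] * len(case_rows) + [PHENO_CONTROL] * len(control_rows)
        return make_dataset(calls, phenotype=pheno)

    def test_equal_frequencies_null_chi2(self):
        rows = [[2, 2]] * 3 + [[0, 0]] * 3
        data = self._dataset(rows, list(rows))
        res = haplotype_assoc(data, ["M1", "M2"])
        for r in res.results:
            if r.tested:
                assert r.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.omnibus_chi2 == pytest.approx(0.0, abs=1e-9)

    def test_protective_haplotype_or_below_one(self):
        # haplotype absent in cases, ~33% of control chromosomes
        cases = [[2, 2]] * 6
        controls = [[0, 0]] * 2 + [[2, 2]] * 4
        data = self._dataset(cases, controls)
        res = haplotype_assoc(data, ["M1", "M2"])
        protective = [r for r in res.results if r.haplotype == "GG"][0]
        assert protective.freq_cases == pytest.approx(0.0, abs=1e-6)
        assert protective.freq_controls == pytest.approx(1 / 3, abs=1e-6)
        assert protective.odds_ratio < 1

    def test_hand_built_counts_match_closed_form(self):
        # carriers 29/6 in cases vs 7/11 in controls as a plain 2x2
        want = chi2_2x2_closed_form(29, 6, 7, 11)
        assert chi2_2x2(29, 6, 7, 11) == pytest.approx(want, rel=1e-12)


class TestLogisticEffect:
    def test_independent_marker_beta_near_zero(self, rng):
        x = rng.integers(0, 3, 400)
        y = rng.integers(0, 2, 400)
        eff = logistic_effect(x, y)
        assert abs(eff.beta) < 0.5
        assert not eff.separation

    def test_binary_carrier_beta_equals_log_or(self):
        # 30/10 carrier split in cases, 10/30 in controls -> beta = ln 9
        x = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        y = np.array([1] * 40 + [0] * 40)
        eff = logistic_effect(x, y)
        assert eff.beta == pytest.approx(np.log(9.0), rel=1e-6)
        assert eff.p is not None

    def test_complete_separation_flagged(self):
        x = np.array([2] * 20 + [0] * 20)
        y = np.array([1] * 20 + [0] * 20)
        eff = logistic_effect(x, y)
        assert eff.separation
        assert eff.p is None

    def test_matches_statsmodels_newton(self, rng):
        import statsmodels.api as sm

        x = rng.integers(0, 3, 200).astype(float)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 * x - 0.2)))).astype(float)
        eff = logistic_effect(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(method="newton", disp=0)
        assert eff.beta == pytest.approx(ref.params[1], rel=1e-6)
        assert eff.se == pytest.approx(ref.bse[1], rel=1e-4)
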