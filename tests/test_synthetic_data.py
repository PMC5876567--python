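import numpy as np
import pandas as pd
import pytest

from susgwas.genotype_io import MISSING, PHENO_CASE, PHENO_CONTROL, read_ped_map
from susgwas.synthetic_data import (
    RiskHaplotype,
    SimConfig,
    _pedigree_f,
    _source_at,
    assign_phenotypes,
    cousin_mating_population,
    simulate_case_control_study,
    simulate_population,
    write_fixture,
)

from conftest import make_dataset

SMALL = SimConfig(
    n_autosomes=3,
    markers_per_autosome=120,
    x_markers=0,
    n_founders=8,
    generation_sizes=(16, 24),
    risk=None,
    missing_rate=0.0,
)


class TestSimulatePopulation:
    def test_deterministic_under_seed(self):
        d1, _ = simulate_population(SMALL, seed=9)
        d2, _ = simulate_population(SMALL, seed=9)
        np.testing.assert_array_equal(d1.calls, d2.calls)
        pd.testing.assert_frame_equal(d1.markers, d2.markers)

    def test_zero_recombination_transmits_intact_haplotypes(self):
        cfg = SimConfig(
            n_autosomes=2, markers_per_autosome=50, x_markers=0,
            n_founders=6, generation_sizes=(8,), risk=None, cm_per_mb=0.0,
            missing_rate=0.0,
        )
        _, truth = simulate_population(cfg, seed=3)
        offspring = truth.individuals[truth.individuals.generation == 1]["iid"]
        for iid in offspring:
            for chrom, (h0, h1) in truth.haplotypes[iid].items():
                assert len(h0) == 1 and len(h1) == 1

    def test_founder_allele_frequencies_recovered(self):
        cfg = SimConfig(
            n_autosomes=1, markers_per_autosome=100, x_markers=0,
            n_founders=10_000, generation_sizes=(), risk=None, missing_rate=0.0,
            founder_maf_range=(0.1, 0.4),
        )
        data, truth = simulate_population(cfg, seed=17)
        freqs = data.calls.mean(axis=0) / 2.0
        target = truth.target_maf["1"]
        # 20,000 founder haplotypes: per-marker sampling sd ~ 0.0035
        assert np.abs(freqs - target).max() < 0.02
        assert np.abs(freqs - target).mean() < 0.005

    def test_mendelian_consistency_of_transmission(self):
        _, truth = simulate_population(SMALL, seed=21)
        info = truth.individuals.set_index("iid")
        for iid in info.index:
            father = info.loc[iid, "father"]
            if father == "0":
                continue
            for chrom, (h0, _) in truth.haplotypes[iid].items():
                fh0, fh1 = truth.haplotypes[father][chrom]
                for end, src in h0:
                    mid = end - 0.5
                    assert src in (_source_at(fh0, mid), _source_at(fh1, mid))

    def test_risk_span_outside_map_rejected(self):
        cfg = SimConfig(
            n_autosomes=2, markers_per_autosome=50, x_markers=0,
            risk=RiskHaplotype(chrom="9"),
        )
        with pytest.raises(ValueError, match="chromosome"):
            simulate_population(cfg, seed=0)

    def test_pedigree_f_tabular_method_on_cousin_loop(self):
        rows = [
            ("A", "0", "0", 0), ("B", "0", "0", 0), ("X", "0", "0", 0),
            ("Y", "0", "0", 0),
            ("S1", "A", "B", 1), ("S2", "A", "B", 1),
            ("C1", "S1", "X", 2), ("C2", "S2", "Y", 2),
            ("O", "C1", "C2", 3),
        ]
        df = pd.DataFrame(rows, columns=["iid", "father", "mother", "generation"])
        f = _pedigree_f(df)
        assert f[-1] == pytest.approx(1 / 16)
        assert (f[:-1] == 0).all()

    def test_realized_autozygosity_tracks_pedigree_f(self):
        means = []
        for seed in (1, 2, 3):
            _, truth = cousin_mating_population(n_offspring=6, n_chromosomes=10, seed=seed)
            off = truth.individuals[truth.individuals.generation == 3]
            means.extend(off["autozygosity"])
        assert np.mean(means) == pytest.approx(1 / 16, abs=0.02)


class TestAssignPhenotypes:
    def _tiny_population(self, n, carrier_frac, seed=0):
        rng = np.random.default_rng(seed)
        carrier = rng.random(n) < carrier_frac
        data = make_dataset(np.zeros((n, 2), dtype=np.int8))
        truth_df = pd.DataFrame(
            {
                "iid": data.sample_ids,
                "father": "0",
                "mother": "0",
                "generation": 1,
                "pedigree_f": 0.0,
                "autozygosity": 0.0,
                "carrier": carrier,
                "n_implant_copies": carrier.astype(int),
            }
        )
        from susgwas.synthetic_data import SimTruth

        return data, SimTruth(individuals=truth_df)

    def test_full_penetrance_yields_only_carrier_cases(self):
        data, truth = self._tiny_population(200, 0.5)
        risk = RiskHaplotype(penetrance_carrier=1.0, penetrance_noncarrier=0.0)
        study = assign_phenotypes(data, truth, risk, 40, 40, seed=1)
        info = truth.individuals.set_index("iid")
        cases = [s for s, p in zip(study.sample_ids, study.phenotypes()) if p == PHENO_CASE]
        assert all(info.loc[c, "carrier"] for c in cases)

    def test_equal_penetrances_are_null(self):
        data, truth = self._tiny_population(400, 0.5)
        risk = RiskHaplotype(penetrance_carrier=0.5, penetrance_noncarrier=0.5)
        info = truth.individuals.set_index("iid")
        diffs = []
        for seed in range(40):
            study = assign_phenotypes(data, truth, risk, 60, 60, seed=seed)
            car = info.loc[study.sample_ids, "carrier"].to_numpy()
            diffs.append(car[study.case_mask()].mean() - car[study.control_mask()].mean())
        assert abs(np.mean(diffs)) < 0.05

    def test_bayes_rule_case_carrier_fraction(self):
        # f1=0.9, f0=0.3 at 50% carriers -> P(carrier | case) = 0.75
        data, truth = self._tiny_population(4000, 0.5, seed=3)
        risk = RiskHaplotype(penetrance_carrier=0.9, penetrance_noncarrier=0.3)
        info = truth.individuals.set_index("iid")
        fracs = []
        for seed in range(25):
            study = assign_phenotypes(data, truth, risk, 300, 100, seed=seed)
            car = info.loc[study.sample_ids, "carrier"].to_numpy()
            fracs.append(car[study.case_mask()].mean())
        assert np.mean(fracs) == pytest.approx(0.75, abs=0.02)

    def test_infeasible_counts_error_reports_maxima(self):
        data, truth = self._tiny_population(20, 0.5)
        risk = RiskHaplotype(penetrance_carrier=0.0, penetrance_noncarrier=0.0)
        with pytest.raises(ValueError, match="0 affected"):
            assign_phenotypes(data, truth, risk, 5, 5, seed=0)


class TestWriteFixture:
    def test_round_trip_and_bookkeeping(self, tmp_path, study):
        data, truth = study
        assert data.n_samples == 53
        assert int(data.case_mask().sum()) == 35
        assert int(data.control_mask().sum()) == 18
        paths = write_fixture(data, truth, tmp_path)
        back = read_ped_map(paths["ped"], paths["map"])
        ref = data.set_minor_allele_first()
        freqs = ref.minor_allele_freqs()
        poly = (freqs > 0) & (freqs < 1)   # monomorphic a1/a2 not recoverable
        np.testing.assert_array_equal(back.calls[:, poly], ref.calls[:, poly])
        truth_df = pd.read_csv(paths["truth"], sep="\t")
        assert set(data.sample_ids) <= set(truth_df["iid"])

    def test_truth_carriers_match_haplotype_recount(self, study):
        data, truth = study
        risk = SimConfig().risk
        markers = data.markers[data.markers["chrom"] == risk.chrom]
        bp = markers["bp"].to_numpy()
        cols = np.flatnonzero((data.markers["chrom"] == risk.chrom).to_numpy())
        from susgwas.synthetic_data import _paint

        for iid in data.sample_ids[:10]:
            h0, h1 = truth.haplotypes[iid][risk.chrom]
            a0 = _paint(h0, truth.founder_alleles[risk.chrom], bp)
            a1 = _paint(h1, truth.founder_alleles[risk.chrom], bp)
            # the genotype equals the two painted haplotypes (pre-missingness)
            g = data.calls[data.sample_ids.index(iid), cols]
            obs = g != MISSING
            np.testing.assert_array_equal(g[obs], (a0 + a1)[obs])
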