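import numpy as np
import pandas as pd
import pytest

import lrvalidate as lv
from lrvalidate.simulate import (
    PedigreeParams,
    SimulationConfig,
    SimulationReport,
    chol_A,
    sample_phenotypes,
)

from conftest import make_scenario


class TestGeneratePedigree:
    def test_counts_and_generations(self):
        ped = lv.generate_pedigree(PedigreeParams(founders=10, generations=2,
                                                  matings=5,
                                                  offspring_per_mating=2), 0)
        assert len(ped) == 20
        assert ped.generation.max() == 1
        assert np.sum(ped.generation == 1) == 10

    def test_seed_determinism(self):
        p = PedigreeParams(founders=12, generations=3, matings=6,
                           offspring_per_mating=2)
        a = lv.generate_pedigree(p, 5)
        b = lv.generate_pedigree(p, 5)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.sire, b.sire)
        np.testing.assert_array_equal(a.dam, b.dam)
        c = lv.generate_pedigree(p, 6)
        assert not (np.array_equal(a.sire, c.sire) and np.array_equal(a.dam, c.dam))

    def test_parents_come_from_previous_generation(self):
        ped = lv.generate_pedigree(PedigreeParams(founders=10, generations=4,
                                                  matings=6,
                                                  offspring_per_mating=2), 9)
        for i in range(len(ped)):
            g = ped.generation[i]
            if g == 0:
                assert ped.sire[i] < 0 and ped.dam[i] < 0
            else:
                assert ped.generation[ped.sire[i]] == g - 1
                assert ped.generation[ped.dam[i]] == g - 1
                assert ped.sire[i] != ped.dam[i]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PedigreeParams(founders=2)
        with pytest.raises(ValueError):
            PedigreeParams(generations=1)


class TestAssignPhenotypes:
    def test_counts_and_determinism(self):
        ped = lv.generate_pedigree(PedigreeParams(founders=40, generations=3,
                                                  matings=20,
                                                  offspring_per_mating=2), 1)
        d1 = lv.assign_phenotypes(ped, 0.5, 3)
        assert len(d1) == round(0.5 * len(ped))
        d2 = lv.assign_phenotypes(ped, 0.5, 3)
        pd.testing.assert_frame_equal(d1.frame, d2.frame)
        full = lv.assign_phenotypes(ped, 1.0, 3)
        assert len(full) == len(ped)
        # every generation keeps at least one record
        assert set(d1.frame["generation"]) == set(np.unique(ped.generation))

    def test_invalid_prop(self):
        ped = lv.generate_pedigree(PedigreeParams(founders=10, generations=2,
                                                  matings=5,
                                                  offspring_per_mating=2), 1)
        with pytest.raises(ValueError):
            lv.assign_phenotypes(ped, 0.0, 1)


class TestSamplePhenotypes:
    def test_moments_match_model(self):
        ped, A, L, data, Z, struct = make_scenario(founders=12, generations=3,
                                                   matings=6, offspring=2,
                                                   prop=0.6, h2=0.4)
        model = struct.model
        rng = np.random.default_rng(8)
        draws = 10_000
        m = len(data)
        Y = np.empty((draws, m))
        Xb = np.linspace(-1, 1, m)   # arbitrary fixed-effect mean
        for r in range(draws):
            Y[r], _ = sample_phenotypes(L, Z, Xb, model, rng)
        V = Z @ (A.values * model.sigma_g2) @ Z.T + np.eye(m) * model.sigma_e2
        # mean: each column within 4 MC SEs of Xb
        se_mean = np.sqrt(np.diag(V) / draws)
        assert np.all(np.abs(Y.mean(axis=0) - Xb) < 4 * se_mean)
        # covariance: elementwise within 4 MC SEs
        emp = np.cov(Y.T)
        se_cov = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V**2) / draws)
        assert np.all(np.abs(emp - V) < 4 * se_cov)

    def test_zero_genetic_variance_limit(self):
        ped, A, L, data, Z, struct = make_scenario(founders=12, generations=3,
                                                   matings=6, offspring=2)
        tiny = lv.ModelSpec(sigma_g2=1e-12, sigma_e2=1.0)
        rng = np.random.default_rng(0)
        y, u = sample_phenotypes(L, Z, np.zeros(len(data)), tiny, rng)
        assert np.abs(u).max() < 1e-5


class TestHarness:
    def test_smoke_run_bookkeeping(self):
        cfg = SimulationConfig(
            pedigree=PedigreeParams(founders=20, generations=3, matings=10,
                                    offspring_per_mating=2),
            h2_grid=(0.3, 0.6), prop_grid=(0.6,), replicates=3, seed=4,
            bootstrap=True, bootstrap_B=200)
        rep = lv.run_replicates(cfg)
        assert rep.replicates["scenario"].nunique() == 2
        # 2 scenarios x 3 replicates x 5 statistics
        assert len(rep.replicates) == 2 * 3 * 5
        assert rep.n_failed == 0
        assert set(rep.intervals["method"]) == {"analytical", "approximated",
                                                "bootstrap"}
        emp = rep.empirical()
        assert (emp["replicates"] == 3).all()

    def test_bit_reproducibility(self):
        cfg = SimulationConfig(
            pedigree=PedigreeParams(founders=16, generations=3, matings=8,
                                    offspring_per_mating=2),
            h2_grid=(0.4,), prop_grid=(0.6,), replicates=3, seed=11,
            bootstrap=True, bootstrap_B=150)
        a = lv.run_replicates(cfg)
        b = lv.run_replicates(cfg)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        pd.testing.assert_frame_equal(a.intervals, b.intervals)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(h2_grid=(0.0,))
        with pytest.raises(ValueError):
            SimulationConfig(prop_grid=(1.5,))
        with pytest.raises(ValueError):
            SimulationConfig(replicates=1)


def _fake_report(lower, upper, est_var, true_values):
    """Minimal report with one scenario/statistic and controllable intervals."""
    reps = len(true_values)
    replicates = pd.DataFrame({
        "scenario": "s", "replicate": range(reps), "statistic": "bias",
        "value": true_values, "true_value": 0.0,
    })
    intervals = pd.DataFrame({
        "scenario": "s", "replicate": range(reps), "statistic": "bias",
        "method": "analytical", "variance": est_var,
        "lower": lower, "upper": upper,
    })
    scenarios = pd.DataFrame([{"scenario": "s", "h2": 0.3, "prop": 0.5,
                               "n_validation": 10, "sigma_gi2": 1.0}])
    cfg = SimulationConfig(replicates=2)
    return SimulationReport(replicates=replicates, intervals=intervals,
                            scenarios=scenarios, config=cfg)


class TestCoverageAndMsd:
    def test_coverage_extremes(self):
        vals = np.linspace(-1, 1, 20)
        rep = _fake_report(lower=-99.0, upper=99.0, est_var=1.0, true_values=vals)
        assert lv.coverage(rep)["coverage"].iloc[0] == 1.0
        rep = _fake_report(lower=5.0, upper=5.0, est_var=1.0, true_values=vals)
        assert lv.coverage(rep)["coverage"].iloc[0] == 0.0

    def test_msd_zero_when_estimates_equal_truth(self):
        vals = np.array([-1.0, 0.0, 1.0, 2.0])
        true_var = vals.var(ddof=1)
        lo, up = np.quantile(vals, 0.025), np.quantile(vals, 0.975)
        rep = _fake_report(lower=lo, upper=up, est_var=true_var, true_values=vals)
        m = lv.msd_table(rep)
        assert m["msd_var"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert m["msd_lower"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert m["msd_upper"].iloc[0] == pytest.approx(0.0, abs=1e-20)

    def test_msd_constant_offset_is_squared(self):
        vals = np.array([-1.0, 0.0, 1.0, 2.0])
        lo, up = np.quantile(vals, 0.025), np.quantile(vals, 0.975)
        d = 0.3
        rep = _fake_report(lower=lo + d, upper=up, est_var=vals.var(ddof=1),
                           true_values=vals)
        m = lv.msd_table(rep)
        assert m["msd_lower"].iloc[0] == pytest.approx(d**2)
        assert m["msd_upper"].iloc[0] == pytest.approx(0.0, abs=1e-20)


class TestReplicateSelfConsistency:
    """Statistic means across replicates hit their theoretical targets."""

    def test_lr_covariance_property(self, replicated_scenario):
        # the defining LR identity: cov(uhat_w, uhat_p) equals var(uhat_p)
        struct, UW, UP, UT = replicated_scenario
        reps, n = UW.shape
        Pc = UP - UP.mean(1, keepdims=True)
        Wc = UW - UW.mean(1, keepdims=True)
        cwp = np.sum(Wc * Pc, 1) / (n - 1)
        vp = np.sum(Pc * Pc, 1) / (n - 1)
        d = cwp - vp
        assert abs(d.mean()) < 4 * d.std(ddof=1) / np.sqrt(reps)

    def test_ratio_of_accuracies_mean(self, replicated_scenario):
        # mean correlation of the two EBV sets equals the mean ratio of
        # true-EBV accuracies from the same replicates
        struct, UW, UP, UT = replicated_scenario
        reps, n = UW.shape
        Pc = UP - UP.mean(1, keepdims=True)
        Wc = UW - UW.mean(1, keepdims=True)
        Tc = UT - UT.mean(1, keepdims=True)
        rho = np.sum(Wc * Pc, 1) / np.sqrt(
            np.sum(Wc * Wc, 1) * np.sum(Pc * Pc, 1))
        accp = np.sum(Tc * Pc, 1) / np.sqrt(
            np.sum(Tc * Tc, 1) * np.sum(Pc * Pc, 1))
        accw = np.sum(Tc * Wc, 1) / np.sqrt(
            np.sum(Tc * Tc, 1) * np.sum(Wc * Wc, 1))
        d = rho - accp / accw
        assert abs(d.mean()) < 4 * d.std(ddof=1) / np.sqrt(reps)

    def test_reliability_estimator_mean(self, replicated_scenario):
        # the covariance-based reliability estimate tracks the squared
        # correlation between true and partial EBV; the sample r**2 carries
        # the standard (1 - rho**2)/n upward small-sample bias, removed here
        # before comparing
        struct, UW, UP, UT = replicated_scenario
        reps, n = UW.shape
        Pc = UP - UP.mean(1, keepdims=True)
        Wc = UW - UW.mean(1, keepdims=True)
        Tc = UT - UT.mean(1, keepdims=True)
        rel_est = np.sum(Wc * Pc, 1) / (n * struct.sigma_gi2)
        r2 = (np.sum(Tc * Pc, 1) ** 2
              / (np.sum(Tc * Tc, 1) * np.sum(Pc * Pc, 1)))
        r2_adj = r2 - (1 - r2) / (n - 2)
        d = rel_est - r2_adj
        assert abs(d.mean()) < 4 * d.std(ddof=1) / np.sqrt(reps)
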