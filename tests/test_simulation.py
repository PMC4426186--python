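"""Scenario generators, AUC calibration and the Monte-Carlo engine."""

import numpy as np
import pytest

from aucselect import (
    SimulationScenario,
    analyze,
    InferenceConfig,
    compute_tables,
    estimate_auc,
    generate_dataset,
    make_icm_like_fixture,
    run_study,
)
from aucselect.simulation import (
    ORDINAL_THRESHOLDS,
    build_covariance,
    calibrate_ordinal_shift,
    ordinal_auc,
    _child_rng,
)


class TestCovarianceBuilders:
    def test_compound_symmetry_rho_zero_identity(self):
        np.testing.assert_array_equal(build_covariance("compound_symmetry", 0.0, 4), np.eye(4))

    def test_compound_symmetry_psd(self):
        S = build_covariance("compound_symmetry", 0.9, 5)
        assert np.linalg.eigvalsh(S).min() > 0
        assert S[0, 1] == 0.9 and S[0, 0] == 1.0

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError):
            build_covariance("compound_symmetry", 1.0, 3)

    def test_unstructured_reproducible_correlation(self):
        S1 = build_covariance("unstructured", 0.0, 5)
        S2 = build_covariance("unstructured", 0.0, 5)
        np.testing.assert_array_equal(S1, S2)
        np.testing.assert_allclose(np.diag(S1), 1.0)
        assert np.linalg.eigvalsh(S1).min() > 0

    def test_hetero_pairing_swaps_with_group(self):
        pos_large = build_covariance("hetero_diagonal_positive_pairing", 0.0, 4, "larger")
        pos_small = build_covariance("hetero_diagonal_positive_pairing", 0.0, 4, "smaller")
        neg_large = build_covariance("hetero_diagonal_negative_pairing", 0.0, 4, "larger")
        neg_small = build_covariance("hetero_diagonal_negative_pairing", 0.0, 4, "smaller")
        np.testing.assert_array_equal(pos_large, neg_small)
        np.testing.assert_array_equal(pos_small, neg_large)
        assert np.diag(pos_large).max() > 1.0
        np.testing.assert_array_equal(np.diag(pos_small), np.ones(4))


class TestOrdinalCalibration:
    def test_zero_shift_gives_half(self):
        assert ordinal_auc(0.0) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("target", [0.6, 0.75, 0.9])
    def test_calibration_hits_target(self, target):
        delta = calibrate_ordinal_shift(target)
        assert ordinal_auc(delta) == pytest.approx(target, abs=1e-5)

    def test_unreachable_target_raises(self):
        # the top category retains mass, so AUC=0.999 cannot be reached
        with pytest.raises(ValueError):
            calibrate_ordinal_shift(0.999)


class TestGenerateDataset:
    def test_group_sizes_and_ccr(self):
        scen = SimulationScenario(N=100, ccr="1:4", true_auc=0.7, auc0=0.7)
        assert scen.group_sizes() == (80, 20)
        data = generate_dataset(scen, np.random.default_rng(0))
        assert (data.n_controls, data.n_cases) == (80, 20)

    def test_lognormal_same_ranks_as_normal(self):
        base = dict(d=3, N=60, true_auc=0.7, auc0=0.6, seed=0)
        d_norm = generate_dataset(SimulationScenario(family="normal", **base), np.random.default_rng(3))
        d_logn = generate_dataset(SimulationScenario(family="lognormal", **base), np.random.default_rng(3))
        t1, t2 = compute_tables(d_norm), compute_tables(d_logn)
        np.testing.assert_array_equal(t1.pooled_midranks, t2.pooled_midranks)
        np.testing.assert_array_equal(estimate_auc(t1), estimate_auc(t2))

    def test_ordinal_five_categories(self):
        scen = SimulationScenario(family="ordinal5", d=2, N=200, true_auc=0.8, auc0=0.8)
        data = generate_dataset(scen, np.random.default_rng(1))
        assert set(np.unique(data.values)) <= {1.0, 2.0, 3.0, 4.0, 5.0}

    @pytest.mark.parametrize("family", ["normal", "ordinal5"])
    def test_auc_calibration_unbiased(self, family):
        """Mean estimated AUC over many draws stays near the target (for
        ordinal data under the explicitly calibrated discretisation)."""
        target = 0.8
        scen = SimulationScenario(family=family, d=2, N=80, true_auc=target,
                                  auc0=target, ordinal_calibration="discretised")
        rng = np.random.default_rng(17)
        reps = 400
        est = np.empty((reps, 2))
        for r in range(reps):
            est[r] = estimate_auc(compute_tables(generate_dataset(scen, rng)))
        mean = est.mean()
        se = est.mean(axis=1).std(ddof=1) / np.sqrt(reps)
        assert abs(mean - target) < 3 * se + 1e-3

    def test_latent_calibration_attenuates_ordinal_auc(self):
        """Default ordinal mode discretises a latent-AUC-calibrated normal,
        so the effective ordinal AUC lies below the (high) latent target."""
        from scipy.stats import norm as normal

        target = 0.9
        latent_delta = np.sqrt(2) * normal.ppf(target)
        expected = ordinal_auc(latent_delta)
        assert expected < target
        scen = SimulationScenario(family="ordinal5", d=2, N=100, true_auc=target,
                                  auc0=target)
        rng = np.random.default_rng(23)
        est = np.array(
            [estimate_auc(compute_tables(generate_dataset(scen, rng))).mean()
             for _ in range(300)]
        )
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - expected) < 3 * se + 1e-3

    def test_binormal_shift_value(self):
        from scipy.stats import norm as normal

        scen = SimulationScenario(d=1, N=1000, true_auc=0.8, auc0=0.8)
        # shift enters the case group mean: empirical check on group means
        rng = np.random.default_rng(5)
        data = generate_dataset(scen, rng)
        delta = np.sqrt(2) * normal.ppf(0.8)
        diff = data.cases.mean() - data.controls.mean()
        assert diff == pytest.approx(delta, abs=0.15)


class TestRunStudy:
    def test_reproducible(self):
        scen = SimulationScenario(d=2, N=40, true_auc=0.5, auc0=0.5, nsim=40,
                                  nboot=80, seed=3, methods=("wb", "bonferroni"))
        r1 = run_study(scen)
        r2 = run_study(scen)
        for m in scen.methods:
            assert r1[m].rate == r2[m].rate
            np.testing.assert_array_equal(r1[m].per_marker_rates, r2[m].per_marker_rates)

    def test_child_seeding_independent_of_nsim(self):
        a = _child_rng(5, 3).standard_normal(4)
        b = _child_rng(5, 3).standard_normal(4)
        np.testing.assert_array_equal(a, b)

    def test_raw_family_rejections_nested(self):
        """Same statistics, ordered quantiles: unadj >= mcp >= bonferroni FWER."""
        scen = SimulationScenario(d=3, N=60, true_auc=0.6, auc0=0.6, nsim=120,
                                  seed=9, methods=("unadjusted", "mcp", "bonferroni"))
        res = run_study(scen)
        assert res["unadjusted"].rate >= res["mcp"].rate >= res["bonferroni"].rate

    def test_d1_unadjusted_fwer_near_alpha(self):
        scen = SimulationScenario(d=1, N=200, true_auc=0.5, auc0=0.5, nsim=500,
                                  seed=13, methods=("unadjusted",))
        res = run_study(scen)["unadjusted"]
        assert abs(res.rate - 0.025) < 3 * np.sqrt(0.025 * 0.975 / 500) + 0.005

    def test_power_increases_with_effect(self):
        base = dict(d=2, N=80, auc0=0.6, nsim=150, seed=21, methods=("logit",))
        weak = run_study(SimulationScenario(true_auc=0.65, **base))["logit"].rate
        strong = run_study(SimulationScenario(true_auc=0.8, **base))["logit"].rate
        assert strong > weak

    def test_mc_se_formula(self):
        scen = SimulationScenario(d=2, N=40, true_auc=0.7, auc0=0.5, nsim=50,
                                  seed=2, methods=("bonferroni",))
        res = run_study(scen)["bonferroni"]
        assert res.mc_se == pytest.approx(np.sqrt(res.rate * (1 - res.rate) / 50))


class TestICMFixture:
    def test_shape_and_degeneracy(self):
        data = make_icm_like_fixture(seed=2015)
        assert (data.n_controls, data.n_cases, data.n_markers) == (41, 26, 4)
        auc = estimate_auc(compute_tables(data))
        assert auc[3] == 1.0
        assert all(0.5 < a < 1 for a in auc[:3])

    def test_seed_determinism(self):
        a = make_icm_like_fixture(seed=2015)
        b = make_icm_like_fixture(seed=2015)
        np.testing.assert_array_equal(a.values, b.values)

    def test_boundary_fix_enables_logit_analysis(self):
        data = make_icm_like_fixture(seed=2015)
        res = analyze(
            data,
            InferenceConfig(auc0=0.8, method="logit", boundary_policy="boundary_fix"),
        )
        assert res.boundary_fixed == (3,)
        assert res.auc_hat[3] < 1.0
        assert np.isfinite(res.lower_bounds).all()
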