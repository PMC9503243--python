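import numpy as np
import pandas as pd
import pytest

from dbnsurv.simulation import (
    DEFAULT_PROBS,
    ScenarioConfig,
    calibrate_censor_scale,
    covariate_sum_pmf,
    cox_comparator_fit,
    dbn_estimator_for_simulation,
    dbn_marginal_at,
    km_marginal_at,
    run_scenario,
    sample_covariates,
    sample_weibull,
    simulate_dataset,
    survival_scale,
    true_marginal_survival,
    true_percentile,
)

from conftest import frame_from_arrays


class TestGenerators:
    def test_covariate_column_means(self):
        X = sample_covariates(100000, DEFAULT_PROBS, seed=1)
        se = np.sqrt(np.array(DEFAULT_PROBS) * (1 - np.array(DEFAULT_PROBS)) / 100000)
        assert np.all(np.abs(X.mean(axis=0) - DEFAULT_PROBS) < 3 * se)

    def test_degenerate_probs_give_constant_columns(self):
        X = sample_covariates(50, (1.0,) * 5, seed=0)
        assert np.all(X == 1)

    def test_seeded_replay(self):
        assert np.array_equal(
            sample_covariates(100, DEFAULT_PROBS, seed=5),
            sample_covariates(100, DEFAULT_PROBS, seed=5),
        )

    def test_survival_scale_is_covariate_sum(self):
        assert survival_scale([0, 1, 0, 1, 1]) == 3
        assert survival_scale([0] * 5) == 0
        assert survival_scale([1] * 5) == 5

    def test_weibull_inversion_identity(self):
        # u = e^{-1} gives s = theta for any shape
        for alpha in (0.5, 1.0, 2.0):
            assert sample_weibull(3.0, alpha, np.exp(-1)) == pytest.approx(3.0)

    def test_weibull_exponential_mean(self):
        rng = np.random.default_rng(2)
        s = sample_weibull(2.0, 1.0, rng.uniform(1e-12, 1, 10**6))
        assert s.mean() == pytest.approx(2.0, rel=0.01)

    def test_weibull_cdf_goodness_of_fit(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(3)
        s = sample_weibull(2.0, 1.7, rng.uniform(1e-12, 1, 10**5))
        stat = kstest(s, lambda x: 1 - np.exp(-((x / 2.0) ** 1.7))).pvalue
        assert stat > 0.01

    def test_invalid_uniform_rejected(self):
        with pytest.raises(ValueError):
            sample_weibull(1.0, 1.0, 0.0)


class TestCalibration:
    def test_exponential_closed_form(self):
        # degenerate covariates with sum 3; competing exponentials:
        # P(C < S) = theta_S / (theta_S + theta_C) -> theta_C = 9 for R = 1/4
        theta_c = calibrate_censor_scale(1.0, 1.0, (1, 1, 1, 0, 0), 0.25)
        assert theta_c == pytest.approx(9.0, abs=1e-5)

    def test_achieved_censoring_matches_request(self):
        theta_c = calibrate_censor_scale(2.0, 2.0, DEFAULT_PROBS, 0.40)
        _, events, _ = simulate_dataset(100000, 2.0, 2.0, theta_c, seed=4)
        achieved = 1 - events.mean()
        assert achieved == pytest.approx(0.40, abs=3 * np.sqrt(0.4 * 0.6 / 100000))

    def test_scale_monotone_decreasing_in_rate(self):
        thetas = [
            calibrate_censor_scale(1.0, 1.0, DEFAULT_PROBS, r) for r in (0.1, 0.3, 0.6)
        ]
        assert thetas[0] > thetas[1] > thetas[2]

    def test_unattainable_rate_rejected(self):
        with pytest.raises((RuntimeError, ValueError)):
            calibrate_censor_scale(1.0, 1.0, DEFAULT_PROBS, 0.9999)


class TestTruth:
    def test_survival_at_zero_is_one(self):
        assert true_marginal_survival(0.0, 2.0) == pytest.approx(1.0)

    def test_exponential_median_degenerate(self):
        assert true_percentile(0.5, 1.0, (1, 0, 0, 0, 0)) == pytest.approx(np.log(2))

    def test_percentiles_monotone_and_invertible(self):
        ts = [true_percentile(p, 2.0) for p in (0.2, 0.5, 0.8)]
        assert ts[0] < ts[1] < ts[2]
        for p, t in zip((0.2, 0.5, 0.8), ts):
            assert true_marginal_survival(t, 2.0) == pytest.approx(1 - p, abs=1e-7)

    def test_truth_matches_monte_carlo(self):
        rng = np.random.default_rng(6)
        X = sample_covariates(10**6, DEFAULT_PROBS, rng)
        s = sample_weibull(
            X.sum(1).astype(float), 2.0, rng.uniform(1e-12, 1, 10**6)
        )
        for p in (0.2, 0.5, 0.8):
            t = true_percentile(p, 2.0)
            emp = (s > t).mean()
            se = np.sqrt((1 - p) * p / 10**6)
            assert abs(emp - (1 - p)) < 4 * se


class TestEstimators:
    def test_dbn_without_covariate_signal_equals_km(self):
        rng = np.random.default_rng(7)
        n = 500
        times = rng.exponential(2, n)
        events = (rng.random(n) < 0.7).astype(np.int8)
        if events.sum() == 0:
            events[0] = 1
        X = rng.integers(0, 2, (n, 5)).astype(np.int8)
        # shuffle X so it is independent of survival: BIC selects nothing
        eval_times = np.quantile(times, [0.3, 0.6])
        km = km_marginal_at(times, events, eval_times)
        dbn, parents = dbn_marginal_at(times, events, X, eval_times, return_parents=True)
        if all(len(p) == 0 for p in parents):
            assert np.allclose(km, dbn, atol=1e-12)

    def test_dbn_full_curve_monotone(self):
        theta_c = 4.18
        times, events, X = simulate_dataset(400, 2.0, 2.0, theta_c, seed=8)
        curve = dbn_estimator_for_simulation(frame_from_arrays(times, events, X))
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] <= 1.0

    def test_greedy_selection_matches_generic_hill_climb(self):
        """The per-slice forward selection equals constrained hill-climbing
        on the unrolled panel (the score decomposes per family)."""
        from dbnsurv.bn import n_node
        from dbnsurv.encoding import SliceGrid, encode_state_arrays
        from dbnsurv.fitting import panel_to_frame
        from dbnsurv.search import SearchConfig, hill_climb, temporal_constraints

        rng = np.random.default_rng(9)
        n = 2000
        z = rng.integers(0, 2, (n, 2)).astype(np.int8)
        # death at slice 1 strongly driven by z1; slice 2 by nothing
        p1 = np.where(z[:, 0] == 1, 0.7, 0.1)
        dies1 = rng.random(n) < p1
        dies2 = ~dies1 & (rng.random(n) < 0.3)
        times = np.where(dies1, 1.0, np.where(dies2, 2.0, 3.0))
        events = (dies1 | dies2).astype(np.int8)
        X = z
        _, parents = dbn_marginal_at(times, events, X, [2.0], return_parents=True)

        grid = SliceGrid(np.unique(times[events == 1]))
        panel = encode_state_arrays(times, events, grid)
        covs = pd.DataFrame({"x1": z[:, 0], "x2": z[:, 1]})
        flat = panel_to_frame(panel, covs)
        cons = temporal_constraints(["x1", "x2"], grid.n_slices)
        dag = hill_climb(flat, SearchConfig(score_name="bic", constraints=cons))
        hc_parents = [
            sorted(
                int(p[1]) - 1
                for p in dag.parents(n_node(t))
                if p.startswith("x")
            )
            for t in range(1, grid.n_slices + 1)
        ]
        assert [sorted(p) for p in parents] == hc_parents[: len(parents)]
        assert parents[0] == [0]  # the true driver of slice-1 survival

    def test_cox_sign_recovery(self):
        # strongly protective binary covariate -> negative coefficient
        rng = np.random.default_rng(10)
        n = 1500
        z = rng.integers(0, 2, n)
        s = rng.exponential(1 + 6 * z)
        c = rng.exponential(8, n)
        df = pd.DataFrame(
            {"time": np.minimum(s, c), "event": (s <= c).astype(int), "z": z}
        )
        marginal = cox_comparator_fit(df)
        assert marginal.model.params_["z"] < 0

    def test_cox_constant_covariates_fall_back_to_km(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 1])
        df = pd.DataFrame({"time": times, "event": events, "z": [1, 1, 1, 1]})
        marginal = cox_comparator_fit(df)
        km = km_marginal_at(times, events.astype(np.int8), [2.5])
        assert marginal([2.5])[0] == pytest.approx(km[0])


class TestScenario:
    def test_rmse_dominates_bias_and_censoring_calibrated(self):
        cfg = ScenarioConfig(
            n=300, censor_rate=0.25, alpha_s=2, alpha_c=2, n_reps=30, seed=3,
            estimators=("km", "dbn"),
        )
        res = run_scenario(cfg)
        for est in res.bias:
            assert np.all(res.rmse[est] >= np.abs(res.bias[est]) - 1e-12)
        se = np.sqrt(0.25 * 0.75 / (300 * 30))
        assert abs(res.achieved_censoring - 0.25) < 4 * se

    def test_replicate_seeding_is_order_independent(self):
        cfg1 = ScenarioConfig(n=200, n_reps=5, seed=11, estimators=("km",))
        cfg2 = ScenarioConfig(n=200, n_reps=5, seed=11, estimators=("km",))
        assert np.array_equal(run_scenario(cfg1).bias["km"], run_scenario(cfg2).bias["km"])

    def test_result_table_layout(self):
        cfg = ScenarioConfig(n=200, n_reps=3, seed=1, estimators=("km",))
        df = run_scenario(cfg).to_frame()
        assert set(df.columns) == {"estimator", "percentile", "bias", "rmse", "mc_se"}
        assert len(df) == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(censor_rate=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(alpha_s=-1)
        with pytest.raises(ValueError):
            ScenarioConfig(percentile_mode="bogus")
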