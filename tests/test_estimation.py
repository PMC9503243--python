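import numpy as np
import pandas as pd
import pytest

from dbnsurv.bn import Dag, n_node
from dbnsurv.encoding import (
    SliceCounts,
    SliceGrid,
    SurvivalRecord,
    build_slice_grid,
    encode_state_arrays,
    encode_states,
    tabulate_counts,
)
from dbnsurv.estimation import (
    curve_to_text,
    dbn_marginal_survival,
    dbn_survival,
    evaluate_at,
    greenwood_variance,
    km_estimate,
)
from dbnsurv.fitting import fit_transition_cpts

from conftest import random_censored_dataset


def _fit(times, events, covs=None, dag=None):
    grid = SliceGrid(np.unique(np.asarray(times)[np.asarray(events) == 1]))
    panel = encode_state_arrays(np.asarray(times, float), np.asarray(events), grid)
    return fit_transition_cpts(panel, covs, dag or Dag([])), grid, panel


class TestKaplanMeier:
    def test_toy_product(self, toy_records):
        grid = build_slice_grid(toy_records)
        counts = tabulate_counts(encode_states(toy_records, grid))
        curve = km_estimate(counts, grid)
        assert curve.survival[0] == pytest.approx(2 / 3)
        assert curve.survival[1] == 0.0

    def test_no_censoring_matches_empirical_fraction(self):
        times = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        events = np.ones(5, dtype=int)
        grid = SliceGrid(np.unique(times))
        counts = tabulate_counts(encode_state_arrays(times, events, grid))
        curve = km_estimate(counts, grid)
        for t, s in zip(grid.slice_times, curve.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_matches_lifelines_on_random_data(self):
        """Independent oracle: lifelines' product-limit implementation."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(13)
        for _ in range(20):
            times, events = random_censored_dataset(rng)
            grid = SliceGrid(np.unique(times[events == 1]))
            counts = tabulate_counts(encode_state_arrays(times, events, grid))
            curve = km_estimate(counts, grid)
            kmf = KaplanMeierFitter().fit(times, events)
            ours = np.array([evaluate_at(curve, t) for t in grid.slice_times])
            theirs = kmf.predict(grid.slice_times).to_numpy()
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_event_in_empty_risk_set_rejected(self):
        counts = SliceCounts(d=np.array([1]), y=np.array([0]), n_total=3)
        with pytest.raises(ValueError):
            km_estimate(counts)


class TestGreenwood:
    def test_toy_variance(self, toy_records):
        grid = build_slice_grid(toy_records)
        counts = tabulate_counts(encode_states(toy_records, grid))
        curve = km_estimate(counts, grid)
        assert curve.variance[0] == pytest.approx(2 / 27)

    def test_no_events_zero_variance(self):
        counts = SliceCounts(d=np.array([0, 0]), y=np.array([5, 4]), n_total=5)
        curve = km_estimate(counts)
        assert np.all(curve.variance == 0)

    def test_matches_bruteforce_on_random_data(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            times, events = random_censored_dataset(rng)
            grid = SliceGrid(np.unique(times[events == 1]))
            counts = tabulate_counts(encode_state_arrays(times, events, grid))
            curve = km_estimate(counts, grid)
            var = greenwood_variance(counts, curve)
            # literal term-by-term re-evaluation
            for j in range(grid.n_slices):
                total, defined = 0.0, True
                for i in range(j + 1):
                    d, y = counts.d[i], counts.y[i]
                    if y == d and d > 0:
                        defined = False
                        break
                    if y > 0:
                        total += d / (y * (y - d))
                expected = curve.survival[j] ** 2 * total
                if defined:
                    assert var[j] == pytest.approx(expected, abs=1e-12)
                else:
                    assert np.isnan(var[j]) or curve.survival[j] == 0.0

    def test_terminal_collapse_gives_zero_variance(self):
        # single subject dying at t1: S=0 and the S^2 factor forces 0
        counts = SliceCounts(d=np.array([1]), y=np.array([1]), n_total=1)
        curve = km_estimate(counts)
        assert curve.survival[0] == 0.0
        assert curve.variance[0] == 0.0


class TestDbnSurvival:
    def test_no_covariates_identical_to_km(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            times, events = random_censored_dataset(rng)
            tbn, grid, panel = _fit(times, events)
            km = km_estimate(tabulate_counts(panel), grid)
            dbn = dbn_survival(tbn)
            assert np.array_equal(dbn.survival, km.survival)

    def test_unknown_profile_covariate_ignored(self, toy_records):
        grid = build_slice_grid(toy_records)
        panel = encode_states(toy_records, grid)
        tbn = fit_transition_cpts(panel, None, Dag([]))
        curve = dbn_survival(tbn, {"nonexistent": 1})
        assert curve.survival[0] == pytest.approx(2 / 3)

    def test_stratified_fit_matches_per_stratum_km(self):
        rng = np.random.default_rng(23)
        n = 500
        z = rng.integers(0, 2, n)
        times = np.round(rng.exponential(2.0 + 3.0 * z), 1) + 0.1
        events = (rng.random(n) < 0.8).astype(np.int8)
        covs = pd.DataFrame({"z": z})
        grid = SliceGrid(np.unique(times[events == 1]))
        panel = encode_state_arrays(times, events, grid)
        nodes = ["z"] + [n_node(t) for t in range(1, grid.n_slices + 1)]
        edges = [("z", n_node(t)) for t in range(1, grid.n_slices + 1)]
        tbn = fit_transition_cpts(panel, covs, Dag(nodes, edges))
        for level in (0, 1):
            mask = z == level
            sub_panel = encode_state_arrays(times[mask], events[mask], grid)
            km = km_estimate(tabulate_counts(sub_panel), grid)
            strat = dbn_survival(tbn, {"z": level})
            # equality wherever the stratum has an informative risk set
            informative = ~np.isin(
                np.arange(grid.n_slices),
                [
                    t - 1
                    for t in range(2, grid.n_slices + 1)
                    if tbn.transition[t][n_node(t)].row_index([1, 0, level])
                    in tbn.transition[t][n_node(t)].flagged_rows
                ],
            )
            first_bad = np.argmin(informative) if not informative.all() else grid.n_slices
            assert np.allclose(
                strat.survival[:first_bad], km.survival[:first_bad], atol=1e-12
            )

    def test_marginal_mixture_of_two_strata(self):
        # two equal strata: survival 1 and 0 after t1 -> mixture 0.5
        times = np.array([1.0, 1.0, 9.0, 9.0])
        events = np.array([1, 1, 0, 0], dtype=np.int8)
        z = np.array([1, 1, 0, 0])
        covs = pd.DataFrame({"z": z})
        grid = SliceGrid(np.array([1.0]))
        panel = encode_state_arrays(times, events, grid)
        tbn = fit_transition_cpts(panel, covs, Dag(["z", n_node(1)], [("z", n_node(1))]))
        marg = dbn_marginal_survival(tbn, covs)
        assert marg.survival[0] == pytest.approx(0.5)

    def test_marginal_reduces_to_km_without_covariate_edges(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 0, 1, 0], dtype=np.int8)
        covs = pd.DataFrame({"z": [0, 1, 0, 1]})
        tbn, grid, panel = _fit(times, events, covs, Dag(["z"]))
        km = km_estimate(tabulate_counts(panel), grid)
        marg = dbn_marginal_survival(tbn, covs)
        assert np.array_equal(marg.survival, km.survival)


class TestEvaluateAt:
    def test_step_semantics(self):
        curve = km_estimate(
            SliceCounts(d=np.array([1, 1]), y=np.array([4, 2]), n_total=4),
            np.array([1.0, 3.0]),
        )
        assert evaluate_at(curve, 0.5) == 1.0
        assert evaluate_at(curve, 1.0) == pytest.approx(0.75)  # right-continuous
        assert evaluate_at(curve, 2.9) == pytest.approx(0.75)
        assert evaluate_at(curve, 100.0) == pytest.approx(0.375)

    def test_negative_time_rejected(self):
        curve = km_estimate(SliceCounts(d=np.array([1]), y=np.array([2]), n_total=2))
        with pytest.raises(ValueError):
            evaluate_at(curve, -0.1)


def test_curve_export_columns(toy_records):
    grid = build_slice_grid(toy_records)
    curve = km_estimate(tabulate_counts(encode_states(toy_records, grid)), grid)
    text = curve_to_text(curve)
    assert text.splitlines()[0].split("\t") == [
        "time", "survival", "variance", "n_at_risk", "n_events",
    ]
    assert len(text.splitlines()) == 3


def test_step_plot_export(toy_records, tmp_path):
    from dbnsurv.estimation import plot_curve

    grid = build_slice_grid(toy_records)
    curve = km_estimate(tabulate_counts(encode_states(toy_records, grid)), grid)
    out = tmp_path / "curve.png"
    plot_curve(curve, out)
    assert out.exists() and out.stat().st_size > 0
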