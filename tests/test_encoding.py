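import numpy as np
import pytest

from dbnsurv.encoding import (
    NoEventsError,
    SliceGrid,
    SurvivalRecord,
    build_slice_grid,
    encode_state_arrays,
    encode_states,
    read_survival_table,
    tabulate_counts,
)

from conftest import random_censored_dataset


class TestSliceGrid:
    def test_grid_uses_unique_event_times_only(self):
        recs = [SurvivalRecord(1, 1), SurvivalRecord(2, 0), SurvivalRecord(3, 1)]
        grid = build_slice_grid(recs)
        assert grid.slice_times.tolist() == [1.0, 3.0]

    def test_tied_events_collapse_to_one_slice(self):
        recs = [SurvivalRecord(2, 1), SurvivalRecord(2, 1), SurvivalRecord(5, 1)]
        assert build_slice_grid(recs).slice_times.tolist() == [2.0, 5.0]

    def test_all_censored_raises(self):
        with pytest.raises(NoEventsError):
            build_slice_grid([SurvivalRecord(1, 0), SurvivalRecord(2, 0)])

    def test_gastrectomy_like_years_give_14_slices(self):
        # events in years 1..12, 14, 15 (none in 13)
        years = list(range(1, 13)) + [14, 15]
        recs = [SurvivalRecord(float(y), 1) for y in years]
        recs += [SurvivalRecord(13.0, 0), SurvivalRecord(16.0, 0)]
        assert build_slice_grid(recs).n_slices == 14

    def test_slice_times_must_increase(self):
        with pytest.raises(ValueError):
            SliceGrid(np.array([1.0, 1.0]))


class TestEncodeStates:
    def test_event_at_slice_time_turns_n_off_from_that_slice(self):
        grid = SliceGrid(np.array([1.0, 2.0, 3.0]))
        panel = encode_states([SurvivalRecord(2, 1)], grid)
        assert panel.n_states[0].tolist() == [1, 0, 0]
        assert panel.q_states[0].tolist() == [0, 0, 0]

    def test_censoring_inside_interval_sets_q_at_interval_start(self):
        grid = SliceGrid(np.array([1.0, 3.0]))
        panel = encode_states([SurvivalRecord(2, 0)], grid)
        assert panel.q_states[0].tolist() == [1, 1]
        assert panel.n_states[0].tolist() == [1, 1]

    def test_survivor_past_last_slice_all_alive_uncensored(self):
        grid = SliceGrid(np.array([1.0, 2.0]))
        panel = encode_states([SurvivalRecord(10, 1)], grid)
        assert panel.n_states[0].tolist() == [1, 1]
        assert panel.q_states[0].tolist() == [0, 0]

    def test_pre_grid_censoring_flagged(self):
        grid = SliceGrid(np.array([2.0, 3.0]))
        panel = encode_states([SurvivalRecord(1, 0), SurvivalRecord(3, 1)], grid)
        assert panel.pre_censored.tolist() == [True, False]
        assert panel.q_states[0].tolist() == [1, 1]

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            encode_state_arrays(
                np.array([-1.0]), np.array([1]), SliceGrid(np.array([1.0]))
            )

    def test_absorbing_invariants_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            times, events = random_censored_dataset(rng)
            grid = SliceGrid(np.unique(times[events == 1]))
            panel = encode_state_arrays(times, events, grid)
            assert np.all(np.diff(panel.n_states, axis=1) <= 0)
            assert np.all(np.diff(panel.q_states, axis=1) >= 0)


class TestTabulateCounts:
    def test_toy_risk_set_accounting(self, toy_records):
        grid = build_slice_grid(toy_records)
        counts = tabulate_counts(encode_states(toy_records, grid))
        assert counts.d.tolist() == [1, 1]
        assert counts.y.tolist() == [3, 1]

    def test_everyone_dies_at_first_slice(self):
        recs = [SurvivalRecord(1, 1) for _ in range(5)]
        counts = tabulate_counts(encode_states(recs, build_slice_grid(recs)))
        assert counts.d[0] == 5 and counts.y[0] == 5

    def test_counts_match_classic_km_accounting(self):
        """Risk sets/events from the state panel equal direct accounting
        on (time, event) pairs, across many random datasets."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            times, events = random_censored_dataset(rng)
            grid = SliceGrid(np.unique(times[events == 1]))
            counts = tabulate_counts(encode_state_arrays(times, events, grid))
            for j, t in enumerate(grid.slice_times):
                at_risk = np.sum(times >= t)
                died = np.sum((times == t) & (events == 1))
                assert counts.y[j] == at_risk
                assert counts.d[j] == died


def test_reader_requires_columns(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("duration,status\n1,1\n")
    with pytest.raises(ValueError, match="time"):
        read_survival_table(p)


def test_reader_roundtrip(tmp_path):
    p = tmp_path / "ok.tsv"
    p.write_text("time\tevent\tsex\n1.5\t1\tF\n2.0\t0\tM\n")
    recs = read_survival_table(p, delimiter="\t")
    assert recs[0].time == 1.5 and recs[0].event == 1
    assert recs[1].covariates == {"sex": "M"}


from hypothesis import given, settings
from hypothesis import strategies as st


class TestEncodingProperties:
    """Invariant checks over arbitrary censored datasets."""

    @staticmethod
    def _dataset(draw):
        import hypothesis.strategies as st

        n = draw(st.integers(2, 40))
        times = [draw(st.floats(0, 50, allow_nan=False)) for _ in range(n)]
        events = [draw(st.integers(0, 1)) for _ in range(n)]
        events[draw(st.integers(0, n - 1))] = 1  # ensure an estimable grid
        return np.asarray(times), np.asarray(events, dtype=np.int8)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_slice_count_equals_unique_event_times(self, data):
        times, events = self._dataset(data.draw)
        grid = SliceGrid(np.unique(times[events == 1]))
        assert grid.n_slices == np.unique(times[events == 1]).size
        panel = encode_state_arrays(times, events, grid)
        counts = tabulate_counts(panel)
        # risk sets shrink, events never exceed them
        assert np.all(np.diff(counts.y) <= 0)
        assert np.all(counts.d <= counts.y)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_states_are_absorbing(self, data):
        times, events = self._dataset(data.draw)
        grid = SliceGrid(np.unique(times[events == 1]))
        panel = encode_state_arrays(times, events, grid)
        assert np.all(np.diff(panel.n_states, axis=1) <= 0)
        assert np.all(np.diff(panel.q_states, axis=1) >= 0)


def test_quantile_grid_coarsens_event_times():
    from dbnsurv.encoding import quantile_slice_grid

    recs = [SurvivalRecord(float(t), 1) for t in range(1, 101)]
    grid = quantile_slice_grid(recs, 5)
    assert grid.n_slices == 5
    assert grid.slice_times[0] == 1.0
    with pytest.raises(NoEventsError):
        quantile_slice_grid([SurvivalRecord(1.0, 0)], 3)
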