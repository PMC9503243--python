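"""Discretization of right-censored survival data onto a slice grid.

A continuous follow-up time together with an event indicator is mapped onto
the discrete time axis of the dynamic network: one *slice* per unique
observed event time.  Each subject then carries two binary state
trajectories over the slices,

* ``N[i, t] = 1`` if subject *i* is known to be alive at slice *t*
  (failure is absorbing: once ``N`` drops to 0 it stays 0),
* ``Q[i, t] = 1`` if subject *i* has been censored at or before slice *t*
  (censoring is absorbing: once ``Q`` rises to 1 it stays 1).

Slice *j* spans the half-open interval ``[t_j, t_{j+1})``; the last slice
extends to infinity.  A censoring time falling inside slice *j* (including
exactly at ``t_j``) sets ``Q[i, j] = 1``, so the subject still counts in the
risk set of slice *j* — the usual events-before-censorings tie convention of
the product-limit estimator.  A subject censored strictly before the first
event time never enters any risk set; such subjects are flagged in
``StatePanel.pre_censored`` and excluded from slice-1 counts, exactly as the
classic Kaplan-Meier risk set excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalRecord",
    "SliceGrid",
    "StatePanel",
    "SliceCounts",
    "build_slice_grid",
    "encode_states",
    "tabulate_counts",
    "read_survival_table",
    "records_to_frame",
    "frame_to_records",
]


class NoEventsError(ValueError):
    """Raised when a dataset contains no observed events.

    Without at least one event time there is no slice grid and no
    estimable survival curve.
    """


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event flag and discrete covariates."""

    time: float
    event: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative follow-up time: {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class SliceGrid:
    """Strictly increasing unique event times defining the slices."""

    slice_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.slice_times, dtype=float)
        object.__setattr__(self, "slice_times", t)
        if t.size == 0:
            raise NoEventsError("slice grid must contain at least one event time")
        if np.any(np.diff(t) <= 0):
            raise ValueError("slice times must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return int(self.slice_times.size)

    def slice_of(self, time: float) -> int:
        """0-based index of the slice whose interval contains ``time``.

        Returns -1 for times strictly before the first slice time.
        """
        return int(np.searchsorted(self.slice_times, time, side="right")) - 1


@dataclass
class StatePanel:
    """Binary survival (N) and censorship (Q) states, subjects x slices."""

    n_states: np.ndarray
    q_states: np.ndarray
    grid: SliceGrid
    pre_censored: np.ndarray  # censored strictly before the first slice time

    @property
    def n_subjects(self) -> int:
        return self.n_states.shape[0]

    def validate(self) -> None:
        n, q = self.n_states, self.q_states
        if n.shape != q.shape or n.shape[1] != self.grid.n_slices:
            raise ValueError("panel shape does not match grid")
        if np.any(np.diff(n.astype(int), axis=1) > 0):
            raise ValueError("N states must be nonincreasing (failure is absorbing)")
        if np.any(np.diff(q.astype(int), axis=1) < 0):
            raise ValueError("Q states must be nondecreasing (censoring is absorbing)")
        # a subject observed to fail is never censored
        if np.any((n[:, -1] == 0) & (q[:, -1] == 1)):
            raise ValueError("a subject cannot both fail and be censored")


@dataclass
class SliceCounts:
    """Events ``d_t`` and at-risk counts ``Y_t`` per slice."""

    d: np.ndarray
    y: np.ndarray
    n_total: int

    def validate(self) -> None:
        if np.any(self.d > self.y) or np.any(self.d < 0):
            raise ValueError("need 0 <= d_t <= Y_t at every slice")
        if np.any(np.diff(self.y) > 0):
            raise ValueError("at-risk counts must be nonincreasing")
        if self.y.size and self.y[0] > self.n_total:
            raise ValueError("initial risk set exceeds cohort size")


def build_slice_grid(records: Sequence[SurvivalRecord]) -> SliceGrid:
    """Slice grid from the unique observed event times.

    Censoring-only times never create slices.  Raises
    :class:`NoEventsError` when no record has ``event == 1``.
    """
    times = np.array([r.time for r in records if r.event == 1], dtype=float)
    if times.size == 0:
        raise NoEventsError("no events observed: survival curve is not estimable")
    return SliceGrid(np.unique(times))


def quantile_slice_grid(records: Sequence[SurvivalRecord], n_slices: int) -> SliceGrid:
    """Coarser alternative grid: event-time quantiles instead of every
    unique event time.  Useful when the full grid is too fine for the
    available sample."""
    if n_slices < 1:
        raise ValueError("need at least one slice")
    times = np.array([r.time for r in records if r.event == 1], dtype=float)
    if times.size == 0:
        raise NoEventsError("no events observed: survival curve is not estimable")
    qs = np.quantile(times, np.linspace(0, 1, n_slices + 1)[:-1])
    return SliceGrid(np.unique(qs))


def encode_states(
    records: Sequence[SurvivalRecord], grid: SliceGrid
) -> StatePanel:
    """Encode each record into its binary N/Q trajectories over ``grid``."""
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=np.int8)
    return encode_state_arrays(times, events, grid)


def encode_state_arrays(
    times: np.ndarray, events: np.ndarray, grid: SliceGrid
) -> StatePanel:
    """Vectorized core of :func:`encode_states` on parallel arrays."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if np.any(times < 0):
        raise ValueError("negative follow-up time")
    ts = grid.slice_times
    n_subj, n_sl = times.size, ts.size

    # N[i, j] = 1 unless an observed event occurred at or before t_j.
    n_states = np.ones((n_subj, n_sl), dtype=np.int8)
    ev = events == 1
    n_states[ev] = (ts[None, :] < times[ev, None]).astype(np.int8)

    # Q[i, j] = 1 from the slice containing the censoring time onward.
    # Censoring strictly before t_1 flags the subject as never at risk and
    # (by convention) sets Q from slice 1.
    q_states = np.zeros((n_subj, n_sl), dtype=np.int8)
    cens = ~ev
    first = np.searchsorted(ts, times[cens], side="right") - 1
    pre = np.zeros(n_subj, dtype=bool)
    pre_idx = first < 0
    pre[np.flatnonzero(cens)[pre_idx]] = True
    first = np.maximum(first, 0)
    q_states[cens] = (np.arange(n_sl)[None, :] >= first[:, None]).astype(np.int8)

    panel = StatePanel(n_states=n_states, q_states=q_states, grid=grid, pre_censored=pre)
    panel.validate()
    return panel


def tabulate_counts(panel: StatePanel) -> SliceCounts:
    """Per-slice events and risk sets from the state panel.

    The risk set of slice 1 is every subject not censored before the first
    event time; the risk set of slice t > 1 is everyone with
    ``N[t-1] = 1`` and ``Q[t-1] = 0``.  An event in slice t is an at-risk
    subject whose N drops to 0 there.  This is classic Kaplan-Meier risk-set
    accounting re-expressed in the state variables.
    """
    n, q = panel.n_states, panel.q_states
    n_sl = panel.grid.n_slices
    at_risk = np.empty((panel.n_subjects, n_sl), dtype=bool)
    at_risk[:, 0] = ~panel.pre_censored
    if n_sl > 1:
        at_risk[:, 1:] = (n[:, :-1] == 1) & (q[:, :-1] == 0)
    y = at_risk.sum(axis=0)
    d = (at_risk & (n == 0)).sum(axis=0)
    counts = SliceCounts(d=d.astype(np.int64), y=y.astype(np.int64), n_total=panel.n_subjects)
    counts.validate()
    return counts


def read_survival_table(
    path, delimiter: str = ",", time_col: str = "time", event_col: str = "event"
) -> list[SurvivalRecord]:
    """Read a delimited text table into survival records.

    Requires a header with ``time`` and ``event`` columns; every remaining
    column is treated as a discrete covariate.
    """
    df = pd.read_csv(path, sep=delimiter)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    return frame_to_records(df, time_col=time_col, event_col=event_col)


def frame_to_records(
    df: pd.DataFrame, time_col: str = "time", event_col: str = "event"
) -> list[SurvivalRecord]:
    cov_cols = [c for c in df.columns if c not in (time_col, event_col)]
    return [
        SurvivalRecord(
            time=float(row[time_col]),
            event=int(row[event_col]),
            covariates={c: row[c] for c in cov_cols},
        )
        for row in df.to_dict("records")
    ]


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    rows = [{"time": r.time, "event": r.event, **r.covariates} for r in records]
    return pd.DataFrame(rows)
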