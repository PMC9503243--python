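"""Survival-probability estimators: Kaplan-Meier, Greenwood variance, and
the dynamic-network estimator with covariate conditioning.

The network estimator multiplies the fitted slice-1 survival probability by
the fitted per-slice conditional survival probabilities of the at-risk
configuration,

    S(t) = P(N@1 = 1 | Z) * prod_{u=2..t} P(N@u = 1 | N@(u-1)=1, Q@(u-1)=0, Z),

each factor conditioning only on the covariates that are parents of that
slice's ``N`` node.  With no covariate edges every factor is the empirical
per-interval survival fraction and the product is the product-limit
estimator, term for term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .bn import TwoSliceTBN, n_node
from .encoding import SliceCounts, SliceGrid

__all__ = [
    "SurvivalCurve",
    "km_estimate",
    "greenwood_variance",
    "dbn_survival",
    "dbn_marginal_survival",
    "evaluate_at",
    "curve_to_text",
]

log = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Stepwise survival estimates over the slice times.

    ``survival[j]`` is the estimate at and after ``times[j]`` (right-
    continuous step function; the value before ``times[0]`` is 1).
    ``variance`` entries are NaN where the Greenwood formula is undefined
    or not applicable.
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_at_risk: np.ndarray | None = None
    n_events: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if np.any((self.survival < -1e-12) | (self.survival > 1 + 1e-12)):
            raise ValueError("survival estimates outside [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimates must be nonincreasing")


def km_estimate(counts: SliceCounts, grid: SliceGrid | np.ndarray | None = None) -> SurvivalCurve:
    """Product-limit estimator from per-slice events and risk sets."""
    counts.validate()
    d, y = counts.d.astype(float), counts.y.astype(float)
    factors = np.ones_like(d)
    nonempty = y > 0
    # (y - d) / y rather than 1 - d/y: the identical float expression used
    # when fitting the network's transition tables, so the two estimators
    # agree bit-for-bit in the covariate-free case
    factors[nonempty] = (y[nonempty] - d[nonempty]) / y[nonempty]
    if np.any((y == 0) & (d > 0)):
        raise ValueError("events recorded in a slice with an empty risk set")
    surv = np.cumprod(factors)
    if grid is None:
        times = np.arange(1, d.size + 1, dtype=float)
    elif isinstance(grid, SliceGrid):
        times = grid.slice_times
    else:
        times = np.asarray(grid, dtype=float)
    curve = SurvivalCurve(
        times=times,
        survival=surv,
        variance=np.full(d.size, np.nan),
        n_at_risk=counts.y.copy(),
        n_events=counts.d.copy(),
    )
    curve.variance = greenwood_variance(counts, curve)
    return curve


def greenwood_variance(counts: SliceCounts, curve: SurvivalCurve) -> np.ndarray:
    """Greenwood's formula: V(t) = S(t)^2 * sum_{t_i<=t} d_i / (Y_i (Y_i - d_i)).

    Where ``Y_i == d_i`` at a slice with S(t) still positive afterwards the
    sum is undefined; those positions (and all later ones) return NaN.
    A slice that drives S to exactly 0 yields variance 0 via the S^2 factor.
    """
    d, y = counts.d.astype(float), counts.y.astype(float)
    denom = y * (y - d)
    terms = np.zeros_like(d)
    ok = denom > 0
    terms[ok] = d[ok] / denom[ok]
    undefined = (~ok) & (d > 0) & (y > 0) & (y == d)
    cum = np.cumsum(terms)
    var = curve.survival**2 * cum
    # once the sum hits an undefined term, later values are undefined too --
    # unless S is exactly 0 there (then S^2 * anything is 0, flagged by S).
    bad = np.cumsum(undefined.astype(int)) > 0
    var[bad & (curve.survival > 0)] = np.nan
    var[bad & (curve.survival == 0)] = 0.0
    return var


def _factor_with_fallback(cpt, profile_vals, one_index, pooled_p):
    row_idx = cpt.row_index(profile_vals)
    if row_idx in cpt.flagged_rows:
        log.info(
            "empty conditional risk set for %s at row %d; using pooled probability",
            cpt.child, row_idx,
        )
        return pooled_p
    return float(cpt.table[row_idx, one_index])


def dbn_survival(
    tbn: TwoSliceTBN, covariate_profile: Mapping[str, object] | None = None
) -> SurvivalCurve:
    """Survival curve for one covariate profile (or the pooled curve).

    Covariates in the profile that the model never uses are ignored with a
    warning; a profile-specific factor whose conditional risk set was empty
    falls back to the pooled per-slice probability.
    """
    profile = dict(covariate_profile or {})
    known = set(tbn.covariate_names)
    for key in list(profile):
        if key not in known:
            log.warning("profile covariate %r not in the model; ignored", key)
            del profile[key]

    n_slices = tbn.n_slices
    pooled = tbn.pooled_survival
    if pooled is None:
        pooled = np.ones(n_slices)

    factors = np.empty(n_slices)
    has_cov_parents = False
    cpt1 = tbn.prior.cpts[n_node(1)]
    cov_ps = [p for p in cpt1.parents if p in known]
    if cov_ps:
        has_cov_parents = True
        missing = [p for p in cov_ps if p not in profile]
        if missing:
            raise ValueError(f"profile missing model covariates {missing}")
        vals = [profile[p] for p in cpt1.parents]
        factors[0] = _factor_with_fallback(cpt1, vals, cpt1.levels.index(1), pooled[0])
    else:
        factors[0] = cpt1.prob(1) if not cpt1.parents else pooled[0]

    for t in range(2, n_slices + 1):
        cpt = tbn.transition[t][n_node(t)]
        # at-risk configuration: N@(t-1)=1, Q@(t-1)=0, then covariate values
        vals = [1, 0]
        cov_tail = cpt.parents[2:]
        if cov_tail:
            has_cov_parents = True
            missing = [p for p in cov_tail if p not in profile]
            if missing:
                raise ValueError(f"profile missing model covariates {missing}")
            vals += [profile[p] for p in cov_tail]
        factors[t - 1] = _factor_with_fallback(
            cpt, vals, cpt.levels.index(1), pooled[t - 1]
        )

    surv = np.cumprod(factors)
    times = (
        tbn.slice_times
        if tbn.slice_times is not None
        else np.arange(1, n_slices + 1, dtype=float)
    )
    variance = np.full(n_slices, np.nan)
    n_at_risk = n_events = None
    if tbn.counts is not None:
        n_at_risk, n_events = tbn.counts.y.copy(), tbn.counts.d.copy()
        if not has_cov_parents:
            # covariate-free case: identical to KM, so Greenwood is exact
            curve = SurvivalCurve(times=times, survival=surv, variance=variance,
                                  n_at_risk=n_at_risk, n_events=n_events)
            curve.variance = greenwood_variance(tbn.counts, curve)
            return curve
    return SurvivalCurve(times=times, survival=surv, variance=variance,
                         n_at_risk=n_at_risk, n_events=n_events)


def dbn_marginal_survival(
    tbn: TwoSliceTBN, covariate_table: pd.DataFrame | None
) -> SurvivalCurve:
    """Population-level curve: the empirical mixture over covariate profiles.

    Profiles are weighted by their empirical joint frequency in
    ``covariate_table`` (not a product of marginals), preserving covariate
    dependence.  With no covariate edges this reduces to the pooled curve.
    """
    used = _used_covariates(tbn)
    if not used or covariate_table is None or covariate_table.empty:
        return dbn_survival(tbn)
    cols = [c for c in tbn.covariate_names if c in used]
    groups = covariate_table.groupby(cols, observed=True).size()
    total = groups.sum()
    surv = None
    for combo, count in groups.items():
        if len(cols) == 1:
            combo = (combo,)
        profile = dict(zip(cols, combo))
        c = dbn_survival(tbn, profile)
        surv = c.survival * (count / total) if surv is None else surv + c.survival * (count / total)
        times = c.times
    return SurvivalCurve(
        times=times,
        survival=surv,
        variance=np.full(surv.size, np.nan),
        n_at_risk=tbn.counts.y.copy() if tbn.counts is not None else None,
        n_events=tbn.counts.d.copy() if tbn.counts is not None else None,
    )


def _used_covariates(tbn: TwoSliceTBN) -> set[str]:
    known = set(tbn.covariate_names)
    used = {p for p in tbn.prior.cpts[n_node(1)].parents if p in known}
    for t, cpts in tbn.transition.items():
        used |= {p for p in cpts[n_node(t)].parents if p in known}
    return used


def evaluate_at(curve: SurvivalCurve, t: float | np.ndarray):
    """Right-continuous step lookup; 1 before the first slice time."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative evaluation time")
    idx = np.searchsorted(curve.times, t_arr, side="right") - 1
    vals = np.where(idx >= 0, curve.survival[np.maximum(idx, 0)], 1.0)
    return float(vals) if np.isscalar(t) or t_arr.ndim == 0 else vals


def plot_curve(curve: SurvivalCurve, path, label: str = "survival") -> None:
    """Render the curve as a right-continuous step plot to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    times = np.concatenate([[0.0], curve.times])
    surv = np.concatenate([[1.0], curve.survival])
    ax.step(times, surv, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def curve_to_text(curve: SurvivalCurve, delimiter: str = "\t") -> str:
    header = ["time", "survival", "variance", "n_at_risk", "n_events"]
    lines = [delimiter.join(header)]
    n = curve.times.size
    at_risk = curve.n_at_risk if curve.n_at_risk is not None else [""] * n
    events = curve.n_events if curve.n_events is not None else [""] * n
    for j in range(n):
        lines.append(
            delimiter.join(
                [
                    f"{curve.times[j]:.10g}",
                    f"{curve.survival[j]:.10g}",
                    f"{curve.variance[j]:.10g}",
                    str(at_risk[j]),
                    str(events[j]),
                ]
            )
        )
    return "\n".join(lines)
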