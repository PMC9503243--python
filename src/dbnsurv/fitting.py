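"""Maximum-likelihood estimation of conditional probability tables.

Transition tables of the survival network are estimated per slice from the
at-risk subjects only: the conditional survival fraction
``P(N@t = 1 | N@(t-1) = 1, Q@(t-1) = 0, Z)`` is the empirical frequency in
the slice-t risk set, which is exactly the per-interval factor of the
product-limit estimator.  Rows that are forced by the absorbing dynamics
(a failed subject stays failed, a censored subject stays censored) are
filled deterministically; at-risk rows with zero support are filled
uniformly and flagged.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import Cpt, Dag, DiscreteBayesNet, TwoSliceTBN, n_node, q_node
from .encoding import StatePanel, tabulate_counts
from .scores import DiscreteData

__all__ = [
    "fit_cpts",
    "fit_transition_cpts",
    "panel_to_frame",
    "tbn_to_json",
    "tbn_from_json",
]


def _rows_to_cpt(
    child: str,
    parents: Sequence[str],
    levels: Sequence,
    parent_levels: Sequence[Sequence],
    counts: np.ndarray,
    pseudo_count: float = 0.0,
) -> Cpt:
    counts = np.asarray(counts, dtype=float) + pseudo_count
    totals = counts.sum(axis=1)
    empty = totals == 0
    table = np.empty_like(counts)
    table[~empty] = counts[~empty] / totals[~empty, None]
    table[empty] = 1.0 / counts.shape[1]
    return Cpt(
        child=child,
        parents=tuple(parents),
        levels=tuple(levels),
        parent_levels=tuple(tuple(pl) for pl in parent_levels),
        table=table,
        flagged_rows=frozenset(np.flatnonzero(empty).tolist()),
    )


def fit_cpts(dag: Dag, data, pseudo_count: float = 0.0,
             domains: Mapping[str, Sequence] | None = None) -> DiscreteBayesNet:
    """Empirical-frequency CPTs for every node of a fixed DAG.

    ``pseudo_count`` adds an optional Laplace/Dirichlet smoothing mass per
    cell; the default 0 keeps pure maximum likelihood.
    """
    if isinstance(data, pd.DataFrame):
        data = DiscreteData(data, domains=domains)
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        fam = data.family_counts(node, parents)
        cpts[node] = _rows_to_cpt(
            node,
            parents,
            data.domains[node],
            [data.domains[p] for p in parents],
            fam.counts,
            pseudo_count=pseudo_count,
        )
    return DiscreteBayesNet(dag=dag, cpts=cpts)


def panel_to_frame(panel: StatePanel, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten a state panel (plus covariates) into one row per subject."""
    cols = {}
    if covariates is not None:
        if len(covariates) != panel.n_subjects:
            raise ValueError("covariate table not row-aligned with the panel")
        for c in covariates.columns:
            cols[c] = covariates[c].to_numpy()
    for t in range(1, panel.grid.n_slices + 1):
        cols[n_node(t)] = panel.n_states[:, t - 1]
        cols[q_node(t)] = panel.q_states[:, t - 1]
    return pd.DataFrame(cols)


def _cov_parents(dag: Dag, node: str, covariate_names: Sequence[str]) -> list[str]:
    covs = set(covariate_names)
    return [p for p in dag.parents(node) if p in covs]


def _cov_codes(cov_parents, cov_data: DiscreteData, n_subjects: int):
    """Mixed-radix code of each subject's levels on the given covariates."""
    code = np.zeros(n_subjects, dtype=np.int64)
    n_cfg = 1
    for p in cov_parents:
        card = cov_data.card(p)
        code = code * card + cov_data.codes[p]
        n_cfg *= card
    return code, n_cfg


def _binary_state_cpt(
    child, cov_parents, cov_levels, n_cfg, ones, totals, prev_parents=None
):
    """CPT over levels (0, 1) from per-config one-counts and totals.

    With ``prev_parents`` given, the parent list is the two previous-slice
    state nodes followed by the covariates, and only the at-risk parent
    configuration (N=1, Q=0) is data-driven; the other three are fixed by
    the absorbing dynamics.
    """
    ones = np.asarray(ones, dtype=float)
    totals = np.asarray(totals, dtype=float)
    empty = totals == 0
    p1 = np.empty(n_cfg)
    p1[~empty] = ones[~empty] / totals[~empty]
    p1[empty] = 0.5
    at_risk_rows = np.stack([1.0 - p1, p1], axis=1)
    if prev_parents is None:
        return Cpt(
            child=child,
            parents=tuple(cov_parents),
            levels=(0, 1),
            parent_levels=tuple(cov_levels),
            table=at_risk_rows,
            flagged_rows=frozenset(np.flatnonzero(empty).tolist()),
        )
    prev_n, prev_q = prev_parents
    # parent order: N@(t-1), Q@(t-1), then covariates; mixed-radix rows
    table = np.zeros((4 * n_cfg, 2))
    flagged = []
    for ni in (0, 1):
        for qi in (0, 1):
            base = (ni * 2 + qi) * n_cfg
            block = slice(base, base + n_cfg)
            if ni == 1 and qi == 0:  # at risk: data-driven
                table[block] = at_risk_rows
                flagged.extend(base + j for j in np.flatnonzero(empty))
            elif child.startswith("N"):
                # failed stays failed; censored-alive stays alive
                table[block, ni] = 1.0
            else:
                # Q: censored stays censored; otherwise stays uncensored
                table[block, 1 if qi == 1 else 0] = 1.0
    return Cpt(
        child=child,
        parents=(prev_n, prev_q) + tuple(cov_parents),
        levels=(0, 1),
        parent_levels=((0, 1), (0, 1)) + tuple(cov_levels),
        table=table,
        flagged_rows=frozenset(flagged),
    )


def fit_transition_cpts(
    panel: StatePanel,
    covariates: pd.DataFrame | None,
    dag: Dag,
    domains: Mapping[str, Sequence] | None = None,
) -> TwoSliceTBN:
    """Fit the full temporal network for a given unrolled structure.

    ``dag`` is over the unrolled node set (covariates plus ``N@t``/``Q@t``);
    only its covariate->state and covariate->covariate edges matter — the
    state chain itself is implied.  The slice-1 survival table is estimated
    on the slice-1 risk set (subjects censored before the first event time
    are excluded), which keeps the estimator identical to Kaplan-Meier.
    """
    n_slices = panel.grid.n_slices
    n_subj = panel.n_subjects
    if covariates is None:
        covariates = pd.DataFrame(index=range(n_subj))
    cov_names = tuple(c for c in covariates.columns)
    cov_data = DiscreteData(covariates, domains=domains) if cov_names else None

    def cov_info(node):
        cps = _cov_parents(dag, node, cov_names) if node in set(dag.nodes) else []
        if not cps:
            return [], [], np.zeros(n_subj, dtype=np.int64), 1
        code, n_cfg = _cov_codes(cps, cov_data, n_subj)
        return cps, [cov_data.domains[p] for p in cps], code, n_cfg

    def tabulate(mask: np.ndarray, outcome: np.ndarray, code, n_cfg):
        totals = np.bincount(code[mask], minlength=n_cfg)
        ones = np.bincount(code[mask & (outcome == 1)], minlength=n_cfg)
        return ones, totals

    N, Q = panel.n_states, panel.q_states

    # ---- prior network: covariates + N@1 + Q@1 -------------------------
    prior_nodes: list[str] = list(cov_names) + [n_node(1), q_node(1)]
    prior_edges: set[tuple[str, str]] = set()
    cpts: dict[str, Cpt] = {}
    if cov_names:
        for z in cov_names:
            zp = [p for p in dag.parents(z) if p in set(cov_names)] if z in set(dag.nodes) else []
            fam = cov_data.family_counts(z, zp)
            cpts[z] = _rows_to_cpt(z, zp, cov_data.domains[z],
                                   [cov_data.domains[p] for p in zp], fam.counts)
            prior_edges |= {(p, z) for p in zp}

    at_start = ~panel.pre_censored
    cps, levels, code, n_cfg = cov_info(n_node(1))
    ones, totals = tabulate(at_start, N[:, 0], code, n_cfg)
    cpts[n_node(1)] = _binary_state_cpt(n_node(1), cps, levels, n_cfg, ones, totals)
    prior_edges |= {(p, n_node(1)) for p in cps}

    cps, levels, code, n_cfg = cov_info(q_node(1))
    ones, totals = tabulate(np.ones(n_subj, dtype=bool), Q[:, 0], code, n_cfg)
    cpts[q_node(1)] = _binary_state_cpt(q_node(1), cps, levels, n_cfg, ones, totals)
    prior_edges |= {(p, q_node(1)) for p in cps}

    prior = DiscreteBayesNet(Dag(prior_nodes, prior_edges), cpts)

    # ---- per-slice transition tables -----------------------------------
    transition: dict[int, dict[str, Cpt]] = {}
    for t in range(2, n_slices + 1):
        at_risk = (N[:, t - 2] == 1) & (Q[:, t - 2] == 0)
        slice_cpts: dict[str, Cpt] = {}
        for maker, node, outcome in (
            ("N", n_node(t), N[:, t - 1]),
            ("Q", q_node(t), Q[:, t - 1]),
        ):
            cps, levels, code, n_cfg = cov_info(node)
            ones, totals = tabulate(at_risk, outcome, code, n_cfg)
            slice_cpts[node] = _binary_state_cpt(
                node, cps, levels, n_cfg, ones, totals,
                prev_parents=(n_node(t - 1), q_node(t - 1)),
            )
        transition[t] = slice_cpts

    counts = tabulate_counts(panel)
    d, y = counts.d.astype(float), counts.y.astype(float)
    pooled = np.ones(n_slices)
    nonempty = y > 0
    pooled[nonempty] = 1.0 - d[nonempty] / y[nonempty]
    return TwoSliceTBN(
        prior=prior,
        transition=transition,
        covariate_names=cov_names,
        pooled_survival=pooled,
        counts=counts,
        slice_times=panel.grid.slice_times.copy(),
    )


# ---------------------------------------------------------------------------
# plain-text (JSON) serialization of a fitted temporal network


def _cpt_dict(cpt: Cpt) -> dict:
    return {
        "child": cpt.child,
        "parents": list(cpt.parents),
        "levels": [_py(lv) for lv in cpt.levels],
        "parent_levels": [[_py(lv) for lv in pl] for pl in cpt.parent_levels],
        "table": cpt.table.tolist(),
        "flagged_rows": sorted(cpt.flagged_rows),
    }


def _py(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _cpt_from_dict(d: dict) -> Cpt:
    return Cpt(
        child=d["child"],
        parents=tuple(d["parents"]),
        levels=tuple(d["levels"]),
        parent_levels=tuple(tuple(pl) for pl in d["parent_levels"]),
        table=np.asarray(d["table"], dtype=float),
        flagged_rows=frozenset(d["flagged_rows"]),
    )


def tbn_to_json(tbn: TwoSliceTBN) -> str:
    doc = {
        "covariate_names": list(tbn.covariate_names),
        "prior": {
            "nodes": list(tbn.prior.dag.nodes),
            "edges": sorted(map(list, tbn.prior.dag.edges)),
            "cpts": {k: _cpt_dict(v) for k, v in tbn.prior.cpts.items()},
        },
        "transition": {
            str(t): {k: _cpt_dict(v) for k, v in cpts.items()}
            for t, cpts in tbn.transition.items()
        },
        "pooled_survival": None
        if tbn.pooled_survival is None
        else tbn.pooled_survival.tolist(),
        "counts": None
        if tbn.counts is None
        else {
            "d": tbn.counts.d.tolist(),
            "y": tbn.counts.y.tolist(),
            "n_total": int(tbn.counts.n_total),
        },
        "slice_times": None if tbn.slice_times is None else tbn.slice_times.tolist(),
    }
    return json.dumps(doc, indent=1)


def tbn_from_json(text: str) -> TwoSliceTBN:
    doc = json.loads(text)
    prior = DiscreteBayesNet(
        Dag(doc["prior"]["nodes"], [tuple(e) for e in doc["prior"]["edges"]]),
        {k: _cpt_from_dict(v) for k, v in doc["prior"]["cpts"].items()},
    )
    transition = {
        int(t): {k: _cpt_from_dict(v) for k, v in cpts.items()}
        for t, cpts in doc["transition"].items()
    }
    counts = doc.get("counts")
    if counts is not None:
        from .encoding import SliceCounts

        counts = SliceCounts(
            d=np.asarray(counts["d"], dtype=np.int64),
            y=np.asarray(counts["y"], dtype=np.int64),
            n_total=counts["n_total"],
        )
    pooled = doc.get("pooled_survival")
    times = doc.get("slice_times")
    return TwoSliceTBN(
        prior=prior,
        transition=transition,
        covariate_names=tuple(doc["covariate_names"]),
        pooled_survival=None if pooled is None else np.asarray(pooled, dtype=float),
        counts=counts,
        slice_times=None if times is None else np.asarray(times, dtype=float),
    )
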