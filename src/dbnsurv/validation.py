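"""Approximate inference by likelihood weighting and repeated hold-out
validation scored by posterior classification error.

Likelihood weighting is importance sampling on the network: non-evidence
nodes are sampled ancestrally, and each sample is weighted by the product
of the evidence nodes' conditional probabilities given the sampled
parents.  The posterior classification error of a node is the fraction of
held-out subjects whose maximum-posterior predicted state is wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import DiscreteBayesNet
from .fitting import fit_cpts
from .scores import DiscreteData
from .search import SearchConfig, hill_climb, tabu_search

__all__ = [
    "likelihood_weighting",
    "posterior_classify",
    "repeated_holdout",
    "ModelSpec",
    "ValidationReport",
]


def likelihood_weighting(
    net: DiscreteBayesNet,
    evidence: Mapping[str, object],
    query: str,
    n_samples: int = 5000,
    seed: int | np.random.Generator = 0,
    _factor_nodes: set[str] | None = None,
) -> np.ndarray:
    """Estimate P(query | evidence) from ``n_samples`` weighted samples.

    Returns a probability vector over the query node's levels (all NaN when
    every sample weight is zero, i.e. the evidence is impossible under the
    network).  ``_factor_nodes`` optionally restricts which evidence nodes
    contribute weight factors; factors whose parents are all evidence are
    constant across samples and cancel in the normalization, so dropping
    them changes nothing but the run time.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if query in evidence:
        out = np.zeros(len(net.levels(query)))
        out[net.levels(query).index(evidence[query])] = 1.0
        return out

    samples: dict[str, np.ndarray] = {}
    log_w = np.zeros(n_samples)
    for node in net.dag.topological_order():
        cpt = net.cpts[node]
        if cpt.parents:
            rows = np.zeros(n_samples, dtype=np.int64)
            for parent, pl in zip(cpt.parents, cpt.parent_levels):
                rows = rows * len(pl) + samples[parent]
            probs = cpt.table[rows]
        else:
            probs = np.broadcast_to(cpt.table[0], (n_samples, len(cpt.levels)))
        if node in evidence:
            idx = cpt.levels.index(evidence[node])
            samples[node] = np.full(n_samples, idx, dtype=np.int64)
            if _factor_nodes is None or node in _factor_nodes:
                with np.errstate(divide="ignore"):
                    log_w += np.log(probs[:, idx])
        else:
            u = rng.random(n_samples)
            samples[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    w = np.exp(log_w - np.max(log_w)) if np.any(np.isfinite(log_w)) else np.zeros(n_samples)
    total = w.sum()
    n_levels = len(net.levels(query))
    if total == 0 or not np.isfinite(total):
        return np.full(n_levels, np.nan)
    post = np.bincount(samples[query], weights=w, minlength=n_levels)[:n_levels]
    return post / total


def posterior_classify(
    net: DiscreteBayesNet,
    evidence: Mapping[str, object],
    query: str,
    n_samples: int = 5000,
    seed: int | np.random.Generator = 0,
    _factor_nodes: set[str] | None = None,
):
    """Maximum-posterior level of the query node; ``None`` when undefined.

    Exact ties resolve to the first level in declared (lexicographic)
    order, which is what ``argmax`` returns.
    """
    post = likelihood_weighting(
        net, evidence, query, n_samples=n_samples, seed=seed, _factor_nodes=_factor_nodes
    )
    if np.any(np.isnan(post)):
        return None
    return net.levels(query)[int(np.argmax(post))]


@dataclass
class ModelSpec:
    """Structure-learning recipe used inside each hold-out repetition."""

    algorithm: str = "tabu"
    search: SearchConfig = field(default_factory=SearchConfig)
    pseudo_count: float = 0.5
    domains: dict | None = None

    def learn(self, train: pd.DataFrame) -> DiscreteBayesNet:
        data = DiscreteData(train, domains=self.domains)
        if self.algorithm == "hc":
            dag = hill_climb(data, self.search)
        elif self.algorithm == "tabu":
            dag = tabu_search(data, self.search)
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        return fit_cpts(dag, data, pseudo_count=self.pseudo_count)


@dataclass
class ValidationReport:
    node_mean_error: dict[str, float]
    node_sd_error: dict[str, float]
    overall_mean_error: float
    n_reps: int
    test_fraction: float
    seed: int
    notes: list[str] = field(default_factory=list)

    def to_text(self, delimiter: str = "\t") -> str:
        lines = [delimiter.join(["node", "mean_error", "sd_error"])]
        for node in self.node_mean_error:
            lines.append(
                delimiter.join(
                    [
                        node,
                        f"{self.node_mean_error[node]:.6f}",
                        f"{self.node_sd_error[node]:.6f}",
                    ]
                )
            )
        lines.append(delimiter.join(["OVERALL", f"{self.overall_mean_error:.6f}", ""]))
        return "\n".join(lines)


def repeated_holdout(
    data: pd.DataFrame,
    model_spec: ModelSpec,
    target_nodes: Sequence[str] | None = None,
    k_reps: int = 10,
    test_fraction: float = 0.30,
    n_samples: int = 1000,
    seed: int = 0,
    evidence_mode: str = "full",
) -> ValidationReport:
    """Repeated hold-out validation of the full learning pipeline.

    Each repetition draws a fresh test subsample (``test_fraction`` of the
    rows), re-learns structure and parameters on the complement, then
    predicts every target node for every test row by likelihood weighting,
    conditioning on all other observed variables (``evidence_mode='full'``)
    or on the covariates only (``'covariates'``).
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    if k_reps < 1:
        raise ValueError("k_reps must be >= 1")
    columns = list(data.columns)
    if target_nodes is None:
        target_nodes = [c for c in columns if c.startswith(("N@", "Q@"))]
    notes: list[str] = []
    errors = {node: np.zeros(k_reps) for node in target_nodes}
    master = np.random.SeedSequence(seed)
    for rep, ss in enumerate(master.spawn(k_reps)):
        rng = np.random.default_rng(ss)
        n = len(data)
        test_idx = rng.choice(n, size=max(1, int(round(test_fraction * n))), replace=False)
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
        train, test = data[~test_mask], data[test_mask]
        net = model_spec.learn(train)
        for node in target_nodes:
            if test[node].nunique() < 2:
                notes.append(f"rep {rep}: test fold has a single level for {node}")
            factor_nodes = {node} | set(net.dag.children(node))
            wrong = 0
            for _, row in test.iterrows():
                if evidence_mode == "full":
                    evidence = {c: row[c] for c in columns if c != node}
                elif evidence_mode == "covariates":
                    evidence = {
                        c: row[c] for c in columns if not c.startswith(("N@", "Q@"))
                    }
                else:
                    raise ValueError(f"unknown evidence_mode {evidence_mode!r}")
                pred = posterior_classify(
                    net, evidence, node, n_samples=n_samples, seed=rng,
                    _factor_nodes=factor_nodes if evidence_mode == "full" else None,
                )
                if pred is None or pred != row[node]:
                    wrong += 1
            errors[node][rep] = wrong / len(test)
    node_mean = {n: float(np.mean(e)) for n, e in errors.items()}
    node_sd = {n: float(np.std(e, ddof=1)) if k_reps > 1 else 0.0 for n, e in errors.items()}
    return ValidationReport(
        node_mean_error=node_mean,
        node_sd_error=node_sd,
        overall_mean_error=float(np.mean(list(node_mean.values()))),
        n_reps=k_reps,
        test_fraction=test_fraction,
        seed=seed,
        notes=notes,
    )
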