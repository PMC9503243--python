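"""Discrete Bayesian-network containers: DAGs, CPTs and the 2-slice
temporal network (prior + per-slice transition models).

State nodes of the temporal network are named ``N@t`` and ``Q@t`` with a
1-based slice index; covariates keep their user-supplied names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Dag",
    "Cpt",
    "DiscreteBayesNet",
    "TwoSliceTBN",
    "EdgeConstraints",
    "is_acyclic",
    "joint_probability",
    "unroll_joint",
    "n_node",
    "q_node",
]

PROB_TOL = 1e-9


def n_node(t: int) -> str:
    """Name of the survival-state node at slice ``t`` (1-based)."""
    return f"N@{t}"


def q_node(t: int) -> str:
    """Name of the censorship-state node at slice ``t`` (1-based)."""
    return f"Q@{t}"


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph over named variables."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        known = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
        if not is_acyclic(self):
            raise ValueError("graph contains a directed cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self.edges if b == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(b for a, b in self.edges if a == node))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.topological_sort(self.to_networkx()))
        return order

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for a, b in sorted(self.edges):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)

    def to_edge_list(self) -> str:
        return "\n".join(f"{a}\t{b}" for a, b in sorted(self.edges))


def is_acyclic(dag: Dag | Iterable[tuple[str, str]]) -> bool:
    """True iff the directed graph has no cycle (topological-sort test)."""
    if isinstance(dag, Dag):
        g = nx.DiGraph(list(dag.edges))
        g.add_nodes_from(dag.nodes)
    else:
        g = nx.DiGraph(list(dag))
    try:
        list(nx.topological_sort(g))
        return True
    except nx.NetworkXUnfeasible:
        return False


def _level_index(levels: Sequence, value) -> int:
    try:
        return levels.index(value)
    except ValueError:
        raise KeyError(f"level {value!r} not in declared domain {levels}") from None


@dataclass
class Cpt:
    """Conditional probability table of one discrete node.

    ``table`` has one row per parent-level combination (mixed-radix order,
    first parent most significant) and one column per child level.  Level
    order is the declared order; use sorted labels when no order is given.
    """

    child: str
    parents: tuple[str, ...]
    levels: tuple
    parent_levels: tuple[tuple, ...]
    table: np.ndarray
    flagged_rows: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.levels = tuple(self.levels)
        self.parent_levels = tuple(tuple(pl) for pl in self.parent_levels)
        self.table = np.asarray(self.table, dtype=float)
        n_rows = int(np.prod([len(pl) for pl in self.parent_levels])) if self.parents else 1
        if self.table.shape != (n_rows, len(self.levels)):
            raise ValueError(
                f"CPT for {self.child!r}: table shape {self.table.shape} != "
                f"({n_rows}, {len(self.levels)})"
            )
        self.validate()

    def validate(self) -> None:
        if np.any(self.table < -PROB_TOL) or np.any(self.table > 1 + PROB_TOL):
            raise ValueError(f"CPT for {self.child!r} has entries outside [0, 1]")
        sums = self.table.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > PROB_TOL):
            raise ValueError(f"CPT rows for {self.child!r} do not sum to 1")

    @property
    def n_parent_configs(self) -> int:
        return self.table.shape[0]

    def row_index(self, parent_values: Sequence) -> int:
        idx = 0
        for value, levels in zip(parent_values, self.parent_levels):
            idx = idx * len(levels) + _level_index(levels, value)
        return idx

    def row(self, parent_values: Sequence = ()) -> np.ndarray:
        return self.table[self.row_index(parent_values)]

    def prob(self, child_value, parent_values: Sequence = ()) -> float:
        return float(self.row(parent_values)[_level_index(self.levels, child_value)])


@dataclass
class DiscreteBayesNet:
    """A DAG plus one CPT per node."""

    dag: Dag
    cpts: dict[str, Cpt]

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for node {node!r}")
            if tuple(self.cpts[node].parents) != self.dag.parents(node):
                raise ValueError(
                    f"CPT parents for {node!r} do not match DAG parents"
                )

    def levels(self, node: str) -> tuple:
        return self.cpts[node].levels

    def joint_probability(self, assignment: Mapping[str, object]) -> float:
        return joint_probability(self, assignment)

    def log_joint(self, assignment: Mapping[str, object]) -> float:
        total = 0.0
        for node in self.dag.nodes:
            cpt = self.cpts[node]
            p = cpt.prob(assignment[node], [assignment[a] for a in cpt.parents])
            if p == 0.0:
                return -math.inf
            total += math.log(p)
        return total

    def enumerate_assignments(self):
        """Yield every full assignment (for small nets / enumeration oracles)."""
        names = list(self.dag.nodes)
        doms = [self.cpts[n].levels for n in names]
        idx = [0] * len(names)
        while True:
            yield {n: dom[i] for n, dom, i in zip(names, doms, idx)}
            for pos in reversed(range(len(names))):
                idx[pos] += 1
                if idx[pos] < len(doms[pos]):
                    break
                idx[pos] = 0
            else:
                return

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Vectorized ancestral sampling; returns level *indices* per node."""
        out: dict[str, np.ndarray] = {}
        for node in self.dag.topological_order():
            cpt = self.cpts[node]
            if not cpt.parents:
                probs = np.broadcast_to(cpt.table[0], (n, len(cpt.levels)))
            else:
                rows = np.zeros(n, dtype=np.int64)
                for parent, pl in zip(cpt.parents, cpt.parent_levels):
                    rows = rows * len(pl) + out[parent]
                probs = cpt.table[rows]
            u = rng.random(n)
            out[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return out


def joint_probability(net: DiscreteBayesNet, assignment: Mapping[str, object]) -> float:
    """Joint probability of a full assignment as the product of CPT factors."""
    missing = [n for n in net.dag.nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment missing nodes: {missing}")
    p = 1.0
    for node in net.dag.nodes:
        cpt = net.cpts[node]
        p *= cpt.prob(assignment[node], [assignment[a] for a in cpt.parents])
    return p


@dataclass
class EdgeConstraints:
    """Edges forced present (whitelist) and forbidden (blacklist)."""

    whitelist: frozenset[tuple[str, str]] = frozenset()
    blacklist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        self.whitelist = frozenset(tuple(e) for e in self.whitelist)
        self.blacklist = frozenset(tuple(e) for e in self.blacklist)
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ValueError(f"edges both white- and blacklisted: {sorted(overlap)}")
        if not is_acyclic(self.whitelist):
            raise ValueError("whitelist edges alone contain a cycle")

    def satisfied_by(self, edges: Iterable[tuple[str, str]]) -> bool:
        es = set(tuple(e) for e in edges)
        return self.whitelist <= es and not (self.blacklist & es)


@dataclass
class TwoSliceTBN:
    """Prior network plus per-slice transition CPTs of the temporal model.

    ``prior`` covers the covariates and the slice-1 state nodes
    (``N@1``, ``Q@1``).  ``transition[t]`` maps each slice-``t`` state node
    (t >= 2) to its CPT, whose parents may only be slice-(t-1) state nodes
    and covariates (Markov order 1).  Tables are slice-specific because the
    conditional survival fraction changes from interval to interval.
    """

    prior: DiscreteBayesNet
    transition: dict[int, dict[str, Cpt]]
    covariate_names: tuple[str, ...]
    # optional fitting context: pooled per-slice survival factors, the
    # pooled event/risk-set counts and the real slice times
    pooled_survival: np.ndarray | None = None
    counts: object | None = None
    slice_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        allowed_cov = set(self.covariate_names)
        for t, cpts in self.transition.items():
            prev = {n_node(t - 1), q_node(t - 1)}
            for name, cpt in cpts.items():
                bad = [p for p in cpt.parents if p not in prev | allowed_cov]
                if bad:
                    raise ValueError(
                        f"transition CPT {name!r} at slice {t} has parents {bad} "
                        "outside the previous slice and the covariates"
                    )

    @property
    def n_slices(self) -> int:
        return 1 + len(self.transition)

    def unrolled(self) -> DiscreteBayesNet:
        """Explicit static network over all slices (enumeration oracle)."""
        nodes = list(self.prior.dag.nodes)
        edges = set(self.prior.dag.edges)
        cpts = dict(self.prior.cpts)
        for t in sorted(self.transition):
            for name, cpt in self.transition[t].items():
                nodes.append(name)
                cpts[name] = cpt
                for p in cpt.parents:
                    edges.add((p, name))
        return DiscreteBayesNet(Dag(nodes, edges), cpts)


def unroll_joint(tbn: TwoSliceTBN, trajectory: Mapping[str, object]) -> float:
    """Joint probability of a full trajectory under the temporal model.

    The prior factorizes the slice-1 variables and covariates; each later
    slice contributes its transition factors.  ``trajectory`` must assign
    every covariate and every ``N@t`` / ``Q@t`` node.
    """
    p = joint_probability(tbn.prior, {k: trajectory[k] for k in tbn.prior.dag.nodes})
    for t in sorted(tbn.transition):
        for name, cpt in tbn.transition[t].items():
            if name not in trajectory:
                raise ValueError(f"trajectory missing state node {name!r}")
            p *= cpt.prob(trajectory[name], [trajectory[a] for a in cpt.parents])
    return p


def cpt_to_text(cpt: Cpt, delimiter: str = "\t") -> str:
    """One row per parent combination: parent levels then child probabilities."""
    header = list(cpt.parents) + [f"P({cpt.child}={lv})" for lv in cpt.levels]
    lines = [delimiter.join(map(str, header))]
    n_rows = cpt.n_parent_configs
    for r in range(n_rows):
        combo = []
        rem = r
        for pl in reversed(cpt.parent_levels):
            combo.append(pl[rem % len(pl)])
            rem //= len(pl)
        combo.reverse()
        lines.append(
            delimiter.join([str(v) for v in combo] + [f"{x:.10g}" for x in cpt.table[r]])
        )
    return "\n".join(lines)
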