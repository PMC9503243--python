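"""Score-based DAG structure search: greedy hill-climbing and tabu search.

Both searches use the canonical single-edge move set (add, delete, reverse)
under whitelist/blacklist constraints, with family-level score caching so a
move is evaluated by rescoring only the affected child families.  Ties
between equal-score moves are broken deterministically by lexicographic
(child, parent, move-type) order, so runs replay exactly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn import Dag, EdgeConstraints, n_node, q_node
from .scores import DiscreteData, local_score

__all__ = ["SearchConfig", "hill_climb", "tabu_search", "temporal_constraints"]

_EPS = 1e-10


@dataclass
class SearchConfig:
    score_name: str = "bic"
    iss: float = 1.0
    constraints: EdgeConstraints = field(default_factory=EdgeConstraints)
    max_iter: int = 1000
    tabu_length: int = 10
    tabu_max_worsening_moves: int = 100
    random_seed: int = 0
    max_parents: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tabu_length < 1:
            raise ValueError("tabu_length must be >= 1")


class _SearchState:
    """Mutable DAG with incremental family scoring."""

    def __init__(self, data: DiscreteData, nodes: tuple[str, ...], config: SearchConfig):
        self.data = data
        self.nodes = nodes
        self.config = config
        self.parents: dict[str, frozenset[str]] = {n: frozenset() for n in nodes}
        self.children: dict[str, set[str]] = {n: set() for n in nodes}
        self._cache: dict[tuple[str, frozenset[str]], float] = {}
        for a, b in config.constraints.whitelist:
            self._apply_add(a, b)

    # -- scoring ---------------------------------------------------------
    def family_score(self, child: str, parents: frozenset[str]) -> float:
        key = (child, parents)
        if key not in self._cache:
            fam = self.data.family_counts(child, sorted(parents))
            self._cache[key] = local_score(self.config.score_name, fam, iss=self.config.iss)
        return self._cache[key]

    def total_score(self) -> float:
        return sum(self.family_score(n, self.parents[n]) for n in self.nodes)

    # -- structure -------------------------------------------------------
    def edges(self) -> set[tuple[str, str]]:
        return {(a, b) for b, ps in self.parents.items() for a in ps}

    def _apply_add(self, a: str, b: str) -> None:
        self.parents[b] = self.parents[b] | {a}
        self.children[a].add(b)

    def _apply_delete(self, a: str, b: str) -> None:
        self.parents[b] = self.parents[b] - {a}
        self.children[a].discard(b)

    def apply(self, move: tuple[str, str, str]) -> None:
        kind, a, b = move
        if kind == "add":
            self._apply_add(a, b)
        elif kind == "delete":
            self._apply_delete(a, b)
        elif kind == "reverse":
            self._apply_delete(a, b)
            self._apply_add(b, a)
        else:  # pragma: no cover
            raise ValueError(kind)

    def reaches(self, src: str, dst: str, skip_edge: tuple[str, str] | None = None) -> bool:
        """Is there a directed path src -> ... -> dst (optionally ignoring one edge)?"""
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for v in self.children[u]:
                if skip_edge is not None and (u, v) == skip_edge:
                    continue
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    # -- move generation -------------------------------------------------
    def legal_moves(self) -> list[tuple[str, str, str]]:
        cfg = self.config
        wl, bl = cfg.constraints.whitelist, cfg.constraints.blacklist
        moves: list[tuple[str, str, str]] = []
        for b in self.nodes:
            for a in self.nodes:
                if a == b:
                    continue
                present = a in self.parents[b]
                if not present:
                    if (a, b) in bl:
                        continue
                    if cfg.max_parents is not None and len(self.parents[b]) >= cfg.max_parents:
                        continue
                    if self.reaches(b, a):
                        continue  # would create a cycle
                    moves.append(("add", a, b))
                else:
                    if (a, b) not in wl:
                        moves.append(("delete", a, b))
                        if (b, a) not in bl and not (
                            cfg.max_parents is not None
                            and len(self.parents[a]) >= cfg.max_parents
                        ):
                            if not self.reaches(a, b, skip_edge=(a, b)):
                                moves.append(("reverse", a, b))
        # deterministic tie-break order: (child, parent, move kind)
        moves.sort(key=lambda m: (m[2], m[1], m[0]))
        return moves

    def delta(self, move: tuple[str, str, str]) -> float:
        kind, a, b = move
        if kind == "add":
            return self.family_score(b, self.parents[b] | {a}) - self.family_score(
                b, self.parents[b]
            )
        if kind == "delete":
            return self.family_score(b, self.parents[b] - {a}) - self.family_score(
                b, self.parents[b]
            )
        # reverse: child b loses a, child a gains b
        d = self.family_score(b, self.parents[b] - {a}) - self.family_score(b, self.parents[b])
        d += self.family_score(a, self.parents[a] | {b}) - self.family_score(a, self.parents[a])
        return d


def _prepare(data, config: SearchConfig) -> tuple[DiscreteData, tuple[str, ...]]:
    if isinstance(data, pd.DataFrame):
        data = DiscreteData(data)
    nodes = data.columns
    for a, b in config.constraints.whitelist | config.constraints.blacklist:
        if a not in nodes or b not in nodes:
            raise ValueError(f"constraint edge ({a!r}, {b!r}) references unknown column")
    return data, nodes


def hill_climb(data, config: SearchConfig | None = None) -> Dag:
    """Greedy ascent over single-edge moves; stops at a local optimum."""
    config = config or SearchConfig()
    data, nodes = _prepare(data, config)
    state = _SearchState(data, nodes, config)
    for _ in range(config.max_iter):
        best_move, best_delta = None, _EPS
        for move in state.legal_moves():
            d = state.delta(move)
            if d > best_delta:
                best_move, best_delta = move, d
        if best_move is None:
            break
        state.apply(best_move)
    return Dag(nodes, state.edges())


def _undo_of(move: tuple[str, str, str]) -> tuple[str, str, str]:
    kind, a, b = move
    if kind == "add":
        return ("delete", a, b)
    if kind == "delete":
        return ("add", a, b)
    return ("reverse", b, a)


def tabu_search(
    data, config: SearchConfig | None = None, start: Dag | None = None
) -> Dag:
    """Tabu search: escapes local optima via bounded worsening moves.

    Keeps a FIFO list of the undo moves of the last ``tabu_length``
    accepted moves and forbids them; returns the best DAG visited.
    """
    config = config or SearchConfig()
    data, nodes = _prepare(data, config)
    state = _SearchState(data, nodes, config)
    if start is not None:
        if not config.constraints.satisfied_by(start.edges):
            raise ValueError("start DAG violates the edge constraints")
        for a, b in start.edges - state.edges():
            state._apply_add(a, b)
    tabu: deque[tuple[str, str, str]] = deque(maxlen=config.tabu_length)
    best_edges = state.edges()
    best_score = current = state.total_score()
    worsening = 0
    for _ in range(config.max_iter):
        best_move, best_delta = None, -np.inf
        for move in state.legal_moves():
            if move in tabu:
                continue
            d = state.delta(move)
            if d > best_delta + _EPS:
                best_move, best_delta = move, d
        if best_move is None:
            break
        state.apply(best_move)
        tabu.append(_undo_of(best_move))
        current += best_delta
        if current > best_score + _EPS:
            best_score = current
            best_edges = state.edges()
            worsening = 0
        else:
            worsening += 1
            if worsening >= config.tabu_max_worsening_moves:
                break
    return Dag(nodes, best_edges)


def temporal_constraints(
    covariate_names,
    n_slices: int,
    allow_covariate_edges: bool = True,
) -> EdgeConstraints:
    """Structural constraints of the survival 2-TBN on the unrolled graph.

    The whitelist forces the N/Q state chain (each slice-t state depends on
    both slice-(t-1) states).  The blacklist forbids everything except
    covariate-to-covariate and covariate-to-state edges: no edges out of
    state nodes, no within-slice state edges, no links between non-adjacent
    slices and no future-to-past edges.
    """
    covs = list(covariate_names)
    states = [n_node(t) for t in range(1, n_slices + 1)] + [
        q_node(t) for t in range(1, n_slices + 1)
    ]
    whitelist = set()
    for t in range(2, n_slices + 1):
        for prev in (n_node(t - 1), q_node(t - 1)):
            whitelist.add((prev, n_node(t)))
            whitelist.add((prev, q_node(t)))
    allowed = set(whitelist)
    if allow_covariate_edges:
        allowed |= {(z, s) for z in covs for s in states}
        allowed |= {(z1, z2) for z1 in covs for z2 in covs if z1 != z2}
    all_nodes = covs + states
    blacklist = {
        (a, b)
        for a in all_nodes
        for b in all_nodes
        if a != b and (a, b) not in allowed
    }
    return EdgeConstraints(whitelist=frozenset(whitelist), blacklist=frozenset(blacklist))
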