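"""Decomposable network scores for score-based structure search.

All six scores used here — multinomial log-likelihood, AIC, BIC, BDe(u),
BDs and K2 — decompose over node families, so a network score is the sum
of local family scores and a single-edge move changes exactly one term.

Conventions (larger is better, everything in log space):

* ``loglik``: maximized multinomial log-likelihood; a parent configuration
  with no observations contributes nothing (0 * log 0 = 0).
* ``aic`` = loglik - k,  ``bic`` = loglik - (k/2) * ln n, with
  k = (r - 1) * prod(parent cardinalities) free parameters per family.
* ``bde``: BDeu marginal likelihood with imaginary sample size ``iss``
  spread uniformly over all parent configurations and child levels.
* ``bds``: BDeu variant assigning the imaginary mass only to parent
  configurations actually observed in the data.
* ``k2``: Cooper-Herskovits marginal likelihood (Dirichlet(1) per cell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .bn import Dag

__all__ = ["FamilyCounts", "DiscreteData", "local_score", "network_score", "SCORE_NAMES"]

SCORE_NAMES = ("loglik", "aic", "bic", "bde", "bds", "k2")


@dataclass
class FamilyCounts:
    """Sufficient statistics of one node family.

    ``counts[j, k]`` is the number of cases with parent configuration ``j``
    and child level ``k``; ``n`` is the total sample size of the dataset
    (used by the BIC penalty even when some configurations are empty).
    """

    child: str
    parents: tuple[str, ...]
    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a (configs x levels) matrix")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")


class DiscreteData:
    """A discrete table with cached integer codes and declared domains."""

    def __init__(self, df: pd.DataFrame, domains: Mapping[str, Sequence] | None = None):
        self.df = df
        self.columns = tuple(df.columns)
        self.domains: dict[str, tuple] = {}
        self.codes: dict[str, np.ndarray] = {}
        self.n = len(df)
        for col in df.columns:
            col_vals = df[col]
            if domains and col in domains:
                levels = tuple(domains[col])
            else:
                levels = tuple(sorted(pd.unique(col_vals.dropna())))
            cat = pd.Categorical(col_vals, categories=list(levels))
            codes = np.asarray(cat.codes, dtype=np.int64)
            if np.any(codes < 0):
                raise ValueError(
                    f"column {col!r} contains values outside its declared domain"
                )
            self.domains[col] = levels
            self.codes[col] = codes

    def card(self, col: str) -> int:
        return len(self.domains[col])

    def family_counts(self, child: str, parents: Sequence[str]) -> FamilyCounts:
        parents = tuple(parents)
        r = self.card(child)
        q = int(np.prod([self.card(p) for p in parents])) if parents else 1
        rows = np.zeros(self.n, dtype=np.int64)
        for p in parents:
            rows = rows * self.card(p) + self.codes[p]
        flat = rows * r + self.codes[child]
        counts = np.bincount(flat, minlength=q * r).reshape(q, r)
        return FamilyCounts(child=child, parents=parents, counts=counts, n=self.n)


def _loglik(counts: np.ndarray) -> float:
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * (np.log(counts) - np.log(row_tot))
    return float(np.nansum(np.where(counts > 0, term, 0.0)))


def _dirichlet_marginal(counts: np.ndarray, alpha_cell: np.ndarray) -> float:
    """log marginal likelihood with per-cell Dirichlet pseudo-counts."""
    alpha_row = alpha_cell.sum(axis=1)
    n_row = counts.sum(axis=1)
    val = gammaln(alpha_row) - gammaln(alpha_row + n_row)
    val = val + (gammaln(alpha_cell + counts) - gammaln(alpha_cell)).sum(axis=1)
    return float(val.sum())


def local_score(score_name: str, family: FamilyCounts, iss: float = 1.0) -> float:
    """Local (per-family) score; see module docstring for conventions."""
    counts = family.counts
    q, r = counts.shape
    if score_name == "loglik":
        return _loglik(counts)
    if score_name == "aic":
        return _loglik(counts) - (r - 1) * q
    if score_name == "bic":
        return _loglik(counts) - 0.5 * (r - 1) * q * np.log(family.n)
    if score_name == "bde":
        if iss <= 0:
            raise ValueError("equivalent sample size must be positive")
        alpha = np.full((q, r), iss / (q * r))
        return _dirichlet_marginal(counts, alpha)
    if score_name == "bds":
        if iss <= 0:
            raise ValueError("equivalent sample size must be positive")
        observed = counts.sum(axis=1) > 0
        q_obs = max(int(observed.sum()), 1)
        alpha = np.zeros((q, r))
        alpha[observed] = iss / (q_obs * r)
        return _dirichlet_marginal(counts[observed], alpha[observed])
    if score_name == "k2":
        alpha = np.ones((q, r))
        return _dirichlet_marginal(counts, alpha)
    raise ValueError(f"unknown score {score_name!r}; expected one of {SCORE_NAMES}")


def network_score(
    score_name: str,
    dag: Dag,
    data: DiscreteData | pd.DataFrame,
    iss: float = 1.0,
) -> float:
    """Sum of local family scores over every node of the DAG."""
    if isinstance(data, pd.DataFrame):
        data = DiscreteData(data)
    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"DAG nodes missing from data: {missing}")
    total = 0.0
    for node in dag.nodes:
        fam = data.family_counts(node, dag.parents(node))
        total += local_score(score_name, fam, iss=iss)
    return total
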