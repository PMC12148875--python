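"""Conditional probability tables and their maximum-likelihood estimation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CategoricalDataset,
    Dag,
    SchemaError,
    crosstab_counts,
    topological_order,
    validate_dag,
)


class EvaluationError(ValueError):
    """A likelihood evaluation required an unobserved (flagged) CPT row."""


@dataclass(frozen=True)
class Cpt:
    """One node's table: rows = parent configurations, columns = node levels.

    Parent configurations are indexed with parents in sorted name order and
    the last sorted parent's level index varying fastest (row-major). Rows
    flagged in ``unobserved`` had no supporting data and hold a uniform
    distribution as a total-function fallback.
    """

    node: str
    parents: tuple[str, ...]
    parent_cards: tuple[int, ...]
    table: np.ndarray  # (n_configs, r_node)
    unobserved: np.ndarray = field(default=None)  # (n_configs,) bool

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        n_cfg = int(np.prod(self.parent_cards)) if self.parents else 1
        if table.shape[0] != n_cfg:
            raise SchemaError(f"{self.node}: expected {n_cfg} rows, got {table.shape[0]}")
        unobs = self.unobserved
        if unobs is None:
            unobs = np.zeros(table.shape[0], dtype=bool)
        object.__setattr__(self, "unobserved", np.asarray(unobs, dtype=bool))
        if np.any(table < -1e-12) or np.any(table > 1 + 1e-12):
            raise SchemaError(f"{self.node}: probabilities outside [0, 1]")
        rows = table.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise SchemaError(f"{self.node}: CPT rows must sum to 1")

    @property
    def strides(self) -> np.ndarray:
        strides = np.ones(len(self.parents), dtype=np.int64)
        for i in range(len(self.parents) - 2, -1, -1):
            strides[i] = strides[i + 1] * self.parent_cards[i + 1]
        return strides

    def config_index(self, parent_levels: Mapping[str, int]) -> int:
        idx = 0
        for p, s in zip(self.parents, self.strides):
            idx += parent_levels[p] * int(s)
        return idx

    def prob(self, level: int, parent_levels: Mapping[str, int]) -> float:
        return float(self.table[self.config_index(parent_levels), level])


class CptSet:
    """All CPTs of a network; together with a Dag this is a full Bayesian network."""

    def __init__(self, cpts: Mapping[str, Cpt] | Sequence[Cpt]):
        if not isinstance(cpts, Mapping):
            cpts = {c.node: c for c in cpts}
        self.cpts = dict(cpts)

    def __getitem__(self, node: str) -> Cpt:
        return self.cpts[node]

    def __contains__(self, node: str) -> bool:
        return node in self.cpts

    def nodes(self) -> list[str]:
        return sorted(self.cpts)

    def has_unobserved(self) -> bool:
        return any(c.unobserved.any() for c in self.cpts.values())


def fit_mle_cpts(data: CategoricalDataset, dag: Dag, pseudocount: float = 0.0) -> CptSet:
    """MLE (optionally Dirichlet-smoothed) CPTs for every node of the DAG.

    entry(node=k | parents=j) = (N_jk + pseudocount) / (N_j + pseudocount * r_node).
    With pseudocount 0, parent configurations never seen in the data are
    returned uniform and flagged ``unobserved`` (with a warning) so that
    downstream inference stays a total function.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if data.n == 0:
        raise ValueError("cannot fit on an empty dataset")
    ok, diag = validate_dag(dag)
    if not ok:
        raise ValueError(diag)
    if set(dag.nodes) - set(data.variables):
        missing = sorted(set(dag.nodes) - set(data.variables))
        raise SchemaError(f"DAG nodes missing from dataset: {missing}")

    cpts = {}
    for node in sorted(dag.nodes):
        parents = dag.parents(node)
        counts, _ = crosstab_counts(data, node, parents)
        r = data.spec(node).cardinality
        smoothed = counts + pseudocount
        row_tot = smoothed.sum(axis=1, keepdims=True)
        empty = row_tot[:, 0] == 0  # only possible with pseudocount 0
        with np.errstate(invalid="ignore"):
            table = smoothed / row_tot
        if empty.any():
            warnings.warn(
                f"{node}: {int(empty.sum())} unobserved parent configuration(s) "
                "returned as uniform",
                stacklevel=2,
            )
            table[empty] = 1.0 / r
        cards = tuple(data.spec(p).cardinality for p in parents)
        cpts[node] = Cpt(node, parents, cards, table, empty)
    return CptSet(cpts)


def loglik(data: CategoricalDataset, dag: Dag, cpts: CptSet) -> float:
    """Sum over records and nodes of ln P(observed level | observed parent levels).

    Returns -inf if a zero-probability entry is hit. Raises
    :class:`EvaluationError` if an unobserved-flagged row is needed.
    """
    total = 0.0
    for node in topological_order(dag):
        cpt = cpts[node]
        cfg = np.zeros(data.n, dtype=np.int64)
        for p, s in zip(cpt.parents, cpt.strides):
            cfg += data.column(p) * int(s)
        if cpt.unobserved.any() and cpt.unobserved[cfg].any():
            raise EvaluationError(
                f"{node}: record requires an unobserved parent configuration"
            )
        probs = cpt.table[cfg, data.column(node)]
        if np.any(probs == 0):
            return float("-inf")
        total += float(np.log(probs).sum())
    return total
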