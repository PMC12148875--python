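"""Exact conditional-probability queries by enumeration or variable elimination."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import Dag, SchemaError, VariableSpec
from .parameters import CptSet


class UndefinedConditionalError(ValueError):
    """The evidence has probability zero under the network."""


@dataclass(frozen=True)
class Query:
    """One conditional-probability question: P(target node = level | evidence)."""

    target: tuple[str, int]
    evidence: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence", dict(self.evidence))
        if self.target[0] in self.evidence:
            raise SchemaError(f"target {self.target[0]!r} cannot also be evidence")


def _cardinalities(schema: Sequence[VariableSpec], dag: Dag) -> dict[str, int]:
    cards = {v.name: v.cardinality for v in schema}
    missing = set(dag.nodes) - set(cards)
    if missing:
        raise SchemaError(f"schema missing nodes: {sorted(missing)}")
    return cards


def joint_probability(
    dag: Dag, cpts: CptSet, assignment: Mapping[str, int], warn_unobserved: bool = True
) -> float:
    """Chain-rule product P(assignment) = prod_node P(level | parent levels)."""
    if set(assignment) != set(dag.nodes):
        raise SchemaError("assignment must cover every node")
    prob = 1.0
    for node in sorted(dag.nodes):  # fixed order => bit-reproducible float product
        cpt = cpts[node]
        idx = cpt.config_index(assignment)
        if warn_unobserved and cpt.unobserved[idx]:
            warnings.warn(f"{node}: unobserved CPT row used in joint probability", stacklevel=2)
        prob *= float(cpt.table[idx, assignment[node]])
    return prob


def query_conditional(
    dag: Dag,
    cpts: CptSet,
    query: Query,
    schema: Sequence[VariableSpec],
    method: str = "eliminate",
) -> float:
    """P(target | evidence), exact.

    ``method`` is ``"eliminate"`` (sum-product variable elimination, the fast
    path) or ``"enumerate"`` (full-joint enumeration, the reference path);
    both agree to ~1e-12.
    """
    cards = _cardinalities(schema, dag)
    node, level = query.target
    if node not in cards:
        raise SchemaError(f"unknown target node {node!r}")
    if not 0 <= level < cards[node]:
        raise SchemaError(f"{node}: level index {level} out of range")
    for ev, lv in query.evidence.items():
        if ev not in cards:
            raise SchemaError(f"unknown evidence node {ev!r}")
        if not 0 <= lv < cards[ev]:
            raise SchemaError(f"{ev}: level index {lv} out of range")

    if method == "enumerate":
        num, den = _enumerate(dag, cpts, cards, query)
    elif method == "eliminate":
        den = _eliminate(dag, cpts, cards, dict(query.evidence))
        num = _eliminate(dag, cpts, cards, {**query.evidence, node: level})
    else:
        raise ValueError(f"unknown method {method!r}")

    if den <= 0.0:
        raise UndefinedConditionalError("evidence has probability zero")
    return num / den


def _enumerate(
    dag: Dag, cpts: CptSet, cards: Mapping[str, int], query: Query
) -> tuple[float, float]:
    node, level = query.target
    free = sorted(n for n in dag.nodes if n not in query.evidence and n != node)
    num = den = 0.0
    target_levels = range(cards[node])
    for combo in itertools.product(*(range(cards[n]) for n in free)):
        assignment = dict(query.evidence)
        assignment.update(zip(free, combo))
        for tl in target_levels:
            assignment[node] = tl
            p = joint_probability(dag, cpts, assignment, warn_unobserved=False)
            den += p
            if tl == level:
                num += p
    return num, den


def _eliminate(
    dag: Dag, cpts: CptSet, cards: Mapping[str, int], evidence: Mapping[str, int]
) -> float:
    """Sum-product elimination of all non-evidence variables; returns P(evidence)."""
    # factors: (ordered var tuple, ndarray with one axis per var)
    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for node in sorted(dag.nodes):
        cpt = cpts[node]
        dims = cpt.parents + (node,)
        shape = cpt.parent_cards + (cards[node],)
        arr = cpt.table.reshape(shape)
        for var in dims:
            if var in evidence:
                axis = list(dims).index(var)
                arr = np.take(arr, evidence[var], axis=axis)
                dims = tuple(d for d in dims if d != var)
        factors.append((dims, arr))

    for var in sorted(n for n in dag.nodes if n not in evidence):
        touching = [f for f in factors if var in f[0]]
        rest = [f for f in factors if var not in f[0]]
        dims, arr = _multiply(touching, cards)
        axis = dims.index(var)
        arr = arr.sum(axis=axis)
        dims = tuple(d for d in dims if d != var)
        factors = rest + [(dims, arr)]

    dims, arr = _multiply(factors, cards)
    assert dims == ()
    return float(arr)


def _multiply(
    factors: list[tuple[tuple[str, ...], np.ndarray]], cards: Mapping[str, int]
) -> tuple[tuple[str, ...], np.ndarray]:
    all_vars = tuple(sorted({v for dims, _ in factors for v in dims}))
    out = np.ones(tuple(cards[v] for v in all_vars))
    for dims, arr in factors:
        # broadcast arr into the joint axis order
        expand = arr
        order = [dims.index(v) for v in all_vars if v in dims]
        expand = np.transpose(arr, axes=order) if dims else arr
        shape = tuple(cards[v] if v in dims else 1 for v in all_vars)
        out = out * expand.reshape(shape)
    return all_vars, out
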