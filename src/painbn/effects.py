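"""Odds-ratio statistics: 2x2 contingency extraction, OR, Woolf log-OR CIs,
and the per-arc relationship report.

Conventions:
  * OR = (p1 / (1 - p1)) / (p2 / (1 - p2)) with p1 = P(event | evidence),
    p2 = P(event | no evidence); equivalently (a/b)/(c/d) from counts.
  * SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d); CI = exp(ln OR -+ z * SE).
  * Multi-level evidence (age) is dichotomized level-vs-rest.
  * Reported conditional probabilities are empirical 2x2 frequencies; a
    model-based variant via exact inference is available separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .model import (
    CategoricalDataset,
    Dag,
    DEMOGRAPHIC,
    SchemaError,
    topological_order,
)


class ZeroCellError(ValueError):
    """A 2x2 cell is zero and no continuity correction was requested."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = event & evidence, b = no-event & evidence,
    c = event & no-evidence, d = no-event & no-evidence."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def p_event_given_evidence(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def p_event_given_no_evidence(self) -> float:
        return self.c / (self.c + self.d)

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RelationshipRow:
    """One evidence -> event association (one report row)."""

    evidence: str  # e.g. "age:senior" or "headache"
    event: str
    p_yes: float  # 100 * P(event=yes | evidence), percent
    p_no: float  # 100 * P(event=yes | no evidence), percent
    or_value: float
    ci_low: float
    ci_high: float
    counts: ContingencyTable2x2
    flags: tuple[str, ...] = ()


def contingency_2x2(
    data: CategoricalDataset,
    evidence: tuple[str, str | int],
    event: tuple[str, str | int],
) -> ContingencyTable2x2:
    """Exact crosstab counts, dichotomizing multi-level evidence level-vs-rest."""
    if data.n == 0:
        raise ValueError("empty dataset")
    ev_node, ev_level = evidence
    tg_node, tg_level = event
    if ev_node == tg_node:
        raise SchemaError("evidence and event variables must differ")
    ev_idx = ev_level if isinstance(ev_level, int) else data.spec(ev_node).level_index(ev_level)
    tg_idx = tg_level if isinstance(tg_level, int) else data.spec(tg_node).level_index(tg_level)

    ev_col = data.column(ev_node) == ev_idx
    tg_col = data.column(tg_node) == tg_idx
    a = int((ev_col & tg_col).sum())
    b = int((ev_col & ~tg_col).sum())
    c = int((~ev_col & tg_col).sum())
    d = int((~ev_col & ~tg_col).sum())
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio_from_probs(p1: float, p2: float) -> float:
    """OR from two conditional probabilities; inf/0 at the boundary."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        if p1 == 1.0 or p2 == 0.0:
            return math.inf
        return 0.0
    return (p1 / (1.0 - p1)) / (p2 / (1.0 - p2))


def odds_ratio_from_counts(t: ContingencyTable2x2) -> float:
    if t.b == 0 or t.c == 0:
        return math.inf
    return (t.a / t.b) / (t.c / t.d) if t.d else 0.0


def _z(level: float) -> float:
    return float(norm.ppf(0.5 + level / 2.0))


def ci_from_counts(
    t: ContingencyTable2x2,
    level: float = 0.95,
    zero_cell: str = "error",
) -> tuple[float, float]:
    """Woolf CI for the odds ratio from 2x2 counts.

    ``zero_cell``: "error" (default) raises on any empty cell; "haldane"
    applies the +0.5 Haldane-Anscombe correction to all four cells.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if t.has_zero_cell():
        if zero_cell == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            raise ZeroCellError(f"zero cell in 2x2 table {t}")
    or_value = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _z(level)
    return math.exp(math.log(or_value) - z * se), math.exp(math.log(or_value) + z * se)


def relationship_row(
    data: CategoricalDataset,
    evidence: tuple[str, str | int],
    event: tuple[str, str | int],
    level: float = 0.95,
    zero_cell: str = "error",
) -> RelationshipRow:
    t = contingency_2x2(data, evidence, event)
    flags: list[str] = []
    if t.has_zero_cell():
        if zero_cell != "haldane":
            raise ZeroCellError(f"zero cell for {evidence} -> {event}")
        flags.append("haldane_correction")
        corrected = (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
        or_value = (corrected[0] / corrected[1]) / (corrected[2] / corrected[3])
    else:
        or_value = odds_ratio_from_counts(t)
    ci_low, ci_high = ci_from_counts(t, level=level, zero_cell=zero_cell)

    ev_node, ev_level = evidence
    ev_spec = data.spec(ev_node)
    ev_label = ev_level if isinstance(ev_level, str) else ev_spec.levels[ev_level]
    ev_name = f"{ev_node}:{ev_label}" if ev_spec.cardinality > 2 or ev_spec.role == DEMOGRAPHIC else ev_node
    return RelationshipRow(
        evidence=ev_name,
        event=event[0],
        p_yes=100.0 * t.p_event_given_evidence,
        p_no=100.0 * t.p_event_given_no_evidence,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        counts=t,
        flags=tuple(flags),
    )


def model_based_odds_ratio(
    dag,
    cpts,
    schema,
    evidence: tuple[str, int],
    event: tuple[str, int],
) -> tuple[float, float, float]:
    """OR from network-marginalized conditional probabilities ("model-based"
    mode, as opposed to the empirical 2x2 route used in reports).

    Returns (p1, p2, OR) with p1 = P(event | evidence level) and
    p2 = P(event | evidence not at that level), computed by exact inference.
    """
    from .inference import Query, query_conditional

    ev_node, ev_level = evidence
    p1 = query_conditional(dag, cpts, Query(event, {ev_node: ev_level}), schema)
    p_ev = query_conditional(dag, cpts, Query((ev_node, ev_level), {}), schema)
    p_event = query_conditional(dag, cpts, Query(event, {}), schema)
    if p_ev >= 1.0:
        raise ValueError("evidence complement has probability zero")
    p2 = (p_event - p1 * p_ev) / (1.0 - p_ev)
    return p1, p2, odds_ratio_from_probs(p1, p2)


def relationship_table(
    data: CategoricalDataset,
    dag: Dag,
    extra_pairs: Sequence[tuple[tuple[str, str | int], tuple[str, str | int]]] = (),
    level: float = 0.95,
    zero_cell: str = "error",
) -> list[RelationshipRow]:
    """One row per (parent -> pain child) arc of the DAG, plus any extra pairs.

    Multi-level demographic parents expand into one row per level
    (level-vs-rest). Row order: demographic parents first (schema order of
    the demographic variable, levels in declared order), then pain -> pain
    arcs with parents in topological order and children lexicographic.
    """
    specs = {v.name: v for v in data.schema}
    rows: list[RelationshipRow] = []

    demo_order = [v.name for v in data.schema if v.role == DEMOGRAPHIC]
    topo = topological_order(dag)

    for parent in demo_order:
        spec = specs[parent]
        children = sorted(c for p, c in dag.arcs if p == parent and specs[c].role == "pain")
        for child in children:
            if spec.cardinality > 2:
                levels = spec.levels
            else:
                levels = spec.levels[:1]  # binary demographic: first level vs rest
            for lv in levels:
                rows.append(relationship_row(data, (parent, lv), (child, "yes"), level, zero_cell))

    for parent in topo:
        if specs[parent].role == DEMOGRAPHIC:
            continue
        for child in sorted(c for p, c in dag.arcs if p == parent and specs[c].role == "pain"):
            rows.append(relationship_row(data, (parent, "yes"), (child, "yes"), level, zero_cell))

    for evidence, event in extra_pairs:
        rows.append(relationship_row(data, evidence, event, level, zero_cell))
    return rows
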