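"""Core domain types: categorical variables, datasets, DAGs, and arc constraints.

All graph operations are deterministic: wherever an order is needed, ties are
broken lexicographically by node name so that every downstream artifact is
bit-reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEMOGRAPHIC = "demographic"
PAIN = "pain"

#: Conventional level order for binary pain indicators: index 0 = "no", 1 = "yes".
PAIN_LEVELS = ("no", "yes")


class SchemaError(ValueError):
    """A dataset, graph, or query refers to unknown variables or levels."""


class CycleError(ValueError):
    """A directed cycle was found where a DAG is required."""


@dataclass(frozen=True)
class VariableSpec:
    """One categorical variable: its name, ordered level labels, and role."""

    name: str
    levels: tuple[str, ...]
    role: str = PAIN

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("variable name must be non-empty")
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise SchemaError(f"{self.name}: needs at least 2 levels")
        if len(set(levels)) != len(levels) or any(not lv for lv in levels):
            raise SchemaError(f"{self.name}: levels must be unique and non-empty")
        if self.role not in (DEMOGRAPHIC, PAIN):
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.role == PAIN and len(levels) != 2:
            raise SchemaError(f"{self.name}: pain variables are binary")

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    def level_index(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise SchemaError(f"{self.name}: unknown level {label!r}") from None


class CategoricalDataset:
    """A records x variables table of 0-based level indices with its schema."""

    def __init__(self, schema: Sequence[VariableSpec], records: np.ndarray):
        self.schema = list(schema)
        records = np.asarray(records, dtype=np.int64)
        if records.ndim != 2 or records.shape[1] != len(self.schema):
            raise SchemaError(
                f"records shape {records.shape} does not match schema width {len(self.schema)}"
            )
        names = [v.name for v in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        for j, var in enumerate(self.schema):
            col = records[:, j]
            if col.size and (col.min() < 0 or col.max() >= var.cardinality):
                raise SchemaError(f"{var.name}: level index out of range")
        self.records = records
        self._index = {v.name: j for j, v in enumerate(self.schema)}

    @property
    def n(self) -> int:
        return self.records.shape[0]

    @property
    def variables(self) -> list[str]:
        return [v.name for v in self.schema]

    def spec(self, name: str) -> VariableSpec:
        try:
            return self.schema[self._index[name]]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.records[:, self._index[name]]

    def to_dataframe(self) -> pd.DataFrame:
        """Labelled view of the data (one column per variable, cells = level labels)."""
        cols = {}
        for j, var in enumerate(self.schema):
            labels = np.asarray(var.levels, dtype=object)
            cols[var.name] = labels[self.records[:, j]]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: Sequence[VariableSpec]) -> "CategoricalDataset":
        schema = list(schema)
        records = np.empty((len(df), len(schema)), dtype=np.int64)
        for j, var in enumerate(schema):
            if var.name not in df.columns:
                raise SchemaError(f"missing column {var.name!r}")
            col = df[var.name]
            if col.isna().any():
                row = int(col.index[col.isna()][0])
                raise SchemaError(f"{var.name}: missing value at row {row}")
            mapping = {lv: i for i, lv in enumerate(var.levels)}
            mapped = col.map(mapping)
            if mapped.isna().any():
                row = int(mapped.index[mapped.isna()][0])
                bad = col.loc[row]
                raise SchemaError(f"{var.name}: unknown label {bad!r} at row {row}")
            records[:, j] = mapped.to_numpy(dtype=np.int64)
        return cls(schema, records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CategoricalDataset):
            return NotImplemented
        return self.schema == other.schema and np.array_equal(self.records, other.records)


@dataclass(frozen=True)
class Dag:
    """Directed graph over named nodes; validity (acyclicity) is checked on demand."""

    nodes: frozenset[str]
    arcs: frozenset[tuple[str, str]]

    def __init__(self, nodes: Iterable[str], arcs: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "nodes", frozenset(nodes))
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in arcs))
        for parent, child in self.arcs:
            if parent not in self.nodes or child not in self.nodes:
                raise SchemaError(f"arc ({parent}, {child}) references undeclared node")
            if parent == child:
                raise SchemaError(f"self-arc on {parent}")

    def parents(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise SchemaError(f"unknown node {node!r}")
        return tuple(sorted(p for p, c in self.arcs if c == node))

    def children(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise SchemaError(f"unknown node {node!r}")
        return tuple(sorted(c for p, c in self.arcs if p == node))

    def with_arc(self, parent: str, child: str) -> "Dag":
        return Dag(self.nodes, self.arcs | {(parent, child)})

    def without_arc(self, parent: str, child: str) -> "Dag":
        return Dag(self.nodes, self.arcs - {(parent, child)})

    def with_reversed_arc(self, parent: str, child: str) -> "Dag":
        return Dag(self.nodes, (self.arcs - {(parent, child)}) | {(child, parent)})

    def has_path(self, source: str, target: str) -> bool:
        """Directed reachability source -> target (used to veto cycle-creating moves)."""
        if source == target:
            return True
        children: dict[str, list[str]] = {}
        for p, c in self.arcs:
            children.setdefault(p, []).append(c)
        stack, seen = [source], {source}
        while stack:
            node = stack.pop()
            for nxt in children.get(node, ()):
                if nxt == target:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False


def topological_order(dag: Dag) -> list[str]:
    """Kahn's algorithm with a min-heap: parents precede children, ties lexicographic."""
    indeg = {node: 0 for node in dag.nodes}
    children: dict[str, list[str]] = {node: [] for node in dag.nodes}
    for parent, child in dag.arcs:
        indeg[child] += 1
        children[parent].append(child)
    ready = [node for node, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        node = heapq.heappop(ready)
        order.append(node)
        for child in sorted(children[node]):
            indeg[child] -= 1
            if indeg[child] == 0:
                heapq.heappush(ready, child)
    if len(order) != len(dag.nodes):
        cycle = _find_cycle(dag)
        raise CycleError(f"graph contains a directed cycle: {' -> '.join(cycle)}")
    return order


def _find_cycle(dag: Dag) -> list[str]:
    children: dict[str, list[str]] = {node: [] for node in dag.nodes}
    for parent, child in dag.arcs:
        children[parent].append(child)
    WHITE, GREY, BLACK = 0, 1, 2
    color = {node: WHITE for node in dag.nodes}
    parent_of: dict[str, str] = {}

    for start in sorted(dag.nodes):
        if color[start] != WHITE:
            continue
        stack = [(start, iter(sorted(children[start])))]
        color[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GREY:
                    cycle = [nxt, node]
                    cur = node
                    while cur != nxt:
                        cur = parent_of[cur]
                        cycle.append(cur)
                    cycle.reverse()
                    return cycle
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    parent_of[nxt] = node
                    stack.append((nxt, iter(sorted(children[nxt]))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return []


def validate_dag(dag: Dag) -> tuple[bool, str | None]:
    """True iff acyclic; otherwise False plus a diagnostic naming one cycle."""
    try:
        topological_order(dag)
    except CycleError as exc:
        return False, str(exc)
    return True, None


@dataclass(frozen=True)
class ArcConstraints:
    """A blacklist of forbidden (parent, child) arcs."""

    blacklist: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __init__(self, blacklist: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "blacklist", frozenset(tuple(a) for a in blacklist))

    def forbids(self, parent: str, child: str) -> bool:
        return (parent, child) in self.blacklist

    @classmethod
    def demographic(cls, schema: Sequence[VariableSpec]) -> "ArcConstraints":
        """Forbid every arc into a demographic variable.

        This covers both arcs from pain variables into demographics and both
        orientations between any two demographic variables.
        """
        names = [v.name for v in schema]
        demo = [v.name for v in schema if v.role == DEMOGRAPHIC]
        black = {(x, d) for d in demo for x in names if x != d}
        return cls(black)


def violates_constraints(dag: Dag, constraints: ArcConstraints) -> bool:
    """True iff any arc of the DAG is blacklisted."""
    return bool(dag.arcs & constraints.blacklist)


def crosstab_counts(
    data: CategoricalDataset, child: str, parents: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Count table for one family.

    Returns ``(counts, strides)`` where ``counts`` has shape
    (n_parent_configs, r_child). Parent configurations are indexed with the
    parents in sorted name order and the level index of the *last* sorted
    parent varying fastest (row-major).
    """
    spec = data.spec(child)
    parents = sorted(parents)
    if child in parents:
        raise SchemaError(f"{child} cannot be its own parent")
    cards = [data.spec(p).cardinality for p in parents]
    n_cfg = int(np.prod(cards)) if parents else 1
    cfg = np.zeros(data.n, dtype=np.int64)
    strides = np.ones(len(parents), dtype=np.int64)
    for i in range(len(parents) - 2, -1, -1):
        strides[i] = strides[i + 1] * cards[i + 1]
    for p, s in zip(parents, strides):
        cfg += data.column(p) * s
    flat = cfg * spec.cardinality + data.column(child)
    counts = np.bincount(flat, minlength=n_cfg * spec.cardinality)
    return counts.reshape(n_cfg, spec.cardinality), strides
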