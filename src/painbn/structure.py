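"""Score-based structure learning: decomposable BIC and constrained hill climbing.

Score convention: family score = sum_jk N_jk * ln(N_jk / N_j) minus
(d/2) * ln(n), with d = (r_child - 1) * prod(r_parents); higher is better.
Zero counts contribute nothing (0 * ln 0 = 0), and parent configurations never
observed in the data add no likelihood and no extra information — but they do
count toward the dimension penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .model import (
    ArcConstraints,
    CategoricalDataset,
    Dag,
    SchemaError,
    crosstab_counts,
    violates_constraints,
)

ADD, DELETE, REVERSE = "add", "delete", "reverse"
_MOVE_RANK = {ADD: 0, DELETE: 1, REVERSE: 2}


@dataclass
class FamilyScoreCache:
    """Memo of (child, sorted parent tuple) -> family BIC, keyed to one dataset."""

    fingerprint: int
    scores: dict[tuple[str, tuple[str, ...]], float] = field(default_factory=dict)

    @classmethod
    def for_dataset(cls, data: CategoricalDataset) -> "FamilyScoreCache":
        return cls(fingerprint=_fingerprint(data))

    def matches(self, data: CategoricalDataset) -> bool:
        return self.fingerprint == _fingerprint(data)


def _fingerprint(data: CategoricalDataset) -> int:
    h = hash((data.n, tuple(v.name for v in data.schema)))
    return h ^ hash(data.records.tobytes())


@dataclass(frozen=True)
class Move:
    kind: str
    parent: str
    child: str

    def sort_key(self) -> tuple[int, str, str]:
        return (_MOVE_RANK[self.kind], self.parent, self.child)


@dataclass
class SearchTrace:
    """Accepted moves with the network score after each, plus the final model."""

    moves: list[tuple[Move, float]]
    dag: Dag
    score: float

    def to_jsonable(self) -> dict:
        return {
            "moves": [
                {"kind": m.kind, "parent": m.parent, "child": m.child, "score": s}
                for m, s in self.moves
            ],
            "arcs": sorted(self.dag.arcs),
            "score": self.score,
        }


def family_bic_score(
    data: CategoricalDataset,
    child: str,
    parents: Iterable[str],
    cache: FamilyScoreCache | None = None,
) -> float:
    parents = tuple(sorted(parents))
    if child in parents:
        raise SchemaError(f"{child} cannot be its own parent")
    if data.n == 0:
        raise ValueError("cannot score an empty dataset")
    if cache is not None:
        cached = cache.scores.get((child, parents))
        if cached is not None:
            return cached

    counts, _ = crosstab_counts(data, child, parents)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_terms = counts * (np.log(counts) - np.log(row_tot))
    ll = float(np.nansum(np.where(counts > 0, ll_terms, 0.0)))

    r_child = data.spec(child).cardinality
    dim = (r_child - 1) * int(np.prod([data.spec(p).cardinality for p in parents]))
    score = ll - 0.5 * dim * math.log(data.n)
    if cache is not None:
        cache.scores[(child, parents)] = score
    return score


def network_bic_score(
    data: CategoricalDataset, dag: Dag, cache: FamilyScoreCache | None = None
) -> float:
    """Decomposable network score: sum of family scores over all nodes."""
    if set(dag.nodes) != set(data.variables):
        raise SchemaError("DAG nodes must match dataset variables")
    return sum(
        family_bic_score(data, node, dag.parents(node), cache) for node in sorted(dag.nodes)
    )


@dataclass(frozen=True)
class HillClimbOptions:
    tolerance: float = 1e-9
    max_iter: int = 10_000
    restarts: int = 0
    perturbations: int = 4  # random legal arc changes applied per restart
    seed: int = 0


def hill_climb(
    data: CategoricalDataset,
    constraints: ArcConstraints | None = None,
    options: HillClimbOptions | None = None,
    start: Dag | None = None,
) -> SearchTrace:
    """Greedy DAG search over add/delete/reverse moves under an arc blacklist.

    Starts from the empty graph, applies the single best strictly-improving
    move each step (ties broken deterministically: add < delete < reverse,
    then lexicographic (parent, child)), and stops at a local optimum.
    Optional random restarts perturb the local optimum and re-climb, keeping
    the best-scoring result.
    """
    constraints = constraints or ArcConstraints()
    options = options or HillClimbOptions()
    cache = FamilyScoreCache.for_dataset(data)

    dag = start if start is not None else Dag(data.variables)
    if violates_constraints(dag, constraints):
        raise ValueError("start graph violates the arc blacklist")
    trace = _climb(data, dag, constraints, options, cache)

    if options.restarts > 0:
        rng = np.random.default_rng(options.seed)
        best = trace
        for _ in range(options.restarts):
            perturbed = _perturb(best.dag, constraints, options.perturbations, rng)
            candidate = _climb(data, perturbed, constraints, options, cache)
            if candidate.score > best.score + options.tolerance:
                best = candidate
        trace = best
    return trace


def _climb(
    data: CategoricalDataset,
    dag: Dag,
    constraints: ArcConstraints,
    options: HillClimbOptions,
    cache: FamilyScoreCache,
) -> SearchTrace:
    nodes = sorted(dag.nodes)
    fam = {node: family_bic_score(data, node, dag.parents(node), cache) for node in nodes}
    score = sum(fam.values())
    moves: list[tuple[Move, float]] = []

    for _ in range(options.max_iter):
        best_move: Move | None = None
        best_delta = 0.0
        best_new: dict[str, float] = {}

        for move in _candidate_moves(dag, constraints, nodes):
            delta, new_fams = _move_delta(data, dag, move, fam, cache)
            if delta <= options.tolerance:
                continue
            better = delta > best_delta + options.tolerance
            tied = best_move is not None and abs(delta - best_delta) <= options.tolerance
            if better or (tied and move.sort_key() < best_move.sort_key()):
                best_move, best_delta, best_new = move, delta, new_fams

        if best_move is None:
            break
        dag = _apply(dag, best_move)
        fam.update(best_new)
        score += best_delta
        moves.append((best_move, score))

    return SearchTrace(moves, dag, score)


def _candidate_moves(dag: Dag, constraints: ArcConstraints, nodes: list[str]):
    arcs = dag.arcs
    for parent in nodes:
        for child in nodes:
            if parent == child:
                continue
            if (parent, child) in arcs:
                yield Move(DELETE, parent, child)
                # reversal must be legal in the new direction and acyclic
                if not constraints.forbids(child, parent) and not _creates_cycle_on_reverse(
                    dag, parent, child
                ):
                    yield Move(REVERSE, parent, child)
            elif (child, parent) not in arcs:
                if not constraints.forbids(parent, child) and not dag.has_path(child, parent):
                    yield Move(ADD, parent, child)


def _creates_cycle_on_reverse(dag: Dag, parent: str, child: str) -> bool:
    return dag.without_arc(parent, child).has_path(parent, child)


def _move_delta(
    data: CategoricalDataset,
    dag: Dag,
    move: Move,
    fam: dict[str, float],
    cache: FamilyScoreCache,
) -> tuple[float, dict[str, float]]:
    new_fams: dict[str, float] = {}
    if move.kind == ADD:
        parents = set(dag.parents(move.child)) | {move.parent}
        new_fams[move.child] = family_bic_score(data, move.child, parents, cache)
    elif move.kind == DELETE:
        parents = set(dag.parents(move.child)) - {move.parent}
        new_fams[move.child] = family_bic_score(data, move.child, parents, cache)
    else:  # REVERSE: child loses the arc, parent gains one
        child_parents = set(dag.parents(move.child)) - {move.parent}
        parent_parents = set(dag.parents(move.parent)) | {move.child}
        new_fams[move.child] = family_bic_score(data, move.child, child_parents, cache)
        new_fams[move.parent] = family_bic_score(data, move.parent, parent_parents, cache)
    delta = sum(new_fams[n] - fam[n] for n in new_fams)
    return delta, new_fams


def _apply(dag: Dag, move: Move) -> Dag:
    if move.kind == ADD:
        return dag.with_arc(move.parent, move.child)
    if move.kind == DELETE:
        return dag.without_arc(move.parent, move.child)
    return dag.with_reversed_arc(move.parent, move.child)


def _perturb(dag: Dag, constraints: ArcConstraints, k: int, rng: np.random.Generator) -> Dag:
    """Apply up to k random legal add/delete moves (for restarts)."""
    nodes = sorted(dag.nodes)
    for _ in range(k):
        legal: list[Move] = []
        for parent in nodes:
            for child in nodes:
                if parent == child:
                    continue
                if (parent, child) in dag.arcs:
                    legal.append(Move(DELETE, parent, child))
                elif (child, parent) not in dag.arcs:
                    if not constraints.forbids(parent, child) and not dag.has_path(child, parent):
                        legal.append(Move(ADD, parent, child))
        if not legal:
            break
        dag = _apply(dag, legal[int(rng.integers(len(legal)))])
    return dag


def adjacency_recall(truth: Dag, learned: Dag) -> float:
    """Fraction of true skeleton edges present (either orientation) in the learned DAG."""
    true_adj = {frozenset(a) for a in truth.arcs}
    learned_adj = {frozenset(a) for a in learned.arcs}
    if not true_adj:
        return 1.0
    return len(true_adj & learned_adj) / len(true_adj)


def structural_hamming_distance(truth: Dag, learned: Dag) -> int:
    """Arc insertions/deletions/reversals separating two DAGs over the same nodes."""
    true_adj = {frozenset(a) for a in truth.arcs}
    learned_adj = {frozenset(a) for a in learned.arcs}
    missing = len(true_adj - learned_adj)
    extra = len(learned_adj - true_adj)
    flipped = sum(
        1
        for a in truth.arcs
        if frozenset(a) in learned_adj and a not in learned.arcs
    )
    return missing + extra + flipped
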