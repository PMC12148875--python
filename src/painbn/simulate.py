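"""Synthetic cohort generator: a calibrated ground-truth network + forward sampling.

The built-in truth network reproduces the published arc set, the marginal
demographic composition, and — via logit-anchored CPTs — the published
pairwise conditional percentages. For a child with a single parent the CPT
rows equal the published Yes%/No% pair exactly; for multi-parent children the
per-parent anchors combine additively on the log-odds scale:

    logit P(child=yes | parent levels) =
        logit(prevalence) + sum over parents [logit(anchor(parent level)) - logit(prevalence)]

clipped to [0.01, 0.99]. This is a parsimonious modelling choice, not a
published table: it preserves each pairwise conditional odds ratio inside the
CPT while keeping marginals near the published prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibration as cal
from .model import CategoricalDataset, Dag, SchemaError, VariableSpec, topological_order
from .parameters import Cpt, CptSet

_CLIP = (0.01, 0.99)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one simulated cohort draw."""

    n: int = cal.COHORT_N
    seed: int = 0
    truth: tuple[Dag, CptSet] | None = None  # default: built-in calibrated network
    gender_split: float = cal.GENDER_SPLIT
    age_mix: tuple[float, float, float] = cal.AGE_MIX
    schema: tuple[VariableSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.gender_split < 1.0:
            raise ValueError("gender_split must lie in (0, 1)")
        if abs(sum(self.age_mix) - 1.0) > 1e-9:
            raise ValueError("age_mix must sum to 1")

    def resolve(self) -> tuple[list[VariableSpec], Dag, CptSet]:
        if self.truth is not None:
            dag, cpts = self.truth
            schema = list(self.schema) if self.schema is not None else cal.default_schema()
        else:
            schema = cal.default_schema()
            dag, cpts = build_default_truth_network(
                gender_split=self.gender_split, age_mix=self.age_mix
            )
        return schema, dag, cpts


def _anchors(parent: str, child: str) -> dict[str, float]:
    """Per-parent-level anchor probabilities P(child=yes | parent level)."""
    out: dict[str, float] = {}
    for p, lvl, c, yes_pct, no_pct, *_ in cal.RELATIONSHIP_TARGETS:
        if p != parent or c != child:
            continue
        out[lvl] = yes_pct / 100.0
        if p == "gender" and lvl == "female":
            out["male"] = no_pct / 100.0
        elif p not in ("age", "gender"):
            out["no"] = no_pct / 100.0
    if not out:
        raise SchemaError(f"no calibration anchors for {parent} -> {child}")
    return out


def build_default_truth_network(
    gender_split: float = cal.GENDER_SPLIT,
    age_mix: tuple[float, float, float] = cal.AGE_MIX,
) -> tuple[Dag, CptSet]:
    """The built-in ground-truth network over the 12 cohort variables."""
    schema = cal.default_schema()
    specs = {v.name: v for v in schema}
    dag = Dag([v.name for v in schema], cal.TRUTH_ARCS)

    cpts: dict[str, Cpt] = {}
    cpts["age"] = Cpt("age", (), (), np.array([list(age_mix)]))
    cpts["gender"] = Cpt("gender", (), (), np.array([[gender_split, 1.0 - gender_split]]))

    for child in cal.PAIN_VARIABLES:
        parents = dag.parents(child)  # sorted
        base = _logit(cal.prevalence(child))
        anchor_by_parent = {p: _anchors(p, child) for p in parents}
        cards = tuple(specs[p].cardinality for p in parents)
        n_cfg = int(np.prod(cards)) if parents else 1
        table = np.empty((n_cfg, 2))
        for cfg in range(n_cfg):
            rem, levels = cfg, []
            for card in reversed(cards):
                levels.append(rem % card)
                rem //= card
            levels.reverse()
            x = base
            for p, lvl_idx in zip(parents, levels):
                label = specs[p].levels[lvl_idx]
                x += _logit(anchor_by_parent[p][label]) - base
            p_yes = min(max(_sigmoid(x), _CLIP[0]), _CLIP[1])
            table[cfg] = (1.0 - p_yes, p_yes)
        cpts[child] = Cpt(child, parents, cards, table)

    return dag, CptSet(cpts)


def forward_sample(config: GeneratorConfig) -> CategoricalDataset:
    """Ancestral sampling: n records drawn node by node in topological order.

    One ``numpy.random.default_rng(seed)`` stream; for each node (topological
    order, lexicographic ties) a single block of n uniforms is consumed, so
    identical configs give bitwise-identical datasets.
    """
    schema, dag, cpts = config.resolve()
    order = topological_order(dag)
    if set(order) != {v.name for v in schema}:
        raise SchemaError("truth network nodes do not match the schema")

    rng = np.random.default_rng(config.seed)
    col_of = {v.name: j for j, v in enumerate(schema)}
    records = np.zeros((config.n, len(schema)), dtype=np.int64)

    for node in order:
        cpt = cpts[node]
        if not np.allclose(cpt.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{node}: CPT rows must sum to 1")
        cfg = np.zeros(config.n, dtype=np.int64)
        for p, s in zip(cpt.parents, cpt.strides):
            cfg += records[:, col_of[p]] * int(s)
        cum = np.cumsum(cpt.table[cfg], axis=1)
        u = rng.random(config.n)
        records[:, col_of[node]] = (u[:, None] >= cum).sum(axis=1)

    return CategoricalDataset(schema, records)
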