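"""File formats (CSV data, DOT graphs, JSON networks/traces, TSV reports)
and the end-to-end pipeline runner."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from .effects import RelationshipRow, relationship_table
from .model import (
    ArcConstraints,
    CategoricalDataset,
    Dag,
    PAIN,
    SchemaError,
    VariableSpec,
    validate_dag,
)
from .parameters import Cpt, CptSet, fit_mle_cpts
from .simulate import GeneratorConfig, forward_sample
from .structure import HillClimbOptions, SearchTrace, hill_climb

log = logging.getLogger("painbn")


# ---------------------------------------------------------------------------
# dataset CSV

def write_dataset_csv(data: CategoricalDataset, path: str | Path) -> None:
    data.to_dataframe().to_csv(path, index=False)


def read_dataset_csv(path: str | Path, schema: Sequence[VariableSpec] | None = None) -> CategoricalDataset:
    """Read a labelled CSV (header = variable names, cells = level labels).

    Without an explicit schema the default cohort schema is used for known
    variable names; any other column is inferred as binary no/yes pain if its
    labels allow, otherwise rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if schema is None:
        schema = infer_schema(df)
    else:
        schema = list(schema)
    return CategoricalDataset.from_dataframe(df, schema)


def infer_schema(df: pd.DataFrame) -> list[VariableSpec]:
    known = {v.name: v for v in cal.default_schema()}
    schema = []
    for col in df.columns:
        if col in known:
            schema.append(known[col])
            continue
        labels = set(df[col].dropna().unique())
        if labels <= {"no", "yes"}:
            schema.append(VariableSpec(col, ("no", "yes"), PAIN))
        else:
            raise SchemaError(
                f"cannot infer schema for column {col!r} with labels {sorted(labels)}"
            )
    return schema


# ---------------------------------------------------------------------------
# DOT export

def write_dag_dot(
    dag: Dag,
    annotations: Mapping[tuple[str, str], RelationshipRow] | None = None,
) -> str:
    """DOT digraph. Annotated arcs get an OR label (3 d.p.); style is solid
    when OR > 1 with a CI excluding 1, dotted blue otherwise."""
    ok, diag = validate_dag(dag)
    if not ok:
        raise ValueError(diag)
    lines = ["digraph pain_network {"]
    for node in sorted(dag.nodes):
        lines.append(f'  "{node}";')
    for parent, child in sorted(dag.arcs):
        attrs = []
        row = annotations.get((parent, child)) if annotations else None
        if row is not None:
            attrs.append(f'label="{row.or_value:.3f}"')
            significant = row.or_value > 1.0 and (row.ci_low > 1.0 or row.ci_high < 1.0)
            if significant:
                attrs.append("style=solid")
            else:
                attrs.append("style=dotted")
                attrs.append("color=blue")
        suffix = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f'  "{parent}" -> "{child}"{suffix};')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# network JSON

def network_to_jsonable(dag: Dag, cpts: CptSet) -> dict:
    return {
        "nodes": sorted(dag.nodes),
        "arcs": sorted(list(a) for a in dag.arcs),
        "cpts": {
            node: {
                "parents": list(cpts[node].parents),
                "parent_cards": list(cpts[node].parent_cards),
                "table": cpts[node].table.tolist(),
                "unobserved": cpts[node].unobserved.tolist(),
            }
            for node in sorted(dag.nodes)
        },
    }


def write_network_json(dag: Dag, cpts: CptSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_jsonable(dag, cpts), indent=1))


def read_network_json(path: str | Path) -> tuple[Dag, CptSet]:
    obj = json.loads(Path(path).read_text())
    dag = Dag(obj["nodes"], [tuple(a) for a in obj["arcs"]])
    cpts = {}
    for node, c in obj["cpts"].items():
        cpts[node] = Cpt(
            node,
            tuple(c["parents"]),
            tuple(c["parent_cards"]),
            np.asarray(c["table"], dtype=float),
            np.asarray(c["unobserved"], dtype=bool),
        )
    return dag, CptSet(cpts)


# ---------------------------------------------------------------------------
# tabular reports

def prevalence_table(data: CategoricalDataset) -> pd.DataFrame:
    """Per pain variable: yes count, no count, prevalence % (1 d.p.)."""
    rows = []
    for var in data.schema:
        if var.role != PAIN:
            continue
        col = data.column(var.name)
        yes = int((col == 1).sum())
        no = int((col == 0).sum())
        pct = round(100.0 * yes / (yes + no), 1) if yes + no else 0.0
        rows.append({"variable": var.name, "yes": yes, "no": no, "prevalence_pct": pct})
    return pd.DataFrame(rows)


def relationship_frame(rows: Sequence[RelationshipRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "relationship": f"{r.evidence} -> {r.event}",
                "yes_pct": round(r.p_yes, 3),
                "no_pct": round(r.p_no, 3),
                "odds_ratio": round(r.or_value, 3),
                "ci_lower": round(r.ci_low, 3),
                "ci_upper": round(r.ci_high, 3),
                "a": r.counts.a,
                "b": r.counts.b,
                "c": r.counts.c,
                "d": r.counts.d,
                "flags": ";".join(r.flags),
            }
            for r in rows
        ]
    )


def forest_plot_frame(rows: Sequence[RelationshipRow]) -> pd.DataFrame:
    """Plot-ready log-scale OR data (value + CI bounds per relationship)."""
    return pd.DataFrame(
        [
            {
                "relationship": f"{r.evidence} -> {r.event}",
                "odds_ratio": r.or_value,
                "ci_lower": r.ci_low,
                "ci_upper": r.ci_high,
                "log_or": float(np.log(r.or_value)) if r.or_value > 0 else float("nan"),
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """End-to-end run settings: simulate-or-load, learn, fit, report."""

    output_dir: str | Path = "painbn_out"
    input_csv: str | Path | None = None  # if None, simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    demographic_constraints: bool = True
    hc_options: HillClimbOptions = field(default_factory=HillClimbOptions)
    pseudocount: float = 0.0
    confidence_level: float = 0.95
    zero_cell: str = "haldane"


@dataclass
class PipelineResult:
    data: CategoricalDataset
    constraints: ArcConstraints
    trace: SearchTrace
    cpts: CptSet
    rows: list[RelationshipRow]
    paths: dict[str, Path]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name: str, started: float, **info) -> None:
        extra = " ".join(f"{k}={v}" for k, v in info.items())
        log.info("stage=%s elapsed=%.3fs %s", name, time.perf_counter() - started, extra)

    t0 = time.perf_counter()
    if config.input_csv is not None:
        data = read_dataset_csv(config.input_csv)
        stage("load", t0, path=config.input_csv, n=data.n)
    else:
        data = forward_sample(config.generator)
        stage("simulate", t0, seed=config.generator.seed, n=data.n)
    paths["data"] = out / "cohort.csv"
    write_dataset_csv(data, paths["data"])

    t0 = time.perf_counter()
    if config.demographic_constraints:
        constraints = ArcConstraints.demographic(data.schema)
    else:
        constraints = ArcConstraints()
    stage("constraints", t0, blacklist=len(constraints.blacklist))

    t0 = time.perf_counter()
    trace = hill_climb(data, constraints, config.hc_options)
    stage("learn", t0, arcs=len(trace.dag.arcs), score=f"{trace.score:.3f}")
    paths["trace"] = out / "search_trace.json"
    paths["trace"].write_text(json.dumps(trace.to_jsonable(), indent=1))

    t0 = time.perf_counter()
    cpts = fit_mle_cpts(data, trace.dag, config.pseudocount)
    stage("fit", t0, pseudocount=config.pseudocount)
    paths["network"] = out / "network.json"
    write_network_json(trace.dag, cpts, paths["network"])

    t0 = time.perf_counter()
    rows = relationship_table(
        data, trace.dag, level=config.confidence_level, zero_cell=config.zero_cell
    )
    stage("report", t0, rows=len(rows))
    paths["relationships"] = out / "relationships.tsv"
    relationship_frame(rows).to_csv(paths["relationships"], sep="\t", index=False)
    paths["forest"] = out / "forest_plot.csv"
    forest_plot_frame(rows).to_csv(paths["forest"], index=False)
    paths["prevalence"] = out / "prevalence.tsv"
    prevalence_table(data).to_csv(paths["prevalence"], sep="\t", index=False)
    annotations = {}
    for r in rows:
        parent = r.evidence.split(":")[0]
        annotations.setdefault((parent, r.event), r)
    paths["dot"] = out / "network.dot"
    paths["dot"].write_text(write_dag_dot(trace.dag, annotations))

    return PipelineResult(data, constraints, trace, cpts, rows, paths)
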