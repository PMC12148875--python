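# painbn

Constrained Bayesian-network analysis of categorical pain-survey cohorts.

The package implements a complete, reproducible pipeline for modelling the
interdependencies among binary pain-location indicators and demographic
covariates (gender, 2 levels; age group, 3 levels):

* **Synthetic cohort generator** (`painbn.simulate`) — a built-in ground-truth
  network calibrated to published marginal prevalences and pairwise
  conditional percentages, plus seeded forward (ancestral) sampling. Because
  the original survey data is not public, every downstream stage is exercised
  on these simulated cohorts.
* **Structure learning** (`painbn.structure`) — decomposable BIC family
  scores (`logL − (d/2)·ln n`, higher is better) and hill climbing over
  add/delete/reverse arc moves under an arc blacklist that forbids arcs into
  demographic variables. Deterministic tie-breaking, optional seeded random
  restarts, strictly increasing score traces.
* **Parameter learning** (`painbn.parameters`) — maximum-likelihood
  conditional probability tables with an optional pseudocount; unobserved
  parent configurations are flagged and returned uniform.
* **Exact inference** (`painbn.inference`) — conditional queries
  `P(target | evidence)` by full enumeration or variable elimination (both
  exact, agreeing to ~1e-12).
* **Effect statistics** (`painbn.effects`) — 2×2 contingency extraction
  (multi-level evidence dichotomized level-vs-rest), odds ratios, Woolf
  log-OR 95% confidence intervals, and the per-arc relationship report.
* **I/O + CLI** (`painbn.io`, `painbn.cli`) — CSV cohorts, DOT graph export
  with OR-annotated arcs (solid when OR > 1 with CI excluding 1, dotted blue
  otherwise), JSON networks and search traces, TSV reports, and an
  end-to-end pipeline runner.

## CLI

```bash
# whole pipeline: simulate -> learn -> fit -> report
painbn run --out-dir out --n 2400 --seed 0

# or stage by stage
painbn simulate --n 2400 --seed 0 --out cohort.csv
painbn learn cohort.csv --out trace.json
painbn fit cohort.csv trace.json --out network.json
painbn report cohort.csv network.json --out relationships.tsv
painbn query network.json --target knee=yes --evidence age=senior,foot=yes,back=yes
```

`painbn run --config cfg.yaml` accepts a YAML pipeline configuration
(generator settings, hill-climb options, pseudocount, output directory).

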