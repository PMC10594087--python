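# ordnet

Regularized partial-correlation network analysis for paired ordinal item
panels (e.g. 0–6 Likert-type clinical scale items measured at baseline
and follow-up), with:

- **`ordnet.simulate`** — synthetic paired-panel generator: a latent
  multivariate normal with a planted block-structured partial-correlation
  network, threshold discretization into 7 ordinal categories, per-subject
  cross-wave dependence, a follow-up wave with uniformly scaled edge
  weights and shifted item means. Ground truth is returned alongside the
  data, so every downstream stage can be validated against it.
- **`ordnet.preprocess`** — panel ingestion (CSV/TSV, listwise deletion),
  item exclusion, the truncated-ECDF nonparanormal transform (Winsorized
  mid-rank Gaussianization), Pearson correlation of the transformed data,
  and an optional polychoric route.
- **`ordnet.estimation`** — graphical lasso (block coordinate descent,
  unpenalized diagonal, numba-accelerated when available) over a
  log-spaced penalty path with extended-BIC model selection
  (`EBIC = -2 loglik + E log n + 4 γ E log p`, default γ = 0.5), plus an
  adaptive-weights penalty option.
- **`ordnet.metrics`** — strength, closeness, betweenness (fractional
  credit for tied shortest paths, edge length `1/|w|`), expected
  influence, global strength, raw and z-standardized tables.
- **`ordnet.stability`** — nonparametric edge-weight bootstrap and
  case-dropping centrality stability with CS-coefficients.
- **`ordnet.comparison`** — dependent-samples permutation network
  comparison test (per-subject wave swap): network-structure statistic
  `M`, global-strength statistic `S`, add-one permutation p-values, and
  Holm-adjusted post hoc edge tests. A minimal unpaired variant is
  included.
- **`ordnet.communities`** — signed spinglass community detection
  (simulated annealing on the signed configuration-model Potts energy),
  repeated over many seeds with canonical partition-frequency tallying
  and domain-merge frequencies.
- **`ordnet.report` / `ordnet.cli`** — configuration-driven end-to-end
  pipeline with one master seed, deterministic per-stage child seeds,
  display thresholding, force-directed layout export, and a run manifest.
  Identically-seeded runs produce byte-identical result files.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (solver oracle
checks against a brute-force optimizer, exhaustive path/partition
enumeration, permutation-distribution enumeration, type-I-error and
parameter-recovery simulations, end-to-end determinism). The type-I
criterion runs 200 permutation-test replications and takes several
minutes by itself.

## CLI

```bash
# synthetic paired panels + ground truth
ordnet generate --n 612 --seed 1 --outdir out/

# single-wave estimation, centrality, stability
ordnet estimate --input out/panel_baseline.csv --outdir out/est
ordnet centrality --network out/est/network_baseline.csv --outdir out/cent
ordnet stability --input out/panel_baseline.csv --outdir out/stab

# paired comparison and community tallies
ordnet compare --baseline out/panel_baseline.csv --followup out/panel_followup.csv --outdir out/cmp
ordnet communities --network out/est/network_baseline.csv --runs 10000 --outdir out/comm

# everything from a config file
ordnet run-all --config config.yaml
```

A config file mirrors `ordnet.report.PipelineConfig`, e.g.

```yaml
outdir: out/full
seed: 31
generator: {n_subjects: 612, seed: 31}
estimator: {gamma: 0.5, n_lambdas: 100, lambda_min_ratio: 0.01}
edge_bootstrap_B: 1000
nct_B: 1000
community_runs: 10000
display_threshold: 0.05
```

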