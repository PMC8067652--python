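# microlvm

Joint latent-variable modelling of microbial count communities along
environmental gradients:

- **data_io** — read/aggregate taxonomy-annotated count tables at a chosen
  rank (orders by default, `*`/`**` flags for taxa unresolved past
  phylum/class), prevalence filtering (≥ 5 sites), derived covariates
  (C:N, E2/E3, SUVA254) and standardization.
- **synthetic** — generators from the fitted model class (negative-binomial
  counts, per-sample effects, sparse coefficients, low-rank loadings) with
  known ground truth, including Gaussian-copula injection of
  modifier-dependent dependence between taxon pairs.
- **gllvm** — Bayesian negative-binomial latent variable model
  (`log m_ij = alpha_i + beta0_j + x_i'beta_j + z_i'lambda_j`) fitted by a
  numba-accelerated adaptive Metropolis-within-Gibbs sampler with exact
  Gibbs moves along the likelihood-flat ridge directions; HPD intervals and
  coefficient significance calls.
- **summaries** — median/IQR summaries of significant coefficients, responder
  counts per covariate x direction x domain, soil-variable Pearson screen.
- **varpart** — per-taxon variance decomposition over covariate groups
  (elevation, pH, C&N, organic matter, P, geographic distance) and the
  latent component; distribution summaries with skewness.
- **network** — residual correlations from loadings (`cov2corr(ΛΛ')`),
  significance-masked co-occurrence graph, component-scaled closeness
  centrality, and OLS of network position on per-taxon HPD width
  (niche breadth).
- **interactions** — cumulative probability models (one category per
  distinct count, Newton-Raphson), probability-scale residuals,
  covariate-adjusted and kernel-smoothed conditional Spearman correlations,
  and detection/counting of interaction shifts along a modifier.
- **pipeline / cli** — end-to-end orchestration with YAML config, seeded
  determinism, tidy TSV outputs and a text report.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (calibration and
recovery simulations); the remaining files are per-module unit and property
tests. The full suite takes a few minutes on one CPU.

## CLI

```sh
microlvm simulate --sites 43 --taxa 80 --seed 1 --outdir sim/
microlvm fit --counts sim/counts.tsv --meta sim/metadata.tsv --d 2 --seed 1 --outdir fit/
microlvm summarize --fit fit/ --out coefficients.tsv
microlvm varpart --fit fit/ --out varpart.tsv
microlvm network --fit fit/ --out edges.tsv
microlvm shifts --counts sim/counts.tsv --meta sim/metadata.tsv --modifier C:N
microlvm run-all --config config.yaml
microlvm report --outdir run_out/
```

A minimal `config.yaml` for `run-all`:

```yaml
counts_path: sim/counts.tsv
metadata_path: sim/metadata.tsv
outdir: run_out
d: 2
seed: 1
modifiers: [ "C:N", "elevation", "pH" ]
```

Count tables are TSV/CSV with taxa as rows: a `taxonomy` column holding a
semicolon-delimited lineage (`k__...;p__...;c__...;o__...` or plain names)
and one integer column per site. Metadata tables have one row per site and
case-insensitive columns among elevation, pH, TC, TN, TP, DOC, A250, A254,
A365, latitude, longitude (plus derived C:N, E2/E3, SUVA254).

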