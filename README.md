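# dispvar

Small-area variation analysis of psychotropic dispensing among children and
youth, as a reusable, fully synthetic-testable pipeline:

* **`dispvar.synthetic`** — generates person-level and division-level cohort
  tables with configurable baseline dispensing rates per drug class
  (antidepressant, stimulant, antipsychotic, benzodiazepine), covariate rate
  ratios, a multiplicative log-normal division effect, and a weighted 10%
  subsample of non-recipients.
* **`dispvar.rates`** — crude and direct age/sex-standardized dispensing rates
  per census division and drug class, indirect expected counts, and subgroup
  proportions.
* **`dispvar.variation`** — extremal quotient, population-weighted coefficient
  of variation, systematic component of variation (SCV) with interpretation
  bands, and per-division chi-square tests against the provincial rate with a
  one-significant-figure per-comparison alpha.
* **`dispvar.gee`** — log-link marginal (GEE) regression of dispensing counts
  on individual- and division-level covariates, fitted on covariate-pattern
  cells with a log-population offset; independent or exchangeable working
  correlation, quasi-Poisson or negative-binomial variance, cluster-robust
  (sandwich) confidence intervals, and a formatted rate-ratio table.
* **`dispvar.descriptives`** — baseline characteristics with standardized
  differences, and Spearman correlations with Fisher-z confidence intervals.
* **`dispvar.cli`** — orchestration and the `dispvar` command-line tool.

The exchangeable working correlation is parameterized at the *person* level
and induced onto aggregated cells (`V = (1-ρ)·diag(v) + ρ·bb'`,
`b_i = sqrt(v_i·n_i)`); for unit cells this is exactly the classical
exchangeable structure. Cell-level equicorrelation is not a coherent model
when cell sizes vary by orders of magnitude (its score equations can have no
root), so the induced form is used throughout.

## Command line

```sh
# full pipeline on a synthetic cohort
dispvar run-all --config config.yaml --out results/ --seed 7

# individual stages
dispvar generate --config generator.yaml --out data/ --seed 7
dispvar rates --persons data/persons.csv --divisions data/divisions.csv --out rates.csv
dispvar variation --rates rates.csv --out-dir results/
dispvar gee --persons data/persons.csv --divisions data/divisions.csv \
    --outcome-class stimulant --out gee.json
dispvar describe --persons data/persons.csv --out table1.csv
```

A minimal `config.yaml`:

```yaml
synthetic:
  n_divisions: 30
  division_population_range: [3500, 738000]
  total_population: 200000
  division_effect_sd: 0.2
numerator_mode: persons    # or prescriptions
alpha_familywise: 0.05
seed: 7
out_dir: results
```

`run-all` writes `rates.csv`, `variation.json`, `division_tests.csv`,
`gee_results.json`, `table2.csv`, `table1.csv`, `correlations.json` and a
`manifest.json` (seed, config hash, versions, per-stage log). Runs are
byte-for-byte deterministic under a fixed seed. To analyse an existing
cohort instead of a synthetic one, replace the `synthetic` block with
`persons_path` / `divisions_path` pointing at CSV tables following the
schemas in `dispvar.schema`.

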