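# itemrel

Estimation of **item-score reliability** — the proportion of a single item
score's variance that is true-score variance — in the classical test theory
framework, with four estimators, a multidimensional graded response model
(GRM) simulator, and a Monte-Carlo study harness for estimator bias and
variability.

## Methods

| method | idea |
|---|---|
| `MS` | approximate the unobservable same-item joint cumulative probabilities from the neighboring cells of the ordered P(++) matrix (and its P(−−) complement), then assemble the reliability |
| `LAMBDA6` | squared multiple correlation of the item regressed on the remaining items (Guttman's λ6 adapted to one item); a conservative lower bound in practice |
| `LCRC` | fit an unconstrained latent class model by multi-start EM and use its implied same-item joint probabilities |
| `CA` | correction for attenuation: squared item–criterion correlation divided by coefficient alpha of the rest score |

All estimates are reported raw (they may exceed 1 and are never clipped).

## Library quick start

```python
import itemrel as ir

data = ir.read_scores("scores.csv")          # N x J integer matrix, 0..m
ir.ms_reliability(data).estimates            # method MS, one value per item
ir.lambda6_all(data).estimates
ir.lcrc_reliability(data, K="bic", n_starts=25, seed=1).estimates
ir.ca_reliability(data).estimates            # rest-score criterion

cond = ir.condition("standard")              # named GRM simulation preset
sim = ir.simulate_dataset(cond, seed=7)
rho = ir.population_item_reliability(cond, 1_000_000, seed=8)

result = ir.run_study(["standard", "long_test"], methods=("MS", "CA"),
                      replications=200, seed=42)
result.summary_rows()                        # median bias, IQR, % outliers
```

Simulation presets: `standard`, `polytomous`, `unequal_alpha`, `two_dim`,
`long_test`, `small_n`.

## CLI

```bash
itemrel estimate --method ms --input scores.csv --dump-pplus pplus.csv
itemrel estimate --method lcrc --input scores.csv --classes bic --starts 25 --seed 1
itemrel estimate --method ca --input scores.csv [--criterion-col y.txt --criterion-rel 0.8]
itemrel simulate --condition standard --seed 7 --out scores.csv
itemrel study --config study.yaml --out results.json --summary-csv summary.csv
itemrel indices --input scores.csv            # item-rest correlation, Hi
```

Input format: one row per person, one column per item, integer cells in
`0..m`, optional header row (`--header`), configurable delimiter.  Inputs
whose minimum exceeds 0 are rejected unless `--shift-to-zero` is given.

A study YAML lists `conditions`, `methods`, `replications`, `seed`, optional
`quartile` (`tukey` or `linear`), `lcrc: {classes, starts}`, and
`population_simulees`.

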