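# valbias

Monte-Carlo harness for quantifying how the choice of validation protocol
biases machine-learning performance estimates when samples are small.

The package generates synthetic datasets (pure Gaussian noise with balanced
binary labels, or a "discriminable" variant where 10 of 50 features carry a
class-conditional mean shift of 0.5), develops feature-selection +
grid-tuned-classifier pipelines, and evaluates them under five validation
protocols:

| scheme     | feature selection | hyperparameter tuning |
|------------|-------------------|-----------------------|
| `split`    | training portion  | training portion      |
| `kfold`    | **all rows**      | **all rows**          |
| `nested`   | per-fold training | per-fold training     |
| `fs_out`   | **all rows**      | per-fold training     |
| `tune_out` | per-fold training | **all rows**          |

On noise data any protocol that pools development and evaluation rows
(`kfold`, `fs_out`) reports accuracy far above the 50% chance level; the
leakage-free protocols do not.  Every `ValidationResult` carries a row-level
ledger proving which samples each development stage saw, so the test suite
can verify each scheme is what it claims.

Two canonical pipelines are built in: `"svm"` (SVM-RFE selection + RBF-SVM,
tuned over C = 2^1..2^7, gamma = 2^-1..2^-7) and `"logreg"` (two-sample
t-test top-10 selection + penalised logistic regression, tuned over
L1/L2 x C = e^0..e^9).

## CLI

```bash
valbias sweep --preset fig3-quick --seed 1 --out results/fig3-quick
valbias sweep --config my_sweep.yaml --seed 1 --out results/custom
valbias toy-boundary --reps 1000 --seed 1 --out results/toy
valbias toy-selection --reps 100 --seed 1 --out results/toysel
valbias survey --table data/s1_studies.csv --out results/survey
valbias survey --fixture-size 55 --seed 1 --out results/survey-fixture
```

Sweep presets named `fig3-svm`, `fig4a-svm`, ... encode the publication-scale
settings (50 runs per design point); the `*-quick` presets downscale runs and
points but never the protocol logic.  Every command writes raw CSV results, a
summary CSV (means, 95% CIs, t-tests against the 50% chance level, pairwise
scheme comparisons) and a `provenance.json` from which the run can be
regenerated exactly.

A YAML sweep config mirrors `valbias.experiments.ExperimentConfig`:

```yaml
variable: sample_size      # n_features | grid_size | n_folds | ratio | ...
values: [20, 60, 100]
schemes: [split, kfold, nested]
pipeline: logreg           # or svm
runs_per_point: 10
```

## Package layout

- `valbias.synthetic_data` — seeded dataset generators (+ CSV import/export)
- `valbias.feature_selection` — pooled-variance t-test ranking and SVM-RFE
- `valbias.model_tuning` — tuning grids, stratified inner-CV grid search
- `valbias.validation_schemes` — the five protocols with leakage ledgers
- `valbias.experiments` — sweep drivers, summaries, presets
- `valbias.toy_demos` — the two small illustrations of overfitting
- `valbias.survey_analysis` — studies-table statistics + fixture generator
- `valbias.cli` — `valbias` command-line entry point
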