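# pcorona

Protein-corona composition prediction with relevance-guided resampling
for imbalanced regression.

## The problem

When a nanoparticle meets a biological fluid, proteins adsorb onto its
surface and form a *protein corona* that defines the particle's
biological identity. Predicting the corona's composition — the
relative protein abundance (RPA) of each protein — from the particle's
physicochemical properties and the incubation protocol is a tabular
regression problem with one awkward property: RPA is strictly positive
and heavily right-skewed. Most incubations bind very little of any
given protein; the biologically interesting high-abundance cases are
rare. A regressor trained on such data resolves the dense low-RPA
region well and the rare high-RPA tail poorly, precisely backwards
from what matters.

`pcorona` implements the full pipeline for this setting:

- **I/O**: mixed-type factor tables (categorical + numerical
  nanoparticle/protocol factors) with per-protein RPA target columns,
  with exhaustive validation reporting (`read_corona_table`,
  `CoronaDataset`).
- **Preprocessing**: full one-hot encoding, min-max normalization with
  train-time bounds reused at prediction time, and a train/test split
  stratified on quantile bins of the continuous target
  (`CoronaEncoder`, `stratified_split`).
- **Relevance function Φ(y)**: a monotone piecewise cubic Hermite
  (pchip) interpolant through control points mapping target values to
  a rarity score in [0, 1], with Fritsch–Carlson slope correction
  (`pchip_fit`, `default_control_points`).
- **Resampling**: three Φ-guided strategies that rebalance the
  training set toward the rare region — Random Oversampling, SmoteR
  (interpolation-based synthesis) and WERCS (weighted relevance-based
  combination of over- and undersampling) — each with full row
  provenance for leakage audits (`resample`).
- **Modeling**: per-protein Random Forest regressors, R²/RMSE metrics,
  cross-validated learning curves, a leakage-audited four-arm ablation
  (no resampling vs each strategy), and Gini feature importance
  aggregated from one-hot columns back to parent factors
  (`run_ablation`, `feature_importance`).
- **Diagnostics**: variance/entropy shift of the training target and
  kernel-density overlays before vs after resampling
  (`distribution_diagnostics`, `kde_overlay`).
- **Synthetic data**: a generator that emulates the statistical shape
  of published corona screens (652 records, 8 categorical + 13
  numerical factors, 60 proteins, lognormal RPA) with planted,
  recoverable signal for end-to-end validation (`generate_dataset`).

## Worked example

```python
import pcorona as pc

# A corona-like dataset: 652 rows, 21 factors, 60 protein targets.
dataset, truth = pc.generate_dataset(pc.SyntheticConfig(seed=0))

# Rebalance one protein's targets toward the rare high-RPA region.
enc = pc.CoronaEncoder().fit_transform(dataset)
y = dataset.rpa["protein_00"].to_numpy()
phi = pc.pchip_fit(pc.default_control_points(y))
rs = pc.resample("random_over", enc.X, y, phi,
                 pc.ResampleParams(seed=0), enc.feature_groups())
print(pc.distribution_diagnostics(y, rs.y))
# (187.91, 387.77, 0.609, 1.122)  <- variance and entropy both increase

# Four-arm ablation: does resampling help held-out accuracy?
reports = pc.run_ablation(dataset, config=pc.ModelConfig(n_trees=100, seed=1))
print(pc.summary_frame(reports))
```

On the default synthetic dataset generated with seed 1 this prints
(values rounded):

| strategy    | mean R² | mean RMSE |
|-------------|---------|-----------|
| none        | 0.854   | 8.20      |
| random_over | 0.881   | 6.51      |
| smoter      | 0.906   | 6.85      |
| wercs       | 0.864   | 6.71      |

and the aggregated feature importances recover exactly the three
planted informative factors above the 0.01 filter
(`incubation_plasma_concentration` 0.62, `surface_modification` 0.35,
`PDI` 0.028), with every pure-noise factor below 0.001.

The `examples/` directory walks through each stage as a narrative
script: data generation, the relevance function, resampling
diagnostics, the ablation, and learning curves / prediction on new
records.

## Command line

```bash
pcorona generate --n-rows 652 --n-proteins 60 --seed 0 \
    --out data.csv --roles-out roles.json
pcorona resample --data data.csv --roles roles.json \
    --protein protein_00 --strategy smoter --out diag.tsv
pcorona ablate --data data.csv --roles roles.json --n-trees 100 --out results/
```

## Documentation

`docs/methods.md` describes the statistical model, every default
parameter and its rationale, the synthetic generator's design and its
realism limits, and the package's numerical choices.
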