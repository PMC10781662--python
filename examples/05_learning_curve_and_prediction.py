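"""Learning curves and predicting RPA for new nanoparticle records.

The learning curve traces cross-validated RMSE against training-set
size, with the resampling step done inside each fold so nothing leaks
from validation data.  Fitted per-protein models carry their encoder
(one-hot level sets and min-max bounds from training time), so brand
new factor records can be scored directly.

Run:  python examples/05_learning_curve_and_prediction.py
"""

import pandas as pd

import pcorona as pc

dataset, _ = pc.generate_dataset(pc.SyntheticConfig(seed=0, n_proteins=3))
enc = pc.CoronaEncoder().fit_transform(dataset)
pid = dataset.protein_ids[0]
y = dataset.rpa[pid].to_numpy()

cfg = pc.ModelConfig(n_trees=60, cv_folds=5, seed=0)
print(f"learning curve for {pid} (5-fold CV RMSE):")
for resampler in (None, "random_over"):
    curve = pc.learning_curve(enc.X, y, cfg, resampler=resampler,
                              feature_kinds=enc.feature_groups(),
                              sizes=[100, 250, 521])
    label = resampler or "none"
    pts = ", ".join(f"n={s}: {m:.2f}±{sd:.2f}" for s, m, sd in curve)
    print(f"  {label:<12} {pts}")

# Train one model per protein and score new records.
reports, models = pc.run_ablation(
    dataset, strategies=("random_over",),
    config=pc.ModelConfig(n_trees=60, seed=0), return_models=True,
)
new_rows = dataset.factors.iloc[:2].copy()
new_rows.loc[new_rows.index[0], "incubation_plasma_concentration"] = 95.0
new_rows.loc[new_rows.index[1], "incubation_plasma_concentration"] = 6.0

pred = pc.predict_new(models["random_over"], new_rows)
table = pd.DataFrame(pred, columns=list(models["random_over"]))
print("\npredicted RPA for two new records (high vs low plasma concentration):")
print(table.round(3).to_string(index=False))
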