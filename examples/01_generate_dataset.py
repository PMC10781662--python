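"""Generate a synthetic protein-corona dataset and look at its shape.

The generator produces nanoparticle-incubation records — 8 categorical
and 13 numerical experiment factors — plus per-protein relative protein
abundance (RPA) targets.  RPA is strictly positive and strongly
right-skewed: most incubations bind little of any given protein, while
a rare combination of surface chemistry and plasma concentration binds
a lot.  That skew is what the rest of the package is about.

Run:  python examples/01_generate_dataset.py
"""

import numpy as np

import pcorona as pc

config = pc.SyntheticConfig(seed=0)  # 652 rows, 21 factors, 60 proteins
dataset, truth = pc.generate_dataset(config)

print(f"rows: {dataset.n_rows}")
print(f"categorical factors: {dataset.categorical_factors}")
print(f"numerical factors: {dataset.numerical_factors}")
print(f"proteins: {len(dataset.protein_ids)}")

rpa = dataset.rpa.to_numpy()
skews = [pc.skewness(rpa[:, j]) for j in range(rpa.shape[1])]
print(f"\nmean target skewness across proteins: {np.mean(skews):.2f}")
print(f"example protein_00 quartiles: {np.percentile(rpa[:, 0], [25, 50, 75, 99]).round(2)}")

# The ground truth records which factors actually drive each protein,
# including the per-protein coating x plasma-concentration synergy.
pid = dataset.protein_ids[0]
print(f"\nplanted effects for {pid}:")
for (p, factor), effect in truth.coefficients.items():
    if p == pid:
        print(f"  {factor}: {effect}")

# Round-trip through the on-disk format.
pc.write_corona_table("scratch_example_data.csv", dataset)
roles = pc.roles_of(dataset)
back = pc.read_corona_table("scratch_example_data.csv", roles)
assert np.allclose(back.rpa.to_numpy(), rpa)
print("\nround-trip through CSV: OK")

import os

os.remove("scratch_example_data.csv")
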