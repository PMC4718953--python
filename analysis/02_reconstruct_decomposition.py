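#!/usr/bin/env python
"""Reconstruct the standardized ACE decomposition from published estimates.

Takes the posterior-mean structural parameters of the single-group
interaction model (M1) and the full gender-interaction model (M2) and
applies the marginal variance decomposition
VAR(C) = exp(gamma0 + 0.5*gamma1^2*VAR(A)), VAR(E) analogously — the
mean of the conditional lognormal variance over A ~ N(0, VAR(A)) — then
standardizes to h2 / c2 / e2 and computes the fraction of full-sample
heritability attributable to genotype-by-environment interaction in men.

Writes results/decomposition_reconstruction.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from hetace import gxe_heritability_fraction, marginal_variances, preset_params

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

_, bio_m1 = preset_params("table8_M1")
_, bio_m2 = preset_params("table7_table8_M2")

rows = []
for label, dec in (
    ("M1 (single group)", marginal_variances(bio_m1, "male")),
    ("M2 males", marginal_variances(bio_m2, "male")),
    ("M2 females", marginal_variances(bio_m2, "female")),
):
    d = dec.as_dict()
    d["group"] = label
    rows.append(d)
table = pd.DataFrame(rows)
table.to_csv(OUT / "decomposition_reconstruction.csv", index=False)

print("Standardized variance components (marginal over A):")
print(table[["group", "h2", "e2", "c2"]].round(3).to_string(index=False))
print()
m1_h2 = rows[0]["h2"]
male_h2 = rows[1]["h2"]
frac = gxe_heritability_fraction(m1_h2, male_h2)
print(f"Heritability drops from {m1_h2:.2f} (full sample) to {male_h2:.2f} (males):")
print(f"  {frac:.0%} of the male heritability is attributable to GxE interaction.")
print()
print("Note the common-environment share in males (c2 ~ 0.20-0.22): invisible")
print("in the pooled analysis, it is revealed once the gender-specific A-by-C")
print("interaction (gamma1 < 0) is modelled.")
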