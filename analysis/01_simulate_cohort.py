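#!/usr/bin/env python
"""Simulate a twin cohort with the full gender-interaction structure.

Generates twin pairs (five zygosity-by-sex cells, including opposite-sex
DZ pairs) from the published full-model parameter preset with 5%
missing-at-random item nonresponse, then reports the descriptive checks
a real survey analysis would start with: pair counts per cell and
Cronbach's alpha of the item roster.

Writes results/cohort/twins.csv and twins_truth.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hetace.data import cronbach_alpha, read_twin_table, summarize_pairs
from hetace.pipeline import RunConfig, cmd_simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

config = RunConfig(
    out_dir=str(OUT),
    seed=42,
    options={
        "preset": "table7_table8_M2",
        "n_pairs": {"MZ-male": 200, "MZ-female": 200, "DZ-male": 130, "DZ-female": 130, "DZ-OS": 140},
        "missing_rate": 0.05,
    },
)
paths = cmd_simulate(config)
dataset = read_twin_table(paths["dataset"])

print(f"Simulated {dataset.n_pairs} twin pairs ({dataset.n_individuals} individuals), "
      f"{dataset.n_missing} missing responses "
      f"({dataset.n_missing / (dataset.n_individuals * 13):.1%} of cells).")
print()
print("Pairs per zygosity-by-sex cell (complete records in parentheses):")
counts = summarize_pairs(dataset)
for _, row in counts.iterrows():
    print(f"  {row['cell']:<10s} {row['n_pairs']:4d} ({row['n_complete']})")
print()
alpha = cronbach_alpha(dataset.table[list(dataset.roster)])
print(f"Cronbach's alpha over the 13 items (complete cases): {alpha:.2f}")
print("(the adult anxious-depression scale this emulates reports 0.83-0.90)")
print()
print(f"Artifacts: {paths['dataset']}, {paths['truth']}")
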