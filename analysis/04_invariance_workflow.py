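#!/usr/bin/env python
"""Measurement-invariance workflow on a planted threshold violation.

Two groups of MZ pairs are simulated with identical parameters except a
+1.0 shift of item 3's first threshold in group 1 — the analogue of a
'crying' item that one sex endorses far less often.  The stepwise
constraint schedule (free -> equal discriminations -> equal residual
correlations -> equal thresholds) is fitted, each step scored by the
marginal plug-in information criterion, and group differences of the
still-free thresholds are screened at the 99% HPD level.

Writes results/invariance/{comparison.csv,flags.csv}.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from hetace import SyntheticConfig, generate_dataset, preset_params
from hetace.invariance import compare_fits, fit_one_step, flag_noninvariant_items
from hetace.mcmc import McmcConfig
from hetace.params import MeasurementParams

OUT = Path(__file__).resolve().parents[1] / "results" / "invariance"
OUT.mkdir(parents=True, exist_ok=True)

meas, bio = preset_params("null_ACE")
meas6 = meas.subset(list(range(6)))
groups = {}
for gi, label in enumerate(("group1", "group2")):
    m = meas6
    if gi == 0:
        tau1 = m.tau1.copy()
        tau1[2] += 1.0
        tau2 = np.maximum(m.tau2, tau1 + 0.1)
        m = MeasurementParams(alpha=m.alpha, tau1=tau1, tau2=tau2, r_mz=m.r_mz, r_dz=m.r_dz, item_names=m.item_names)
    cfg = SyntheticConfig(n_pairs={"MZ-female": 200}, measurement=m, biometric=bio, seed=4000 + gi)
    ds, _ = generate_dataset(cfg)
    groups[label] = ds

cfgm = McmcConfig(n_iterations=1000, n_burnin=500, n_chains=1, seed=56)
fits = {s: fit_one_step(groups, s, cfgm) for s in ("step0", "step1a", "step1b", "step1c")}
comparison = compare_fits(fits)
comparison.to_csv(OUT / "comparison.csv", index=False)
print("Constraint schedule (criterion = marginal plug-in deviance + 2k):")
print(comparison.round(1).to_string(index=False))
print()
flags = flag_noninvariant_items(fits["step1b"], 0.99)
flags.to_csv(OUT / "flags.csv", index=False)
flagged = flags[flags.flagged]
print("Items whose group difference excludes 0 at the 99% level:")
print(flagged[["item", "parameter", "diff_mean", "hpd_low", "hpd_high"]].round(2).to_string(index=False))
print()
print("Equal thresholds (step 1c) degrade the fit and item 3 is flagged;")
print("the analysis would proceed on the remaining items, exactly as a")
print("gender-invariance check that drops a non-invariant item.")
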