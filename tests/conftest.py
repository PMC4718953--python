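import numpy as np
import pandas as pd
import pytest

from hetace import SyntheticConfig, TwinDataset, generate_dataset, preset_params
from hetace.data import DEFAULT_ROSTER


@pytest.fixture()
def toy_csv(tmp_path):
    """Two twin pairs, 13 items, one missing cell."""
    rows = []
    for pid, zyg, sexes in (("P1", "MZ", "MM"), ("P2", "DZ", "MF")):
        for j, sex in enumerate(sexes, start=1):
            rows.append([pid, j, zyg, sex, 30, 2009] + [0] * 13)
    df = pd.DataFrame(rows, columns=["pair_id", "member", "zygosity", "sex", "age", "occasion", *DEFAULT_ROSTER])
    df.loc[0, "item05"] = 2
    df.loc[3, "item01"] = pd.NA
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False, na_rep="NA")
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """120 mixed pairs from the null (linear ACE) preset, 5% missing."""
    meas, bio = preset_params("null_ACE")
    cfg = SyntheticConfig(
        n_pairs={"MZ-male": 30, "MZ-female": 30, "DZ-male": 20, "DZ-female": 20, "DZ-OS": 20},
        measurement=meas,
        biometric=bio,
        missing_rate=0.05,
        seed=123,
    )
    ds, state = generate_dataset(cfg)
    return ds, state


@pytest.fixture(scope="session")
def tiny_fit():
    """Small shared posterior fit (linear model) for structural checks."""
    from hetace.mcmc import McmcConfig, ModelSpec, sample_posterior

    meas, bio = preset_params("null_ACE")
    cfg = SyntheticConfig(
        n_pairs={"MZ-male": 40, "MZ-female": 40, "DZ-male": 40, "DZ-female": 40},
        measurement=meas.subset([0, 1, 2, 3]),
        biometric=bio,
        missing_rate=0.05,
        seed=9,
    )
    ds, _ = generate_dataset(cfg)
    fit = sample_posterior(
        ds,
        model=ModelSpec(interactions=True, gender_moderation=True),
        config=McmcConfig(n_iterations=400, n_burnin=200, n_chains=2, seed=17),
    )
    return fit
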