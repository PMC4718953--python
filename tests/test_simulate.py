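import math

import numpy as np
import pytest
from scipy import stats

from hetace import SyntheticConfig, apply_missingness, generate_dataset, preset_params
from hetace.params import BiometricParams


@pytest.fixture(scope="module")
def null_big():
    """25k pairs from the linear ACE preset (VarA, VarC, VarE) = (.5, .2, .3)."""
    meas, bio = preset_params("null_ACE")
    cfg = SyntheticConfig(n_pairs={"MZ-male": 12500, "DZ-male": 12500}, measurement=meas, biometric=bio, seed=3)
    return generate_dataset(cfg)


class TestLatentStructure:
    def test_total_variance_matches_closed_form(self, null_big):
        _, state = null_big
        # VAR(theta) = exp(omega0)+exp(gamma0)+exp(beta0) = 0.5+0.2+0.3 = 1
        assert state.theta.var() == pytest.approx(1.0, rel=0.02)

    def test_twin_correlations_match_ace_formulas(self, null_big):
        ds, state = null_big
        arr = ds.pair_arrays()
        th1, th2 = state.theta[arr["member1"]], state.theta[arr["member2"]]
        mz = arr["is_mz"]
        # MZ: (VarA+VarC)/Var = 0.7 ; DZ: (VarA/2+VarC)/Var = 0.45
        assert np.corrcoef(th1[mz], th2[mz])[0, 1] == pytest.approx(0.70, abs=0.02)
        assert np.corrcoef(th1[~mz], th2[~mz])[0, 1] == pytest.approx(0.45, abs=0.02)

    def test_mz_genetic_scores_identical_dz_correlate_half(self, null_big):
        ds, state = null_big
        arr = ds.pair_arrays()
        mz = arr["is_mz"]
        A1, A2 = state.A[arr["member1"]], state.A[arr["member2"]]
        assert np.array_equal(A1[mz], A2[mz])
        assert np.corrcoef(A1[~mz], A2[~mz])[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_common_environment_shared_when_no_interaction(self, null_big):
        ds, state = null_big
        arr = ds.pair_arrays()
        assert np.allclose(state.C[arr["member1"]], state.C[arr["member2"]])

    def test_residual_propensity_correlation_matches_r(self, null_big):
        ds, state = null_big
        meas, _ = preset_params("null_ACE")
        arr = ds.pair_arrays()
        mz = arr["is_mz"]
        resid = state.propensity - meas.alpha * state.theta[:, None]
        for k in (0, 4, 12):
            r_emp = np.corrcoef(resid[arr["member1"]][mz][:, k], resid[arr["member2"]][mz][:, k])[0, 1]
            assert r_emp == pytest.approx(meas.r_mz[k], abs=0.03)

    def test_interaction_induces_excess_kurtosis(self):
        meas, bio = preset_params("table7_table8_M2")
        cfg = SyntheticConfig(n_pairs={"MZ-male": 15000, "DZ-male": 10000}, measurement=meas, biometric=bio, seed=11)
        _, state = generate_dataset(cfg)
        assert stats.kurtosis(state.theta) > 0.1

    def test_no_interaction_theta_is_gaussian(self, null_big):
        _, state = null_big
        assert abs(stats.kurtosis(state.theta)) < 0.1
        assert abs(stats.skew(state.theta)) < 0.05


class TestMissingness:
    def test_rate_zero_is_identity(self, null_big):
        ds, _ = null_big
        sub = ds.subset_pairs(ds.table["pair_id"].unique()[:100])
        assert apply_missingness(sub, 0.0, seed=1) is sub

    def test_masked_fraction_matches_rate(self):
        meas, bio = preset_params("null_ACE")
        cfg = SyntheticConfig(n_pairs={"MZ-male": 500, "DZ-male": 500}, measurement=meas, biometric=bio, seed=5)
        ds, _ = generate_dataset(cfg)
        masked = apply_missingness(ds, 0.1, seed=2)
        n_cells = masked.n_individuals * 13
        frac = masked.n_missing / n_cells
        se = math.sqrt(0.1 * 0.9 / n_cells)
        assert abs(frac - 0.1) < 3 * se

    def test_same_seed_reproduces_mask(self, null_big):
        ds, _ = null_big
        sub = ds.subset_pairs(ds.table["pair_id"].unique()[:200])
        m1 = apply_missingness(sub, 0.3, seed=7)
        m2 = apply_missingness(sub, 0.3, seed=7)
        assert m1.table.equals(m2.table)

    def test_rate_one_rejected(self, null_big):
        ds, _ = null_big
        with pytest.raises(ValueError):
            apply_missingness(ds, 1.0, seed=1)


class TestPresets:
    def test_item5_matches_published_estimates(self):
        meas, _ = preset_params("table7_table8_M2")
        k = 4  # item 5
        assert (meas.alpha[k], meas.tau1[k], meas.tau2[k], meas.r_dz[k], meas.r_mz[k]) == (0.52, 0.09, 1.47, 0.12, 0.31)

    def test_m1_biometric_values(self):
        _, bio = preset_params("table8_M1")
        assert math.exp(bio.omega0_overall) == pytest.approx(0.64)
        assert (bio.beta0_overall, bio.beta1_overall) == (-0.68, 0.34)
        assert (bio.gamma0_overall, bio.gamma1_overall) == (-4.04, -1.38)

    def test_null_preset_has_no_interactions_or_gender_effects(self):
        _, bio = preset_params("null_ACE")
        assert bio.beta1_overall == bio.gamma1_overall == 0.0
        assert bio.omega0_female == bio.beta0_female == bio.gamma0_female == 0.0
        assert bio.nu == 0.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            preset_params("no_such_preset")


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        meas, bio = preset_params("null_ACE")
        with pytest.raises(ValueError):
            SyntheticConfig(n_pairs={"MZ-male": -1}, measurement=meas, biometric=bio)

    def test_unknown_cell_rejected(self):
        meas, bio = preset_params("null_ACE")
        with pytest.raises(ValueError):
            SyntheticConfig(n_pairs={"MZ-male-young": 10}, measurement=meas, biometric=bio)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ValueError):
            BiometricParams(beta1_overall=float("nan"))

    def test_same_seed_reproduces_dataset(self):
        meas, bio = preset_params("table7_table8_M2")
        cfg = SyntheticConfig(n_pairs={"MZ-female": 50, "DZ-OS": 50}, measurement=meas, biometric=bio, missing_rate=0.1, seed=21)
        d1, _ = generate_dataset(cfg)
        d2, _ = generate_dataset(cfg)
        assert d1.table.equals(d2.table)


class TestMeasurementSerialization:
    def test_csv_roundtrip_preserves_parameters(self, tmp_path):
        meas, _ = preset_params("table7_table8_M2")
        path = tmp_path / "items.csv"
        meas.to_csv(path)
        back = type(meas).from_csv(path)
        assert back.item_names == meas.item_names
        assert np.allclose(back.alpha, meas.alpha)
        assert np.allclose(back.tau1, meas.tau1)
        assert np.allclose(back.tau2, meas.tau2)
        assert np.allclose(back.r_mz, meas.r_mz)
        assert np.allclose(back.r_dz, meas.r_dz)
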