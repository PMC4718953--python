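import math
import warnings

import numpy as np
import pandas as pd
import pytest

from hetace import SyntheticConfig, generate_dataset, preset_params
from hetace.data import DEFAULT_ROSTER, TwinDataset
from hetace.invariance import (
    STEPS,
    ConstraintSchedule,
    GroupingSpec,
    age_bins,
    compare_fits,
    fit_one_step,
    flag_noninvariant_items,
    marginal_pair_loglik,
    split_groups,
)
from hetace.mcmc import McmcConfig, _PairData
from hetace.params import MeasurementParams


class TestAgeBins:
    @pytest.mark.parametrize("age,label", [(18, "18-19"), (19, "18-19"), (20, "20-21"), (24, "22-24"), (25, "25-34"), (35, "35-70"), (70, "35-70")])
    def test_band_assignment(self, age, label):
        assert age_bins([age])[0] == label

    def test_out_of_range_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            labels = age_bins([17, 25, 71])
        assert labels[0] is None and labels[2] is None and labels[1] == "25-34"

    def test_bands_must_be_contiguous(self):
        with pytest.raises(ValueError):
            GroupingSpec("age_band", age_bands=((18, 19), (21, 24)))

    def test_unknown_grouping_variable(self):
        with pytest.raises(ValueError):
            GroupingSpec("height")


def _pair_rows(pid, zyg, sexes, ages, occ=2009):
    rows = []
    for j, (sex, age) in enumerate(zip(sexes, ages), start=1):
        rows.append([pid, j, zyg, sex, age, occ] + [0] * 13)
    return rows


class TestSplitGroups:
    def _dataset(self, specs):
        rows = []
        for spec in specs:
            rows.extend(_pair_rows(*spec))
        df = pd.DataFrame(rows, columns=["pair_id", "member", "zygosity", "sex", "age", "occasion", *DEFAULT_ROSTER])
        return TwinDataset(df)

    def test_same_band_pair_kept_cross_band_dropped(self):
        ds = self._dataset([("P1", "MZ", "FF", (19, 19)), ("P2", "DZ", "MM", (19, 21))])
        with pytest.warns(UserWarning, match="cross-group"):
            groups = split_groups(ds, GroupingSpec("age_band"))
        assert list(groups) == ["18-19"]
        assert groups["18-19"].n_pairs == 1

    def test_gender_grouping_three_dz_groups(self):
        ds = self._dataset([("P1", "DZ", "MM", (30, 30)), ("P2", "DZ", "FF", (30, 30)), ("P3", "DZ", "MF", (30, 30)), ("P4", "MZ", "FF", (40, 40))])
        groups = split_groups(ds, GroupingSpec("gender"))
        assert set(groups) == {"male", "female", "opposite-sex"}
        assert groups["opposite-sex"].n_pairs == 1

    def test_grouped_plus_dropped_equals_total(self):
        ds = self._dataset(
            [("P1", "MZ", "FF", (19, 19)), ("P2", "DZ", "MM", (19, 21)), ("P3", "MZ", "MM", (40, 40)), ("P4", "DZ", "FF", (17, 17))]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = split_groups(ds, GroupingSpec("age_band"))
        grouped = sum(g.n_pairs for g in groups.values())
        assert grouped == 2  # P2 crosses bands, P4 is under-age
        assert ds.n_pairs - grouped == 2


class TestConstraintSchedule:
    def test_default_steps_strictly_nested(self):
        schedule = ConstraintSchedule()
        assert schedule.steps == STEPS

    def test_non_nested_order_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSchedule(("step1c", "step1a"))

    def test_free_parameter_count_strictly_decreasing(self):
        counts = [ConstraintSchedule.free_parameter_count(s, n_groups=5, n_items=13) for s in STEPS]
        assert all(a > b for a, b in zip(counts, counts[1:]))


@pytest.fixture(scope="module")
def invariant_groups():
    meas, bio = preset_params("null_ACE")
    meas6 = meas.subset(list(range(6)))
    out = {}
    for gi, label in enumerate(("g1", "g2")):
        cfg = SyntheticConfig(n_pairs={"MZ-female": 150}, measurement=meas6, biometric=bio, seed=600 + gi)
        ds, _ = generate_dataset(cfg)
        out[label] = ds
    return out


@pytest.fixture(scope="module")
def shifted_tau_groups():
    """Group 1 carries a +1.0 shift on item 3's first threshold."""
    meas, bio = preset_params("null_ACE")
    meas6 = meas.subset(list(range(6)))
    out = {}
    for gi, label in enumerate(("g1", "g2")):
        m = meas6
        if gi == 0:
            t1 = m.tau1.copy()
            t1[2] += 1.0
            t2 = np.maximum(m.tau2, t1 + 0.1)
            m = MeasurementParams(alpha=m.alpha, tau1=t1, tau2=t2, r_mz=m.r_mz, r_dz=m.r_dz, item_names=m.item_names)
        cfg = SyntheticConfig(n_pairs={"MZ-female": 200}, measurement=m, biometric=bio, seed=4000 + gi)
        ds, _ = generate_dataset(cfg)
        out[label] = ds
    return out


class TestMarginalPairLoglik:
    def test_single_item_against_integration_oracle(self):
        meas, bio = preset_params("null_ACE")
        cfg = SyntheticConfig(n_pairs={"MZ-female": 5}, measurement=meas.subset([4]), biometric=bio, seed=31)
        ds, _ = generate_dataset(cfg)
        data = _PairData(ds, ["item05"])
        params = {
            "alpha": np.array([0.52]),
            "tau": np.array([[0.09, 1.47]]),
            "r": {"MZ": np.array([0.31])},
            "mu": 0.1,
            "var": 0.9,
            "rho": {"MZ": 0.7},
        }
        lp = marginal_pair_loglik(data, params, n_theta=24, n_u=24)
        from hetace.measurement import pair_item_loglikelihood
        from hetace.params import MeasurementParams
        from scipy.integrate import dblquad

        mp = MeasurementParams(alpha=[0.52], tau1=[0.09], tau2=[1.47], r_mz=[0.31], r_dz=[0.1], identified=False)
        sd = math.sqrt(0.9)
        rho = 0.7
        for p in range(data.P):
            x1, x2 = int(data.X1[p, 0]), int(data.X2[p, 0])

            def integrand(t2, t1):
                prior = math.exp(
                    -((t1 - 0.1) ** 2 / 0.9 - 2 * rho * (t1 - 0.1) * (t2 - 0.1) / 0.9 + (t2 - 0.1) ** 2 / 0.9) / (2 * (1 - rho**2))
                ) / (2 * math.pi * 0.9 * math.sqrt(1 - rho**2))
                return prior * math.exp(pair_item_loglikelihood(x1, x2, t1, t2, mp, 0, "MZ"))

            ref, _ = dblquad(integrand, -5 * sd, 5 * sd, lambda _: -5 * sd, lambda _: 5 * sd, epsabs=1e-9)
            assert lp[p] == pytest.approx(math.log(ref), abs=2e-3)

    def test_outcome_probabilities_sum_to_one(self):
        # enumerate all 9 outcomes for one pair and one item
        params = {
            "alpha": np.array([1.0]),
            "tau": np.array([[0.2, 1.3]]),
            "r": {"MZ": np.array([0.25])},
            "mu": 0.0,
            "var": 1.0,
            "rho": {"MZ": 0.6},
        }
        meas, bio = preset_params("null_ACE")
        cfg = SyntheticConfig(n_pairs={"MZ-male": 1}, measurement=meas.subset([0]), biometric=bio, seed=1)
        ds, _ = generate_dataset(cfg)
        data = _PairData(ds, ["item01"])
        total = 0.0
        for x1 in range(3):
            for x2 in range(3):
                data.X1[0, 0], data.X2[0, 0] = x1, x2
                data.masks1 = tuple((data.X1 == k) for k in range(3))
                data.masks2 = tuple((data.X2 == k) for k in range(3))
                total += math.exp(marginal_pair_loglik(data, params, n_theta=20, n_u=16)[0])
        assert total == pytest.approx(1.0, abs=1e-6)


class TestWorkflow:
    def test_single_group_rejected(self, invariant_groups):
        only = {"g1": invariant_groups["g1"]}
        with pytest.raises(ValueError):
            fit_one_step(only, "step0", McmcConfig(n_iterations=20, n_burnin=10, n_chains=1))

    def test_identical_fit_compares_to_zero_difference(self, invariant_groups):
        cfg = McmcConfig(n_iterations=300, n_burnin=150, n_chains=1, seed=12)
        fit = fit_one_step(invariant_groups, "step0", cfg)
        comp = compare_fits({"step0": fit, "step0_again": fit})
        assert comp["delta"].iloc[1] == 0.0
        assert bool(comp["pass"].all())

    def test_invariant_groups_pass_full_schedule(self, invariant_groups):
        cfg = McmcConfig(n_iterations=800, n_burnin=400, n_chains=1, seed=13)
        fits = {s: fit_one_step(invariant_groups, s, cfg) for s in STEPS}
        comp = compare_fits(fits)
        assert bool(comp["pass"].all()), comp.to_string()

    def test_planted_threshold_shift_fails_step1c_and_is_flagged(self, shifted_tau_groups):
        cfg = McmcConfig(n_iterations=1000, n_burnin=500, n_chains=1, seed=56)
        fits = {s: fit_one_step(shifted_tau_groups, s, cfg) for s in ("step0", "step1a", "step1b", "step1c")}
        comp = compare_fits(fits).set_index("step")
        assert comp.loc["step1b", "pass"]
        assert not comp.loc["step1c", "pass"]
        flags = flag_noninvariant_items(fits["step1b"], 0.99)
        tau_flags = flags[(flags.parameter == "tau1") & flags.flagged]
        assert list(tau_flags["item"]) == ["item03"]

    def test_flagged_item_exclusion_feeds_model_spec(self, shifted_tau_groups):
        # excluding the flagged item leaves a 5-item roster for refitting
        ds = shifted_tau_groups["g1"]
        reduced = ds.subset_items([c for c in ds.roster if c != "item03"])
        assert len(reduced.roster) == 5


class TestOccasionHomogeneity:
    def test_per_occasion_decomposition_table(self):
        import pandas as pd

        from hetace.invariance import occasion_homogeneity

        meas, bio = preset_params("null_ACE")
        meas4 = meas.subset([0, 1, 2, 3])
        frames = []
        for occ, seed in ((1991, 50), (1997, 51)):
            cfg = SyntheticConfig(
                n_pairs={"MZ-male": 40, "DZ-male": 40}, measurement=meas4, biometric=bio, seed=seed, occasion=occ
            )
            ds, _ = generate_dataset(cfg)
            frames.append(ds.table)
        merged = pd.concat(frames, ignore_index=True)
        merged["pair_id"] = merged["pair_id"] + "_" + merged["occasion"].astype(str)
        ds_all = TwinDataset(merged, roster=meas4.item_names)
        table = occasion_homogeneity(ds_all, McmcConfig(n_iterations=300, n_burnin=150, n_chains=1, seed=9))
        assert set(table["occasion"]) == {"1991", "1997"}
        assert set(table["component"]) == {"h2", "c2", "e2"}
        # same generative process in both occasions: HPDs should overlap
        assert table["hpds_overlap"].all()
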