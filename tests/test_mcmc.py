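import numpy as np
import pytest
from scipy import stats

from hetace import SyntheticConfig, generate_dataset, preset_params
from hetace.mcmc import (
    McmcConfig,
    ModelSpec,
    PosteriorSamples,
    gelman_rubin,
    hpd_interval,
    posterior_summary,
    sample_posterior,
)


class TestHpdInterval:
    def test_normal_draws_match_quantile_oracle(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = hpd_interval(x, 0.99)
        z = stats.norm.ppf(0.995)
        assert lo == pytest.approx(-z, abs=0.01)
        assert hi == pytest.approx(z, abs=0.01)

    def test_uniform_draws_width(self):
        x = np.random.default_rng(1).random(200_000)
        lo, hi = hpd_interval(x, 0.99)
        assert hi - lo == pytest.approx(0.99, abs=0.005)

    def test_constant_draws_degenerate_interval(self):
        assert hpd_interval(np.full(500, 3.25), 0.99) == (3.25, 3.25)

    def test_skewed_draws_shorter_than_central_interval(self):
        x = np.random.default_rng(2).exponential(size=100_000)
        lo, hi = hpd_interval(x, 0.9)
        q = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) < (q[1] - q[0])
        assert lo == pytest.approx(0.0, abs=0.01)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(50), 0.99)
        with pytest.raises(ValueError):
            hpd_interval(np.arange(500), 1.2)


class TestGelmanRubin:
    def test_converged_chains_near_one(self):
        rng = np.random.default_rng(3)
        draws = {"x": rng.standard_normal((2, 10_000))}
        assert 1.0 <= gelman_rubin(draws)["x"] < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(4)
        arr = np.stack([rng.standard_normal(1000), 10 + rng.standard_normal(1000)])
        # W ~= 1, B/n ~= 50 -> R ~= sqrt(50) >> 3
        assert gelman_rubin({"x": arr})["x"] > 3.0

    def test_constant_chains_convention(self):
        assert gelman_rubin({"x": np.ones((2, 100))})["x"] == 1.0

    def test_matches_arviz_reference(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        arr = np.stack([rng.standard_normal(2000), 0.3 + 1.2 * rng.standard_normal(2000)])
        ours = gelman_rubin({"x": arr})["x"]
        ref = float(az.rhat(az.convert_to_dataset(arr))["x"].values.item())
        # estimator variants (rank-normalised vs classic) agree loosely
        assert ours == pytest.approx(ref, abs=0.1)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin({"x": np.ones((1, 100))})


class TestSamplePosterior:
    def test_empty_dataset_rejected(self):
        from hetace.data import DEFAULT_ROSTER, TwinDataset
        import pandas as pd

        ds = TwinDataset(pd.DataFrame(columns=["pair_id", "member", "zygosity", "sex", "age", "occasion", *DEFAULT_ROSTER]))
        with pytest.raises(ValueError):
            sample_posterior(ds, config=McmcConfig(n_iterations=10, n_burnin=5, n_chains=1))

    def test_degenerate_item_named_in_error(self):
        meas, bio = preset_params("null_ACE")
        cfg = SyntheticConfig(n_pairs={"MZ-male": 20}, measurement=meas.subset([0, 1]), biometric=bio, seed=1)
        ds, _ = generate_dataset(cfg)
        ds.table["item02"] = 1  # no variation
        with pytest.raises(ValueError, match="item02"):
            sample_posterior(ds, config=McmcConfig(n_iterations=10, n_burnin=5, n_chains=1))

    def test_gender_moderation_needs_both_sexes(self):
        meas, bio = preset_params("null_ACE")
        cfg = SyntheticConfig(n_pairs={"MZ-male": 30, "DZ-male": 30}, measurement=meas.subset([0, 1, 2]), biometric=bio, seed=2)
        ds, _ = generate_dataset(cfg)
        with pytest.raises(ValueError, match="both sexes"):
            sample_posterior(ds, model=ModelSpec(gender_moderation=True), config=McmcConfig(n_iterations=10, n_burnin=5, n_chains=1))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=100, n_burnin=50, n_chains=0)

    def test_reproducible_under_seed(self):
        meas, bio = preset_params("null_ACE")
        cfg = SyntheticConfig(n_pairs={"MZ-male": 20, "MZ-female": 20, "DZ-male": 20, "DZ-female": 20}, measurement=meas.subset([0, 1, 2]), biometric=bio, seed=8)
        ds, _ = generate_dataset(cfg)
        mc = McmcConfig(n_iterations=120, n_burnin=60, n_chains=1, seed=42)
        f1 = sample_posterior(ds, config=mc)
        f2 = sample_posterior(ds, config=mc)
        for name in f1.names:
            assert np.array_equal(f1.get(name), f2.get(name))

    def test_draws_respect_prior_support(self, tiny_fit):
        fit = tiny_fit
        for name in fit.names:
            x = fit.stacked(name)
            cls = fit.prior_class[name]
            if cls == "uniform(-5,5)":
                assert x.min() >= -5.0 and x.max() <= 5.0
            elif cls == "sqrt-uniform(0,1)":
                assert x.min() >= 0.0 and x.max() < 1.0
        items = fit.provenance["items"]
        for item in items:
            assert np.all(fit.stacked(f"tau1[{item}]") < fit.stacked(f"tau2[{item}]"))

    def test_derived_proportions_sum_to_one_per_draw(self, tiny_fit):
        fit = tiny_fit
        total = fit.stacked("h2_male") + fit.stacked("c2_male") + fit.stacked("e2_male")
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_excluded_items_absent_from_draws(self):
        meas, bio = preset_params("null_ACE")
        cfg = SyntheticConfig(n_pairs={"MZ-male": 25, "DZ-male": 25}, measurement=meas.subset([0, 1, 2, 3]), biometric=bio, seed=3)
        ds, _ = generate_dataset(cfg)
        fit = sample_posterior(
            ds,
            model=ModelSpec(gender_moderation=False, exclude_items=("item03",)),
            config=McmcConfig(n_iterations=60, n_burnin=30, n_chains=1, seed=5),
        )
        assert not any("item03" in n for n in fit.names)
        assert fit.provenance["items"] == ["item01", "item02", "item04"]


class TestPosteriorSummary:
    def test_degenerate_draws(self):
        samples = PosteriorSamples(draws={"x": np.full((2, 200), 1.5)}, prior_class={"x": "uniform(-5,5)"}, provenance={})
        row = posterior_summary(samples).iloc[0]
        assert row["mean"] == 1.5 and row["hpd_low"] == 1.5 and row["hpd_high"] == 1.5

    def test_symmetric_draws_mean_near_hpd_midpoint(self):
        rng = np.random.default_rng(6)
        samples = PosteriorSamples(draws={"x": rng.standard_normal((2, 20_000))}, prior_class={"x": "u"}, provenance={})
        row = posterior_summary(samples, level=0.95).iloc[0]
        assert row["mean"] == pytest.approx((row["hpd_low"] + row["hpd_high"]) / 2, abs=0.05)

    def test_summary_covers_all_parameters(self, tiny_fit):
        table = posterior_summary(tiny_fit)
        assert set(table["parameter"]) == set(tiny_fit.names)
        assert (table["hpd_low"] <= table["mean"]).all()
        assert (table["mean"] <= table["hpd_high"]).all()
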