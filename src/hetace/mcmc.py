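"""Bayesian estimation of the heteroscedastic ACE item model by MCMC.

The sampler is Metropolis-within-Gibbs on a non-centred
parameterisation: every latent quantity is expressed through
standard-normal kernels (pair-shared and member-unique genetic kernels
enforcing the 1 / 0.5 MZ / DZ correlation by construction, one shared
common-environment kernel per pair, member-unique unique-environment
kernels, and one shared kernel per pair and item carrying the residual
cross-twin item correlation).  Conditional on the item kernel U the two
members' scores are independent and each category probability is a
normal-CDF difference with mean ``alpha * theta + sqrt(r) * U`` and
variance ``1 - r``, so the ordinal propensities are marginalised
analytically; missing responses drop out of the likelihood, which is
equivalent to sampling them as parameters.  Structural and measurement
parameters use adaptive random-walk Metropolis with adaptation frozen
at the end of burn-in; thresholds are proposed jointly with rejection
of order violations (flat prior on the ordered region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from hetace.biometric import marginal_variances
from hetace.data import TwinDataset
from hetace.params import BiometricParams

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "ModelSpec",
    "PosteriorSamples",
    "sample_posterior",
    "gelman_rubin",
    "hpd_interval",
    "posterior_summary",
]

_STRUCT_NAMES = (
    "nu",
    "omega0_overall",
    "omega0_female",
    "beta0_overall",
    "beta0_female",
    "beta1_overall",
    "beta1_female",
    "gamma0_overall",
    "gamma0_female",
    "gamma1_overall",
    "gamma1_female",
)


@dataclass(frozen=True)
class PriorSpec:
    """Prior supports: uniform boxes plus the ordered-threshold region.

    Defaults follow the reference analysis: uniform(-5, 5) for
    discriminations (all but the fixed first), nu and the omega/beta/
    gamma parameters; a joint flat prior on ordered threshold pairs;
    uniform(0, 1) on sqrt(r) for both zygosities (preventing sign
    switching of the residual correlations).  Narrower per-class boxes
    (intercepts = the log-variance omega0/beta0/gamma0 parameters and
    their female offsets; slopes = the interaction parameters; nu) can
    be supplied, e.g. for prior-matched calibration experiments.
    """

    box_low: float = -5.0
    box_high: float = 5.0
    intercept_bounds: tuple[float, float] | None = None
    slope_bounds: tuple[float, float] | None = None
    nu_bounds: tuple[float, float] | None = None
    # ordered-flat threshold prior truncated to a wide box: keeps the
    # posterior proper when a category is (nearly) empty in the data
    tau_bounds: tuple[float, float] = (-10.0, 10.0)

    def bounds(self, name: str) -> tuple[float, float]:
        default = (self.box_low, self.box_high)
        if name.startswith(("omega0", "beta0", "gamma0")):
            return self.intercept_bounds or default
        if name.startswith(("beta1", "gamma1")):
            return self.slope_bounds or default
        if name == "nu":
            return self.nu_bounds or default
        return default

    def in_box(self, value: float, name: str = "") -> bool:
        lo, hi = self.bounds(name)
        return lo <= value <= hi


@dataclass(frozen=True)
class ModelSpec:
    """Model structure flags for :func:`sample_posterior`."""

    interactions: bool = True
    gender_moderation: bool = True
    exclude_items: tuple[str, ...] = ()


@dataclass(frozen=True)
class McmcConfig:
    n_iterations: int = 20_000
    n_burnin: int = 10_000
    n_chains: int = 2
    seed: int = 0
    thinning: int = 1
    adapt_window: int = 50  # batch length for acceptance-rate adaptation

    def __post_init__(self) -> None:
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


# test-scale default used throughout the test-suite and examples
TEST_CONFIG = McmcConfig(n_iterations=2_000, n_burnin=1_000, n_chains=2)


@dataclass
class PosteriorSamples:
    """Posterior draws: ``draws[name]`` has shape (n_chains, n_kept)."""

    draws: dict[str, np.ndarray]
    prior_class: dict[str, str]
    provenance: dict

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated."""
        return self.draws[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        recs = []
        for name, arr in self.draws.items():
            for c in range(arr.shape[0]):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(arr.shape[1]),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)


# --------------------------------------------------------------------------
# likelihood kernels
# --------------------------------------------------------------------------

_LOG_FLOOR = 1e-300


def _category_loglik(mean, s, tau, masks, obs):
    """(P, I) log-likelihood of 3-category scores.

    mean: (P, I) propensity means; s: (P, I) or scalar propensity sds;
    tau: (I, 2) thresholds; masks: boolean (m0, m1, m2) each (P, I);
    obs: (P, I) observation mask.
    """
    lo = ndtr((tau[:, 0] - mean) / s)
    hi = ndtr((tau[:, 1] - mean) / s)
    m0, m1, m2 = masks
    p = np.where(m0, lo, np.where(m1, hi - lo, 1.0 - hi))
    out = np.log(np.clip(p, _LOG_FLOOR, None))
    out[~obs] = 0.0
    return out


class _PairData:
    """Pair-structured views of a TwinDataset for the sampler."""

    def __init__(self, dataset: TwinDataset, items: list[str]):
        df = dataset.table
        if len(df) == 0:
            raise ValueError("empty dataset")
        self.items = items
        arr = dataset.pair_arrays()
        X = df[items].to_numpy(dtype=float, na_value=np.nan)
        self.X1 = X[arr["member1"]]
        self.X2 = X[arr["member2"]]
        self.is_mz = arr["is_mz"]
        fem = arr["female"]
        self.g1 = fem[arr["member1"]]
        self.g2 = fem[arr["member2"]]
        self.P, self.I = self.X1.shape
        self.obs1 = ~np.isnan(self.X1)
        self.obs2 = ~np.isnan(self.X2)
        self.masks1 = tuple((self.X1 == k) for k in range(3))
        self.masks2 = tuple((self.X2 == k) for k in range(3))
        pooled = np.vstack([self.X1, self.X2])
        for k, name in enumerate(items):
            col = pooled[:, k]
            col = col[~np.isnan(col)]
            if col.size == 0 or np.unique(col).size < 2:
                raise ValueError(f"degenerate item {name!r}: fewer than two observed categories")
        self.pooled = pooled


# --------------------------------------------------------------------------
# sampler state
# --------------------------------------------------------------------------


class _ChainState:
    def __init__(self, data: _PairData, model: ModelSpec, prior: PriorSpec, rng: np.random.Generator):
        self.data = data
        self.model = model
        self.prior = prior
        self.rng = rng
        P, I = data.P, data.I

        # measurement parameters
        pooled = data.pooled
        p0 = np.nanmean(pooled == 0, axis=0)
        p01 = np.nanmean(pooled <= 1, axis=0)
        from scipy.special import ndtri

        t1 = ndtri(np.clip(p0, 0.02, 0.98))
        t2 = ndtri(np.clip(p01, 0.02, 0.98))
        t2 = np.maximum(t2, t1 + 0.2)
        self.alpha = np.ones(I)
        self.tau = np.column_stack([t1, t2]) + 0.05 * rng.standard_normal((I, 2)) * [1.0, 1.0]
        self.tau[:, 1] = np.maximum(self.tau[:, 1], self.tau[:, 0] + 0.1)
        self.sr_mz = np.full(I, 0.45)
        self.sr_dz = np.full(I, 0.30)

        # structural parameters (within prior box); started from a crude
        # Falconer-style decomposition of a standardized sum-score proxy,
        # then chain-jittered — keeps short chains out of mirror basins
        self.struct = dict.fromkeys(_STRUCT_NAMES, 0.0)
        proxy = np.nanmean(np.where(np.isnan(data.X1), np.nan, data.X1), axis=1), np.nanmean(
            np.where(np.isnan(data.X2), np.nan, data.X2), axis=1
        )
        with np.errstate(invalid="ignore"):
            p1 = (proxy[0] - np.nanmean(proxy[0])) / (np.nanstd(proxy[0]) + 1e-9)
            p2 = (proxy[1] - np.nanmean(proxy[1])) / (np.nanstd(proxy[1]) + 1e-9)

        def _cor(rows):
            a, b = p1[rows], p2[rows]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 10:
                return 0.4
            return float(np.clip(np.corrcoef(a[ok], b[ok])[0, 1], -0.2, 0.95))

        r_mz_theta = _cor(data.is_mz) if data.is_mz.any() else 0.6
        r_dz_theta = _cor(~data.is_mz) if (~data.is_mz).any() else 0.35
        var_a0 = float(np.clip(2.0 * (r_mz_theta - r_dz_theta), 0.05, 0.9))
        var_c0 = float(np.clip(2.0 * r_dz_theta - r_mz_theta, 0.03, 0.6))
        var_e0 = float(np.clip(1.0 - var_a0 - var_c0, 0.1, 0.9))
        self.struct["omega0_overall"] = math.log(var_a0)
        self.struct["beta0_overall"] = math.log(var_e0)
        self.struct["gamma0_overall"] = math.log(var_c0)
        self.free_struct = ["omega0_overall", "beta0_overall", "gamma0_overall"]
        if model.interactions:
            self.free_struct += ["beta1_overall", "gamma1_overall"]
        if model.gender_moderation:
            self.free_struct += ["nu", "omega0_female", "beta0_female", "gamma0_female"]
            if model.interactions:
                self.free_struct += ["beta1_female", "gamma1_female"]
        for name in self.free_struct:
            lo, hi = prior.bounds(name)
            margin = 0.05 * (hi - lo)
            self.struct[name] = float(np.clip(self.struct[name] + 0.15 * rng.standard_normal(), lo + margin, hi - margin))

        # latent kernels
        self.za_sh = rng.standard_normal(P)
        self.za_u1 = rng.standard_normal(P)
        self.za_u2 = rng.standard_normal(P)
        self.zc = rng.standard_normal(P)
        self.w1 = rng.standard_normal(P)
        self.w2 = rng.standard_normal(P)
        self.U = rng.standard_normal((P, I))

        # proposal scales (log), adapted during burn-in
        self.scales = {
            "za_sh": 0.5,
            "za_u": 0.5,
            "zc": 0.5,
            "w": 0.6,
            "U": 0.8,
            "alpha": 0.06,
            "tau": 0.06,
            "sr_mz": 0.06,
            "sr_dz": 0.06,
        }
        for name in self.free_struct:
            self.scales[name] = 0.08
        if model.interactions:
            self.scales["ridge_beta"] = 0.15
            self.scales["ridge_gamma"] = 0.15
        self.scales["xchg"] = 0.3
        self.scales["asis_omega0_overall"] = 0.3
        self.scales["asis_omega0_female"] = 0.3
        self.scales["swap"] = 1.0  # unused magnitude; key tracks acceptance only
        self._acc = {k: [0, 0] for k in self.scales}

        self._refresh_residual()
        self.theta1, self.theta2 = self._compute_theta()
        self._refresh_loglik()

    # -- derived quantities ------------------------------------------------
    def _refresh_residual(self) -> None:
        d = self.data
        r_pair = np.where(d.is_mz[:, None], (self.sr_mz**2)[None, :], (self.sr_dz**2)[None, :])
        self.sr = np.sqrt(r_pair)
        self.s = np.sqrt(1.0 - r_pair)

    def _compute_theta(self, struct=None, za_sh=None, za_u1=None, za_u2=None, zc=None, w1=None, w2=None):
        st = struct if struct is not None else self.struct
        d = self.data
        za_sh = self.za_sh if za_sh is None else za_sh
        za_u1 = self.za_u1 if za_u1 is None else za_u1
        za_u2 = self.za_u2 if za_u2 is None else za_u2
        zc = self.zc if zc is None else zc
        w1 = self.w1 if w1 is None else w1
        w2 = self.w2 if w2 is None else w2
        half = math.sqrt(0.5)
        out = []
        for g, za_u, w in ((d.g1, za_u1, w1), (d.g2, za_u2, w2)):
            sd_a = np.exp(0.5 * (st["omega0_overall"] + st["omega0_female"] * g))
            kern = np.where(d.is_mz, za_sh, half * za_sh + half * za_u)
            A = sd_a * kern
            C = np.exp(0.5 * (st["gamma0_overall"] + st["gamma0_female"] * g + (st["gamma1_overall"] + st["gamma1_female"] * g) * A)) * zc
            E = np.exp(0.5 * (st["beta0_overall"] + st["beta0_female"] * g + (st["beta1_overall"] + st["beta1_female"] * g) * A)) * w
            out.append(st["nu"] * g + A + C + E)
        return out[0], out[1]

    def _mean(self, theta, member: int, alpha=None, U=None, sr=None):
        alpha = self.alpha if alpha is None else alpha
        U = self.U if U is None else U
        sr = self.sr if sr is None else sr
        return alpha[None, :] * theta[:, None] + sr * U

    def _member_ll(self, theta, member: int, alpha=None, tau=None, U=None, sr=None, s=None):
        d = self.data
        tau = self.tau if tau is None else tau
        s = self.s if s is None else s
        masks = d.masks1 if member == 1 else d.masks2
        obs = d.obs1 if member == 1 else d.obs2
        return _category_loglik(self._mean(theta, member, alpha, U, sr), s, tau, masks, obs)

    def _refresh_loglik(self) -> None:
        self.L1 = self._member_ll(self.theta1, 1)
        self.L2 = self._member_ll(self.theta2, 2)

    # -- adaptation --------------------------------------------------------
    def _record(self, key: str, accepted: float, total: float) -> None:
        a = self._acc[key]
        a[0] += accepted
        a[1] += total

    def adapt(self, step: float) -> None:
        for key, (acc, tot) in self._acc.items():
            if tot == 0:
                continue
            rate = acc / tot
            target = 0.35
            self.scales[key] = float(np.clip(self.scales[key] * math.exp(step * (rate - target)), 1e-4, 5.0))
        self._acc = {k: [0, 0] for k in self.scales}

    # -- update blocks -----------------------------------------------------
    def _latent_pair_block(self, key: str, arrays: dict) -> None:
        """Generic per-pair MH update of one or more latent kernel arrays."""
        rng = self.rng
        P = self.data.P
        eps = self.scales[key]
        prop = {name: arr + eps * rng.standard_normal(P) for name, arr in arrays.items()}
        th1, th2 = self._compute_theta(**prop)
        L1 = self._member_ll(th1, 1)
        L2 = self._member_ll(th2, 2)
        logr = (L1 - self.L1).sum(axis=1) + (L2 - self.L2).sum(axis=1)
        for name, arr in arrays.items():
            logr += 0.5 * (arr**2 - prop[name] ** 2)
        acc = np.log(rng.random(P)) < logr
        for name, arr in arrays.items():
            arr[acc] = prop[name][acc]
        self.theta1[acc] = th1[acc]
        self.theta2[acc] = th2[acc]
        self.L1[acc] = L1[acc]
        self.L2[acc] = L2[acc]
        self._record(key, acc.sum(), P)

    def update_latents(self) -> None:
        d = self.data
        self._latent_pair_block("za_sh", {"za_sh": self.za_sh})
        if not d.is_mz.all():
            self._latent_pair_block("za_u", {"za_u1": self.za_u1, "za_u2": self.za_u2})
        self._latent_pair_block("zc", {"zc": self.zc})
        self._latent_pair_block("w", {"w1": self.w1, "w2": self.w2})
        self._update_U()

    def _update_U(self) -> None:
        rng = self.rng
        d = self.data
        prop = self.U + self.scales["U"] * rng.standard_normal((d.P, d.I))
        L1 = self._member_ll(self.theta1, 1, U=prop)
        L2 = self._member_ll(self.theta2, 2, U=prop)
        logr = (L1 - self.L1) + (L2 - self.L2) + 0.5 * (self.U**2 - prop**2)
        acc = np.log(rng.random((d.P, d.I))) < logr
        self.U[acc] = prop[acc]
        self.L1[acc] = L1[acc]
        self.L2[acc] = L2[acc]
        self._record("U", acc.sum(), acc.size)

    def _itemwise_accept(self, key: str, L1, L2, valid: np.ndarray) -> np.ndarray:
        """Column-sum MH acceptance per item; returns accepted-item mask."""
        delta = (L1 - self.L1).sum(axis=0) + (L2 - self.L2).sum(axis=0)
        logr = np.where(valid, delta, -np.inf)
        acc = np.log(self.rng.random(self.data.I)) < logr
        self.L1[:, acc] = L1[:, acc]
        self.L2[:, acc] = L2[:, acc]
        self._record(key, acc.sum(), valid.sum() if valid.any() else 1)
        return acc

    def update_measurement(self) -> None:
        rng = self.rng
        d = self.data
        pr = self.prior
        # discriminations (item 1 fixed at 1 for identification)
        prop = self.alpha + self.scales["alpha"] * rng.standard_normal(d.I)
        prop[0] = self.alpha[0]
        valid = (prop >= pr.box_low) & (prop <= pr.box_high)
        valid[0] = False
        L1 = self._member_ll(self.theta1, 1, alpha=prop)
        L2 = self._member_ll(self.theta2, 2, alpha=prop)
        acc = self._itemwise_accept("alpha", L1, L2, valid)
        self.alpha[acc] = prop[acc]

        # thresholds: joint proposal, flat prior on the ordered region
        prop_tau = self.tau + self.scales["tau"] * rng.standard_normal((d.I, 2))
        valid = (prop_tau[:, 0] < prop_tau[:, 1]) & (prop_tau[:, 0] >= pr.tau_bounds[0]) & (prop_tau[:, 1] <= pr.tau_bounds[1])
        L1 = self._member_ll(self.theta1, 1, tau=prop_tau)
        L2 = self._member_ll(self.theta2, 2, tau=prop_tau)
        acc = self._itemwise_accept("tau", L1, L2, valid)
        self.tau[acc] = prop_tau[acc]

        # residual correlations on the sqrt scale, uniform(0,1)
        for key, attr, rows in (("sr_mz", "sr_mz", d.is_mz), ("sr_dz", "sr_dz", ~d.is_mz)):
            if not rows.any():
                continue
            cur = getattr(self, attr)
            prop_sr = cur + self.scales[key] * rng.standard_normal(d.I)
            valid = (prop_sr > 0.0) & (prop_sr < 1.0)
            prop_sr = np.where(valid, prop_sr, cur)
            new = {attr: prop_sr}
            sr_mz = new.get("sr_mz", self.sr_mz)
            sr_dz = new.get("sr_dz", self.sr_dz)
            r_pair = np.where(d.is_mz[:, None], (sr_mz**2)[None, :], (sr_dz**2)[None, :])
            sr_mat = np.sqrt(r_pair)
            s_mat = np.sqrt(1.0 - r_pair)
            L1 = self._member_ll(self.theta1, 1, sr=sr_mat, s=s_mat)
            L2 = self._member_ll(self.theta2, 2, sr=sr_mat, s=s_mat)
            # only rows of this zygosity change, but full-matrix delta is exact
            acc = self._itemwise_accept(key, L1, L2, valid)
            cur[acc] = prop_sr[acc]
            self._refresh_residual()

    def _try_struct(self, key: str, trial: dict, log_jacobian: float = 0.0) -> None:
        """Generic MH accept/reject of a full structural proposal."""
        if not all(self.prior.in_box(trial[n], n) for n in self.free_struct):
            self._record(key, 0, 1)
            return
        th1, th2 = self._compute_theta(struct=trial)
        L1 = self._member_ll(th1, 1)
        L2 = self._member_ll(th2, 2)
        logr = (L1 - self.L1).sum() + (L2 - self.L2).sum() + log_jacobian
        if math.log(self.rng.random()) < logr:
            self.struct = trial
            self.theta1, self.theta2 = th1, th2
            self.L1, self.L2 = L1, L2
            self._record(key, 1, 1)
        else:
            self._record(key, 0, 1)

    def _ridge_moves(self) -> None:
        """Shear proposals along the marginal-variance ridge.

        The likelihood constrains the marginal environmental variances
        exp(c0 + 0.5*c1^2*VAR(A)) much more strongly than the slopes, so
        a slope step is paired with the intercept adjustment that keeps
        each sex's marginal variance fixed.  The map is unit-Jacobian
        and the noise is symmetric, so plain MH acceptance applies.
        """
        st = self.struct
        s2a = {0: math.exp(st["omega0_overall"]), 1: math.exp(st["omega0_overall"] + st["omega0_female"])}
        gm = self.model.gender_moderation
        for slope_o, slope_f, icpt_o, icpt_f, key in (
            ("beta1_overall", "beta1_female", "beta0_overall", "beta0_female", "ridge_beta"),
            ("gamma1_overall", "gamma1_female", "gamma0_overall", "gamma0_female", "ridge_gamma"),
        ):
            if slope_o not in self.free_struct:
                continue
            # move the overall slope, compensating both sexes' intercepts
            eps = self.scales[key] * self.rng.standard_normal()
            trial = dict(st)
            trial[slope_o] = st[slope_o] + eps
            d_male = 0.5 * (trial[slope_o] ** 2 - st[slope_o] ** 2) * s2a[0]
            trial[icpt_o] = st[icpt_o] - d_male
            if gm:
                e1_f = st[slope_o] + st[slope_f]
                d_fem = 0.5 * ((e1_f + eps) ** 2 - e1_f**2) * s2a[1]
                trial[icpt_f] = st[icpt_f] - d_fem + d_male
            self._try_struct(key, trial)
            if gm and slope_f in self.free_struct:
                st = self.struct
                eps = self.scales[key] * self.rng.standard_normal()
                trial = dict(st)
                trial[slope_f] = st[slope_f] + eps
                e1_f = st[slope_o] + st[slope_f]
                trial[icpt_f] = st[icpt_f] - 0.5 * ((e1_f + eps) ** 2 - e1_f**2) * s2a[1]
                self._try_struct(key, trial)
            st = self.struct

    def _exchange_moves(self) -> None:
        """Trade VAR(A) against VAR(C) at (approximately) fixed total.

        The total phenotypic variance is tightly constrained while the
        A/C split is informed only by the MZ-DZ correlation contrast, so
        a move in omega0 is paired with the gamma0 adjustment preserving
        exp(omega0) + exp(gamma0) for the sex concerned.  The gamma0
        companion is nonlinear; its Jacobian exp(gamma0 - gamma0') enters
        the acceptance ratio.
        """
        gm = self.model.gender_moderation

        def male_totals(st):
            return math.exp(st["omega0_overall"]), math.exp(st["gamma0_overall"])

        # male (overall) exchange, leaving the female totals untouched
        st = self.struct
        eps = self.scales["xchg"] * self.rng.standard_normal()
        va, vc = male_totals(st)
        va_new = math.exp(st["omega0_overall"] + eps)
        vc_new = vc + va - va_new
        if vc_new > 0:
            trial = dict(st)
            trial["omega0_overall"] = st["omega0_overall"] + eps
            trial["gamma0_overall"] = math.log(vc_new)
            logj = st["gamma0_overall"] - trial["gamma0_overall"]
            if gm:
                trial["omega0_female"] = st["omega0_female"] - eps
                trial["gamma0_female"] = st["gamma0_female"] - (trial["gamma0_overall"] - st["gamma0_overall"])
            self._try_struct("xchg", trial, logj)
        else:
            self._record("xchg", 0, 1)
        if not gm:
            return
        # female exchange
        st = self.struct
        eps = self.scales["xchg"] * self.rng.standard_normal()
        va = math.exp(st["omega0_overall"] + st["omega0_female"])
        vc = math.exp(st["gamma0_overall"] + st["gamma0_female"])
        va_new = va * math.exp(eps)
        vc_new = vc + va - va_new
        if vc_new > 0:
            trial = dict(st)
            trial["omega0_female"] = st["omega0_female"] + eps
            g_eff_new = math.log(vc_new)
            trial["gamma0_female"] = g_eff_new - st["gamma0_overall"]
            logj = (st["gamma0_overall"] + st["gamma0_female"]) - g_eff_new
            self._try_struct("xchg", trial, logj)
        else:
            self._record("xchg", 0, 1)

    def _asis_omega(self) -> None:
        """Interweaved update of the A-variance parameters.

        A step in omega0 is paired with the affine kernel remapping that
        keeps every genetic score A — hence theta and the likelihood —
        exactly fixed.  The proposal is deterministic given the
        symmetric step, so the acceptance ratio is the kernel-prior
        ratio times the Jacobian of the affine map.  Interweaving this
        with the non-centred updates breaks the slow random walk in the
        A-variance direction.
        """
        d = self.data
        dz = ~d.is_mz
        names = ["omega0_overall"] + (["omega0_female"] if "omega0_female" in self.free_struct else [])
        for name in names:
            key = f"asis_{name}"
            eps = self.scales[key] * self.rng.standard_normal()
            trial = dict(self.struct)
            trial[name] = trial[name] + eps
            if not self.prior.in_box(trial[name], name):
                self._record(key, 0, 1)
                continue
            f = math.exp(-eps / 2.0)
            # affine remapping x -> slope * x + shift per kernel, chosen so
            # that A is invariant; only kernels entering A are touched
            if name == "omega0_overall":
                plans = [
                    ("za_sh", np.ones(d.P, dtype=bool), f * np.ones(d.P), 0.0),
                    ("za_u1", dz, f * np.ones(d.P), 0.0),
                    ("za_u2", dz, f * np.ones(d.P), 0.0),
                ]
            else:
                both_f = (d.g1 == 1.0) & (d.g2 == 1.0)
                os1 = dz & (d.g1 == 1.0) & (d.g2 == 0.0)
                os2 = dz & (d.g2 == 1.0) & (d.g1 == 0.0)
                # same-sex female pairs scale uniformly; in opposite-sex
                # pairs the shared kernel serves the male member, so only
                # the female unique kernel moves: za_u' = f*(za_u+za_sh)-za_sh
                plans = [
                    ("za_sh", both_f, f * np.ones(d.P), 0.0),
                    ("za_u1", both_f & dz, f * np.ones(d.P), 0.0),
                    ("za_u2", both_f & dz, f * np.ones(d.P), 0.0),
                    ("za_u1", os1, f * np.ones(d.P), (f - 1.0) * self.za_sh),
                    ("za_u2", os2, f * np.ones(d.P), (f - 1.0) * self.za_sh),
                ]
            logr = 0.0
            work = {attr: getattr(self, attr).copy() for attr, _, _, _ in plans}
            for attr, rows, slope, shift in plans:
                x = work[attr]
                xn = np.where(rows, slope * x + shift, x)
                logr += float((0.5 * (x[rows] ** 2 - xn[rows] ** 2)).sum()) + math.log(f) * int(rows.sum())
                work[attr] = xn
            if math.log(self.rng.random()) < logr:
                self.struct = trial
                for attr, xn in work.items():
                    setattr(self, attr, xn)
                self._record(key, 1, 1)
            else:
                self._record(key, 0, 1)

    def _asis_env_scales(self) -> None:
        """Interweaved updates of the E- and C-variance intercepts.

        beta0 moves rescale the member-unique kernels w so that every E
        value is fixed (theta and the likelihood unchanged); gamma0
        moves rescale the shared kernel zc likewise for C.  The female
        gamma0 offset cannot keep both members' C fixed in opposite-sex
        pairs (zc is shared there), so that move re-evaluates the
        likelihood, which changes only on those pairs.
        """
        d = self.data
        ones = np.ones(d.P, dtype=bool)
        fem1, fem2 = d.g1 == 1.0, d.g2 == 1.0
        both_f = fem1 & fem2
        os_pair = fem1 != fem2
        moves = [("beta0_overall", [("w1", ones), ("w2", ones)], False)]
        if "beta0_female" in self.free_struct:
            moves.append(("beta0_female", [("w1", fem1), ("w2", fem2)], False))
        moves.append(("gamma0_overall", [("zc", ones)], False))
        if "gamma0_female" in self.free_struct:
            moves.append(("gamma0_female", [("zc", both_f)], bool(os_pair.any())))
        for name, plans, need_lik in moves:
            key = f"asis_{name}"
            if key not in self.scales:
                self.scales[key] = 0.3
                self._acc[key] = [0, 0]
            eps = self.scales[key] * self.rng.standard_normal()
            trial = dict(self.struct)
            trial[name] = trial[name] + eps
            if not self.prior.in_box(trial[name], name):
                self._record(key, 0, 1)
                continue
            f = math.exp(-eps / 2.0)
            logr = 0.0
            work = {}
            for attr, rows in plans:
                x = work.get(attr, getattr(self, attr))
                xn = np.where(rows, f * x, x)
                logr += float((0.5 * (x[rows] ** 2 - xn[rows] ** 2)).sum()) + math.log(f) * int(rows.sum())
                work[attr] = xn
            if need_lik:
                th1, th2 = self._compute_theta(struct=trial, **work)
                L1 = self._member_ll(th1, 1)
                L2 = self._member_ll(th2, 2)
                logr += (L1 - self.L1).sum() + (L2 - self.L2).sum()
            if math.log(self.rng.random()) < logr:
                self.struct = trial
                for attr, xn in work.items():
                    setattr(self, attr, xn)
                if need_lik:
                    self.theta1, self.theta2 = th1, th2
                    self.L1, self.L2 = L1, L2
                self._record(key, 1, 1)
            else:
                self._record(key, 0, 1)

    def _swap_move(self) -> None:
        """Propose exchanging the A and C variance roles outright.

        The mirror mode with VAR(A) and VAR(C) interchanged often has
        non-negligible mass in small samples; a deterministic swap of
        (omega0, gamma0) — an involution with unit Jacobian — lets the
        chain jump between basins instead of diffusing along the
        exchange ridge.
        """
        st = self.struct
        trial = dict(st)
        trial["omega0_overall"], trial["gamma0_overall"] = st["gamma0_overall"], st["omega0_overall"]
        if self.model.gender_moderation:
            trial["omega0_female"], trial["gamma0_female"] = st["gamma0_female"], st["omega0_female"]
        self._try_struct("swap", trial)

    def update_structural(self) -> None:
        rng = self.rng
        pr = self.prior
        self._asis_omega()
        self._asis_env_scales()
        self._ridge_moves()
        self._exchange_moves()
        self._swap_move()
        for name in self.free_struct:
            prop_val = self.struct[name] + self.scales[name] * rng.standard_normal()
            ok = pr.in_box(prop_val, name)
            if ok:
                trial = dict(self.struct)
                trial[name] = prop_val
                th1, th2 = self._compute_theta(struct=trial)
                L1 = self._member_ll(th1, 1)
                L2 = self._member_ll(th2, 2)
                logr = (L1 - self.L1).sum() + (L2 - self.L2).sum()
                if math.log(rng.random()) < logr:
                    self.struct = trial
                    self.theta1, self.theta2 = th1, th2
                    self.L1, self.L2 = L1, L2
                    self._record(name, 1, 1)
                    continue
            self._record(name, 0, 1)

    def sweep(self) -> None:
        self.update_latents()
        self.update_measurement()
        self.update_structural()


def _derived(struct: dict, gender_moderation: bool) -> dict[str, float]:
    params = BiometricParams(**struct)
    out = {}
    groups = ("male", "female") if gender_moderation else ("male",)
    for g in groups:
        dec = marginal_variances(params, g)
        suffix = f"_{g}" if gender_moderation else ""
        out[f"h2{suffix}"] = dec.h2
        out[f"c2{suffix}"] = dec.c2
        out[f"e2{suffix}"] = dec.e2
        out[f"var_a{suffix}"] = dec.var_a
    return out


def sample_posterior(
    dataset: TwinDataset,
    model: ModelSpec | None = None,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
) -> PosteriorSamples:
    """Draw from the posterior of the full measurement + biometric model.

    Identification: the first item's discrimination is fixed at 1; the
    phenotypic mean is 0 for males, with the female offset ``nu`` free
    only when gender moderation is on.  Returns all free measurement
    and structural parameters plus per-draw derived quantities
    (h2/c2/e2 and VAR(A), per sex under gender moderation).
    """
    model = model or ModelSpec()
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    items = [c for c in dataset.roster if c not in set(model.exclude_items)]
    if not items:
        raise ValueError("all items excluded")
    data = _PairData(dataset, items)
    if model.gender_moderation and (data.g1.sum() + data.g2.sum() in (0.0, data.P * 2.0)):
        raise ValueError("gender moderation requires both sexes in the data")

    n_keep = (config.n_iterations - config.n_burnin) // config.thinning
    chain_draws: list[dict[str, np.ndarray]] = []
    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed) % (2**31), chain])
        state = _ChainState(data, model, priors, rng)
        store: dict[str, list[float]] = {}
        kept = 0
        for it in range(config.n_iterations):
            state.sweep()
            if it < config.n_burnin:
                if (it + 1) % config.adapt_window == 0:
                    state.adapt(step=min(0.5, 10.0 / (it + 1) ** 0.5))
            elif (it - config.n_burnin) % config.thinning == 0:
                rec = {}
                for k, name in enumerate(items):
                    if k > 0:
                        rec[f"alpha[{name}]"] = state.alpha[k]
                    rec[f"tau1[{name}]"] = state.tau[k, 0]
                    rec[f"tau2[{name}]"] = state.tau[k, 1]
                    if data.is_mz.any():
                        rec[f"r_mz[{name}]"] = state.sr_mz[k] ** 2
                    if not data.is_mz.all():
                        rec[f"r_dz[{name}]"] = state.sr_dz[k] ** 2
                for name in state.free_struct:
                    rec[name] = state.struct[name]
                rec.update(_derived(state.struct, model.gender_moderation))
                for key, val in rec.items():
                    store.setdefault(key, []).append(val)
                kept += 1
        chain_draws.append({k: np.asarray(v) for k, v in store.items()})

    draws = {k: np.stack([cd[k] for cd in chain_draws]) for k in chain_draws[0]}
    prior_class = {}
    for name in draws:
        if name.startswith(("tau1", "tau2")):
            prior_class[name] = "ordered-flat"
        elif name.startswith(("r_mz", "r_dz")):
            prior_class[name] = "sqrt-uniform(0,1)"
        elif name.startswith(("h2", "c2", "e2", "var_a")):
            prior_class[name] = "derived"
        else:
            prior_class[name] = "uniform(-5,5)"
    provenance = {
        "model": {"interactions": model.interactions, "gender_moderation": model.gender_moderation, "exclude_items": list(model.exclude_items)},
        "items": items,
        "n_pairs": data.P,
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "n_burnin": config.n_burnin,
        "n_chains": config.n_chains,
        "thinning": config.thinning,
    }
    return PosteriorSamples(draws=draws, prior_class=prior_class, provenance=provenance)


# --------------------------------------------------------------------------
# diagnostics and summaries
# --------------------------------------------------------------------------


def gelman_rubin(samples: PosteriorSamples | dict[str, np.ndarray]) -> dict[str, float]:
    """Potential scale reduction factor per parameter.

    Classic between/within form: with m chains of length n,
    ``W`` the mean within-chain variance and ``B/n`` the variance of the
    chain means, ``R = sqrt(((n-1)/n * W + B/n) / W)``.  Constant
    identical chains return 1.0 by convention.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else samples
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin needs >= 2 chains")
        m, n = arr.shape
        if n < 10:
            raise ValueError("gelman_rubin needs >= 10 draws per chain")
        W = arr.var(axis=1, ddof=1).mean()
        B_over_n = arr.mean(axis=1).var(ddof=1)
        if W == 0.0:
            out[name] = 1.0
            continue
        var_plus = (n - 1) / n * W + B_over_n
        # floored at 1: sampling noise can push the raw ratio slightly below
        out[name] = max(1.0, float(math.sqrt(var_plus / W)))
    return out


def hpd_interval(draws, level: float) -> tuple[float, float]:
    """Shortest interval containing ``ceil(level * n)`` sorted draws."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if n < 100:
        raise ValueError("need >= 100 draws for an HPD interval")
    k = int(math.ceil(level * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def posterior_summary(samples: PosteriorSamples, level: float = 0.99) -> pd.DataFrame:
    """Tidy table of posterior mean and HPD bounds per parameter."""
    rows = []
    for name in samples.names:
        x = samples.stacked(name)
        if np.ptp(x) == 0:
            lo = hi = float(x[0])
        elif x.size >= 100:
            lo, hi = hpd_interval(x, level)
        else:
            lo = hi = float("nan")
        rows.append({"parameter": name, "mean": float(x.mean()), "hpd_low": lo, "hpd_high": hi, "level": level})
    return pd.DataFrame(rows)
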