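"""Multi-group homogeneity and measurement-invariance testing.

Groups (survey occasion, age band, or sex composition) are compared by
a stepwise constraint schedule on a multi-group model in which the
latent phenotype pair (theta1, theta2) is bivariate normal with free
mean, variance and cross-twin correlation per group (no ACE split), and
the graded-response measurement model links theta to the items:

    step 0   all measurement parameters free per group
    step 1a  discriminations alpha_i equal across groups
    step 1b  + residual correlations r_MZ,i / r_DZ,i equal
    step 1c  + thresholds tau_i1, tau_i2 equal
    step 2a  + MEAN(theta), VAR(theta) equal
    step 2b  + COR(theta1, theta2) equal

Identification anchors group 1: VAR(theta)=1 there once alphas are
shared (free elsewhere), MEAN(theta)=0 there once thresholds are shared.
Step fits are compared on a predictive information criterion (WAIC
computed from per-pair log-likelihoods conditional on the latent state),
and group differences of still-free measurement parameters are flagged
when their posterior HPD excludes zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from hetace.data import TwinDataset
from hetace.mcmc import McmcConfig, PriorSpec, _category_loglik, _PairData, hpd_interval

__all__ = [
    "GroupingSpec",
    "ConstraintSchedule",
    "InvarianceFit",
    "age_bins",
    "split_groups",
    "fit_schedule",
    "compare_fits",
    "flag_noninvariant_items",
    "occasion_homogeneity",
]

DEFAULT_AGE_BANDS = ((18, 19), (20, 21), (22, 24), (25, 34), (35, 70))

STEPS = ("step0", "step1a", "step1b", "step1c", "step2a", "step2b")
_STEP_SETS = {
    "step0": frozenset(),
    "step1a": frozenset({"alpha"}),
    "step1b": frozenset({"alpha", "r"}),
    "step1c": frozenset({"alpha", "r", "tau"}),
    "step2a": frozenset({"alpha", "r", "tau", "moments"}),
    "step2b": frozenset({"alpha", "r", "tau", "moments", "rho"}),
}


@dataclass(frozen=True)
class GroupingSpec:
    """How to split twin pairs into independent groups."""

    variable: str  # "occasion", "age_band" or "gender"
    age_bands: tuple[tuple[int, int], ...] = DEFAULT_AGE_BANDS

    def __post_init__(self) -> None:
        if self.variable not in ("occasion", "age_band", "gender"):
            raise ValueError(f"unknown grouping variable {self.variable!r}")
        bands = self.age_bands
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if lo2 != hi1 + 1:
                raise ValueError("age bands must be disjoint and contiguous")


@dataclass(frozen=True)
class ConstraintSchedule:
    """Ordered, strictly nested constraint steps."""

    steps: tuple[str, ...] = STEPS

    def __post_init__(self) -> None:
        prev: frozenset | None = None
        for s in self.steps:
            if s not in _STEP_SETS:
                raise ValueError(f"unknown step {s!r}")
            if prev is not None and not prev < _STEP_SETS[s]:
                raise ValueError("steps must be strictly nested")
            prev = _STEP_SETS[s]

    @staticmethod
    def constrained(step: str) -> frozenset:
        return _STEP_SETS[step]

    @staticmethod
    def free_parameter_count(step: str, n_groups: int, n_items: int, zygosities: tuple[str, ...] = ("MZ", "DZ")) -> int:
        """Number of free parameters at a step (used to verify nesting)."""
        shared = _STEP_SETS[step]
        G, I, Z = n_groups, n_items, len(zygosities)
        n = 0
        n += (I - 1) * (1 if "alpha" in shared else G)  # alpha_1 fixed
        n += Z * I * (1 if "r" in shared else G)
        n += 2 * I * (1 if "tau" in shared else G)
        if "moments" in shared:
            pass  # mu=0, var=1 everywhere
        else:
            if "alpha" in shared:
                n += G - 1  # var free except group 1
            if "tau" in shared:
                n += G - 1  # mu free except group 1
        n += Z * (1 if "rho" in shared else G)
        return n


def age_bins(ages, spec: GroupingSpec | None = None) -> np.ndarray:
    """Band label per individual; ages outside the bands yield None with a warning."""
    spec = spec or GroupingSpec("age_band")
    ages = np.asarray(ages)
    labels = np.empty(ages.shape, dtype=object)
    labels[:] = None
    for lo, hi in spec.age_bands:
        labels[(ages >= lo) & (ages <= hi)] = f"{lo}-{hi}"
    if (labels == None).any():  # noqa: E711
        warnings.warn(f"{int((labels == None).sum())} individual(s) outside the age bands were excluded", stacklevel=2)  # noqa: E711
    return labels


def _pair_sex_group(grp: pd.DataFrame) -> str:
    sexes = set(grp["sex"])
    if len(sexes) == 2:
        return "opposite-sex"
    return "male" if sexes == {"M"} else "female"


def split_groups(dataset: TwinDataset, spec: GroupingSpec) -> dict[str, TwinDataset]:
    """Partition pairs into independent groups; cross-group pairs are dropped.

    For age-band grouping, a pair whose members fall in different bands
    is omitted (it would break group independence).  For gender
    grouping, DZ opposite-sex pairs form their own third group.
    """
    df = dataset.table
    assignments: dict[str, list] = {}
    dropped = 0
    for pid, grp in df.groupby("pair_id"):
        if spec.variable == "gender":
            label = _pair_sex_group(grp)
        elif spec.variable == "occasion":
            occ = set(grp["occasion"])
            if len(occ) != 1:
                dropped += 1
                continue
            label = str(occ.pop())
        else:
            labs = set(age_bins(grp["age"].to_numpy(), spec))
            if None in labs:
                dropped += 1
                continue
            if len(labs) != 1:
                dropped += 1
                continue
            label = labs.pop()
        assignments.setdefault(label, []).append(pid)
    if dropped:
        warnings.warn(f"dropped {dropped} cross-group or out-of-range pair(s) from the grouped analysis", stacklevel=2)
    out = {}
    for label in sorted(assignments):
        out[label] = dataset.subset_pairs(assignments[label])
    return out


# --------------------------------------------------------------------------
# multi-group measurement sampler (bivariate-normal phenotype)
# --------------------------------------------------------------------------


def _bvn_logpdf(t1, t2, mu1, mu2, var, rho):
    z1 = (t1 - mu1) / math.sqrt(var)
    z2 = (t2 - mu2) / math.sqrt(var)
    om = 1.0 - rho * rho
    return -math.log(2 * math.pi * var) - 0.5 * math.log(om) - (z1 * z1 - 2 * rho * z1 * z2 + z2 * z2) / (2 * om)


class _Group:
    def __init__(self, dataset: TwinDataset, items: list[str], rng: np.random.Generator):
        self.data = _PairData(dataset, items)
        d = self.data
        self.zygs = [z for z, present in (("MZ", d.is_mz.any()), ("DZ", (~d.is_mz).any())) if present]
        self.theta1 = rng.standard_normal(d.P) * 0.5
        self.theta2 = rng.standard_normal(d.P) * 0.5
        self.U = rng.standard_normal((d.P, d.I))
        self.mu = 0.0
        self.logvar = 0.0
        self.rho = {z: 0.3 for z in self.zygs}


class _MultiGroupState:
    """Metropolis-within-Gibbs sampler for the step fits."""

    def __init__(self, groups, items, step, prior, rng):
        self.rng = rng
        self.prior = prior
        self.shared = _STEP_SETS[step]
        self.items = items
        self.I = len(items)
        self.groups = [_Group(ds, items, rng) for ds in groups.values()]
        self.labels = list(groups)
        G, I = len(self.groups), self.I
        self.alpha = [np.ones(I) for _ in range(G)]
        self.tau = []
        self.sr = [{z: np.full(I, 0.4) for z in g.zygs} for g in self.groups]
        from scipy.special import ndtri

        # constrained parameters must start equal across groups (shared
        # proposals preserve equality); free taus start from group data
        if "tau" in self.shared:
            pooled_all = [np.vstack([g.data.pooled for g in self.groups])] * G
        else:
            pooled_all = [g.data.pooled for g in self.groups]
        jitter = 0.03 * rng.standard_normal((I, 2))
        for g, pooled in enumerate(pooled_all):
            p0 = np.clip(np.nanmean(pooled == 0, axis=0), 0.02, 0.98)
            p01 = np.clip(np.nanmean(pooled <= 1, axis=0), 0.02, 0.98)
            t1, t2 = ndtri(p0), ndtri(p01)
            t2 = np.maximum(t2, t1 + 0.2)
            tau = np.column_stack([t1, t2]) + (jitter if "tau" in self.shared else 0.03 * rng.standard_normal((I, 2)))
            tau[:, 1] = np.maximum(tau[:, 1], tau[:, 0] + 0.05)
            self.tau.append(tau)
        self.scales = {"theta": 0.6, "U": 0.8, "alpha": 0.06, "tau": 0.06, "sr": 0.06, "mu": 0.08, "logvar": 0.08, "rho": 0.06}
        self._acc = {k: [0, 0] for k in self.scales}
        for g in range(G):
            self._refresh_group(g)

    # parameter sharing -----------------------------------------------------
    @property
    def var_free(self) -> bool:
        return "alpha" in self.shared and "moments" not in self.shared

    @property
    def mu_free(self) -> bool:
        return "tau" in self.shared and "moments" not in self.shared

    def _sr_mats(self, g: int):
        grp = self.groups[g]
        d = grp.data
        sr = self.sr[g]
        r = np.zeros((d.P, self.I))
        if "MZ" in sr:
            r[d.is_mz] = (sr["MZ"] ** 2)[None, :]
        if "DZ" in sr:
            r[~d.is_mz] = (sr["DZ"] ** 2)[None, :]
        return np.sqrt(r), np.sqrt(1.0 - r)

    def _member_ll(self, g: int, member: int, theta=None, alpha=None, tau=None, U=None, sr_s=None):
        grp = self.groups[g]
        d = grp.data
        theta = (grp.theta1 if member == 1 else grp.theta2) if theta is None else theta
        alpha = self.alpha[g] if alpha is None else alpha
        tau = self.tau[g] if tau is None else tau
        U = grp.U if U is None else U
        sr, s = self._sr_mats(g) if sr_s is None else sr_s
        mean = alpha[None, :] * theta[:, None] + sr * U
        masks = d.masks1 if member == 1 else d.masks2
        obs = d.obs1 if member == 1 else d.obs2
        return _category_loglik(mean, s, tau, masks, obs)

    def _refresh_group(self, g: int) -> None:
        grp = self.groups[g]
        grp.L1 = self._member_ll(g, 1)
        grp.L2 = self._member_ll(g, 2)

    def _record(self, key, accepted, total):
        self._acc[key][0] += accepted
        self._acc[key][1] += total

    def adapt(self, step: float) -> None:
        for key, (acc, tot) in self._acc.items():
            if tot:
                self.scales[key] = float(np.clip(self.scales[key] * math.exp(step * (acc / tot - 0.35)), 1e-4, 5.0))
        self._acc = {k: [0, 0] for k in self.scales}

    # updates ---------------------------------------------------------------
    def _prior_lp(self, grp: _Group, t1, t2):
        var = math.exp(grp.logvar)
        d = grp.data
        out = np.zeros(d.P)
        for z in grp.zygs:
            rows = d.is_mz if z == "MZ" else ~d.is_mz
            out[rows] = _bvn_logpdf(t1[rows], t2[rows], grp.mu, grp.mu, var, grp.rho[z])
        return out

    def _update_theta(self, g: int) -> None:
        rng, grp = self.rng, self.groups[g]
        d = grp.data
        for member in (1, 2):
            cur = grp.theta1 if member == 1 else grp.theta2
            prop = cur + self.scales["theta"] * rng.standard_normal(d.P)
            L = self._member_ll(g, member, theta=prop)
            Lcur = grp.L1 if member == 1 else grp.L2
            t1, t2 = (prop, grp.theta2) if member == 1 else (grp.theta1, prop)
            logr = (L - Lcur).sum(axis=1) + self._prior_lp(grp, t1, t2) - self._prior_lp(grp, grp.theta1, grp.theta2)
            acc = np.log(rng.random(d.P)) < logr
            cur[acc] = prop[acc]
            Lcur[acc] = L[acc]
            self._record("theta", acc.sum(), d.P)

    def _update_U(self, g: int) -> None:
        rng, grp = self.rng, self.groups[g]
        d = grp.data
        prop = grp.U + self.scales["U"] * rng.standard_normal((d.P, self.I))
        L1 = self._member_ll(g, 1, U=prop)
        L2 = self._member_ll(g, 2, U=prop)
        logr = (L1 - grp.L1) + (L2 - grp.L2) + 0.5 * (grp.U**2 - prop**2)
        acc = np.log(rng.random((d.P, self.I))) < logr
        grp.U[acc] = prop[acc]
        grp.L1[acc] = L1[acc]
        grp.L2[acc] = L2[acc]
        self._record("U", acc.sum(), acc.size)

    def _itemwise_update(self, kind: str) -> None:
        """alpha/tau/sr updates, shared or per group according to the step."""
        rng = self.rng
        G = len(self.groups)
        shared = {"alpha": "alpha" in self.shared, "tau": "tau" in self.shared, "sr": "r" in self.shared}[kind]
        group_sets = [list(range(G))] if shared else [[g] for g in range(G)]
        for gs in group_sets:
            if kind == "alpha":
                delta = self.scales["alpha"] * rng.standard_normal(self.I)
                delta[0] = 0.0  # alpha_1 fixed at 1
                props = [self.alpha[g] + delta for g in gs]
                valid = np.all([(p >= self.prior.box_low) & (p <= self.prior.box_high) for p in props], axis=0)
                valid[0] = False
                news = [[self._member_ll(g, m, alpha=props[i]) for m in (1, 2)] for i, g in enumerate(gs)]
            elif kind == "tau":
                delta = self.scales["tau"] * rng.standard_normal((self.I, 2))
                props = [self.tau[g] + delta for g in gs]
                lo, hi = self.prior.tau_bounds
                valid = np.all([(p[:, 0] < p[:, 1]) & (p[:, 0] >= lo) & (p[:, 1] <= hi) for p in props], axis=0)
                news = [[self._member_ll(g, m, tau=props[i]) for m in (1, 2)] for i, g in enumerate(gs)]
            else:  # sr, per zygosity
                for zyg in ("MZ", "DZ"):
                    sub = [g for g in gs if zyg in self.groups[g].zygs]
                    if not sub:
                        continue
                    delta = self.scales["sr"] * rng.standard_normal(self.I)
                    props = [self.sr[g][zyg] + delta for g in sub]
                    valid = np.all([(p > 0.0) & (p < 1.0) for p in props], axis=0)
                    news = []
                    for i, g in enumerate(sub):
                        trial = dict(self.sr[g])
                        trial[zyg] = np.where(valid, props[i], self.sr[g][zyg])
                        saved = self.sr[g]
                        self.sr[g] = trial
                        news.append([self._member_ll(g, 1), self._member_ll(g, 2)])
                        self.sr[g] = saved
                    self._accept_items("sr", sub, props, valid, news, lambda g, acc, p: self.sr[g][zyg].__setitem__(acc, p[acc]))
                continue
            setter = (lambda g, acc, p: self.alpha[g].__setitem__(acc, p[acc])) if kind == "alpha" else (lambda g, acc, p: self.tau[g].__setitem__(acc, p[acc]))
            self._accept_items(kind, gs, props, valid, news, setter)

    def _accept_items(self, key, gs, props, valid, news, setter) -> None:
        delta_ll = np.zeros(self.I)
        for i, g in enumerate(gs):
            grp = self.groups[g]
            delta_ll += (news[i][0] - grp.L1).sum(axis=0) + (news[i][1] - grp.L2).sum(axis=0)
        logr = np.where(valid, delta_ll, -np.inf)
        acc = np.log(self.rng.random(self.I)) < logr
        for i, g in enumerate(gs):
            grp = self.groups[g]
            setter(g, acc, props[i])
            grp.L1[:, acc] = news[i][0][:, acc]
            grp.L2[:, acc] = news[i][1][:, acc]
        self._record(key, acc.sum(), max(int(valid.sum()), 1))

    def _update_moments(self) -> None:
        rng = self.rng
        for g, grp in enumerate(self.groups):
            if self.mu_free and g > 0:
                prop = grp.mu + self.scales["mu"] * rng.standard_normal()
                if self.prior.in_box(prop):
                    old = grp.mu
                    lp0 = self._prior_lp(grp, grp.theta1, grp.theta2).sum()
                    grp.mu = prop
                    lp1 = self._prior_lp(grp, grp.theta1, grp.theta2).sum()
                    if math.log(rng.random()) < lp1 - lp0:
                        self._record("mu", 1, 1)
                    else:
                        grp.mu = old
                        self._record("mu", 0, 1)
            if self.var_free and g > 0:
                prop = grp.logvar + self.scales["logvar"] * rng.standard_normal()
                if self.prior.in_box(prop):
                    old = grp.logvar
                    lp0 = self._prior_lp(grp, grp.theta1, grp.theta2).sum()
                    grp.logvar = prop
                    lp1 = self._prior_lp(grp, grp.theta1, grp.theta2).sum()
                    if math.log(rng.random()) < lp1 - lp0:
                        self._record("logvar", 1, 1)
                    else:
                        grp.logvar = old
                        self._record("logvar", 0, 1)

    def _update_rho(self) -> None:
        rng = self.rng
        shared = "rho" in self.shared
        for zyg in ("MZ", "DZ"):
            gs = [g for g, grp in enumerate(self.groups) if zyg in grp.zygs]
            if not gs:
                continue
            group_sets = [gs] if shared else [[g] for g in gs]
            for sub in group_sets:
                delta = self.scales["rho"] * rng.standard_normal()
                props = {g: self.groups[g].rho[zyg] + delta for g in sub}
                if any(not (-0.999 < p < 0.999) for p in props.values()):
                    self._record("rho", 0, 1)
                    continue
                lp0 = lp1 = 0.0
                for g in sub:
                    grp = self.groups[g]
                    lp0 += self._prior_lp(grp, grp.theta1, grp.theta2).sum()
                    old = grp.rho[zyg]
                    grp.rho[zyg] = props[g]
                    lp1 += self._prior_lp(grp, grp.theta1, grp.theta2).sum()
                    grp.rho[zyg] = old
                if math.log(rng.random()) < lp1 - lp0:
                    for g in sub:
                        self.groups[g].rho[zyg] = props[g]
                    self._record("rho", 1, 1)
                else:
                    self._record("rho", 0, 1)

    def sweep(self) -> None:
        for g in range(len(self.groups)):
            self._update_theta(g)
            self._update_U(g)
        for kind in ("alpha", "tau", "sr"):
            self._itemwise_update(kind)
        self._update_moments()
        self._update_rho()

    # recording -------------------------------------------------------------
    def record(self) -> dict[str, float]:
        rec: dict[str, float] = {}
        for g, (label, grp) in enumerate(zip(self.labels, self.groups)):
            for k, name in enumerate(self.items):
                if k > 0:
                    rec[f"alpha[{label}][{name}]"] = self.alpha[g][k]
                rec[f"tau1[{label}][{name}]"] = self.tau[g][k, 0]
                rec[f"tau2[{label}][{name}]"] = self.tau[g][k, 1]
                for zyg in grp.zygs:
                    rec[f"r_{zyg.lower()}[{label}][{name}]"] = self.sr[g][zyg][k] ** 2
            rec[f"mean_theta[{label}]"] = grp.mu
            rec[f"var_theta[{label}]"] = math.exp(grp.logvar)
            for zyg in grp.zygs:
                rec[f"cor_theta[{label}][{zyg}]"] = grp.rho[zyg]
        return rec


@dataclass
class InvarianceFit:
    """Posterior fit of one constraint step."""

    step: str
    labels: list[str]
    items: list[str]
    draws: dict[str, np.ndarray]  # (n_chains, n_kept)
    config: McmcConfig
    group_data: list = field(default_factory=list, repr=False)  # _PairData per group

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def mean_group_params(self, g: int) -> dict:
        """Posterior-mean parameters of group ``g`` for plug-in evaluation."""
        label = self.labels[g]
        I = len(self.items)
        alpha = np.ones(I)
        tau = np.zeros((I, 2))
        r = {}
        for k, name in enumerate(self.items):
            if k > 0:
                alpha[k] = self.stacked(f"alpha[{label}][{name}]").mean()
            tau[k, 0] = self.stacked(f"tau1[{label}][{name}]").mean()
            tau[k, 1] = self.stacked(f"tau2[{label}][{name}]").mean()
            for zyg in ("MZ", "DZ"):
                key = f"r_{zyg.lower()}[{label}][{name}]"
                if key in self.draws:
                    r.setdefault(zyg, np.zeros(I))[k] = self.stacked(key).mean()
        out = {
            "alpha": alpha,
            "tau": tau,
            "r": r,
            "mu": float(self.stacked(f"mean_theta[{label}]").mean()),
            "var": float(self.stacked(f"var_theta[{label}]").mean()),
            "rho": {},
        }
        for zyg in ("MZ", "DZ"):
            key = f"cor_theta[{label}][{zyg}]"
            if key in self.draws:
                out["rho"][zyg] = float(self.stacked(key).mean())
        return out


def fit_one_step(groups: dict[str, TwinDataset], step: str, config: McmcConfig, prior: PriorSpec | None = None) -> InvarianceFit:
    """Fit the multi-group model with one step's equality constraints."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for a multi-group fit")
    prior = prior or PriorSpec()
    items = list(next(iter(groups.values())).roster)
    all_draws = []
    group_data = None
    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed) % (2**31), 7_000 + chain])
        state = _MultiGroupState(groups, items, step, prior, rng)
        if group_data is None:
            group_data = [g.data for g in state.groups]
        store: dict[str, list[float]] = {}
        for it in range(config.n_iterations):
            state.sweep()
            if it < config.n_burnin:
                if (it + 1) % config.adapt_window == 0:
                    state.adapt(step=min(0.5, 10.0 / (it + 1) ** 0.5))
            elif (it - config.n_burnin) % config.thinning == 0:
                rec = state.record()
                for k, v in rec.items():
                    store.setdefault(k, []).append(v)
        all_draws.append({k: np.asarray(v) for k, v in store.items()})
    draws = {k: np.stack([cd[k] for cd in all_draws]) for k in all_draws[0]}
    return InvarianceFit(step=step, labels=list(groups), items=items, draws=draws, config=config, group_data=group_data)


def fit_schedule(groups: dict[str, TwinDataset], schedule: ConstraintSchedule | None = None, config: McmcConfig | None = None) -> dict[str, InvarianceFit]:
    """Fit every step of the constraint schedule on the same groups."""
    schedule = schedule or ConstraintSchedule()
    config = config or McmcConfig()
    return {step: fit_one_step(groups, step, config) for step in schedule.steps}


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite_e.hermegauss(n)
    return z, w / w.sum()


def marginal_pair_loglik(data, params: dict, n_theta: int = 12, n_u: int = 10) -> np.ndarray:
    """Exact (quadrature) marginal log-likelihood of each pair's item scores.

    The phenotype pair is bivariate normal (mu, var, rho per zygosity);
    given theta, each item's propensity pair shares a standard-normal
    kernel carrying the residual correlation r.  Both latent layers are
    integrated out by Gauss-Hermite quadrature (``n_theta`` nodes per
    phenotype dimension, ``n_u`` per item kernel), giving a
    deterministic per-pair log-likelihood for model comparison.
    """
    zq, wq = _gh_nodes(n_theta)
    zu, wu = _gh_nodes(n_u)
    alpha, tau = params["alpha"], params["tau"]
    mu, var = params["mu"], params["var"]
    sd = math.sqrt(var)
    I = alpha.shape[0]
    out = np.empty(data.P)
    for zyg in ("MZ", "DZ"):
        rows = data.is_mz if zyg == "MZ" else ~data.is_mz
        if not rows.any():
            continue
        rho = params["rho"][zyg]
        r = params["r"][zyg]
        z1 = np.repeat(zq, n_theta)
        z2 = np.tile(zq, n_theta)
        wgrid = np.repeat(wq, n_theta) * np.tile(wq, n_theta)
        th1 = mu + sd * z1
        th2 = mu + sd * (rho * z1 + math.sqrt(max(1.0 - rho * rho, 1e-12)) * z2)
        Q = th1.shape[0]
        lp_items = np.zeros((int(rows.sum()), Q))
        X1, X2 = data.X1[rows], data.X2[rows]
        for i in range(I):
            s_i = math.sqrt(1.0 - r[i])
            cats = []
            for th in (th1, th2):
                mean = alpha[i] * th[:, None] + math.sqrt(r[i]) * zu[None, :]
                lo = ndtr((tau[i, 0] - mean) / s_i)
                hi = ndtr((tau[i, 1] - mean) / s_i)
                cats.append(np.stack([lo, hi - lo, 1.0 - hi]))  # (3, Q, U)
            x1, x2 = X1[:, i], X2[:, i]
            t1 = np.where(np.isnan(x1)[:, None, None], 1.0, cats[0][np.nan_to_num(x1).astype(int)])
            t2 = np.where(np.isnan(x2)[:, None, None], 1.0, cats[1][np.nan_to_num(x2).astype(int)])
            p_item = np.einsum("pqu,u->pq", t1 * t2, wu)
            lp_items += np.log(np.clip(p_item, 1e-300, None))
        out[rows] = logsumexp(lp_items + np.log(wgrid)[None, :], axis=1)
    return out


def _free_param_count(fit: InvarianceFit) -> int:
    shared = _STEP_SETS[fit.step]
    G = len(fit.labels)
    I = len(fit.items)
    zygs_per_group = [sum([d.is_mz.any(), (~d.is_mz).any()]) for d in fit.group_data]
    z_union = max(zygs_per_group) if zygs_per_group else 1
    n = (I - 1) * (1 if "alpha" in shared else G)
    n += 2 * I * (1 if "tau" in shared else G)
    n += I * (z_union if "r" in shared else sum(zygs_per_group))
    if "moments" not in shared:
        if "alpha" in shared:
            n += G - 1  # VAR(theta) free except group 1
        if "tau" in shared:
            n += G - 1  # MEAN(theta) free except group 1
    n += z_union if "rho" in shared else sum(zygs_per_group)
    return n


def compare_fits(fits: dict[str, InvarianceFit]) -> pd.DataFrame:
    """Predictive-criterion comparison table across schedule steps.

    Each step is scored by an AIC-type criterion: minus twice the exact
    marginal log-likelihood (latents integrated out by quadrature)
    evaluated at the posterior-mean parameters, plus twice the number of
    free parameters.  A step passes when its criterion does not exceed
    the previous step's by more than one standard error of the paired
    per-pair deviance difference.
    """
    steps = list(fits)
    npairs = {s: sum(d.P for d in fits[s].group_data) for s in steps}
    if len(set(npairs.values())) != 1:
        raise ValueError("fits must share the same data and grouping")
    rows = []
    prev_dev = None
    prev_crit = None
    for s in steps:
        fit = fits[s]
        li = np.concatenate([marginal_pair_loglik(d, fit.mean_group_params(g)) for g, d in enumerate(fit.group_data)])
        dev = -2.0 * li
        k = _free_param_count(fit)
        crit = float(dev.sum() + 2 * k)
        if prev_dev is None:
            delta = se = 0.0
            ok = True
        else:
            d = dev - prev_dev
            delta = float(crit - prev_crit)
            se = float(math.sqrt(d.size * d.var(ddof=1)))
            ok = delta <= se
        rows.append({"step": s, "criterion": crit, "deviance": float(dev.sum()), "k": k, "delta": delta, "se": se, "pass": ok})
        prev_dev = dev
        prev_crit = crit
    return pd.DataFrame(rows)


def flag_noninvariant_items(fit: InvarianceFit, level: float = 0.99) -> pd.DataFrame:
    """Cross-group differences of group-specific measurement parameters.

    For every parameter retained group-specific in ``fit``, the posterior
    of (group - reference group) is summarised per item; an item is
    flagged when the HPD at ``level`` excludes zero.
    """
    shared = _STEP_SETS[fit.step]
    kinds = []
    if "alpha" not in shared:
        kinds.append(("alpha", ["alpha"]))
    if "tau" not in shared:
        kinds.append(("tau", ["tau1", "tau2"]))
    if "r" not in shared:
        kinds.append(("r", ["r_mz", "r_dz"]))
    ref = fit.labels[0]
    rows = []
    for _, prefixes in kinds:
        for prefix in prefixes:
            for item in fit.items:
                base = f"{prefix}[{ref}][{item}]"
                if base not in fit.draws:
                    continue
                for label in fit.labels[1:]:
                    other = f"{prefix}[{label}][{item}]"
                    if other not in fit.draws:
                        continue
                    diff = fit.stacked(base) - fit.stacked(other)
                    lo, hi = hpd_interval(diff, level)
                    rows.append(
                        {
                            "item": item,
                            "parameter": prefix,
                            "group": label,
                            "diff_mean": float(diff.mean()),
                            "hpd_low": lo,
                            "hpd_high": hi,
                            "flagged": bool(lo > 0.0 or hi < 0.0),
                        }
                    )
    return pd.DataFrame(rows)


def occasion_homogeneity(dataset: TwinDataset, config: McmcConfig, level: float = 0.99) -> pd.DataFrame:
    """Standard (no-interaction) ACE decomposition per occasion group.

    Fits the linear ACE model separately within each occasion and
    reports h2/c2/e2 posterior means with HPD bounds plus a
    ``hpds_overlap`` verdict per component: True when every pair of
    occasion HPDs intersects, the criterion used to justify aggregating
    occasions.
    """
    from hetace.mcmc import ModelSpec, sample_posterior

    groups = split_groups(dataset, GroupingSpec("occasion"))
    rows = []
    for label, ds in groups.items():
        fit = sample_posterior(ds, model=ModelSpec(interactions=False, gender_moderation=False), config=config)
        for comp in ("h2", "c2", "e2"):
            x = fit.stacked(comp)
            lo, hi = hpd_interval(x, level)
            rows.append({"occasion": label, "component": comp, "mean": float(x.mean()), "hpd_low": lo, "hpd_high": hi})
    out = pd.DataFrame(rows)
    overlap = {}
    for comp, sub in out.groupby("component"):
        overlap[comp] = bool(sub["hpd_low"].max() <= sub["hpd_high"].min())
    out["hpds_overlap"] = out["component"].map(overlap)
    return out
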