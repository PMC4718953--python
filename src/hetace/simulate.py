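"""Synthetic twin-pair generator with the exact structure the model assumes.

Emulates a volunteer twin-register survey: MZ and DZ pairs (including
opposite-sex DZ), 13 three-category items under a graded-response
probit measurement model with cross-twin residual item correlations,
an ACE latent structure whose C and E variances are log-linear in the
genetic score A (gender-moderated), and missing-at-random item
nonresponse.  The true latent state is returned alongside the data so
recovery tests can compare against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hetace.data import META_COLUMNS, TwinDataset
from hetace.params import BiometricParams, MeasurementParams

__all__ = ["SyntheticConfig", "LatentState", "generate_dataset", "apply_missingness"]

# generation order of the five zygosity-by-sex cells
CELLS = ("MZ-male", "MZ-female", "DZ-male", "DZ-female", "DZ-OS")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative configuration: cell sizes, parameters, missingness, seed."""

    n_pairs: dict[str, int]
    measurement: MeasurementParams
    biometric: BiometricParams
    missing_rate: float = 0.0
    seed: int = 0
    age_range: tuple[int, int] = (18, 70)
    occasion: int = 2009

    def __post_init__(self) -> None:
        unknown = set(self.n_pairs) - set(CELLS)
        if unknown:
            raise ValueError(f"unknown cells {sorted(unknown)}; valid: {CELLS}")
        if any(v < 0 for v in self.n_pairs.values()):
            raise ValueError("pair counts must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class LatentState:
    """True latent scores per individual, aligned with the dataset rows."""

    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    theta: np.ndarray
    propensity: np.ndarray  # (n_individuals, n_items), pre-categorisation

    def sidecar(self, dataset: TwinDataset) -> pd.DataFrame:
        df = dataset.table
        return pd.DataFrame(
            {
                "pair_id": df["pair_id"],
                "member": df["member"],
                "A": self.A,
                "C": self.C,
                "E": self.E,
                "theta": self.theta,
            }
        )


def _draw_cell(rng, zyg, sexes, n, meas, bio):
    """Latent draws and propensities for n pairs of one zygosity/sex cell.

    Returns per-member arrays stacked as (member1, member2).
    """
    eff = [bio.effective(s) for s in sexes]
    sd_a = [np.sqrt(np.exp(e["omega0"])) for e in eff]
    z_shared = rng.standard_normal(n)
    if zyg == "MZ":
        a_kern = [z_shared, z_shared]
    else:
        w = np.sqrt(0.5)
        a_kern = [w * z_shared + w * rng.standard_normal(n) for _ in range(2)]
    A = [sd_a[j] * a_kern[j] for j in range(2)]
    z_c = rng.standard_normal(n)  # one shared C kernel per pair
    C = [np.exp(0.5 * (eff[j]["gamma0"] + eff[j]["gamma1"] * A[j])) * z_c for j in range(2)]
    E = [np.exp(0.5 * (eff[j]["beta0"] + eff[j]["beta1"] * A[j])) * rng.standard_normal(n) for j in range(2)]
    theta = [eff[j]["nu"] + A[j] + C[j] + E[j] for j in range(2)]

    r = meas.r(zyg)  # (I,)
    u = rng.standard_normal((n, meas.n_items))  # shared item kernels
    prop = []
    for j in range(2):
        e_item = rng.standard_normal((n, meas.n_items))
        eps = np.sqrt(r) * u + np.sqrt(1.0 - r) * e_item
        prop.append(meas.alpha * theta[j][:, None] + eps)
    return A, C, E, theta, prop


def generate_dataset(config: SyntheticConfig) -> tuple[TwinDataset, LatentState]:
    """Generate a twin dataset plus its true latent state.

    Pairs are drawn cell by cell (MZ-male, MZ-female, DZ-male,
    DZ-female, DZ-OS; in DZ-OS member 1 is male).  Ages are uniform over
    ``age_range`` and shared within pair; a single occasion label is
    used (the generator has no age or occasion effects).
    """
    rng = np.random.default_rng(config.seed)
    meas, bio = config.measurement, config.biometric
    frames = []
    lat = {k: [] for k in ("A", "C", "E", "theta", "prop")}
    pair_counter = 0
    for cell in CELLS:
        n = int(config.n_pairs.get(cell, 0))
        if n == 0:
            continue
        zyg, comp = cell.split("-", 1)
        sexes = {"male": ("M", "M"), "female": ("F", "F"), "OS": ("M", "F")}[comp]
        A, C, E, theta, prop = _draw_cell(rng, zyg, sexes, n, meas, bio)
        ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
        pids = np.array([f"P{pair_counter + p:05d}" for p in range(n)])
        # interleave members so rows arrive in (pair, member) order
        for j in range(2):
            scores = (prop[j] >= meas.tau1).astype(int) + (prop[j] >= meas.tau2).astype(int)
            df = pd.DataFrame(
                {
                    "pair_id": pids,
                    "member": j + 1,
                    "zygosity": zyg,
                    "sex": sexes[j],
                    "age": ages,
                    "occasion": config.occasion,
                }
            )
            for k, col in enumerate(meas.item_names):
                df[col] = scores[:, k]
            frames.append(df)
            lat["A"].append(A[j])
            lat["C"].append(C[j])
            lat["E"].append(E[j])
            lat["theta"].append(theta[j])
            lat["prop"].append(prop[j])
        pair_counter += n
    if frames:
        df = pd.concat(frames, ignore_index=True)
        order = np.lexsort((df["member"].to_numpy(), df["pair_id"].to_numpy()))
    else:
        df = pd.DataFrame(columns=list(META_COLUMNS) + list(meas.item_names))
        order = np.array([], dtype=int)
    for col in meas.item_names:
        df[col] = df[col].astype("Int64")
    dataset = TwinDataset(df.iloc[order], roster=meas.item_names)

    def _cat(key):
        arrs = lat[key]
        return np.concatenate(arrs)[order] if arrs else np.empty((0,))

    state = LatentState(A=_cat("A"), C=_cat("C"), E=_cat("E"), theta=_cat("theta"), propensity=_cat("prop"))
    if config.missing_rate > 0:
        dataset = apply_missingness(dataset, config.missing_rate, seed=config.seed + 1)
    return dataset, state


def apply_missingness(dataset: TwinDataset, rate: float, seed: int) -> TwinDataset:
    """Mask each observed cell independently with probability ``rate`` (MAR)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return dataset
    rng = np.random.default_rng(seed)
    df = dataset.table.copy()
    mask = rng.random((len(df), len(dataset.roster))) < rate
    for k, col in enumerate(dataset.roster):
        vals = df[col].copy()
        vals[mask[:, k]] = pd.NA
        df[col] = vals
    return TwinDataset(df, roster=dataset.roster)
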