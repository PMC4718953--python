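"""ACE variance arithmetic for the heteroscedastic twin model.

The latent phenotype decomposes as theta = nu*GENDER + A + C + E where
the conditional environmental variances are log-linear in the genetic
factor score A:

    VAR(C|A) = exp(gamma0 + gamma1 * A)
    VAR(E|A) = exp(beta0  + beta1  * A)

Because A ~ Normal(0, VAR(A)), the marginal variance of each
environmental component is the mean of a lognormal:

    E[exp(c0 + c1 * A)] = exp(c0 + 0.5 * c1**2 * VAR(A))

Standardising the three marginal components gives the heritability h2
and the marginal environmental proportions c2 and e2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from hetace.params import BiometricParams, _gender_code

__all__ = [
    "VarianceDecomposition",
    "conditional_variances",
    "var_A",
    "marginal_variances",
    "gxe_heritability_fraction",
    "phenotype_cov_structure",
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Marginal ACE variances and standardized proportions for one group."""

    group: str
    var_a: float
    var_c: float
    var_e: float

    @property
    def total(self) -> float:
        return self.var_a + self.var_c + self.var_e

    @property
    def h2(self) -> float:
        return self.var_a / self.total

    @property
    def c2(self) -> float:
        return self.var_c / self.total

    @property
    def e2(self) -> float:
        return self.var_e / self.total

    def as_dict(self) -> dict[str, float]:
        return {
            "group": self.group,
            "var_a": self.var_a,
            "var_c": self.var_c,
            "var_e": self.var_e,
            "h2": self.h2,
            "c2": self.c2,
            "e2": self.e2,
        }


def conditional_variances(A, gender, params: BiometricParams):
    """(VAR(C|A), VAR(E|A)) at genetic score A for one sex.

    Both are strictly positive for any finite A.  Broadcasts over
    array-valued ``A``.
    """
    eff = params.effective(gender)
    A = np.asarray(A, dtype=float)
    var_c = np.exp(eff["gamma0"] + eff["gamma1"] * A)
    var_e = np.exp(eff["beta0"] + eff["beta1"] * A)
    if A.ndim == 0:
        return float(var_c), float(var_e)
    return var_c, var_e


def var_A(gender, params: BiometricParams) -> float:
    """VAR(A) = exp(omega0_overall [+ omega0_female for females])."""
    return math.exp(params.effective(gender)["omega0"])


def marginal_variances(params: BiometricParams, gender, *, paper_literal: bool = False) -> VarianceDecomposition:
    """Marginal ACE decomposition for one sex.

    The default pairs each interaction slope with its own component and
    includes VAR(A) in the lognormal-mean exponent:

        VAR(C) = exp(gamma0 + 0.5 * gamma1**2 * VAR(A))
        VAR(E) = exp(beta0  + 0.5 * beta1**2  * VAR(A))

    ``paper_literal=True`` switches to the variant sometimes printed in
    the applied literature, exp(beta0 + 0.5*beta1^2) for C and
    exp(gamma0 + 0.5*gamma1^2) for E (no VAR(A) factor, slopes swapped
    across components); it is provided for comparison only and does not
    equal the lognormal mean.
    """
    eff = params.effective(gender)
    s2a = math.exp(eff["omega0"])
    if paper_literal:
        var_c = math.exp(eff["beta0"] + 0.5 * eff["beta1"] ** 2)
        var_e = math.exp(eff["gamma0"] + 0.5 * eff["gamma1"] ** 2)
    else:
        var_c = math.exp(eff["gamma0"] + 0.5 * eff["gamma1"] ** 2 * s2a)
        var_e = math.exp(eff["beta0"] + 0.5 * eff["beta1"] ** 2 * s2a)
    label = "female" if _gender_code(gender) else "male"
    return VarianceDecomposition(group=label, var_a=s2a, var_c=var_c, var_e=var_e)


def gxe_heritability_fraction(h2_reference: float, h2_group: float) -> float:
    """Fraction of reference-group heritability attributable to GxE.

    Defined as ``1 - h2_group / h2_reference``: the drop in standardized
    heritability once the interaction structure of the group is
    modelled, relative to the reference fit.
    """
    if not (0.0 < h2_reference <= 1.0) or not (0.0 < h2_group <= 1.0):
        raise ValueError("heritabilities must lie in (0, 1]")
    return 1.0 - h2_group / h2_reference


def phenotype_cov_structure(
    zygosity: str,
    decomposition1: VarianceDecomposition,
    decomposition2: VarianceDecomposition | None = None,
    *,
    interaction_slopes: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
) -> np.ndarray:
    """2x2 covariance of (theta1, theta2) under the linear ACE model.

    Diagonal entries are the members' total variances; the off-diagonal
    is ``a * sigma_A1 * sigma_A2 + sigma_C1 * sigma_C2`` with genetic
    correlation ``a = 1`` (MZ) or ``0.5`` (DZ).  For opposite-sex DZ
    pairs pass both members' decompositions.  Only valid when all
    interaction slopes are zero: under A-by-C/A-by-E interaction the
    joint distribution of (theta1, theta2) is non-Gaussian and a
    covariance matrix is not a sufficient description.
    """
    if any(abs(s) > 0 for s in interaction_slopes):
        raise ValueError("covariance structure is unsupported with nonzero interaction slopes")
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    d1 = decomposition1
    d2 = decomposition2 if decomposition2 is not None else decomposition1
    a = 1.0 if zygosity == "MZ" else 0.5
    off = a * math.sqrt(d1.var_a * d2.var_a) + math.sqrt(d1.var_c * d2.var_c)
    return np.array([[d1.total, off], [off, d2.total]])
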