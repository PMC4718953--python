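import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetace import (
    conditional_variances,
    gxe_heritability_fraction,
    marginal_variances,
    phenotype_cov_structure,
    preset_params,
    var_A,
)
from hetace.biometric import VarianceDecomposition
from hetace.params import BiometricParams


@pytest.fixture(scope="module")
def m2():
    return preset_params("table7_table8_M2")[1]


class TestConditionalVariances:
    def test_m2_male_at_zero(self, m2):
        var_c, var_e = conditional_variances(0.0, "male", m2)
        assert var_c == pytest.approx(math.exp(-2.24), abs=1e-12)
        assert var_e == pytest.approx(math.exp(-0.87), abs=1e-12)

    def test_no_interaction_constant_in_a(self):
        _, bio = preset_params("null_ACE")
        v0 = conditional_variances(0.0, "male", bio)
        v3 = conditional_variances(3.0, "male", bio)
        assert v0 == v3

    def test_positive_beta1_increases_var_e_with_a(self, m2):
        # beta1 > 0: unique-environment variance grows with genetic liability
        assert m2.beta1_overall > 0
        _, e0 = conditional_variances(0.0, "male", m2)
        _, e1 = conditional_variances(1.0, "male", m2)
        assert e1 > e0


class TestVarA:
    def test_preset_group_variances(self, m2):
        assert var_A("male", m2) == pytest.approx(0.40)
        assert var_A("female", m2) == pytest.approx(0.64)

    def test_zero_offset_equalizes_sexes(self):
        bio = BiometricParams(omega0_overall=math.log(0.5))
        assert var_A("male", bio) == var_A("female", bio)


class TestMarginalVariances:
    def test_m2_male_closed_form(self, m2):
        dec = marginal_variances(m2, "male")
        assert dec.var_c == pytest.approx(math.exp(-2.24 + 0.5 * 1.93**2 * 0.40), rel=1e-12)
        assert dec.var_e == pytest.approx(math.exp(-0.87 + 0.5 * 0.91**2 * 0.40), rel=1e-12)
        assert dec.var_c == pytest.approx(0.2242, abs=5e-4)
        assert dec.var_e == pytest.approx(0.4944, abs=5e-4)
        assert dec.total == pytest.approx(1.1186, abs=1e-3)

    def test_no_interaction_marginal_equals_conditional(self):
        _, bio = preset_params("null_ACE")
        dec = marginal_variances(bio, "male")
        var_c0, var_e0 = conditional_variances(0.0, "male", bio)
        assert dec.var_c == var_c0 and dec.var_e == var_e0

    def test_monte_carlo_expectation_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(1_000_000)
        for gamma0, gamma1, s2a in ((-2.24, -1.93, 0.40), (-0.7, 0.9, 1.0), (-4.0, 1.4, 0.25)):
            bio = BiometricParams(omega0_overall=math.log(s2a), gamma0_overall=gamma0, gamma1_overall=gamma1, beta0_overall=-1.0)
            mc = np.exp(gamma0 + gamma1 * math.sqrt(s2a) * z).mean()
            assert marginal_variances(bio, "male").var_c == pytest.approx(mc, rel=0.01)

    def test_paper_literal_variant_differs(self, m2):
        lit = marginal_variances(m2, "male", paper_literal=True)
        std = marginal_variances(m2, "male")
        # the standard (lognormal-mean) form reproduces the published male e2;
        # the literal printed formula lands visibly away from it
        assert std.e2 == pytest.approx(0.44, abs=0.005)
        assert abs(lit.e2 - 0.44) > 0.03
        assert abs(lit.e2 - std.e2) > 0.03

    def test_increasing_slope_never_decreases_var_e(self):
        vals = [
            marginal_variances(BiometricParams(beta0_overall=-1.0, beta1_overall=b), "male").var_e
            for b in (0.0, 0.5, 1.0, 2.0)
        ]
        assert vals == sorted(vals)

    def test_zero_female_offsets_equalize_decompositions(self):
        bio = BiometricParams(omega0_overall=-0.7, beta0_overall=-1.0, beta1_overall=0.6, gamma0_overall=-2.0, gamma1_overall=-0.8)
        male = marginal_variances(bio, "male")
        female = marginal_variances(bio, "female")
        assert (male.var_a, male.var_c, male.var_e) == (female.var_a, female.var_c, female.var_e)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        om=st.floats(-3, 1),
        b0=st.floats(-5, 0),
        b1=st.floats(-2, 2),
        g0=st.floats(-5, 0),
        g1=st.floats(-2, 2),
    )
    def test_proportions_sum_to_one(self, om, b0, b1, g0, g1):
        bio = BiometricParams(omega0_overall=om, beta0_overall=b0, beta1_overall=b1, gamma0_overall=g0, gamma1_overall=g1)
        dec = marginal_variances(bio, "male")
        assert dec.h2 + dec.c2 + dec.e2 == pytest.approx(1.0, abs=1e-10)
        assert min(dec.h2, dec.c2, dec.e2) >= 0.0


class TestGxeFraction:
    def test_published_value(self):
        assert gxe_heritability_fraction(0.52, 0.35) == pytest.approx(1 - 0.35 / 0.52)
        assert round(100 * gxe_heritability_fraction(0.52, 0.35)) == 33

    def test_equal_heritabilities_give_zero(self):
        assert gxe_heritability_fraction(0.4, 0.4) == 0.0

    def test_halving(self):
        assert gxe_heritability_fraction(0.5, 0.25) == pytest.approx(0.5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gxe_heritability_fraction(0.0, 0.3)
        with pytest.raises(ValueError):
            gxe_heritability_fraction(0.5, 1.2)


class TestPhenotypeCovStructure:
    def test_mz_off_diagonal(self):
        d = VarianceDecomposition("g", 0.5, 0.2, 0.3)
        cov = phenotype_cov_structure("MZ", d)
        assert cov[0, 1] == pytest.approx(0.7)
        assert cov[0, 0] == pytest.approx(1.0)

    def test_dz_same_sex(self):
        d = VarianceDecomposition("g", 0.5, 0.2, 0.3)
        assert phenotype_cov_structure("DZ", d)[0, 1] == pytest.approx(0.45)

    def test_dz_opposite_sex_genetic_covariance(self):
        dm = VarianceDecomposition("male", 0.40, 0.0, 0.6)
        df = VarianceDecomposition("female", 0.64, 0.0, 0.5)
        cov = phenotype_cov_structure("DZ", dm, df)
        assert cov[0, 1] == pytest.approx(0.5 * math.sqrt(0.40 * 0.64), abs=1e-12)

    def test_interaction_slopes_unsupported(self):
        d = VarianceDecomposition("g", 0.5, 0.2, 0.3)
        with pytest.raises(ValueError):
            phenotype_cov_structure("MZ", d, interaction_slopes=(0.9, 0.0, 0.0, 0.0))
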