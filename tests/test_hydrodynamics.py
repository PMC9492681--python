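"""Hydrodynamic correlations: closed forms, limits, units and regimes.

Frozen expected values were computed with an independent term-by-term
evaluation of each correlation (plain arithmetic on the printed constants),
separate from the implementation under test.
"""

from fractions import Fraction

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budscale import (
    CultureConditions,
    MediumProperties,
    RegimeBand,
    VesselGeometry,
    classify_regime,
    kla,
    modified_newton_number,
    modified_volumetric_power,
    reynolds_number,
    volumetric_power_input,
)


def make_cond(d=0.085, volume_mL=80.0, rpm=250.0, d0=0.05):
    return CultureConditions.from_practical(d, volume_mL, rpm, d0)


class TestReynolds:
    def test_zero_shaking_gives_zero(self, medium):
        assert reynolds_number(make_cond(rpm=0.0), medium) == 0.0

    @pytest.mark.parametrize(
        "rho, eta, rpm, d, expected, rel",
        [
            (1000.0, 1e-3, 60.0, 0.1, 1.0e4, 1e-12),  # hand evaluation
            (995.67, 7.97e-4, 250.0, 0.085, 37608.30065872021, 1e-12),  # independent oracle
        ],
    )
    def test_known_values(self, rho, eta, rpm, d, expected, rel):
        medium = MediumProperties(rho=rho, eta_app=eta)
        cond = CultureConditions(VesselGeometry(d), 8e-5, rpm / 60.0)
        assert reynolds_number(cond, medium) == pytest.approx(expected, rel=rel)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MediumProperties(rho=-1.0)
        with pytest.raises(ValueError):
            VesselGeometry(0.0)


class TestModifiedNewton:
    def test_unit_reynolds_is_exact(self):
        # all three power terms equal 1: 70 + 25 + 1.5
        assert modified_newton_number(1.0) == 96.5

    def test_independent_term_sum(self):
        # 70e-4 + 25*10^(-2.4) + 1.5*10^(-0.8), evaluated independently
        assert modified_newton_number(1e4) == pytest.approx(0.34426077150754136, rel=1e-12)

    def test_high_re_dominant_term(self):
        re = 1e12
        assert modified_newton_number(re) / (1.5 * re**-0.2) == pytest.approx(1.0, rel=1e-3)

    def test_domain_error_at_zero(self):
        with pytest.raises(ValueError):
            modified_newton_number(0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e10), st.floats(min_value=1.0001, max_value=10.0))
    def test_strictly_decreasing_and_positive(self, re, factor):
        lo, hi = modified_newton_number(re), modified_newton_number(re * factor)
        assert lo > hi > 0.0


class TestVolumetricPower:
    def test_zero_shaking_limit(self, medium):
        assert volumetric_power_input(make_cond(rpm=0.0), medium) == 0.0

    def test_reference_condition(self, medium, ref_condition):
        # independent chained evaluation Re -> Ne' -> P/V_L at the reference condition
        assert volumetric_power_input(ref_condition, medium) == pytest.approx(
            464.1756093057754, rel=1e-12
        )

    def test_cubic_in_n_at_fixed_newton_number(self, medium):
        # dividing out Ne' isolates the explicit n^3 power law
        c1, c2 = make_cond(rpm=120.0), make_cond(rpm=240.0)
        r1 = volumetric_power_input(c1, medium) / modified_newton_number(reynolds_number(c1, medium))
        r2 = volumetric_power_input(c2, medium) / modified_newton_number(reynolds_number(c2, medium))
        assert r2 / r1 == pytest.approx(8.0, rel=1e-12)


class TestKla:
    def test_linear_in_n(self, medium):
        base = kla(make_cond(rpm=100.0), medium)
        assert kla(make_cond(rpm=0.0), medium) == 0.0
        assert kla(make_cond(rpm=200.0), medium) == pytest.approx(2.0 * base, rel=1e-12)

    def test_reference_condition(self, medium, ref_condition):
        # independent factor-by-factor evaluation of the correlation
        assert kla(ref_condition, medium) == pytest.approx(3.221524151531476, rel=1e-12)


class TestModifiedVolumetricPower:
    def test_static_culture_all_zero(self, medium):
        h = modified_volumetric_power(make_cond(rpm=0.0), medium)
        assert h.reynolds == h.power_per_volume == h.kla == h.pva_si == h.pva_milli == 0.0
        assert math.isnan(h.newton_mod)  # Ne' undefined at Re = 0

    def test_reference_condition_product(self, medium, ref_condition):
        h = modified_volumetric_power(ref_condition, medium)
        assert h.pva_milli == pytest.approx(6.634960417347882, rel=1e-12)

    def test_definitional_identity(self, medium, ref_condition):
        h = modified_volumetric_power(ref_condition, medium)
        d5 = ref_condition.vessel.inner_diameter**5
        assert h.pva_si == pytest.approx(d5 * h.kla * h.power_per_volume, rel=1e-12)
        assert h.pva_milli == 1000.0 * h.pva_si

    def test_strictly_increasing_in_n(self, medium):
        grid = np.linspace(0.05, 20.0, 200)
        pva = [modified_volumetric_power(make_cond(rpm=60.0 * n), medium).pva_milli for n in grid]
        assert np.all(np.diff(pva) > 0)


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "pva, expected",
        [(0.3, "low"), (0.72, "optimal"), (1.0, "optimal"), (1.65, "optimal"), (2.5, "high")],
    )
    def test_band_with_inclusive_boundaries(self, pva, expected):
        assert classify_regime(pva, RegimeBand(0.72, 1.65)) == expected

    def test_total_on_nonnegative_axis(self):
        for pva in (0.0, 1e-9, 1e9):
            assert classify_regime(pva) in ("low", "optimal", "high")
        with pytest.raises(ValueError):
            classify_regime(-0.1)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            RegimeBand(1.65, 0.72)
        with pytest.raises(ValueError):
            RegimeBand(0.0, 1.0)


class TestDimensionalConsistency:
    """Symbolic exponent bookkeeping over (kg, m, s) with exact fractions."""

    # dimensions of each factor as (mass, length, time) exponents
    DIMS = {
        "d": (0, 1, 0),
        "d0": (0, 1, 0),
        "n": (0, 0, -1),
        "VL": (0, 3, 0),
        "D": (0, 2, -1),
        "nu": (0, 2, -1),
        "g": (0, 1, -2),
        "rho": (1, -3, 0),
    }

    @staticmethod
    def _combine(powers: dict[str, Fraction]) -> tuple[Fraction, Fraction, Fraction]:
        total = [Fraction(0)] * 3
        for factor, power in powers.items():
            for axis, exponent in enumerate(TestDimensionalConsistency.DIMS[factor]):
                total[axis] += Fraction(exponent) * power
        return tuple(total)

    def test_kla_correlation_is_per_second(self):
        powers = {
            "d": Fraction(73, 36),
            "n": Fraction(1),
            "d0": Fraction(1, 4),
            "VL": Fraction(-8, 9),
            "D": Fraction(1, 2),
            "nu": Fraction(-13, 54),
            "g": Fraction(-7, 54),
        }
        assert self._combine(powers) == (Fraction(0), Fraction(0), Fraction(-1))

    def test_power_per_volume_is_watt_per_cubic_metre(self):
        powers = {"rho": Fraction(1), "n": Fraction(3), "d": Fraction(4), "VL": Fraction(-2, 3)}
        # W/m^3 = kg m^2 s^-3 / m^3 = kg m^-1 s^-3
        assert self._combine(powers) == (Fraction(1), Fraction(-1), Fraction(-3))

    def test_composite_parameter_is_watt_square_metre_per_second(self):
        # d^5 [m^5] x k_La [s^-1] x P/V_L [kg m^-1 s^-3] = kg m^4 s^-4 = W.m^2/s
        d5 = self._combine({"d": Fraction(5)})
        kla_dims = (Fraction(0), Fraction(0), Fraction(-1))
        ppv_dims = (Fraction(1), Fraction(-1), Fraction(-3))
        total = tuple(a + b + c for a, b, c in zip(d5, kla_dims, ppv_dims))
        assert total == (Fraction(1), Fraction(4), Fraction(-4))
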