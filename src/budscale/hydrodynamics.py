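"""Shake-flask hydrodynamics for engineered-living-material (ELM) scale-up.

Unbaffled orbitally-shaken flasks transfer mechanical energy and oxygen to
the culture at rates set entirely by the vessel geometry, fill volume and
shaking frequency.  This module implements the standard correlations for

* the flask Reynolds number ``Re = rho * n * d**2 / eta_app``,
* the modified Newton (power) number
  ``Ne' = 70/Re + 25/Re**0.6 + 1.5/Re**0.2``,
* the volumetric power input
  ``P/V_L = Ne' * rho * n**3 * d**4 / V_L**(2/3)`` (W/m^3),
* a dimensional orbital-shaker correlation for the volumetric oxygen
  mass-transfer coefficient ``k_La`` (s^-1),

and combines them into the composite scale-up predictor

    ``P_V,A = d**5 * k_La * (P/V_L)``   (reported in mW.m^2/s),

the "modified volumetric power".  Material size in shaken ELM cultures is
maximal when P_V,A falls inside an intermediate ("optimal") band; the band
used for regime classification defaults to 0.72-1.65 mW.m^2/s.

All quantities are SI internally.  Shaking frequency is ``n`` in s^-1;
helpers accept rpm explicitly (never implicitly) because the predictor
scales like d**11 * n**3.8 across geometry and silent unit slips would be
catastrophic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "MediumProperties",
    "VesselGeometry",
    "CultureConditions",
    "HydroResult",
    "RegimeBand",
    "WATER_30C",
    "DEFAULT_BAND",
    "VESSEL_PRESETS",
    "rpm_to_hz",
    "hz_to_rpm",
    "reynolds_number",
    "modified_newton_number",
    "volumetric_power_input",
    "kla",
    "modified_volumetric_power",
    "classify_regime",
]

RegimeLabel = Literal["low", "optimal", "high"]


def rpm_to_hz(rpm: float) -> float:
    """Convert shaking speed in revolutions per minute to frequency in s^-1."""
    return rpm / 60.0


def hz_to_rpm(hz: float) -> float:
    """Convert shaking frequency in s^-1 to revolutions per minute."""
    return hz * 60.0


@dataclass(frozen=True)
class MediumProperties:
    """Physical properties of the culture medium.

    Defaults are water-like values at the standard growth temperature of
    30 degC, appropriate for dilute bacterial media at inoculation.

    Parameters
    ----------
    rho : float
        Liquid density, kg/m^3.
    eta_app : float
        Apparent dynamic viscosity, Pa.s.
    nu : float
        Kinematic viscosity, m^2/s.
    diffusion_coeff : float
        Oxygen diffusion coefficient D used by the k_La correlation, m^2/s.
    gravity : float
        Gravitational acceleration, m/s^2.
    """

    rho: float = 995.67
    eta_app: float = 7.97e-4
    nu: float = 8.005e-7
    diffusion_coeff: float = 2.5655e-5
    gravity: float = 9.807

    def __post_init__(self) -> None:
        for name in ("rho", "eta_app", "nu", "diffusion_coeff", "gravity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MediumProperties.{name} must be strictly positive")


#: Medium defaults used throughout: water at 30 degC.
WATER_30C = MediumProperties()


@dataclass(frozen=True)
class VesselGeometry:
    """Flask geometry: inner diameter d and shaking orbit diameter d0, in m."""

    inner_diameter: float
    orbit_diameter: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        if not self.inner_diameter > 0:
            raise ValueError("inner_diameter must be > 0")
        if not self.orbit_diameter > 0:
            raise ValueError("orbit_diameter must be > 0")


#: Assumed inner diameters for nominal Erlenmeyer sizes.  These are typical
#: catalogue values, NOT measured ones: the predictor scales as d**11, so
#: always prefer an explicitly measured diameter.
VESSEL_PRESETS: dict[str, VesselGeometry] = {
    "125mL": VesselGeometry(0.066, label="125 mL Erlenmeyer (assumed d)"),
    "250mL": VesselGeometry(0.085, label="250 mL Erlenmeyer (assumed d)"),
    "500mL": VesselGeometry(0.105, label="500 mL Erlenmeyer (assumed d)"),
}


@dataclass(frozen=True)
class CultureConditions:
    """One flask setup: vessel, fill volume V_L (m^3), shaking frequency n (s^-1)."""

    vessel: VesselGeometry
    fill_volume: float
    shaking_frequency: float

    def __post_init__(self) -> None:
        if not self.fill_volume > 0:
            raise ValueError("fill_volume must be > 0")
        if self.shaking_frequency < 0:
            raise ValueError("shaking_frequency must be >= 0")

    @classmethod
    def from_practical(
        cls,
        inner_diameter_m: float,
        fill_volume_mL: float,
        shaking_rpm: float,
        orbit_diameter_m: float = 0.05,
        label: str = "",
    ) -> "CultureConditions":
        """Build conditions from bench units (mL, rpm)."""
        vessel = VesselGeometry(inner_diameter_m, orbit_diameter_m, label)
        return cls(vessel, fill_volume_mL * 1e-6, rpm_to_hz(shaking_rpm))


@dataclass(frozen=True)
class HydroResult:
    """Derived hydrodynamic quantities for one culture condition.

    ``kla`` stores the combined product k_L*a: the correlation never
    separates the transfer coefficient from the interfacial area, so neither
    factor exists on its own here.
    """

    reynolds: float
    newton_mod: float
    power_per_volume: float  # W/m^3
    kla: float  # s^-1
    pva_si: float  # W.m^2/s
    pva_milli: float = field(default=float("nan"))  # mW.m^2/s

    def __post_init__(self) -> None:
        if math.isnan(self.pva_milli):
            object.__setattr__(self, "pva_milli", 1000.0 * self.pva_si)


@dataclass(frozen=True)
class RegimeBand:
    """Closed optimal interval of P_V,A in mW.m^2/s."""

    lower: float = 0.72
    upper: float = 1.65

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(f"invalid regime band [{self.lower}, {self.upper}]: need 0 < lower < upper")


#: Optimal modified-volumetric-power band, mW.m^2/s.
DEFAULT_BAND = RegimeBand(0.72, 1.65)


def reynolds_number(cond: CultureConditions, medium: MediumProperties = WATER_30C) -> float:
    """Flask Reynolds number Re = rho * n * d^2 / eta_app (dimensionless).

    Returns 0 for a static culture (n = 0).
    """
    d = cond.vessel.inner_diameter
    return medium.rho * cond.shaking_frequency * d * d / medium.eta_app


def modified_newton_number(reynolds: float) -> float:
    """Modified Newton (power) number for unbaffled shake flasks.

    Ne' = 70 Re^-1 + 25 Re^-0.6 + 1.5 Re^-0.2.  Strictly decreasing and
    positive; diverges as Re -> 0, so callers must special-case n = 0
    (static cultures draw no power).
    """
    if reynolds <= 0:
        raise ValueError("modified_newton_number requires Re > 0; handle n = 0 upstream")
    return 70.0 / reynolds + 25.0 * reynolds**-0.6 + 1.5 * reynolds**-0.2


def volumetric_power_input(cond: CultureConditions, medium: MediumProperties = WATER_30C) -> float:
    """Volumetric power input P/V_L = Ne' * rho * n^3 * d^4 / V_L^(2/3), W/m^3.

    The n = 0 limit is 0: Ne' * n^3 scales like n^2 for small n.
    """
    n = cond.shaking_frequency
    if n == 0:
        return 0.0
    ne = modified_newton_number(reynolds_number(cond, medium))
    d = cond.vessel.inner_diameter
    return ne * medium.rho * n**3 * d**4 / cond.fill_volume ** (2.0 / 3.0)


def kla(cond: CultureConditions, medium: MediumProperties = WATER_30C) -> float:
    """Volumetric oxygen mass-transfer coefficient k_La, s^-1.

    Dimensional orbital-shaker correlation

        k_La = 0.5 * d^(73/36) * n * d0^(1/4) * V_L^(-8/9)
                   * D^(1/2) * nu^(-13/54) * g^(-7/54)

    with all quantities in SI.  Linear in n, hence 0 for static cultures.
    The exponents sum to net dimensions of s^-1 (checked symbolically in the
    test suite).
    """
    d = cond.vessel.inner_diameter
    return (
        0.5
        * d ** (73.0 / 36.0)
        * cond.shaking_frequency
        * cond.vessel.orbit_diameter**0.25
        * cond.fill_volume ** (-8.0 / 9.0)
        * medium.diffusion_coeff**0.5
        * medium.nu ** (-13.0 / 54.0)
        * medium.gravity ** (-7.0 / 54.0)
    )


def modified_volumetric_power(
    cond: CultureConditions, medium: MediumProperties = WATER_30C
) -> HydroResult:
    """Full forward model: Re, Ne', P/V_L, k_La and P_V,A for one condition.

    P_V,A = d^5 * k_La * (P/V_L), in W.m^2/s; ``pva_milli`` reports the same
    quantity in mW.m^2/s, the scale on which the optimal band 0.72-1.65 is
    quoted.  Static cultures (n = 0) give all-zero outputs with Ne'
    reported as NaN (undefined at Re = 0).
    """
    n = cond.shaking_frequency
    if n == 0:
        return HydroResult(0.0, float("nan"), 0.0, 0.0, 0.0, 0.0)
    re = reynolds_number(cond, medium)
    ne = modified_newton_number(re)
    ppv = volumetric_power_input(cond, medium)
    k = kla(cond, medium)
    pva_si = cond.vessel.inner_diameter**5 * k * ppv
    return HydroResult(re, ne, ppv, k, pva_si)


def classify_regime(pva_milli: float, band: RegimeBand = DEFAULT_BAND) -> RegimeLabel:
    """Classify a P_V,A value (mW.m^2/s) as low / optimal / high.

    Band boundaries are inclusive: the optimal range is the closed interval
    [band.lower, band.upper].
    """
    if pva_milli < 0 or math.isnan(pva_milli):
        raise ValueError(f"pva_milli must be a number >= 0, got {pva_milli}")
    if pva_milli < band.lower:
        return "low"
    if pva_milli > band.upper:
        return "high"
    return "optimal"
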