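"""Inverse design of shake-flask conditions from a target modified volumetric power.

Given a vessel and either the fill volume or the shaking frequency, solve for
the other so that the culture hits a target P_V,A — the procedure used to
transfer an optimal operating window found in small flasks to larger ones.
P_V,A is strictly increasing in n and strictly decreasing in V_L (the volume
enters with exponents -2/3 and -8/9), so plain bisection on an explicit
bracket is exact and robust; an unattainable target is reported as a
non-converged solution rather than raised, so design sweeps can partially
succeed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy.optimize import bisect

from .hydrodynamics import (
    DEFAULT_BAND,
    WATER_30C,
    CultureConditions,
    MediumProperties,
    RegimeBand,
    VesselGeometry,
    classify_regime,
    modified_volumetric_power,
)

__all__ = ["DesignQuery", "DesignSolution", "solve_frequency", "solve_volume", "design_table"]

#: Default solver brackets: 0.1-10 s^-1 covers 6-600 rpm; 1e-5-5e-4 m^3
#: covers 10-500 mL.  Artifact defaults, adjustable per query.
DEFAULT_FREQ_BRACKET = (0.1, 10.0)
DEFAULT_VOLUME_BRACKET = (1e-5, 5e-4)

_RTOL = 1e-9  # relative tolerance on the solved variable


@dataclass(frozen=True)
class DesignQuery:
    """One inverse-design problem: fix one of (V_L, n), solve the other.

    Exactly one of ``fixed_fill_volume`` (m^3) and ``fixed_frequency``
    (s^-1) must be set; ``target_pva`` is in mW.m^2/s.
    """

    vessel: VesselGeometry
    target_pva: float
    fixed_fill_volume: Optional[float] = None
    fixed_frequency: Optional[float] = None
    medium: MediumProperties = WATER_30C
    band: RegimeBand = DEFAULT_BAND

    def __post_init__(self) -> None:
        if (self.fixed_fill_volume is None) == (self.fixed_frequency is None):
            raise ValueError("exactly one of fixed_fill_volume / fixed_frequency must be set")
        if not self.target_pva > 0:
            raise ValueError("target_pva must be > 0")


@dataclass(frozen=True)
class DesignSolution:
    """Outcome of an inverse-design solve.

    ``value`` is the solved variable in SI units (s^-1 for frequency, m^3
    for volume).  When ``converged`` is False the target lay outside the
    bracket's image; ``achieved_pva`` then reports the nearer bracket
    endpoint's P_V,A as a diagnostic.
    """

    solved_variable: str
    value: float
    achieved_pva: float
    regime: str
    converged: bool
    iterations: int
    message: str = ""


def _pva_at(vessel: VesselGeometry, volume: float, freq: float, medium: MediumProperties) -> float:
    cond = CultureConditions(vessel, volume, freq)
    return modified_volumetric_power(cond, medium).pva_milli


def _bisect_monotone(
    f, lo: float, hi: float, target: float, name: str, band: RegimeBand
) -> DesignSolution:
    """Bisection for f(x) = target on [lo, hi]; f strictly monotone."""
    f_lo, f_hi = f(lo), f(hi)
    increasing = f_hi >= f_lo
    below, above = (f_lo, f_hi) if increasing else (f_hi, f_lo)
    if not (below <= target <= above):
        # target outside the image of the bracket: report the nearer endpoint
        at_lo = abs(f_lo - target) <= abs(f_hi - target)
        x = lo if at_lo else hi
        ach = f_lo if at_lo else f_hi
        return DesignSolution(
            name, x, ach, classify_regime(ach, band), False, 0,
            f"target {target:g} outside attainable range [{below:g}, {above:g}]",
        )

    def g(x: float) -> float:
        return f(x) - target

    counter = itertools.count()

    def g_counted(x: float) -> float:
        next(counter)
        return g(x)

    root, res = bisect(g_counted, lo, hi, rtol=max(_RTOL, 9e-16), full_output=True)
    ach = f(root)
    # when converged the achieved value differs from the target only by the
    # solver tolerance; classify the target so inclusive band edges hold
    regime = classify_regime(target if res.converged else ach, band)
    return DesignSolution(name, root, ach, regime, res.converged, res.iterations)


def solve_frequency(query: DesignQuery, bracket: tuple[float, float] = DEFAULT_FREQ_BRACKET) -> DesignSolution:
    """Solve for the shaking frequency n (s^-1) that achieves ``target_pva``.

    P_V,A is strictly increasing in n at fixed geometry and volume, so the
    root on the bracket, when it exists, is unique.
    """
    if query.fixed_fill_volume is None:
        raise ValueError("solve_frequency needs fixed_fill_volume")
    volume = query.fixed_fill_volume

    def f(n: float) -> float:
        return _pva_at(query.vessel, volume, n, query.medium)

    return _bisect_monotone(f, bracket[0], bracket[1], query.target_pva, "shaking_frequency", query.band)


def solve_volume(query: DesignQuery, bracket: tuple[float, float] = DEFAULT_VOLUME_BRACKET) -> DesignSolution:
    """Solve for the fill volume V_L (m^3) that achieves ``target_pva``.

    P_V,A is strictly decreasing in V_L at fixed geometry and frequency.
    """
    if query.fixed_frequency is None:
        raise ValueError("solve_volume needs fixed_frequency")
    freq = query.fixed_frequency

    def f(v: float) -> float:
        return _pva_at(query.vessel, v, freq, query.medium)

    return _bisect_monotone(f, bracket[0], bracket[1], query.target_pva, "fill_volume", query.band)


def design_table(
    vessel: VesselGeometry,
    n_grid,
    volume_grid,
    medium: MediumProperties = WATER_30C,
    band: RegimeBand = DEFAULT_BAND,
) -> pd.DataFrame:
    """Full-factorial condition table annotated with hydrodynamics and regime.

    ``n_grid`` in s^-1, ``volume_grid`` in m^3.  One row per (n, V_L) pair,
    for planning which bench conditions land in which P_V,A regime.
    """
    n_grid = list(n_grid)
    volume_grid = list(volume_grid)
    if not n_grid or not volume_grid:
        raise ValueError("n_grid and volume_grid must be non-empty")
    rows = []
    for volume, n in itertools.product(volume_grid, n_grid):
        cond = CultureConditions(vessel, volume, n)
        h = modified_volumetric_power(cond, medium)
        rows.append(
            {
                "inner_diameter_m": vessel.inner_diameter,
                "orbit_diameter_m": vessel.orbit_diameter,
                "fill_volume_m3": volume,
                "shaking_frequency_hz": n,
                "Re": h.reynolds,
                "Ne_mod": h.newton_mod,
                "P_per_V_W_m3": h.power_per_volume,
                "kLa_per_s": h.kla,
                "Pva_mW_m2_s": h.pva_milli,
                "regime": classify_regime(h.pva_milli, band),
            }
        )
    return pd.DataFrame(rows)
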