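"""Seeded synthetic data for every pipeline stage.

Real inputs to this package are bench condition tables, flask-bottom
photographs and two-channel stain micrographs.  These generators emulate
their statistical structure with exact, machine-checkable ground truth:

* :func:`gen_condition_table` — culture conditions whose material-size
  response is unimodal (Gaussian in log10 of a chosen hydrodynamic
  predictor) with additive noise; conditions are constructed by inverse-
  solving the shaking frequency so the predictor values span the planted
  peak;
* :func:`gen_flask_image` — a flask-bottom photograph: calibration rim
  circle, large "bundled" disks, small "scattered" specks, background
  gradient, optional pixel noise; the sidecar lists each object's
  *rasterized* pixel area, so segmentation errors are attributable to the
  segmentation and never to pixelation;
* :func:`gen_coloc_field` — a two-channel stain field with an exactly
  planted overlap fraction between the cell-free matrix region and the
  stain.

All draws come from one ``numpy.random.default_rng(seed)`` stream per
call: identical configuration and seed give byte-identical outputs.

The default response-model parameters place the planted optimum so that
its half-maximum band reproduces the shape of the reference optimal window
0.72-1.65 mW.m^2/s (peak at the geometric midpoint, log10 ~ 0.037, width
0.153 log10 units); amplitude 4 cm^2 over a 0.5 cm^2 baseline with noise
SD equal to 10% of the amplitude approximates replicate scatter in
apparent-size data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .colocalization import TwoChannelField
from .hydrodynamics import (
    WATER_30C,
    CultureConditions,
    MediumProperties,
    VesselGeometry,
    kla as _kla,
    modified_volumetric_power,
    volumetric_power_input,
)
from .size_quant import FlaskImage

__all__ = [
    "ConditionTableConfig",
    "FlaskImageConfig",
    "ColocFieldConfig",
    "gen_condition_table",
    "gen_flask_image",
    "gen_coloc_field",
]

#: Planted response defaults: peak at the geometric midpoint of the
#: reference optimal window, width chosen so the half-maximum band matches
#: its log10 extent.
DEFAULT_PEAK_LOG10_PVA = math.log10(math.sqrt(0.72 * 1.65))
DEFAULT_WIDTH = (math.log10(1.65) - math.log10(0.72)) / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class ConditionTableConfig:
    """Parameters of the condition-table generator."""

    n_conditions: int = 30
    replicates: int = 1
    diameters_m: tuple[float, ...] = (0.066, 0.085, 0.105)
    orbit_diameter_m: float = 0.05
    volume_range_mL: tuple[float, float] = (25.0, 160.0)
    response_variable: str = "Pva_mW_m2_s"  # or "kLa_per_s" / "P_per_V_W_m3"
    peak_log10: float = DEFAULT_PEAK_LOG10_PVA
    width: float = DEFAULT_WIDTH
    amplitude_cm2: float = 4.0
    baseline_cm2: float = 0.5
    noise_sd_fraction: float = 0.1
    span_widths: float = 2.5  # predictor targets span peak +/- this many widths
    freq_bracket: tuple[float, float] = (0.05, 20.0)


def _predictor_value(cond: CultureConditions, medium: MediumProperties, which: str) -> float:
    if which == "Pva_mW_m2_s":
        return modified_volumetric_power(cond, medium).pva_milli
    if which == "kLa_per_s":
        return _kla(cond, medium)
    if which == "P_per_V_W_m3":
        return volumetric_power_input(cond, medium)
    raise ValueError(f"unknown response variable {which!r}")


def _solve_freq_for_target(
    vessel: VesselGeometry, volume: float, target: float, which: str,
    medium: MediumProperties, bracket: tuple[float, float],
) -> Optional[float]:
    """Bisection for the n giving predictor(n) = target; None if unattainable."""

    def f(n: float) -> float:
        return _predictor_value(CultureConditions(vessel, volume, n), medium, which)

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        return None
    for _ in range(200):  # plain bisection; every predictor is monotone in n
        mid = 0.5 * (lo + hi)
        if (f(mid) < target) == (f_lo < f_hi):
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def gen_condition_table(
    cfg: ConditionTableConfig = ConditionTableConfig(),
    seed: int = 0,
    medium: MediumProperties = WATER_30C,
) -> tuple[pd.DataFrame, dict]:
    """Generate a condition-size table with a planted unimodal response.

    Each condition draws a flask diameter and a log-uniform fill volume,
    samples a target predictor value log-uniformly across the planted peak,
    and inverse-solves the shaking frequency to hit it; the measured size
    is the planted response curve evaluated at the realized predictor plus
    Gaussian noise (truncated at zero).  Returns the table (canonical
    condition columns plus ``size_cm2``, ``replicate``) and a ground-truth
    sidecar with the planted parameters and per-row noiseless sizes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    made = 0
    attempts = 0
    while made < cfg.n_conditions:
        attempts += 1
        if attempts > 200 * cfg.n_conditions:
            raise RuntimeError("condition generation failed: targets unattainable in frequency bracket")
        d = float(rng.choice(cfg.diameters_m))
        log_v = rng.uniform(math.log(cfg.volume_range_mL[0]), math.log(cfg.volume_range_mL[1]))
        volume_mL = math.exp(log_v)
        target_log10 = rng.uniform(
            cfg.peak_log10 - cfg.span_widths * cfg.width,
            cfg.peak_log10 + cfg.span_widths * cfg.width,
        )
        vessel = VesselGeometry(d, cfg.orbit_diameter_m)
        n = _solve_freq_for_target(
            vessel, volume_mL * 1e-6, 10.0**target_log10,
            cfg.response_variable, medium, cfg.freq_bracket,
        )
        if n is None:
            continue
        cond = CultureConditions(vessel, volume_mL * 1e-6, n)
        realized = _predictor_value(cond, medium, cfg.response_variable)
        clean = cfg.amplitude_cm2 * math.exp(
            -((math.log10(realized) - cfg.peak_log10) ** 2) / (2.0 * cfg.width**2)
        ) + cfg.baseline_cm2
        for rep in range(cfg.replicates):
            noise = rng.normal(0.0, cfg.noise_sd_fraction * cfg.amplitude_cm2)
            rows.append(
                {
                    "label": f"cond{made:03d}",
                    "flask_inner_diameter_m": d,
                    "orbit_diameter_m": cfg.orbit_diameter_m,
                    "fill_volume_mL": volume_mL,
                    "shaking_rpm": n * 60.0,
                    "size_cm2": max(0.0, clean + noise),
                    "replicate": f"r{rep + 1}",
                }
            )
        truth_rows.append({"label": f"cond{made:03d}", "true_predictor": realized, "true_size_cm2": clean})
        made += 1
    sidecar = {
        "seed": seed,
        "response_variable": cfg.response_variable,
        "peak_log10": cfg.peak_log10,
        "width": cfg.width,
        "amplitude_cm2": cfg.amplitude_cm2,
        "baseline_cm2": cfg.baseline_cm2,
        "noise_sd": cfg.noise_sd_fraction * cfg.amplitude_cm2,
        "per_condition": pd.DataFrame(truth_rows),
    }
    return pd.DataFrame(rows), sidecar


@dataclass(frozen=True)
class FlaskImageConfig:
    """Parameters of the flask-bottom image generator (intensities in uint8)."""

    height: int = 512
    width: int = 512
    n_bundled: int = 5
    n_scattered: int = 50
    bundled_radius_px: tuple[float, float] = (15.0, 30.0)
    scattered_radius_px: tuple[float, float] = (1.0, 3.0)
    background_level: float = 10.0
    gradient_amplitude: float = 20.0
    bundled_intensity: float = 200.0
    scattered_intensity: float = 160.0
    circle_radius_px: float = 240.0
    flask_inner_diameter_cm: float = 8.5
    noise_sd: float = 0.0
    min_gap_px: float = 3.0


def _disk_mask(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2


def gen_flask_image(
    cfg: FlaskImageConfig = FlaskImageConfig(), seed: int = 0
) -> tuple[FlaskImage, pd.DataFrame]:
    """Render a synthetic flask-bottom photograph with exact ground truth.

    The calibration rim is drawn in the red and green channels only; the
    blue channel carries the background gradient and the material objects,
    mirroring the real images' use of the blue channel for segmentation.
    Objects are non-overlapping disks separated by at least ``min_gap_px``
    so 8-connected labelling cannot merge them.  The sidecar lists each
    object's class, centre, radius and rasterized pixel area.
    """
    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if cfg.circle_radius_px > min(cy, cx):
        raise ValueError("calibration circle does not fit in the frame")

    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    specs: list[tuple[str, float]] = [("bundled", rng.uniform(*cfg.bundled_radius_px)) for _ in range(cfg.n_bundled)]
    specs += [("scattered", rng.uniform(*cfg.scattered_radius_px)) for _ in range(cfg.n_scattered)]

    records = []
    for object_class, radius in specs:
        max_r = cfg.circle_radius_px - radius - cfg.min_gap_px
        if max_r <= 0:
            raise ValueError("infeasible packing: object larger than the calibration circle")
        for attempt in range(2000):
            # uniform over the allowed disk of centre positions
            rad = max_r * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            r0, c0 = cy + rad * math.sin(theta), cx + rad * math.cos(theta)
            if all(
                math.hypot(r0 - r1, c0 - c1) > radius + rad1 + cfg.min_gap_px
                for r1, c1, rad1 in placed
            ):
                placed.append((r0, c0, radius))
                records.append({"object_class": object_class, "center_row": r0,
                                "center_col": c0, "radius_px": radius})
                break
        else:
            raise ValueError("infeasible packing: could not place all objects without overlap")

    cols = np.arange(w, dtype=float)
    background = cfg.background_level + cfg.gradient_amplitude * cols / (w - 1)
    blue = np.tile(background, (h, 1))
    for rec in records:
        mask = _disk_mask(h, w, rec["center_row"], rec["center_col"], rec["radius_px"])
        rec["area_px"] = int(mask.sum())
        blue[mask] = (
            cfg.bundled_intensity if rec["object_class"] == "bundled" else cfg.scattered_intensity
        )

    # calibration rim: a 3 px ring in red+green only
    rr, cc = np.ogrid[:h, :w]
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    ring = np.abs(dist - cfg.circle_radius_px) <= 1.5
    red = np.tile(background, (h, 1))
    red[ring] = 255.0
    rgb = np.stack([red, red.copy(), blue], axis=2)
    if cfg.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, cfg.noise_sd, size=rgb.shape)
    pixels = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    image = FlaskImage(pixels, cfg.flask_inner_diameter_cm, (cy, cx, cfg.circle_radius_px))
    return image, pd.DataFrame(records)


@dataclass(frozen=True)
class ColocFieldConfig:
    """Parameters of the two-channel stain-field generator.

    The material ROI is a rectangle and the cell-free holes have radius at
    most ``hole_radius_px[1]``; keeping that radius below the downstream
    morphological-closing radius guarantees the closing of the union mask
    recovers the planted ROI pixel-exactly, so noiseless recovery of the
    planted overlap fraction is exact by construction.
    """

    height: int = 256
    width: int = 256
    margin_px: int = 24
    n_holes: int = 8
    hole_radius_px: tuple[float, float] = (2.0, 3.0)
    planted_overlap_fraction: float = 0.3
    background_level: float = 5.0
    cell_intensity: float = 180.0
    stain_intensity: float = 200.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_overlap_fraction <= 1.0:
            raise ValueError("planted_overlap_fraction must be in [0, 1]")


def gen_coloc_field(
    cfg: ColocFieldConfig = ColocFieldConfig(), seed: int = 0
) -> tuple[TwoChannelField, dict]:
    """Generate a two-channel field with an exactly planted overlap fraction.

    Stains exactly ``round(fraction * |cellfree|)`` cell-free pixels; the
    sidecar reports the realized fraction (exact rational count) together
    with the ground-truth masks.
    """
    rng = np.random.default_rng(seed)
    h, w, m = cfg.height, cfg.width, cfg.margin_px
    if h - 2 * m < 16 or w - 2 * m < 16:
        raise ValueError("margin leaves no room for the ROI")
    roi = np.zeros((h, w), dtype=bool)
    roi[m : h - m, m : w - m] = True

    holes = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    pad = cfg.hole_radius_px[1] + 3.0  # keep holes clear of the ROI boundary
    for _ in range(cfg.n_holes):
        radius = rng.uniform(*cfg.hole_radius_px)
        for attempt in range(2000):
            r0 = rng.uniform(m + pad, h - m - pad)
            c0 = rng.uniform(m + pad, w - m - pad)
            if all(math.hypot(r0 - r1, c0 - c1) > radius + rad1 + 3.0 for r1, c1, rad1 in placed):
                placed.append((r0, c0, radius))
                holes |= _disk_mask(h, w, r0, c0, radius)
                break
        else:
            raise ValueError("infeasible packing of cell-free holes")
    if not holes.any():
        raise ValueError("planted overlap fraction needs a non-empty cell-free region")

    cell_mask = roi & ~holes
    cellfree_idx = np.flatnonzero(holes.ravel())
    k = int(round(cfg.planted_overlap_fraction * cellfree_idx.size))
    stained = rng.choice(cellfree_idx, size=k, replace=False) if k else np.empty(0, dtype=int)
    stain_mask = np.zeros(h * w, dtype=bool)
    stain_mask[stained] = True
    stain_mask = stain_mask.reshape(h, w)

    cell = np.full((h, w), cfg.background_level)
    cell[cell_mask] = cfg.cell_intensity
    stain = np.full((h, w), cfg.background_level)
    stain[stain_mask] = cfg.stain_intensity
    if cfg.noise_sd > 0:
        cell = cell + rng.normal(0.0, cfg.noise_sd, size=cell.shape)
        stain = stain + rng.normal(0.0, cfg.noise_sd, size=stain.shape)
    cell = np.clip(cell, 0, None)
    stain = np.clip(stain, 0, None)

    field = TwoChannelField(cell, stain, ("cells", "stain"))
    sidecar = {
        "seed": seed,
        "cell_mask": cell_mask,
        "stain_mask": stain_mask,
        "roi_mask": roi,
        "cellfree_px": int(cellfree_idx.size),
        "stained_px": k,
        "true_fraction": k / cellfree_idx.size,
    }
    return field, sidecar
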