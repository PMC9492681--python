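"""Fitting the unimodal size-vs-P_V,A response and selecting the predictor.

Material size in shaken cultures rises and then falls as the modified
volumetric power P_V,A increases: too little power leaves a fragmented thin
pellicle, too much shears pellicles apart.  This module fits that unimodal
response with a Gaussian bump in log10 P_V,A,

    size = amplitude * exp(-(log10 p - peak)^2 / (2 width^2)) + baseline,

derives an optimal operating band as the interval where the fitted size
exceeds ``baseline + f * amplitude`` (f = 0.5 by default, a full-width-
half-maximum analogue), and compares P_V,A against its ingredients P/V_L
and k_La as predictors by the goodness of the same fit.  The comparison is
only meaningful across multiple flask diameters — within one flask the
three quantities are monotone functions of each other.

A nonparametric band mode is also provided: the span of conditions whose
mean size reaches a fraction ``alpha`` of the best condition's mean size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .hydrodynamics import (
    WATER_30C,
    CultureConditions,
    MediumProperties,
    RegimeBand,
    modified_volumetric_power,
)

__all__ = [
    "OptimalRangeFit",
    "UnimodalResponseModel",
    "annotate_pva",
    "fit_unimodal",
    "empirical_band",
    "compare_parameters",
]

#: Canonical condition-table columns consumed by :func:`annotate_pva`.
CONDITION_COLUMNS = ("flask_inner_diameter_m", "orbit_diameter_m", "fill_volume_mL", "shaking_rpm")


@dataclass(frozen=True)
class OptimalRangeFit:
    """Result of a unimodal response fit.

    ``derived_band`` is the half-maximum band on the predictor's own scale
    (mW.m^2/s when the predictor is P_V,A); it is None when the fit failed,
    never a fabricated interval.
    """

    peak_log10_pva: float
    width: float
    amplitude: float
    baseline: float
    derived_band: Optional[RegimeBand]
    goodness: float
    converged: bool
    message: str = ""


def _gaussian_log10(x: np.ndarray, amplitude: float, peak: float, width: float, baseline: float) -> np.ndarray:
    return amplitude * np.exp(-((x - peak) ** 2) / (2.0 * width**2)) + baseline


class UnimodalResponseModel(BaseEstimator, RegressorMixin):
    """Gaussian-in-log10 unimodal response regressor.

    Fits ``y = A exp(-(log10 x - mu)^2 / (2 s^2)) + b`` by bounded
    least squares (A >= 0, s > 0) and derives the band where the fitted
    response exceeds ``b + band_fraction * A``.

    Parameters
    ----------
    band_fraction : float
        Fraction f of the amplitude defining the optimal band (default 0.5,
        i.e. the full width at half maximum on the log10 axis).
    min_distinct : int
        Minimum number of distinct positive predictor values required.

    Attributes
    ----------
    peak_log10_ : float
        Fitted peak location mu on the log10 predictor axis.
    width_ : float
        Fitted Gaussian width s (log10 units).
    amplitude_ : float
        Fitted amplitude A (size units).
    baseline_ : float
        Fitted baseline b (size units).
    band_ : RegimeBand or None
        Optimal band on the predictor's linear scale; None if not converged.
    r_squared_ : float
        Coefficient of determination of the fit, clipped to [0, 1].
    converged_ : bool
        Whether the fit succeeded; failure reasons are in ``message_``.
    """

    def __init__(self, band_fraction: float = 0.5, min_distinct: int = 5):
        self.band_fraction = band_fraction
        self.min_distinct = min_distinct

    def fit(self, X, y):
        if not 0 < self.band_fraction < 1:
            raise ValueError("band_fraction must be in (0, 1)")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        ok = np.isfinite(x) & np.isfinite(y) & (x > 0)
        x, y = x[ok], y[ok]
        self.n_samples_ = int(x.size)
        if np.unique(x).size < self.min_distinct:
            return self._fail(f"need >= {self.min_distinct} distinct positive predictor values")
        if np.ptp(y) == 0:
            return self._fail("flat response: no curvature to fit")

        lx = np.log10(x)
        p0 = (
            max(y.max() - y.min(), 1e-12),  # amplitude
            lx[np.argmax(y)],  # peak at the largest observed response
            max(np.ptp(lx) / 4.0, 1e-3),  # width
            y.min(),  # baseline
        )
        span = np.ptp(lx)
        bounds = (
            [0.0, lx.min() - span, 1e-6, -np.inf],
            [np.inf, lx.max() + span, np.inf, np.inf],
        )
        try:
            popt, _ = curve_fit(_gaussian_log10, lx, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            return self._fail(f"least-squares fit did not converge: {exc}")

        amplitude, peak, width, baseline = map(float, popt)
        resid = y - _gaussian_log10(lx, *popt)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        self.r_squared_ = float(np.clip(r2, 0.0, 1.0))
        if amplitude <= 0:
            return self._fail("degenerate fit: non-positive amplitude")
        self.amplitude_ = amplitude
        self.peak_log10_ = peak
        self.width_ = width
        self.baseline_ = baseline
        half_width = width * math.sqrt(-2.0 * math.log(self.band_fraction))
        self.band_ = RegimeBand(10.0 ** (peak - half_width), 10.0 ** (peak + half_width))
        self.converged_ = True
        self.message_ = ""
        return self

    def _fail(self, message: str):
        self.amplitude_ = self.peak_log10_ = self.width_ = self.baseline_ = float("nan")
        self.band_ = None
        self.r_squared_ = 0.0
        self.converged_ = False
        self.message_ = message
        return self

    def predict(self, X):
        check_is_fitted(self, "converged_")
        if not self.converged_:
            raise ValueError(f"model did not converge: {self.message_}")
        x = np.asarray(X, dtype=float).reshape(-1)
        return _gaussian_log10(np.log10(x), self.amplitude_, self.peak_log10_, self.width_, self.baseline_)

    def as_range_fit(self) -> OptimalRangeFit:
        check_is_fitted(self, "converged_")
        return OptimalRangeFit(
            self.peak_log10_, self.width_, self.amplitude_, self.baseline_,
            self.band_, self.r_squared_, self.converged_, self.message_,
        )


def annotate_pva(records: pd.DataFrame, medium: MediumProperties = WATER_30C) -> pd.DataFrame:
    """Add the forward-model columns to a condition(-size) table.

    ``records`` needs the canonical condition columns
    (``flask_inner_diameter_m``, ``orbit_diameter_m``, ``fill_volume_mL``,
    ``shaking_rpm``); the returned copy gains ``Re``, ``Ne_mod``,
    ``P_per_V_W_m3``, ``kLa_per_s``, ``Pva_mW_m2_s`` and a ``static`` flag
    for zero-shaking rows.  Rows with invalid geometry are flagged in the
    ``error`` column rather than aborting the table.
    """
    missing = [c for c in CONDITION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing condition columns: {missing}")
    out = records.copy()
    cols = {"Re": [], "Ne_mod": [], "P_per_V_W_m3": [], "kLa_per_s": [], "Pva_mW_m2_s": [],
            "static": [], "error": []}
    for _, row in out.iterrows():
        try:
            cond = CultureConditions.from_practical(
                row["flask_inner_diameter_m"], row["fill_volume_mL"],
                row["shaking_rpm"], row["orbit_diameter_m"],
            )
            h = modified_volumetric_power(cond, medium)
            cols["Re"].append(h.reynolds)
            cols["Ne_mod"].append(h.newton_mod)
            cols["P_per_V_W_m3"].append(h.power_per_volume)
            cols["kLa_per_s"].append(h.kla)
            cols["Pva_mW_m2_s"].append(h.pva_milli)
            cols["static"].append(cond.shaking_frequency == 0)
            cols["error"].append("")
        except ValueError as exc:
            for key in ("Re", "Ne_mod", "P_per_V_W_m3", "kLa_per_s", "Pva_mW_m2_s"):
                cols[key].append(np.nan)
            cols["static"].append(False)
            cols["error"].append(str(exc))
    for key, vals in cols.items():
        out[key] = vals
    return out


def _mean_by_condition(records: pd.DataFrame, predictor: str, size_col: str) -> pd.DataFrame:
    """Average replicate sizes per distinct predictor value."""
    return (
        records.groupby(predictor, as_index=False)[size_col]
        .mean()
        .sort_values(predictor, ignore_index=True)
    )


def fit_unimodal(
    records: pd.DataFrame,
    predictor: str = "Pva_mW_m2_s",
    size_col: str = "size_cm2",
    band_fraction: float = 0.5,
    aggregate_replicates: bool = True,
    medium: MediumProperties = WATER_30C,
) -> OptimalRangeFit:
    """Fit the Gaussian-in-log10 unimodal response and derive the optimal band.

    Replicates are averaged per distinct predictor value before fitting
    (``aggregate_replicates=False`` fits raw rows).  The table is annotated
    with the forward model first if the predictor column is absent.
    """
    if predictor not in records.columns:
        records = annotate_pva(records, medium)
    if size_col not in records.columns:
        raise ValueError(f"records lack a {size_col!r} column")
    data = _mean_by_condition(records, predictor, size_col) if aggregate_replicates else records
    model = UnimodalResponseModel(band_fraction=band_fraction)
    model.fit(data[predictor], data[size_col])
    return model.as_range_fit()


def empirical_band(
    records: pd.DataFrame,
    predictor: str = "Pva_mW_m2_s",
    size_col: str = "size_cm2",
    alpha: float = 0.5,
    medium: MediumProperties = WATER_30C,
) -> RegimeBand:
    """Nonparametric optimal band: the predictor span of good conditions.

    A condition is "good" when its replicate-mean size is at least
    ``alpha`` times the best condition's mean size; the band runs from the
    smallest to the largest good predictor value.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if predictor not in records.columns:
        records = annotate_pva(records, medium)
    means = _mean_by_condition(records, predictor, size_col)
    good = means[means[size_col] >= alpha * means[size_col].max()]
    lo, hi = float(good[predictor].min()), float(good[predictor].max())
    if not lo < hi:
        raise ValueError("empirical band degenerate: fewer than two good conditions")
    return RegimeBand(lo, hi)


def compare_parameters(
    records: pd.DataFrame,
    size_col: str = "size_cm2",
    band_fraction: float = 0.5,
    medium: MediumProperties = WATER_30C,
) -> pd.DataFrame:
    """Rank P/V_L, k_La and P_V,A as size predictors by unimodal-fit R^2.

    Returns one row per candidate predictor, sorted by descending goodness.
    With fewer than two distinct flask diameters the candidates are
    confounded (each is a monotone function of n at fixed geometry); the
    result then carries ``confounded = True`` on every row and a warning is
    emitted.
    """
    if "Pva_mW_m2_s" not in records.columns:
        records = annotate_pva(records, medium)
    n_diam = records["flask_inner_diameter_m"].nunique() if "flask_inner_diameter_m" in records.columns else 1
    confounded = n_diam < 2
    if confounded:
        warnings.warn(
            "conditions span a single flask diameter: P/V_L, k_La and P_V,A are confounded",
            stacklevel=2,
        )
    rows = []
    for predictor in ("P_per_V_W_m3", "kLa_per_s", "Pva_mW_m2_s"):
        fit = fit_unimodal(records, predictor=predictor, size_col=size_col,
                           band_fraction=band_fraction, medium=medium)
        rows.append(
            {
                "predictor": predictor,
                "r_squared": fit.goodness,
                "converged": fit.converged,
                "peak_log10": fit.peak_log10_pva,
                "confounded": confounded,
            }
        )
    table = pd.DataFrame(rows).sort_values("r_squared", ascending=False, ignore_index=True)
    return table
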