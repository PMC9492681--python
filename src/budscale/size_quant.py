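"""Apparent material size from flask-bottom photographs.

Macroscopic engineered-living-material pieces settle on the bottom of the
culture flask; a photograph of the flask bottom is segmented into three
classes — background, *scattered* material (small unassociated aggregates)
and *bundled* material (large connected pieces) — and each image is
summarised by a single calibrated size: the mean flat area of the bundled
pieces in the top five percentile of per-piece area.

The two-stage segmentation is deliberately simple and deterministic:

* stage 1: optional Gaussian smoothing of the blue channel followed by a
  global threshold (automatic bimodal Otsu threshold by default) gives the
  foreground mask;
* stage 2: 8-connected components are classified by area — pieces of at
  least ``min_bundle_area_px`` pixels are *bundled*, smaller ones
  *scattered*; components below ``min_object_px`` are discarded as noise.

Pixel areas convert to cm^2 through a linear scale derived from the flask's
known inner diameter and its imaged rim circle (no lens-distortion model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage import filters, measure
from sklearn.base import BaseEstimator

__all__ = [
    "FlaskImage",
    "SegmentationResult",
    "SizeSummary",
    "MaterialSegmenter",
    "extract_blue_channel",
    "segment_material",
    "calibrate_pixels",
    "representative_size",
    "batch_size_measure",
]


@dataclass(frozen=True)
class FlaskImage:
    """A flask-bottom RGB photograph plus the calibration metadata.

    ``calibration_circle`` is (center_row, center_col, radius_px) of the
    flask rim in the image; together with ``flask_inner_diameter_cm`` it
    fixes the pixel->cm scale.
    """

    pixels: np.ndarray
    flask_inner_diameter_cm: float
    calibration_circle: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("pixels must be at least 16x16, 2-D or 3-D (H, W[, C])")
        if not self.flask_inner_diameter_cm > 0:
            raise ValueError("flask_inner_diameter_cm must be > 0")
        if self.calibration_circle is not None:
            r, c, rad = self.calibration_circle
            h, w = px.shape[:2]
            if rad <= 0 or not (0 <= r < h and 0 <= c < w):
                raise ValueError("calibration_circle must lie within image bounds with radius > 0")


@dataclass(frozen=True)
class SegmentationResult:
    """Labelled objects from one image.

    ``label_mask`` holds 0 for background and contiguous labels 1..N for
    objects; ``object_table`` has one row per object with columns
    ``label``, ``object_class`` ("bundled"/"scattered"), ``area_px`` and,
    once calibrated, ``area_cm2``.  ``discarded_px`` counts foreground
    pixels dropped as sub-``min_object_px`` noise.
    """

    label_mask: np.ndarray
    object_table: pd.DataFrame
    discarded_px: int = 0


@dataclass(frozen=True)
class SizeSummary:
    """Representative apparent size of one image: mean of top-5% bundled areas."""

    representative_size_cm2: float
    n_bundled_objects: int
    percentile_threshold_cm2: float
    pixel_scale_cm_per_px: float
    empty: bool = False


def extract_blue_channel(img: Union[FlaskImage, np.ndarray]) -> np.ndarray:
    """Return the blue channel (RGB index 2) of a flask image, dtype preserved.

    Material contrasts best against the flask and background in the blue
    channel, which is the only channel the segmentation uses.  A 2-D input
    is passed through with a warning.
    """
    px = np.asarray(img.pixels if isinstance(img, FlaskImage) else img)
    if px.ndim == 2:
        warnings.warn("single-channel image: using it as-is", stacklevel=2)
        return px
    if px.shape[2] < 3:
        raise ValueError(f"expected >= 3 channels, got {px.shape[2]}")
    return px[:, :, 2]


class MaterialSegmenter(BaseEstimator):
    """Two-stage threshold-and-classify segmenter for flask-bottom images.

    Parameters
    ----------
    sigma : float
        Gaussian smoothing applied to the blue channel before thresholding.
        0 disables smoothing (the default; raise to ~1-2 px for noisy
        photographs).
    threshold : "isodata", "otsu" or float
        Global foreground threshold.  "isodata" (default) is the
        Ridler-Calvard intermeans threshold, which lands mid-gap between
        background and material modes even when the foreground fraction is
        tiny; "otsu" is the between-class-variance threshold; a float is
        used as-is on the (smoothed) intensity scale.
    min_object_px : int
        Components smaller than this are discarded as noise.
    min_bundle_area_px : int
        Components with at least this many pixels are classified *bundled*;
        smaller (surviving) ones are *scattered*.
    """

    def __init__(
        self,
        sigma: float = 0.0,
        threshold: Union[str, float] = "isodata",
        min_object_px: int = 1,
        min_bundle_area_px: int = 100,
    ):
        self.sigma = sigma
        self.threshold = threshold
        self.min_object_px = min_object_px
        self.min_bundle_area_px = min_bundle_area_px

    def _validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if isinstance(self.threshold, str) and self.threshold not in ("isodata", "otsu"):
            raise ValueError(f"unknown threshold method {self.threshold!r}")
        if self.min_object_px < 1 or self.min_bundle_area_px < 1:
            raise ValueError("min_object_px and min_bundle_area_px must be >= 1")

    def segment(self, blue: np.ndarray) -> SegmentationResult:
        """Segment a 2-D intensity array into labelled scattered/bundled objects."""
        self._validate()
        blue = np.asarray(blue)
        if blue.ndim != 2:
            raise ValueError("segment expects a 2-D intensity array")
        img = blue.astype(float)
        if self.sigma > 0:
            img = filters.gaussian(img, sigma=self.sigma, preserve_range=True)

        if isinstance(self.threshold, str):
            if img.min() == img.max():  # flat image: no bimodality, no foreground
                return self._empty_result(blue.shape)
            method = filters.threshold_isodata if self.threshold == "isodata" else filters.threshold_otsu
            thr = method(img)
        else:
            thr = float(self.threshold)
        fg = img > thr
        if not fg.any():
            return self._empty_result(blue.shape)

        labels = measure.label(fg, connectivity=2)  # 8-connectivity
        areas = np.bincount(labels.ravel())[1:]  # per-label pixel counts
        keep = np.flatnonzero(areas >= self.min_object_px) + 1
        discarded = int(areas[areas < self.min_object_px].sum())

        # relabel contiguously 1..N in original label order
        remap = np.zeros(labels.max() + 1, dtype=labels.dtype)
        remap[keep] = np.arange(1, keep.size + 1)
        label_mask = remap[labels]
        kept_areas = areas[keep - 1]
        classes = np.where(kept_areas >= self.min_bundle_area_px, "bundled", "scattered")
        table = pd.DataFrame(
            {
                "label": np.arange(1, keep.size + 1),
                "object_class": classes,
                "area_px": kept_areas.astype(int),
            }
        )
        return SegmentationResult(label_mask, table, discarded)

    @staticmethod
    def _empty_result(shape: tuple[int, int]) -> SegmentationResult:
        table = pd.DataFrame({"label": pd.Series(dtype=int),
                              "object_class": pd.Series(dtype=object),
                              "area_px": pd.Series(dtype=int)})
        return SegmentationResult(np.zeros(shape, dtype=np.int32), table, 0)


def segment_material(blue: np.ndarray, params: Optional[MaterialSegmenter] = None, **kwargs) -> SegmentationResult:
    """Functional wrapper over :class:`MaterialSegmenter`.

    Keyword arguments override the segmenter defaults (``sigma``,
    ``threshold``, ``min_object_px``, ``min_bundle_area_px``).
    """
    seg = params if params is not None else MaterialSegmenter(**kwargs)
    return seg.segment(blue)


def calibrate_pixels(img: FlaskImage, explicit_scale_cm_per_px: Optional[float] = None) -> float:
    """Pixel->cm linear scale from the flask rim circle.

    scale = flask inner diameter / rim diameter in pixels; areas convert by
    scale^2.  An explicit scale bypasses the circle (and wins if both are
    given).
    """
    if explicit_scale_cm_per_px is not None:
        if not explicit_scale_cm_per_px > 0:
            raise ValueError("explicit scale must be > 0")
        return explicit_scale_cm_per_px
    if img.calibration_circle is None:
        raise ValueError("no calibration circle and no explicit scale: cannot calibrate")
    radius_px = img.calibration_circle[2]
    return img.flask_inner_diameter_cm / (2.0 * radius_px)


def representative_size(
    seg: SegmentationResult, pixel_scale_cm_per_px: float, percentile: float = 95.0
) -> SizeSummary:
    """Mean of the top-(100-percentile)% bundled-piece areas, in cm^2.

    The per-image representative size: compute the ``percentile``-th
    percentile (linear interpolation) of bundled-object areas, then average
    every object whose area is >= that threshold.  With no bundled objects
    the summary is 0 with ``empty=True``.
    """
    if not pixel_scale_cm_per_px > 0:
        raise ValueError("pixel_scale_cm_per_px must be > 0")
    scale2 = pixel_scale_cm_per_px**2
    bundled = seg.object_table.loc[seg.object_table["object_class"] == "bundled", "area_px"]
    if bundled.empty:
        return SizeSummary(0.0, 0, 0.0, pixel_scale_cm_per_px, empty=True)
    areas_cm2 = bundled.to_numpy(dtype=float) * scale2
    thr = float(np.percentile(areas_cm2, percentile))
    top = areas_cm2[areas_cm2 >= thr]
    return SizeSummary(float(top.mean()), int(areas_cm2.size), thr, pixel_scale_cm_per_px)


def batch_size_measure(
    images: Sequence[FlaskImage],
    params: Optional[MaterialSegmenter] = None,
    groups: Optional[Sequence[str]] = None,
    percentile: float = 95.0,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Run the full size pipeline on a batch of images.

    Returns a per-image table and, when ``groups`` is given, a per-group
    table of mean representative sizes.  A failing image is recorded in its
    row's ``error`` column and the batch continues.
    """
    if len(images) == 0:
        raise ValueError("batch_size_measure needs at least one image")
    if groups is not None and len(groups) != len(images):
        raise ValueError("groups must match images in length")
    seg = params if params is not None else MaterialSegmenter()
    rows = []
    for i, img in enumerate(images):
        row: dict = {"image_index": i, "group": groups[i] if groups is not None else ""}
        try:
            scale = calibrate_pixels(img)
            result = seg.segment(extract_blue_channel(img))
            summary = representative_size(result, scale, percentile=percentile)
            row.update(
                representative_size_cm2=summary.representative_size_cm2,
                n_bundled_objects=summary.n_bundled_objects,
                percentile_threshold_cm2=summary.percentile_threshold_cm2,
                pixel_scale_cm_per_px=summary.pixel_scale_cm_per_px,
                empty=summary.empty,
                error="",
            )
        except (ValueError, RuntimeError) as exc:  # record and continue
            row.update(
                representative_size_cm2=np.nan, n_bundled_objects=0,
                percentile_threshold_cm2=np.nan, pixel_scale_cm_per_px=np.nan,
                empty=True, error=str(exc),
            )
        rows.append(row)
    per_image = pd.DataFrame(rows)
    per_group = None
    if groups is not None:
        ok = per_image[per_image["error"] == ""]
        per_group = (
            ok.groupby("group", as_index=False)["representative_size_cm2"]
            .agg(mean_size_cm2="mean", n_images="size")
        )
    return per_image, per_group
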