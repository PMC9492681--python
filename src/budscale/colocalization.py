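"""Mask-overlap statistic for matrix-composition staining.

Two-channel fluorescence fields — a cell channel (e.g. mKate2-labelled
bacteria) and a stain channel (matrix protein stain such as SpyCatcher-GFP
or Congo Red, or a lipid stain such as DiO) — are reduced to binary masks,
and the composition question "is the cell-free matrix stained?" becomes a
pixel count:

    overlap % = 100 * |stain AND cellfree| / |cellfree|,

where the cell-free region is the material region of interest (ROI) minus
the cell mask, and the ROI is the morphological closing of the union of
both masks.  A protein stain of the matrix yields a high percentage, a
lipid stain of a lipid-free matrix a near-zero one.  This is a binary-mask
statistic; it is not a Pearson/Manders intensity colocalization
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage import filters, morphology
from sklearn.base import BaseEstimator

__all__ = [
    "TwoChannelField",
    "OverlapResult",
    "OverlapAnalyzer",
    "make_masks",
    "overlap_percentage",
    "batch_overlap",
    "summarize_overlap",
]


@dataclass(frozen=True)
class TwoChannelField:
    """Paired cell/stain intensity images of equal shape."""

    cell_channel: np.ndarray
    stain_channel: np.ndarray
    channel_names: tuple[str, str] = ("cells", "stain")

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell_channel)
        stain = np.asarray(self.stain_channel)
        if cell.shape != stain.shape or cell.ndim != 2:
            raise ValueError("cell and stain channels must be equal-shaped 2-D arrays")
        if cell.min() < 0 or stain.min() < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of the stain with the cell-free matrix region, one image.

    ``defined`` is False when the cell-free region is empty (cells fill the
    ROI); ``overlap_percent`` is NaN in that case.
    """

    overlap_percent: float
    cellfree_px: int
    stained_px: int
    intersection_px: int
    roi_px: int
    defined: bool = True


class OverlapAnalyzer(BaseEstimator):
    """Threshold channels, define the ROI, and compute the overlap statistic.

    Parameters
    ----------
    cell_threshold, stain_threshold : "otsu", "isodata" or float
        Per-channel global thresholds; "otsu"/"isodata" pick an automatic
        bimodal value, a float is applied as-is (useful for reproducible
        pipelines and for stains that are genuinely absent, where automatic
        thresholding is meaningless).
    closing_radius : int
        Radius (px) of the disk structuring element used to close the union
        mask into the material ROI.
    denominator : "cellfree" or "roi"
        Normalisation of the overlap count.  The default expresses the
        stained fraction of the *cell-free* matrix; "roi" normalises by the
        whole material region instead.
    """

    def __init__(
        self,
        cell_threshold: Union[str, float] = "otsu",
        stain_threshold: Union[str, float] = "otsu",
        closing_radius: int = 5,
        denominator: str = "cellfree",
    ):
        self.cell_threshold = cell_threshold
        self.stain_threshold = stain_threshold
        self.closing_radius = closing_radius
        self.denominator = denominator

    def _threshold(self, channel: np.ndarray, spec: Union[str, float]) -> np.ndarray:
        img = np.asarray(channel, dtype=float)
        if isinstance(spec, str):
            if spec not in ("otsu", "isodata"):
                raise ValueError(f"unknown threshold method {spec!r}")
            if img.min() == img.max():
                return np.zeros(img.shape, dtype=bool)
            method = filters.threshold_otsu if spec == "otsu" else filters.threshold_isodata
            return img > method(img)
        return img > float(spec)

    def make_masks(self, field: TwoChannelField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (cell_mask, stain_mask, roi_mask) for one field.

        ROI = morphological closing of cell OR stain; raises if the ROI is
        empty (no material in frame).
        """
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.denominator not in ("cellfree", "roi"):
            raise ValueError(f"unknown denominator {self.denominator!r}")
        cell = self._threshold(field.cell_channel, self.cell_threshold)
        stain = self._threshold(field.stain_channel, self.stain_threshold)
        union = cell | stain
        if self.closing_radius > 0:
            roi = morphology.closing(union, morphology.disk(self.closing_radius))
        else:
            roi = union
        if not roi.any():
            raise ValueError("empty ROI: no material detected in either channel")
        return cell, stain, roi

    def overlap(self, field: TwoChannelField) -> OverlapResult:
        """Full pipeline on one field: masks then overlap percentage."""
        cell, stain, roi = self.make_masks(field)
        return overlap_percentage(cell, stain, roi, denominator=self.denominator)


def make_masks(
    field: TwoChannelField, params: Optional[OverlapAnalyzer] = None, **kwargs
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Functional wrapper over :meth:`OverlapAnalyzer.make_masks`."""
    analyzer = params if params is not None else OverlapAnalyzer(**kwargs)
    return analyzer.make_masks(field)


def overlap_percentage(
    cell_mask: np.ndarray,
    stain_mask: np.ndarray,
    roi_mask: np.ndarray,
    denominator: str = "cellfree",
) -> OverlapResult:
    """Percentage of the cell-free ROI that is stained.

    With ``denominator="cellfree"`` (default):
    ``100 * |stain AND (roi \\ cell)| / |roi \\ cell|``.  An empty cell-free
    region yields an undefined result (``defined=False``), not a number.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    stain = np.asarray(stain_mask, dtype=bool)
    roi = np.asarray(roi_mask, dtype=bool)
    if not (cell.shape == stain.shape == roi.shape):
        raise ValueError("masks must be equal-shaped")
    cellfree = roi & ~cell
    inter = stain & cellfree
    n_cellfree = int(cellfree.sum())
    n_inter = int(inter.sum())
    n_roi = int(roi.sum())
    n_stain = int((stain & roi).sum())
    if denominator == "cellfree":
        denom = n_cellfree
    elif denominator == "roi":
        denom = n_roi
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return OverlapResult(float("nan"), n_cellfree, n_stain, n_inter, n_roi, defined=False)
    return OverlapResult(100.0 * n_inter / denom, n_cellfree, n_stain, n_inter, n_roi)


def batch_overlap(
    fields: Sequence[TwoChannelField],
    groups: Optional[Sequence[str]] = None,
    params: Optional[OverlapAnalyzer] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image overlap plus per-group distribution summaries.

    The group summary reports the descriptors shown on a box plot of such
    data: mean, sample standard deviation (ddof=1; NaN for a single image),
    median and the 25-75% interquartile bounds.  Groups with no defined
    image are dropped with a warning.
    """
    if len(fields) == 0:
        raise ValueError("batch_overlap needs at least one field")
    if groups is None:
        groups = [""] * len(fields)
    if len(groups) != len(fields):
        raise ValueError("groups must match fields in length")
    analyzer = params if params is not None else OverlapAnalyzer()
    rows = []
    for i, (field, grp) in enumerate(zip(fields, groups)):
        res = analyzer.overlap(field)
        rows.append(
            {
                "image_index": i,
                "group": grp,
                "overlap_percent": res.overlap_percent,
                "cellfree_px": res.cellfree_px,
                "stained_px": res.stained_px,
                "intersection_px": res.intersection_px,
                "roi_px": res.roi_px,
                "defined": res.defined,
            }
        )
    per_image = pd.DataFrame(rows)
    return per_image, summarize_overlap(per_image)


def summarize_overlap(per_image: pd.DataFrame) -> pd.DataFrame:
    """Box-plot descriptors per group from a per-image overlap table.

    Needs ``group``, ``overlap_percent`` and ``defined`` columns (the
    latter defaults to all-True if absent).  Reports mean, sample SD
    (ddof=1, NaN for n=1), median and the 25/75% quartiles; groups without
    a single defined value are omitted with a warning.
    """
    import warnings

    if "defined" not in per_image.columns:
        per_image = per_image.assign(defined=True)
    summaries = []
    for grp, sub in per_image.groupby("group"):
        vals = sub.loc[sub["defined"], "overlap_percent"].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {grp!r} has no defined overlap values; omitted", stacklevel=2)
            continue
        summaries.append(
            {
                "group": grp,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(summaries)
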