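"""Unit-tagged CSV and image I/O.

Every tabular interface declares its units in the column names
(``_m``, ``_cm``, ``_mL``, ``_rpm``); values are converted to SI exactly
once, at the boundary.  The canonical condition table is::

    label, flask_inner_diameter_m, orbit_diameter_m, fill_volume_mL, shaking_rpm

and annotated outputs append ``Re, Ne_mod, P_per_V_W_m3, kLa_per_s,
Pva_mW_m2_s, regime``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .hydrodynamics import CultureConditions
from .size_quant import FlaskImage

__all__ = [
    "CONDITIONS_COLUMNS",
    "read_conditions_frame",
    "read_conditions_csv",
    "read_image_manifest",
    "load_flask_image",
]

CONDITIONS_COLUMNS = (
    "label",
    "flask_inner_diameter_m",
    "orbit_diameter_m",
    "fill_volume_mL",
    "shaking_rpm",
)

MANIFEST_COLUMNS = (
    "path",
    "flask_inner_diameter_cm",
    "circle_row",
    "circle_col",
    "circle_radius_px",
    "group",
)


def read_conditions_frame(path: Union[str, Path]) -> pd.DataFrame:
    """Read a conditions CSV, validating the header and every row.

    Rows with a missing or non-positive diameter or volume, or a negative
    shaking speed, are rejected with their (1-based, header-exclusive) row
    number.
    """
    df = pd.read_csv(path)
    missing = [c for c in CONDITIONS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"conditions CSV {path} missing columns: {', '.join(missing)}")
    problems = []
    for i, row in df.iterrows():
        if not np.isfinite(row["flask_inner_diameter_m"]) or row["flask_inner_diameter_m"] <= 0:
            problems.append(f"row {i + 1}: flask_inner_diameter_m must be > 0")
        if not np.isfinite(row["orbit_diameter_m"]) or row["orbit_diameter_m"] <= 0:
            problems.append(f"row {i + 1}: orbit_diameter_m must be > 0")
        if not np.isfinite(row["fill_volume_mL"]) or row["fill_volume_mL"] <= 0:
            problems.append(f"row {i + 1}: fill_volume_mL must be > 0")
        if not np.isfinite(row["shaking_rpm"]) or row["shaking_rpm"] < 0:
            problems.append(f"row {i + 1}: shaking_rpm must be >= 0")
    if problems:
        raise ValueError(f"invalid rows in {path}: " + "; ".join(problems))
    return df


def read_conditions_csv(path: Union[str, Path]) -> list[CultureConditions]:
    """Read a conditions CSV into :class:`CultureConditions` (SI units)."""
    df = read_conditions_frame(path)
    return [
        CultureConditions.from_practical(
            row["flask_inner_diameter_m"],
            row["fill_volume_mL"],
            row["shaking_rpm"],
            row["orbit_diameter_m"],
            str(row["label"]),
        )
        for _, row in df.iterrows()
    ]


def read_image_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a flask-image batch manifest CSV (paths relative to the manifest)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"image manifest {path} missing columns: {', '.join(missing)}")
    base = Path(path).parent
    df = df.copy()
    df["path"] = [str((base / p).resolve()) if not Path(p).is_absolute() else p for p in df["path"]]
    return df


def load_flask_image(
    path: Union[str, Path],
    flask_inner_diameter_cm: float,
    circle_row: float,
    circle_col: float,
    circle_radius_px: float,
) -> FlaskImage:
    """Load a PNG/TIFF flask photograph with its calibration metadata."""
    pixels = np.asarray(iio.imread(path))
    return FlaskImage(pixels, flask_inner_diameter_cm, (circle_row, circle_col, circle_radius_px))
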