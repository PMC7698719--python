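"""Iodine-concentration calibration: fit a line C_I = slope * E + intercept.

One calibration curve per imaging protocol (SE / DE / DCE); the fit is an
ordinary least-squares regression of concentration on enhancement, with the
coefficient of determination reported so degenerate calibrations can be
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .image import Volume

PROTOCOLS = ("SE", "DE", "DCE")

#: minimum R^2 below which a calibration is flagged as unreliable
R2_THRESHOLD = 0.9


@dataclass
class CalibrationCurve:
    """Linear map from enhancement (HU) to iodine concentration (mg I/mL)."""

    slope: float      # (mg I/mL) per HU
    intercept: float  # mg I/mL
    r2: float
    protocol: str

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")

    @property
    def ok(self) -> bool:
        """True when the fit is usable (positive slope, R^2 above threshold)."""
        return self.slope > 0 and self.r2 >= R2_THRESHOLD


def fit_calibration(points: Sequence[tuple[float, float]], protocol: str = "SE") -> CalibrationCurve:
    """OLS line of concentration on enhancement from phantom VOI measurements.

    Parameters
    ----------
    points:
        (enhancement_HU, concentration_mg_I_per_mL) pairs from the calibration
        phantom VOIs.  At least 3 points with at least 3 distinct
        concentrations are required; duplicated points count twice (no
        deduplication or reweighting).
    protocol:
        Which acquisition protocol this curve calibrates.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (E, C) pairs")
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 calibration points, got {pts.shape[0]}")
    e, c = pts[:, 0], pts[:, 1]
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations for a stable fit")
    if np.ptp(e) == 0:
        raise ValueError("all enhancement values identical: degenerate calibration input")
    slope, intercept = np.polyfit(e, c, 1)
    resid = c - (slope * e + intercept)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return CalibrationCurve(float(slope), float(intercept), min(r2, 1.0), protocol)


def apply_calibration(e: Volume, cal: CalibrationCurve, floor: float | None = None) -> Volume:
    """Voxelwise C_I = slope * E + intercept on an enhancement image.

    Negative concentrations are retained by default so VOI means stay
    unbiased; pass ``floor`` (e.g. 0.0) to clamp.
    """
    if e.kind != "enhancement_hu":
        raise ValueError(f"apply_calibration expects an enhancement_hu volume, got {e.kind!r}")
    if e.protocol is not None and e.protocol != cal.protocol:
        raise ValueError(
            f"calibration protocol {cal.protocol!r} does not match image protocol {e.protocol!r}"
        )
    if cal.slope <= 0:
        raise ValueError(f"calibration slope must be > 0 to convert to concentration, got {cal.slope}")
    ci = cal.slope * e.data + cal.intercept
    if floor is not None:
        ci = np.maximum(ci, floor)
    return Volume(ci, e.spacing, "iodine_mg_ml", frame=e.frame, protocol=e.protocol)


def save_calibration(cal: CalibrationCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"slope_mg_ml_per_hu": cal.slope, "intercept_mg_ml": cal.intercept,
             "r2": cal.r2, "protocol": cal.protocol}, fh)


def load_calibration(path: str | Path) -> CalibrationCurve:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return CalibrationCurve(d["slope_mg_ml_per_hu"], d["intercept_mg_ml"], d["r2"], d["protocol"])
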