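"""Patlak analysis of dynamic contrast-enhanced planar series.

The tracer model is an irreversible two-compartment system: contrast leaves
the intravascular space at rate K^trans and accumulates in the
extravascular-interstitial space, so

    C_tissue(t) / C_AIF(t) = Ktrans * int_0^t C_AIF(u) du / C_AIF(t) + rBV

is linear in x(t) = int_0^t C_AIF / C_AIF(t) with slope K^trans and intercept
rBV.  The integral is a cumulative trapezoid from t = 0, shared exactly
between the forward model (phantom generation) and the inversion so that
noise-free round trips are exact.  Regression is performed in seconds; the
slope is reported in min^-1 and the intercept as a percentage.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .image import PlanarSeries

CURVE_LABELS = ("lv", "muscle", "tumor")


@dataclass(frozen=True)
class EllipseROI:
    """Axis-aligned 2-D ellipse on a planar frame, world units (mm)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def mask(self, shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
        c = np.asarray(self.center, dtype=np.float64)
        a = np.asarray(self.semi_axes, dtype=np.float64)
        if np.any(a <= 0):
            raise ValueError("ellipse semi-axes must be > 0")
        ys = ((np.arange(shape[0]) * spacing[0] - c[0]) / a[0]) ** 2
        xs = ((np.arange(shape[1]) * spacing[1] - c[1]) / a[1]) ** 2
        return ys[:, None] + xs[None, :] <= 1.0


@dataclass
class TimeConcentrationCurve:
    """Time-C_I samples for one region; label ``lv`` marks the AIF."""

    times_s: np.ndarray
    ci_mg_ml: np.ndarray
    label: str
    smoothing: str | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.ci_mg_ml = np.asarray(self.ci_mg_ml, dtype=np.float64)
        if self.times_s.shape != self.ci_mg_ml.shape or self.times_s.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class PatlakWindow:
    """Regression window [t1, t2] in seconds; default 30-80 s."""

    t1_s: float = 30.0
    t2_s: float = 80.0

    def __post_init__(self) -> None:
        if not self.t1_s < self.t2_s:
            raise ValueError(f"require t1 < t2, got [{self.t1_s}, {self.t2_s}]")


@dataclass
class PatlakPoints:
    """Transformed (x, y) samples with their acquisition times."""

    times_s: np.ndarray
    x_s: np.ndarray          # normalized integrated AIF exposure, seconds
    y: np.ndarray            # tissue/AIF concentration ratio, dimensionless


@dataclass
class KineticFit:
    ktrans_per_min: float
    rbv_percent: float
    window: PatlakWindow
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("kinetic fit requires at least 3 points")
        if not np.isfinite(self.rbv_percent):
            raise ValueError("rBV must be finite")


def extract_curve(series: PlanarSeries, roi: EllipseROI, label: str,
                  thickness_mm: float | None = None) -> TimeConcentrationCurve:
    """Per-frame ROI mean over a planar series.

    ``thickness_mm`` divides areal-iodine frames (mg I/mL * mm) by the mean
    chord thickness of the imaged region so the curve is in mg I/mL; leave it
    None for series already in concentration units.
    """
    m = roi.mask(series.frames.shape[1:], series.pixel_spacing)
    if not m.any():
        raise ValueError("ROI does not intersect the frame")
    vals = series.frames[:, m].mean(axis=1)
    if thickness_mm is not None:
        if thickness_mm <= 0:
            raise ValueError("thickness_mm must be > 0")
        vals = vals / thickness_mm
    return TimeConcentrationCurve(series.times_s.copy(), vals, label)


def smooth_curve(curve: TimeConcentrationCurve, window_s: float) -> TimeConcentrationCurve:
    """Centered moving average with truncated windows at the edges."""
    dt = float(np.median(np.diff(curve.times_s)))
    half = int(round(window_s / dt)) // 2
    n = len(curve)
    if 2 * half + 1 > n:
        raise ValueError(f"smoothing window {window_s}s exceeds curve length")
    if half == 0:
        return replace(curve, smoothing="moving_average:1")
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = curve.ci_mg_ml[lo:hi].mean()
    return TimeConcentrationCurve(curve.times_s.copy(), out, curve.label,
                                  smoothing=f"moving_average:{2 * half + 1}")


def patlak_forward(aif: TimeConcentrationCurve, ktrans_per_min: float,
                   rbv_fraction: float, label: str = "tumor") -> TimeConcentrationCurve:
    """Forward two-compartment model on the AIF sampling grid.

    C_tissue(t) = (Ktrans/60) * cumtrapz(C_AIF)(t) + rBV * C_AIF(t), with
    Ktrans in min^-1 and rBV a dimensionless fraction.
    """
    if ktrans_per_min < 0:
        raise ValueError("Ktrans must be >= 0")
    if not 0 <= rbv_fraction <= 1:
        raise ValueError("rBV fraction must lie in [0, 1]")
    integral = cumulative_trapezoid(aif.ci_mg_ml, aif.times_s, initial=0.0)
    ct = (ktrans_per_min / 60.0) * integral + rbv_fraction * aif.ci_mg_ml
    return TimeConcentrationCurve(aif.times_s.copy(), ct, label)


def patlak_transform(tissue: TimeConcentrationCurve, aif: TimeConcentrationCurve,
                     window: PatlakWindow | None = None) -> PatlakPoints:
    """Linearizing transform: x = cumtrapz(AIF)/AIF, y = tissue/AIF.

    The AIF integral always starts at t = 0 on the full shared grid; when a
    window is given only in-window samples are evaluated (the AIF may be zero
    before the window, e.g. at the foot of an infusion ramp).
    """
    if tissue.times_s.shape != aif.times_s.shape or not np.allclose(tissue.times_s, aif.times_s):
        raise ValueError("tissue and AIF curves must share one time grid")
    integral = cumulative_trapezoid(aif.ci_mg_ml, aif.times_s, initial=0.0)
    t = aif.times_s
    sel = np.ones_like(t, dtype=bool) if window is None else (
        (t >= window.t1_s) & (t <= window.t2_s))
    bad = sel & (aif.ci_mg_ml <= 0)
    if bad.any():
        raise ValueError(f"AIF is not positive at t = {t[bad][0]:g} s")
    return PatlakPoints(t[sel], integral[sel] / aif.ci_mg_ml[sel],
                        tissue.ci_mg_ml[sel] / aif.ci_mg_ml[sel])


def patlak_fit(points: PatlakPoints, window: PatlakWindow | None = None) -> KineticFit:
    """OLS of y on x restricted to the window; reports Ktrans (min^-1), rBV (%).

    The slope is converted from s^-1 to min^-1 (x is in seconds) and the
    intercept, a vascular volume fraction, is multiplied by 100.
    """
    window = window or PatlakWindow()
    sel = (points.times_s >= window.t1_s) & (points.times_s <= window.t2_s)
    x, y = points.x_s[sel], points.y[sel]
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"need >= 3 points in [{window.t1_s}, {window.t2_s}] s, got {n}")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - float(np.sum(resid**2)) / ss_tot))
    return KineticFit(float(slope) * 60.0, float(intercept) * 100.0, window, r2, n)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_curve(curve: TimeConcentrationCurve, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_s", "ci_mg_ml", "label"])
        for t, c in zip(curve.times_s, curve.ci_mg_ml):
            w.writerow([float(t), float(c), curve.label])


def load_curve(path: str | Path) -> TimeConcentrationCurve:
    times, vals, label = [], [], "tumor"
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            times.append(float(row["t_s"]))
            vals.append(float(row["ci_mg_ml"]))
            label = row.get("label", label)
    return TimeConcentrationCurve(np.asarray(times), np.asarray(vals), label)


def save_fit(fit: KineticFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"ktrans_per_min": fit.ktrans_per_min, "rbv_percent": fit.rbv_percent,
                   "r2": fit.r2, "t1_s": fit.window.t1_s, "t2_s": fit.window.t2_s,
                   "n": fit.n}, fh, indent=2)
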