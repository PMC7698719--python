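"""Ellipsoidal VOIs, tumor-region derivation and per-region quantification.

A voxel belongs to an ellipsoid VOI iff its center satisfies
``sum(((x - c) / a)^2) <= 1`` in world coordinates (index * spacing).
The central tumor ("core") is the tumor ellipsoid with halved semi-axes; the
tumor periphery is quantified from four small VOIs placed inside the tumor
but outside the core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .image import Volume

VOI_LABELS = frozenset(
    {"aorta", "ivc", "kidney", "liver", "spleen", "muscle", "tumor", "core",
     "periphery_1", "periphery_2", "periphery_3", "periphery_4", "lv", "custom"}
)


class PeripheryPlacementError(ValueError):
    """Raised when the default periphery placement is geometrically infeasible."""


@dataclass(frozen=True)
class EllipsoidVOI:
    """Axis-aligned ellipsoid in world coordinates (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", tuple(float(a) for a in self.semi_axes))
        if len(self.center) != 3 or len(self.semi_axes) != 3:
            raise ValueError("center and semi_axes must be 3-vectors")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be > 0, got {self.semi_axes}")
        if self.label not in VOI_LABELS:
            raise ValueError(f"unknown VOI label {self.label!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test for world points, shape (..., 3)."""
        pts = np.asarray(points, dtype=np.float64)
        q = ((pts - np.asarray(self.center)) / np.asarray(self.semi_axes)) ** 2
        return q.sum(axis=-1) <= 1.0

    def mask(self, shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
        """Boolean voxel mask on a grid (voxel centers at index * spacing)."""
        c = np.asarray(self.center)
        a = np.asarray(self.semi_axes)
        sp = np.asarray(spacing, dtype=np.float64)
        axes = [((np.arange(n) * s - ci) / ai) ** 2
                for n, s, ci, ai in zip(shape, sp, c, a)]
        q = (axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :])
        return q <= 1.0

    def surface_points(self, n: int = 500) -> np.ndarray:
        """Deterministic quasi-uniform sample of the ellipsoid surface."""
        i = np.arange(n, dtype=np.float64) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        unit = np.stack([np.sin(phi) * np.cos(theta),
                         np.sin(phi) * np.sin(theta),
                         np.cos(phi)], axis=1)
        return unit * np.asarray(self.semi_axes) + np.asarray(self.center)


@dataclass
class RegionStats:
    """Mean/SD of one sampled VOI; ``kind`` records the sampled value kind."""

    label: str
    n_voxels: int
    mean: float
    sd: float
    kind: str

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("RegionStats requires n_voxels >= 1")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def derive_core(tumor: EllipsoidVOI) -> EllipsoidVOI:
    """Central tumor: same center, semi-axes halved, label ``core``.

    The label precondition guards accidental double application; composing on
    a core-labelled VOI is possible by relabelling explicitly.
    """
    if tumor.label != "tumor":
        raise ValueError(f"derive_core expects a 'tumor' VOI, got {tumor.label!r}")
    return EllipsoidVOI(tumor.center, tuple(a / 2 for a in tumor.semi_axes), "core")


def derive_periphery(tumor: EllipsoidVOI, core: EllipsoidVOI,
                     offset_frac: float = 0.75, scale: float = 0.2,
                     n_check: int = 1000) -> list[EllipsoidVOI]:
    """Four peripheral VOIs inside the tumor and outside the core.

    The VOIs are centered at +/- ``offset_frac`` of the tumor semi-axis along
    x and y, each with semi-axes ``scale`` times the tumor's.  Placement is
    verified geometrically by sampling each VOI surface: every sampled point
    must lie inside the tumor and outside the core, and the VOIs must be
    pairwise disjoint.
    """
    c = np.asarray(tumor.center)
    a = np.asarray(tumor.semi_axes)
    sub_axes = tuple(scale * a)
    offsets = [np.array([offset_frac * a[0], 0, 0]),
               np.array([-offset_frac * a[0], 0, 0]),
               np.array([0, offset_frac * a[1], 0]),
               np.array([0, -offset_frac * a[1], 0])]
    vois = [EllipsoidVOI(tuple(c + off), sub_axes, f"periphery_{i + 1}")
            for i, off in enumerate(offsets)]

    for voi in vois:
        pts = voi.surface_points(n_check)
        if not tumor.contains(pts).all():
            raise PeripheryPlacementError(
                f"{voi.label} extends outside the tumor ellipsoid "
                f"(offset_frac={offset_frac}, scale={scale})")
        if core.contains(pts).any() or core.contains(np.asarray(voi.center)):
            raise PeripheryPlacementError(
                f"{voi.label} intersects the core ellipsoid "
                f"(offset_frac={offset_frac}, scale={scale})")
    for i, vi in enumerate(vois):
        for vj in vois[i + 1:]:
            # axis-aligned equal ellipsoids: disjoint if center gap exceeds
            # the joint extent along every axis where they could overlap
            if vj.contains(vi.surface_points(n_check)).any():
                raise PeripheryPlacementError(f"{vi.label} overlaps {vj.label}")
    return vois


def sample_voi(vol: Volume, voi: EllipsoidVOI) -> RegionStats:
    """Mean/SD over voxels whose centers fall inside the VOI.

    Voxels outside the volume bounds are simply not part of the grid, so a
    VOI that straddles the boundary is truncated; ``n_voxels`` reflects that.
    Sample SD (ddof=1) is reported for n >= 2, 0 for a single voxel.
    """
    m = voi.mask(vol.shape, vol.spacing)
    n = int(m.sum())
    if n == 0:
        raise ValueError(f"VOI {voi.label!r} does not intersect the volume")
    vals = vol.data[m]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RegionStats(voi.label, n, float(vals.mean()), sd, vol.kind)


def sample_pooled(vol: Volume, vois: Iterable[EllipsoidVOI],
                  label: str = "periphery", mean_of_means: bool = False) -> RegionStats:
    """Aggregate several VOIs into one region statistic.

    Pools voxels by default (union, duplicates not double-counted); the
    mean-of-means alternative averages per-VOI means and is provided for
    sensitivity checks.
    """
    vois = list(vois)
    if not vois:
        raise ValueError("no VOIs to pool")
    if mean_of_means:
        stats = [sample_voi(vol, v) for v in vois]
        means = np.array([s.mean for s in stats])
        return RegionStats(label, sum(s.n_voxels for s in stats),
                           float(means.mean()), float(means.std(ddof=1)) if len(means) > 1 else 0.0,
                           vol.kind)
    m = np.zeros(vol.shape, dtype=bool)
    for v in vois:
        m |= v.mask(vol.shape, vol.spacing)
    n = int(m.sum())
    if n == 0:
        raise ValueError("pooled VOIs do not intersect the volume")
    vals = vol.data[m]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RegionStats(label, n, float(vals.mean()), sd, vol.kind)


def rbv_from_ci(tissue: RegionStats, aorta: RegionStats) -> RegionStats:
    """Relative blood volume: rBV% = 100 * C_I,tissue / C_I,aorta.

    SD is propagated with the first-order ratio rule
    ``sd = rBV * sqrt((sd_t/m_t)^2 + (sd_a/m_a)^2)`` (zero when the tissue
    mean is zero).
    """
    for s in (tissue, aorta):
        if s.kind != "iodine_mg_ml":
            raise ValueError(f"rbv_from_ci expects iodine_mg_ml stats, got {s.kind!r} for {s.label}")
    if aorta.mean <= 0:
        raise ValueError(f"aorta C_I mean must be > 0 (got {aorta.mean}): AIF invalid")
    rbv = 100.0 * tissue.mean / aorta.mean
    if tissue.mean != 0:
        sd = abs(rbv) * np.sqrt((tissue.sd / tissue.mean) ** 2 + (aorta.sd / aorta.mean) ** 2)
    else:
        sd = 0.0
    return RegionStats(tissue.label, tissue.n_voxels, rbv, float(sd), "rbv_percent")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_UNITS = {"hu": "HU", "enhancement_hu": "HU", "iodine_mg_ml": "mg I/mL",
          "rbv_percent": "%", "attenuation_mu": "1/mm"}


def quant_table(rows: Iterable[tuple[str, str, RegionStats]]) -> pd.DataFrame:
    """Long-format table of (protocol, animal, RegionStats) rows."""
    recs = [{"protocol": protocol, "animal": animal, "region": s.label,
             "n_voxels": s.n_voxels, "mean": s.mean, "sd": s.sd,
             "units": _UNITS.get(s.kind, s.kind)}
            for protocol, animal, s in rows]
    return pd.DataFrame.from_records(
        recs, columns=["protocol", "animal", "region", "n_voxels", "mean", "sd", "units"])


def aggregate_animals(table: pd.DataFrame) -> pd.DataFrame:
    """Across-animal summary as mean +/- standard error of the mean."""
    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    g = table.groupby(["protocol", "region", "units"])["mean"]
    out = g.agg(mean="mean", sem=_sem, n="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------

def save_vois(vois: Iterable[EllipsoidVOI], path: str | Path) -> None:
    data = [{"label": v.label, "center_mm": list(v.center),
             "semi_axes_mm": list(v.semi_axes)} for v in vois]
    with open(path, "w") as fh:
        yaml.safe_dump({"vois": data}, fh)


def load_vois(path: str | Path) -> list[EllipsoidVOI]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [EllipsoidVOI(tuple(d["center_mm"]), tuple(d["semi_axes_mm"]), d["label"])
            for d in data["vois"]]
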