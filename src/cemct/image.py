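"""Image model, I/O, HU calibration and subtraction.

The central data structure is :class:`Volume`, a 3-D scalar image tagged with
voxel spacing (mm), a frame-of-reference id and a value kind.  Value kinds move
through the pipeline in one direction only::

    attenuation_mu --hu_calibrate--> hu --subtract--> enhancement_hu
        --apply_calibration--> iodine_mg_ml

World coordinates are ``index * spacing`` measured from the volume origin
corner (0-based indices).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile

VALUE_KINDS = ("attenuation_mu", "hu", "enhancement_hu", "iodine_mg_ml")

#: planar-series value kinds; ``iodine_areal`` is a parallel projection of an
#: iodine map (units mg I/mL * mm along the projection axis)
PLANAR_KINDS = ("hu", "enhancement_hu", "iodine_mg_ml", "iodine_areal")


class FrameMismatchError(ValueError):
    """Raised when two volumes are combined without sharing a frame of reference."""


@dataclass
class Volume:
    """3-D scalar image with spacing, frame-of-reference and value-kind tags.

    Parameters
    ----------
    data:
        3-D array; converted to ``float64``.
    spacing:
        Voxel spacing in mm per axis, all > 0.
    kind:
        One of :data:`VALUE_KINDS`.
    frame:
        Frame-of-reference id.  Arithmetic between volumes requires identical
        shape, spacing and frame.
    protocol:
        Optional acquisition-protocol tag (``"SE"``, ``"DE"``, ``"DCE"``) used
        to match calibration curves.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: str
    frame: str = "unknown"
    protocol: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.kind!r}; expected one of {VALUE_KINDS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "Volume":
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       kind=self.kind if kind is None else kind)

    def check_compatible(self, other: "Volume") -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")
        if self.frame != other.frame:
            raise FrameMismatchError(
                f"frame mismatch: {self.frame!r} vs {other.frame!r}; "
                "register the moving volume first"
            )


@dataclass
class PlanarSeries:
    """Time-ordered 2-D projections with timestamps.

    ``frames`` has shape (T, H, W); ``times_s`` is strictly increasing.
    """

    frames: np.ndarray
    times_s: np.ndarray
    pixel_spacing: tuple[float, float]
    kind: str = "iodine_areal"
    frame: str = "unknown"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.times_s.shape != (self.frames.shape[0],):
            raise ValueError("times_s length must match number of frames")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel spacing must be positive")
        if self.kind not in PLANAR_KINDS:
            raise ValueError(f"unknown planar kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SubtractionConfig:
    """Subtraction mode and weight.

    ``temporal`` computes CE − baseline; ``weighted_de`` computes HE − α·LE
    with the dual-energy weighting factor α (default 0.55).
    """

    mode: str = "temporal"
    alpha: float = 0.55

    def __post_init__(self) -> None:
        if self.mode not in ("temporal", "weighted_de"):
            raise ValueError(f"unknown subtraction mode {self.mode!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


def hu_calibrate(vol: Volume, mu_water: float) -> Volume:
    """Convert a linear-attenuation volume to Hounsfield units.

    HU = 1000 * (mu - mu_water) / mu_water, so water maps to 0 HU and vacuum
    to -1000 HU.

    Parameters
    ----------
    vol:
        Volume of kind ``attenuation_mu``.
    mu_water:
        Attenuation coefficient of water for the acquisition protocol (> 0),
        same units as the volume values.
    """
    if mu_water <= 0:
        raise ValueError(f"mu_water must be > 0, got {mu_water}")
    if vol.kind != "attenuation_mu":
        raise ValueError(f"hu_calibrate expects an attenuation_mu volume, got {vol.kind!r}")
    hu = 1000.0 * (vol.data - mu_water) / mu_water
    return vol.with_data(hu, kind="hu")


def subtract(a: Volume, b: Volume, cfg: SubtractionConfig | None = None) -> Volume:
    """Enhancement image from a registered image pair.

    Temporal mode: ``E = a - b`` with a = CE, b = baseline.
    Weighted mode: ``E = a - alpha * b`` with a = HE, b = LE.

    Both volumes must share shape, spacing and frame of reference (i.e. any
    registration has already been applied); a frame mismatch raises
    :class:`FrameMismatchError`.
    """
    cfg = cfg or SubtractionConfig()
    a.check_compatible(b)
    if cfg.mode == "temporal":
        e = a.data - b.data
    else:
        e = a.data - cfg.alpha * b.data
    return Volume(e, a.spacing, "enhancement_hu", frame=a.frame, protocol=a.protocol)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_nifti(vol: Volume, path: str | Path) -> None:
    """Write as NIfTI-1 with voxel spacing in the header zooms."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.spacing)
    img.header["descrip"] = f"kind={vol.kind}".encode()
    nib.save(img, str(path))


def read_nifti(path: str | Path, kind: str = "hu", frame: str = "unknown",
               protocol: str | None = None) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asanyarray(img.dataobj), spacing, kind, frame=frame, protocol=protocol)


def write_tiff_stack(vol: Volume, path: str | Path) -> None:
    tifffile.imwrite(str(path), vol.data.astype(np.float32), photometric="minisblack",
                     metadata={"spacing_mm": list(vol.spacing), "kind": vol.kind})


def read_tiff_stack(path: str | Path, spacing: Sequence[float],
                    kind: str = "hu", frame: str = "unknown") -> Volume:
    data = tifffile.imread(str(path))
    return Volume(np.asarray(data), tuple(spacing), kind, frame=frame)


def write_planar_series(series: PlanarSeries, tiff_path: str | Path,
                        times_csv_path: str | Path) -> None:
    """Multi-page TIFF (one page per frame) plus a CSV timestamp sidecar."""
    tifffile.imwrite(str(tiff_path), series.frames.astype(np.float32),
                     photometric="minisblack")
    with open(times_csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "t_s"])
        for i, t in enumerate(series.times_s):
            w.writerow([i, float(t)])


def read_planar_series(tiff_path: str | Path, times_csv_path: str | Path,
                       pixel_spacing: Sequence[float],
                       kind: str = "iodine_areal") -> PlanarSeries:
    frames = np.asarray(tifffile.imread(str(tiff_path)), dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    times = []
    with open(times_csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            times.append(float(row["t_s"]))
    return PlanarSeries(frames, np.asarray(times), tuple(pixel_spacing), kind=kind)
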