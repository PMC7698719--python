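"""Digital phantom generator.

Produces every input the quantification pipeline needs, with known ground
truth: baseline/CE single-energy volume pairs, LE/HE dual-energy pairs whose
unenhanced tissue cancels exactly under weighted subtraction with alpha,
dynamic planar series driven by the irreversible two-compartment forward
model under a continuous-infusion arterial input, iodinated calibration
phantoms, and histology tables with a controllable correlation to imaging
parameters.

All randomness is seeded through the spec; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .image import PlanarSeries, Volume
from .kinetics import EllipseROI, TimeConcentrationCurve, patlak_forward
from .registration import AffineTransform
from .voi import EllipsoidVOI

DEFAULT_CAL_SLOPE = 0.02   # (mg I/mL) per HU, i.e. 50 HU per mg I/mL
DEFAULT_ALPHA = 0.55       # dual-energy tissue-cancellation weight


@dataclass
class Organ:
    """One ellipsoidal organ: geometry, baseline attenuation, iodine uptake."""

    voi: EllipsoidVOI
    baseline_hu: float
    iodine_mg_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.iodine_mg_ml < 0:
            raise ValueError(f"iodine concentration must be >= 0 for {self.voi.label!r}")


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise description of one digital phantom."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    organs: list[Organ]
    background_hu: float = 0.0
    noise_sigma_hu: float = 0.0
    misalignment: AffineTransform | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.noise_sigma_hu < 0:
            raise ValueError("noise sigma must be >= 0")
        extent = (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        for organ in self.organs:
            c = np.asarray(organ.voi.center)
            a = np.asarray(organ.voi.semi_axes)
            if np.any(c - a < 0) or np.any(c + a > extent):
                raise ValueError(
                    f"organ {organ.voi.label!r} extends outside the volume bounds")

    def organ(self, label: str) -> Organ:
        for o in self.organs:
            if o.voi.label == label:
                return o
        raise KeyError(f"no organ labelled {label!r} in the phantom spec")


@dataclass
class KineticGroundTruth:
    """Generating kinetic parameters and the continuous-infusion AIF.

    ``regions`` maps organ labels to (Ktrans in min^-1, rBV as a fraction).
    The AIF rises linearly from 0 to ``plateau_mg_ml`` over ``ramp_end_s``
    seconds and stays constant afterwards.
    """

    regions: dict[str, tuple[float, float]]
    ramp_end_s: float = 20.0
    plateau_mg_ml: float = 6.0
    times_s: np.ndarray = field(default_factory=lambda: np.arange(0.0, 81.0, 1.0))

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("sampling grid must be strictly increasing")
        if self.plateau_mg_ml <= 0:
            raise ValueError("AIF plateau must be > 0")
        for label, (ktrans, rbv) in self.regions.items():
            if ktrans < 0:
                raise ValueError(f"Ktrans must be >= 0 for {label!r}")
            if not 0 <= rbv <= 1:
                raise ValueError(f"rBV fraction must lie in [0, 1] for {label!r}")

    def aif(self) -> TimeConcentrationCurve:
        ci = self.plateau_mg_ml * np.clip(self.times_s / self.ramp_end_s, 0.0, 1.0)
        return TimeConcentrationCurve(self.times_s.copy(), ci, "lv")

    def tissue_curve(self, label: str) -> TimeConcentrationCurve:
        ktrans, rbv = self.regions[label]
        return patlak_forward(self.aif(), ktrans, rbv, label=label)


def _paint(spec: PhantomSpec, organ_value) -> np.ndarray:
    """Rasterize the phantom: background plus per-organ values (later wins)."""
    vol = np.full(spec.shape, float(organ_value(None)), dtype=np.float64)
    for organ in spec.organs:
        vol[organ.voi.mask(spec.shape, spec.spacing)] = float(organ_value(organ))
    return vol


def _noisy(data: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return data
    return data + rng.normal(0.0, sigma, size=data.shape)


def make_se_pair(spec: PhantomSpec,
                 cal_slope: float = DEFAULT_CAL_SLOPE) -> tuple[Volume, Volume]:
    """Baseline and contrast-enhanced single-energy volumes.

    The CE volume adds iodine-induced enhancement C_I / cal_slope (HU) inside
    enhancing organs; noise is drawn independently per volume; the optional
    misalignment warps the baseline member.
    """
    rng = np.random.default_rng(spec.seed)
    base = _paint(spec, lambda o: spec.background_hu if o is None else o.baseline_hu)
    enh = _paint(spec, lambda o: 0.0 if o is None else o.iodine_mg_ml / cal_slope)
    ce = base + enh
    baseline = Volume(base, spec.spacing, "hu", frame="baseline", protocol="SE")
    if spec.misalignment is not None:
        baseline = spec.misalignment.resample(baseline, baseline)
        baseline.frame = "baseline"
    baseline.data = _noisy(baseline.data, spec.noise_sigma_hu, rng)
    ce_vol = Volume(_noisy(ce, spec.noise_sigma_hu, rng), spec.spacing, "hu",
                    frame="ce", protocol="SE")
    return baseline, ce_vol


def make_de_pair(spec: PhantomSpec, alpha: float = DEFAULT_ALPHA,
                 cal_slope: float = DEFAULT_CAL_SLOPE) -> tuple[Volume, Volume]:
    """Low- and high-energy volumes with exact tissue cancellation.

    Before noise, unenhanced tissue satisfies HE = alpha * LE, so the weighted
    subtraction HE - alpha*LE vanishes outside iodinated organs; iodinated
    organs carry an HE-only additive term C_I / cal_slope.
    """
    rng = np.random.default_rng(spec.seed)
    le = _paint(spec, lambda o: spec.background_hu if o is None else o.baseline_hu)
    iodine = _paint(spec, lambda o: 0.0 if o is None else o.iodine_mg_ml / cal_slope)
    he = alpha * le + iodine
    le_vol = Volume(le, spec.spacing, "hu", frame="le", protocol="DE")
    if spec.misalignment is not None:
        le_vol = spec.misalignment.resample(le_vol, le_vol)
        le_vol.frame = "le"
    le_vol.data = _noisy(le_vol.data, spec.noise_sigma_hu, rng)
    he_vol = Volume(_noisy(he, spec.noise_sigma_hu, rng), spec.spacing, "hu",
                    frame="he", protocol="DE")
    return le_vol, he_vol


# ---------------------------------------------------------------------------
# DCE planar series
# ---------------------------------------------------------------------------

def make_dce_series(spec: PhantomSpec, truth: KineticGroundTruth, axis: int = 0,
                    overlap: Organ | None = None,
                    noise_sigma: float = 0.0) -> PlanarSeries:
    """Dynamic planar series via the two-compartment forward model.

    Each frame is a fixed-angle parallel projection — the sum of the 3-D
    iodine-concentration map along ``axis`` scaled by the voxel size — so
    frame values are areal iodine (mg I/mL * mm).  Organs named in ``truth``
    follow their forward kinetic curves; other organs contribute their static
    iodine concentration.  ``overlap`` adds an extra organ (e.g. behind the
    tumor along the projection axis) to emulate planar tissue
    superimposition; it may carry its own kinetic truth entry or a static
    concentration.

    Raises ``KeyError`` when a truth region has no organ in the spec.
    """
    labels = {o.voi.label for o in spec.organs}
    if overlap is not None:
        labels.add(overlap.voi.label)
    for region in truth.regions:
        if region not in labels:
            raise KeyError(f"kinetic truth region {region!r} is not an organ in the spec")

    organs = list(spec.organs) + ([overlap] if overlap is not None else [])
    curves = {label: truth.tissue_curve(label).ci_mg_ml for label in truth.regions}
    masks = [(o, o.voi.mask(spec.shape, spec.spacing)) for o in organs]

    dz = spec.spacing[axis]
    times = truth.times_s
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((times.size,) + tuple(n for i, n in enumerate(spec.shape) if i != axis))
    cmap = np.empty(spec.shape, dtype=np.float64)
    for k in range(times.size):
        cmap[:] = 0.0
        for organ, m in masks:
            label = organ.voi.label
            cmap[m] = curves[label][k] if label in curves else organ.iodine_mg_ml
        frames[k] = cmap.sum(axis=axis) * dz
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)

    pix = tuple(s for i, s in enumerate(spec.spacing) if i != axis)
    return PlanarSeries(frames, times.copy(), pix, kind="iodine_areal", frame="dce")


def projected_roi(spec: PhantomSpec, label: str, axis: int = 0) -> EllipseROI:
    """Elliptical ROI matching an organ's parallel projection along ``axis``."""
    organ = spec.organ(label)
    keep = [i for i in range(3) if i != axis]
    return EllipseROI(tuple(organ.voi.center[i] for i in keep),
                      tuple(organ.voi.semi_axes[i] for i in keep))


def projection_thickness(spec: PhantomSpec, label: str, axis: int = 0,
                         roi: EllipseROI | None = None) -> float:
    """Mean chord thickness (mm) of an organ over an ROI of its projection.

    Computed by brute-force column counting on the voxel mask, so it matches
    the discrete projection operator exactly; divide areal-iodine ROI means by
    this factor to recover concentration.
    """
    organ = spec.organ(label)
    mask = organ.voi.mask(spec.shape, spec.spacing)
    thickness = mask.sum(axis=axis) * spec.spacing[axis]
    if roi is None:
        roi = projected_roi(spec, label, axis)
    pix = tuple(s for i, s in enumerate(spec.spacing) if i != axis)
    sel = roi.mask(thickness.shape, pix)
    if not sel.any():
        raise ValueError("ROI does not intersect the projection")
    return float(thickness[sel].mean())


# ---------------------------------------------------------------------------
# Calibration phantom
# ---------------------------------------------------------------------------

def make_calibration_phantom(concentrations: Sequence[float],
                             hu_per_mg_ml: float = 1.0 / DEFAULT_CAL_SLOPE,
                             intercept_hu: float = 0.0,
                             insert_radius_mm: float = 3.0,
                             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                             noise_sigma_hu: float = 0.0,
                             seed: int = 0) -> tuple[Volume, list[EllipsoidVOI]]:
    """Iodinated calibration phantom: one insert per known concentration.

    Returns an enhancement-HU volume (inserts on a zero background, values
    ``hu_per_mg_ml * C + intercept_hu``) and the matching VOIs, laid out in a
    row.  At least 3 distinct concentrations are required so the downstream
    line fit is well posed.
    """
    conc = [float(c) for c in concentrations]
    if any(c < 0 for c in conc):
        raise ValueError("concentrations must be >= 0")
    if len(set(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations for calibration")

    r = insert_radius_mm
    gap = 4.0 * r
    ny = int(np.ceil((gap * len(conc) + gap) / spacing[1]))
    nx = int(np.ceil(4 * r / spacing[2]))
    nz = int(np.ceil(4 * r / spacing[0]))
    shape = (nz, ny, nx)
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)

    rng = np.random.default_rng(seed)
    data = np.zeros(shape, dtype=np.float64)
    vois = []
    for i, c in enumerate(conc):
        center = (extent[0] / 2, gap * (i + 1), extent[2] / 2)
        voi = EllipsoidVOI(center, (r, r, r), "custom")
        data[voi.mask(shape, spacing)] = hu_per_mg_ml * c + intercept_hu
        vois.append(voi)
    if noise_sigma_hu > 0:
        data = data + rng.normal(0.0, noise_sigma_hu, size=shape)
    vol = Volume(data, spacing, "enhancement_hu", frame="calphantom")
    return vol, vois


# ---------------------------------------------------------------------------
# Histology
# ---------------------------------------------------------------------------

HISTOLOGY_COLUMNS = ("pn_percent", "pi_percent", "mvd_vessels_per_hpf")


@dataclass
class HistologySimSpec:
    """Targets for the simulated histology table.

    ``rho`` maps histology column names to the target Pearson correlation
    with the supplied imaging parameter; ``means``/``sds`` set the marginals.
    Percent variables are clipped to [0, 100] and MVD to >= 0 after
    generation.
    """

    n_tumors: int
    rho: dict[str, float] = field(default_factory=lambda: dict.fromkeys(HISTOLOGY_COLUMNS, 0.0))
    means: dict[str, float] = field(default_factory=lambda: {
        "pn_percent": 38.1, "pi_percent": 68.7, "mvd_vessels_per_hpf": 6.9})
    sds: dict[str, float] = field(default_factory=lambda: {
        "pn_percent": 15.0, "pi_percent": 10.0, "mvd_vessels_per_hpf": 2.5})
    seed: int = 0

    def __post_init__(self) -> None:
        for col, r in self.rho.items():
            if col not in HISTOLOGY_COLUMNS:
                raise ValueError(f"unknown histology column {col!r}")
            if abs(r) > 1:
                raise ValueError(f"|rho| must be <= 1 for {col!r}")
        for col, sd in self.sds.items():
            if sd <= 0:
                raise ValueError(f"SD must be > 0 for {col!r}")


def make_histology_table(sim: HistologySimSpec,
                         imaging_values: Sequence[float]) -> pd.DataFrame:
    """Histology records correlated with an imaging parameter.

    Each histology variable is built as ``rho * z + sqrt(1 - rho^2) * eps``
    on standardized scales, so the sample Pearson r converges to rho as n
    grows and equals rho exactly when |rho| = 1.
    """
    v = np.asarray(imaging_values, dtype=np.float64)
    if v.size != sim.n_tumors:
        raise ValueError(f"expected {sim.n_tumors} imaging values, got {v.size}")
    if sim.n_tumors < 3:
        raise ValueError("need at least 3 tumors (correlation undefined below)")
    if v.std() == 0:
        raise ValueError("imaging values are constant; correlation target unachievable")
    # compound seed: decouples this stream from caller streams seeded with the
    # same integer (e.g. the imaging values themselves)
    rng = np.random.default_rng([sim.seed, 0x4915])
    z = (v - v.mean()) / v.std()

    out = {"tumor_id": [f"tumor_{i + 1:03d}" for i in range(sim.n_tumors)]}
    for col in HISTOLOGY_COLUMNS:
        rho = sim.rho.get(col, 0.0)
        eps = rng.standard_normal(sim.n_tumors)
        h = rho * z + np.sqrt(1.0 - rho**2) * eps
        vals = sim.means.get(col, 0.0) + sim.sds.get(col, 1.0) * h
        if col.endswith("percent"):
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.maximum(vals, 0.0)
        out[col] = vals
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# YAML spec I/O
# ---------------------------------------------------------------------------

def load_phantom_spec(path: str | Path) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    organs = [Organ(EllipsoidVOI(tuple(o["center_mm"]), tuple(o["semi_axes_mm"]),
                                 o.get("label", "custom")),
                    baseline_hu=float(o.get("baseline_hu", 0.0)),
                    iodine_mg_ml=float(o.get("iodine_mg_ml", 0.0)))
              for o in d.get("organs", [])]
    mis = None
    if "misalignment" in d:
        m = d["misalignment"]
        mis = AffineTransform(np.asarray(m["matrix"]), np.asarray(m["translation_mm"]),
                              np.asarray(m.get("center_mm", [0, 0, 0])))
    return PhantomSpec(shape=tuple(d["shape"]), spacing=tuple(d["spacing_mm"]),
                       organs=organs, background_hu=float(d.get("background_hu", 0.0)),
                       noise_sigma_hu=float(d.get("noise_sigma_hu", 0.0)),
                       misalignment=mis, seed=int(d.get("seed", 0)))


def default_rat_spec(seed: int = 0, noise_sigma_hu: float = 0.0) -> PhantomSpec:
    """A small abdomen-like phantom: aorta, muscle and a flank tumor."""
    organs = [
        Organ(EllipsoidVOI((24.0, 16.0, 16.0), (12.0, 3.0, 3.0), "aorta"),
              baseline_hu=40.0, iodine_mg_ml=6.2),
        Organ(EllipsoidVOI((24.0, 34.0, 14.0), (10.0, 5.0, 4.0), "muscle"),
              baseline_hu=50.0, iodine_mg_ml=0.72),
        Organ(EllipsoidVOI((22.0, 24.0, 33.0), (8.0, 6.0, 5.0), "tumor"),
              baseline_hu=35.0, iodine_mg_ml=1.55),
    ]
    return PhantomSpec(shape=(49, 49, 49), spacing=(1.0, 1.0, 1.0), organs=organs,
                       background_hu=0.0, noise_sigma_hu=noise_sigma_hu, seed=seed)
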