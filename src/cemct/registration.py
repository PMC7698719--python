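"""Intensity-based affine registration.

Registers a moving volume to a fixed volume by maximizing normalized
cross-correlation with Powell's method over a multi-resolution pyramid.
The contract is parameter recovery (translations to fractions of a voxel,
small affines to ~10 %), not any particular optimizer.

Transform convention: a transform maps *fixed*-frame world points to
*moving*-frame world points,

    p_moving = A @ (p_fixed - c) + c + t

with ``c`` the rotation center (mm).  Resampling the moving volume through
this map expresses it on the fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .image import Volume


class RegistrationError(RuntimeError):
    def __init__(self, message: str, metric: float):
        super().__init__(f"{message} (final NCC = {metric:.4f})")
        self.metric = metric


@dataclass
class AffineTransform:
    """3x3 linear part + translation (mm), applied about ``center``."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    order: int = 1  # linear interpolation

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("linear part of affine transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        # p_f = inv @ (p_m - c - t) + c  ==  inv @ (p_m - c) + c + t'
        t_prime = -inv @ self.translation
        return AffineTransform(inv, t_prime, self.center, self.order)

    def resample(self, moving: Volume, like: Volume) -> Volume:
        """Resample ``moving`` onto the grid of ``like`` through this transform."""
        s_like = np.asarray(like.spacing)
        s_mov = np.asarray(moving.spacing)
        # index-space map: idx_mov = Smov^-1 (A @ (Slike idx - c) + c + t)
        m_idx = (self.matrix * s_like[None, :]) / s_mov[:, None]
        off = (self.center + self.translation - self.matrix @ self.center) / s_mov
        data = ndimage.affine_transform(
            moving.data, m_idx, offset=off, output_shape=like.shape,
            order=self.order, mode="constant", cval=float(moving.data.min()),
            prefilter=self.order > 1)
        return Volume(data, like.spacing, moving.kind, frame=like.frame,
                      protocol=moving.protocol)


def _euler(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


_DOF_NPARAMS = {"translation": 3, "rigid": 6, "affine": 12}


def _params_to_transform(params: np.ndarray, dof: str, center: np.ndarray) -> AffineTransform:
    t = params[:3]
    mat = np.eye(3)
    if dof in ("rigid", "affine"):
        mat = _euler(*params[3:6])
    if dof == "affine":
        scale = np.diag(np.exp(params[6:9]))
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = params[9:12]
        mat = mat @ scale @ shear
    return AffineTransform(mat, t, center)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _downsample(vol: Volume, f: int) -> Volume:
    if f == 1:
        return vol
    shape = tuple((n // f) * f for n in vol.shape)
    d = vol.data[: shape[0], : shape[1], : shape[2]]
    d = d.reshape(shape[0] // f, f, shape[1] // f, f, shape[2] // f, f).mean(axis=(1, 3, 5))
    return Volume(d, tuple(s * f for s in vol.spacing), vol.kind, frame=vol.frame)


def register_affine(moving: Volume, fixed: Volume, dof: str = "affine",
                    shrink_factors: tuple[int, ...] = (4, 2, 1),
                    min_ncc: float = 0.2) -> tuple[AffineTransform, Volume]:
    """Register ``moving`` to ``fixed`` and return (transform, resampled moving).

    Parameters
    ----------
    moving, fixed:
        Volumes with identical spacing and overlapping fields of view.
    dof:
        ``"translation"`` (3 parameters), ``"rigid"`` (+3 rotations) or
        ``"affine"`` (+3 log-scales, +3 shears).
    shrink_factors:
        Pyramid levels, coarse to fine; 1 must be last for a full-resolution
        polish.
    min_ncc:
        Final-similarity floor below which :class:`RegistrationError` is raised.

    Notes
    -----
    If both volumes already carry the same (non-default) frame-of-reference id
    the identity transform is returned without optimizing.
    """
    if not np.allclose(moving.spacing, fixed.spacing):
        raise ValueError("registration requires identical voxel spacing")
    if dof not in _DOF_NPARAMS:
        raise ValueError(f"dof must be one of {sorted(_DOF_NPARAMS)}, got {dof!r}")

    center = (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing) / 2.0

    if moving.frame == fixed.frame and fixed.frame != "unknown":
        ident = AffineTransform(np.eye(3), np.zeros(3), center)
        return ident, ident.resample(moving, fixed)

    params = np.zeros(_DOF_NPARAMS[dof])
    result = None
    for f in shrink_factors:
        mov_l, fix_l = _downsample(moving, f), _downsample(fixed, f)

        def cost(p: np.ndarray) -> float:
            tr = _params_to_transform(p, dof, center)
            res = tr.resample(mov_l, fix_l)
            return 1.0 - _ncc(res.data, fix_l.data)

        result = optimize.minimize(cost, params, method="Powell",
                                   options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 50})
        params = result.x

    transform = _params_to_transform(params, dof, center)
    resampled = transform.resample(moving, fixed)
    final_ncc = _ncc(resampled.data, fixed.data)
    if final_ncc < min_ncc:
        raise RegistrationError("registration failed to converge", final_ncc)
    return transform, resampled
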