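"""Rigid + affine intensity-based registration to the atlas template.

The transform convention matches the resampling direction: an
:class:`AffineTransform` maps points from the *fixed* (target) world space
into the *moving* (source) world space, i.e. it is applied directly when
pulling moving intensities onto the fixed grid.

Registration maximizes normalized cross-correlation (NCC — robust to a
global HU offset) with Powell's gradient-free optimizer over a
multi-resolution schedule: two Gaussian-smoothed, downsampled levels
(factors 4 and 2) localize the pose, a sparsely sampled native-resolution
stage recovers sub-voxel accuracy cheaply, and a short densely sampled
full-resolution stage refines the rigid pose before the full 12-parameter
affine stage.  Every stage has a fixed iteration cap and no stochastic
sampling, so runs are deterministic.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volume import BinaryMask, Volume

__all__ = [
    "AffineTransform",
    "RegistrationConfig",
    "register_affine",
    "resample",
    "resample_mask",
    "random_rigid_transform",
    "ncc",
]

AIR_HU = -1000.0


class TransformError(ValueError):
    """Raised for degenerate (non-invertible) transforms."""


@dataclass
class AffineTransform:
    """World-coordinate affine map ``x -> matrix @ x + translation`` (mm).

    ``space`` tags the world-coordinate convention (NIfTI affine
    convention throughout this package); ``converged`` is False when the
    producing registration was flagged low-confidence.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    space: str = "world"
    converged: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise TransformError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array of world points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation, self.space, self.converged)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
            self.space,
            self.converged and other.converged,
        )

    @property
    def homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        h[:3, :3] = self.matrix
        h[:3, 3] = self.translation
        return h

    def save(self, path: str | os.PathLike) -> None:
        """Serialize as a row-major 4x4 matrix text file (world mm)."""
        np.savetxt(str(path), self.homogeneous, fmt="%.12g")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "AffineTransform":
        h = np.loadtxt(str(path))
        if h.shape != (4, 4):
            raise TransformError(f"{path!r}: expected a 4x4 matrix, got {h.shape}")
        return cls(h[:3, :3], h[:3, 3])

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()


@dataclass(frozen=True)
class RegistrationConfig:
    """Multi-resolution schedule and iteration caps (all deterministic)."""

    coarse_factors: tuple[int, ...] = (4, 2)
    sparse_stride: int = 2
    coarse_maxiter: int = 5
    sparse_maxiter: int = 5
    dense_maxiter: int = 2
    affine_maxiter: int = 3
    do_affine_stage: bool = True
    #: final-NCC floor below which the result is flagged low-confidence
    min_similarity: float = 0.5


# --------------------------------------------------------------- resampling

def _resample_values(
    values: np.ndarray,
    source: Volume | BinaryMask,
    t: AffineTransform,
    target: Volume | BinaryMask,
    order: int,
    cval: float,
) -> np.ndarray:
    # voxel(target) -> world(fixed) --t--> world(moving) -> voxel(moving)
    full = np.linalg.inv(source.affine) @ t.homogeneous @ target.affine
    return ndimage.affine_transform(
        values,
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=cval,
    )


def resample(v: Volume, t: AffineTransform, target: Volume | BinaryMask) -> Volume:
    """Pull ``v`` onto ``target``'s grid through the fixed->moving transform
    ``t`` with trilinear interpolation; out-of-field voxels become air
    (-1000 HU)."""
    vals = _resample_values(v.values, v, t, target, order=1, cval=AIR_HU)
    return Volume(vals, np.asarray(target.spacing, float).copy(),
                  np.asarray(target.origin, float).copy(),
                  np.asarray(target.direction, float).copy())


def resample_mask(m: BinaryMask, t: AffineTransform, target: Volume | BinaryMask) -> BinaryMask:
    """Nearest-neighbour resampling for masks."""
    vals = _resample_values(m.values.astype(np.float64), m, t, target, order=0, cval=0.0)
    return BinaryMask(vals > 0.5, np.asarray(target.spacing, float).copy(),
                      np.asarray(target.origin, float).copy(),
                      np.asarray(target.direction, float).copy())


# -------------------------------------------------------------- similarity

def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped arrays."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _rotation(angles: np.ndarray) -> np.ndarray:
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _params_to_transform(p: np.ndarray, center: np.ndarray, affine: bool) -> AffineTransform:
    """Rigid: p = (tx, ty, tz, rx, ry, rz), rotation about ``center``.
    Affine: p = (tx, ty, tz) + row-major deviation of the linear part from I."""
    A = np.eye(3) + p[3:12].reshape(3, 3) if affine else _rotation(p[3:6])
    return AffineTransform(A, center - A @ center + p[:3])


def _smooth_level(v: Volume, factor: int) -> Volume:
    if factor == 1:
        return v
    sm = ndimage.gaussian_filter(v.values, sigma=factor / 2.0)
    return Volume(sm[::factor, ::factor, ::factor], v.spacing * factor,
                  v.origin, v.direction)


def _sparse_level(v: Volume, stride: int) -> Volume:
    """Strided sampling grid with native (unsmoothed) intensities."""
    if stride == 1:
        return v
    return Volume(v.values[::stride, ::stride, ::stride], v.spacing * stride,
                  v.origin, v.direction)


def _grid_center_world(v: Volume) -> np.ndarray:
    center_idx = (np.asarray(v.shape, float) - 1.0) / 2.0
    return (v.affine @ np.append(center_idx, 1.0))[:3]


def register_affine(
    moving: Volume,
    fixed: Volume,
    config: RegistrationConfig | None = None,
) -> tuple[AffineTransform, Volume]:
    """Align ``moving`` to ``fixed``: rigid stages, then a full affine stage.

    Returns the fixed->moving world transform and the moving volume
    resampled onto the fixed grid.  The pose is initialized by aligning the
    grid centers (center-of-geometry).  If the final full-resolution NCC is
    worse than the initial one, the initial transform is returned instead;
    if it falls below ``config.min_similarity``, a warning is issued and
    the transform is flagged ``converged=False``.
    """
    config = config or RegistrationConfig()
    center = _grid_center_world(fixed)
    shift0 = _grid_center_world(moving) - center
    p = np.concatenate([shift0, np.zeros(3)])
    n_eval = 0

    def stage(p0, cost, maxiter, xtol):
        nonlocal n_eval

        def counted(q):
            nonlocal n_eval
            n_eval += 1
            return cost(q)

        res = optimize.minimize(
            counted, p0, method="Powell",
            options=dict(maxiter=maxiter, xtol=xtol, ftol=1e-9),
        )
        return res.x

    # coarse smoothed rigid stages
    for factor in config.coarse_factors:
        f_l = _smooth_level(fixed, factor)
        m_l = _smooth_level(moving, factor)
        p = stage(
            p,
            lambda q, f=f_l, m=m_l: -ncc(resample(m, _params_to_transform(q, center, False), f).values, f.values),
            config.coarse_maxiter, 1e-3,
        )
    # sparse native-resolution rigid stage
    f_s = _sparse_level(fixed, config.sparse_stride)
    p = stage(
        p,
        lambda q: -ncc(resample(moving, _params_to_transform(q, center, False), f_s).values, f_s.values),
        config.sparse_maxiter, 1e-4,
    )
    # short dense full-resolution rigid refinement
    p = stage(
        p,
        lambda q: -ncc(resample(moving, _params_to_transform(q, center, False), fixed).values, fixed.values),
        config.dense_maxiter, 1e-4,
    )
    best = _params_to_transform(p, center, False)
    if config.do_affine_stage:
        q = np.concatenate([p[:3], (_rotation(p[3:6]) - np.eye(3)).ravel()])
        q = stage(
            q,
            lambda r: -ncc(resample(moving, _params_to_transform(r, center, True), f_s).values, f_s.values),
            config.affine_maxiter, 1e-4,
        )
        best = _params_to_transform(q, center, True)

    initial = _params_to_transform(np.concatenate([shift0, np.zeros(3)]), center, False)
    final_sim = ncc(resample(moving, best, fixed).values, fixed.values)
    init_sim = ncc(resample(moving, initial, fixed).values, fixed.values)
    if final_sim < init_sim:  # never return something worse than the start
        best, final_sim = initial, init_sim
    if final_sim < config.min_similarity:
        warnings.warn(
            f"registration similarity {final_sim:.3f} below "
            f"{config.min_similarity}; transform flagged low-confidence",
            RuntimeWarning,
            stacklevel=2,
        )
        best.converged = False
    return best, resample(moving, best, fixed)


def random_rigid_transform(
    rng: np.random.Generator,
    max_translation_mm: float = 10.0,
    max_rotation_deg: float = 10.0,
    center_mm: np.ndarray | None = None,
) -> AffineTransform:
    """A random rigid world transform (rotation about ``center_mm``), used to
    perturb phantoms for registration testing."""
    angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    shift = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    rot = _rotation(angles)
    center = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
    return AffineTransform(rot, center - rot @ center + shift)
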