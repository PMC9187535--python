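"""Per-voxel Gaussian normative atlas and confidence-interval outlier detection.

The detection mechanism at the heart of the package: independent Gaussian
densities are fitted at every voxel across a cohort of co-registered normal
scans, per-voxel lower/upper bounds of a two-sided confidence interval
(default 90%) are derived from the fitted mean and standard deviation, and a
test scan's voxels are flagged as outliers wherever they fall strictly
outside those bounds inside the brain mask.

:class:`NormativeAtlas` follows the scikit-learn estimator protocol:
hyperparameters (``ci_level``, ``sigma_floor``) are constructor arguments
available through ``get_params``/``set_params``; fitted state lives in
trailing-underscore attributes (``mean_``, ``std_``, ``lower_``, ``upper_``,
``z_``, ``n_train_``, ``brain_mask_``, ``template_``).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .volume import (
    BinaryMask,
    Volume,
    compute_brain_mask,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = ["NormativeAtlas", "OutlierMap", "fit_normative_atlas", "detect_outliers"]


@dataclass
class OutlierMap:
    """Voxel-level outlier flags with their deviation direction.

    ``direction`` is +1 where the scan exceeds the upper bound, -1 where it
    falls below the lower bound, and 0 at inliers; it is nonzero exactly
    where ``flags`` is set.
    """

    flags: BinaryMask
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=np.int8)
        if self.direction.shape != self.flags.shape:
            raise ValueError("direction grid must match flag grid")
        if not np.array_equal(self.direction != 0, self.flags.values):
            raise ValueError("direction must be nonzero exactly at flagged voxels")

    @property
    def n_outliers(self) -> int:
        return self.flags.n_voxels


class NormativeAtlas(BaseEstimator):
    """Voxel-wise Gaussian normative model of normal head CT.

    Parameters
    ----------
    ci_level : float, default=0.90
        Two-sided confidence level; the half-width multiplier is the
        standard-normal quantile ``z = Phi^{-1}((1 + ci_level) / 2)``
        (1.6449 at the default).
    sigma_floor : float, default=1.0
        Lower clamp (HU) on the per-voxel standard deviation, preventing
        zero-width intervals at voxels with degenerate training variance.
    brain_hu_window : tuple of float, default=(0.0, 80.0)
        HU window used when the brain mask is derived from the mean
        template rather than supplied.

    Attributes
    ----------
    mean_, std_, lower_, upper_ : ndarray
        Per-voxel sample mean, sample sd (ddof=1, clamped at
        ``sigma_floor``), and CI bounds ``mean_ -/+ z_ * std_``.
    z_ : float
        CI half-width multiplier actually used.
    n_train_ : int
        Number of training scans.
    brain_mask_ : BinaryMask
        Mask within which outliers are evaluated.
    template_ : Volume
        The voxel-wise mean volume (the atlas template).
    """

    def __init__(
        self,
        ci_level: float = 0.90,
        sigma_floor: float = 1.0,
        brain_hu_window: tuple[float, float] = (0.0, 80.0),
    ) -> None:
        self.ci_level = ci_level
        self.sigma_floor = sigma_floor
        self.brain_hu_window = brain_hu_window

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        X: list[Volume],
        y=None,
        brain_mask: BinaryMask | None = None,
    ) -> "NormativeAtlas":
        """Fit the per-voxel model from co-registered normal volumes.

        ``X`` is a list of :class:`Volume` on one common grid (at least 2).
        If ``brain_mask`` is not given it is computed from the mean volume.
        """
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.sigma_floor <= 0:
            raise ValueError(f"sigma_floor must be > 0, got {self.sigma_floor}")
        if len(X) < 2:
            raise ValueError(f"need at least 2 training volumes, got {len(X)}")
        ref = X[0]
        for i, v in enumerate(X[1:], start=1):
            if not ref.same_geometry(v):
                raise ValueError(f"training volume {i} is not on the reference grid")

        stack = np.stack([v.values for v in X], axis=0)
        mean = stack.mean(axis=0)
        std = stack.std(axis=0, ddof=1)
        np.maximum(std, self.sigma_floor, out=std)

        self.z_ = float(stats.norm.ppf(0.5 * (1.0 + self.ci_level)))
        self.mean_ = mean
        self.std_ = std
        self.lower_ = mean - self.z_ * std
        self.upper_ = mean + self.z_ * std
        self.n_train_ = len(X)
        self.template_ = ref.with_values(mean)
        if brain_mask is not None:
            if not ref.same_geometry(brain_mask):
                raise ValueError("brain_mask is not on the training grid")
            self.brain_mask_ = brain_mask
        else:
            self.brain_mask_ = compute_brain_mask(self.template_, self.brain_hu_window)
        return self

    # ------------------------------------------------------------ detection
    def detect_outliers(self, scan: Volume) -> OutlierMap:
        """Flag voxels of a registered scan lying strictly outside the CI.

        A voxel is an outlier iff it is inside the brain mask and its value
        is ``< lower_`` or ``> upper_`` (values exactly on a bound are
        inliers).
        """
        check_is_fitted(self, "mean_")
        if not self.template_.same_geometry(scan):
            raise ValueError("scan grid does not match the atlas grid")
        inside = self.brain_mask_.values
        above = inside & (scan.values > self.upper_)
        below = inside & (scan.values < self.lower_)
        direction = np.zeros(scan.shape, dtype=np.int8)
        direction[above] = 1
        direction[below] = -1
        return OutlierMap(BinaryMask.like(scan, above | below), direction)

    def predict(self, X: list[Volume]) -> list[OutlierMap]:
        """Outlier maps for a list of registered scans."""
        return [self.detect_outliers(v) for v in X]

    # ---------------------------------------------------------- persistence
    def save(self, out_dir: str | os.PathLike) -> None:
        """Persist the atlas as NIfTI fields plus a JSON sidecar."""
        check_is_fitted(self, "mean_")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        t = self.template_
        for name, arr in [
            ("mean", self.mean_),
            ("std", self.std_),
            ("lower", self.lower_),
            ("upper", self.upper_),
        ]:
            write_volume(t.with_values(arr), out / f"{name}.nii.gz")
        write_mask(self.brain_mask_, out / "brain_mask.nii.gz")
        sidecar = {
            "ci_level": self.ci_level,
            "sigma_floor": self.sigma_floor,
            "z": self.z_,
            "n_train": self.n_train_,
        }
        (out / "atlas.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, atlas_dir: str | os.PathLike) -> "NormativeAtlas":
        d = Path(atlas_dir)
        sidecar = json.loads((d / "atlas.json").read_text())
        atlas = cls(ci_level=sidecar["ci_level"], sigma_floor=sidecar["sigma_floor"])
        mean_vol = read_volume(d / "mean.nii.gz")
        atlas.mean_ = mean_vol.values
        atlas.std_ = read_volume(d / "std.nii.gz").values
        atlas.lower_ = read_volume(d / "lower.nii.gz").values
        atlas.upper_ = read_volume(d / "upper.nii.gz").values
        atlas.brain_mask_ = read_mask(d / "brain_mask.nii.gz")
        atlas.template_ = mean_vol
        atlas.z_ = sidecar["z"]
        atlas.n_train_ = sidecar["n_train"]
        return atlas


def fit_normative_atlas(
    training_volumes: list[Volume],
    brain_mask: BinaryMask | None = None,
    ci_level: float = 0.90,
    sigma_floor: float = 1.0,
) -> NormativeAtlas:
    """Functional wrapper over :meth:`NormativeAtlas.fit`."""
    return NormativeAtlas(ci_level=ci_level, sigma_floor=sigma_floor).fit(
        training_volumes, brain_mask=brain_mask
    )


def detect_outliers(scan: Volume, atlas: NormativeAtlas) -> OutlierMap:
    """Functional wrapper over :meth:`NormativeAtlas.detect_outliers`."""
    return atlas.detect_outliers(scan)
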