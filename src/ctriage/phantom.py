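"""Synthetic head-CT phantom cohorts with injected stroke-like lesions.

The phantoms are stylized heads built from homogeneous tissue compartments —
an ellipsoidal skull shell enclosing brain parenchyma (cortical grey rind
over a white-matter core) with a central ventricle cavity — plus additive
independent Gaussian scanner noise.  Four stroke-related lesion classes can
be injected with known ground-truth masks:

``chronic_ischemia``
    Large wedge-shaped cortical/subcortical hypodensity mimicking an old
    territorial infarct (obvious finding; default -20 HU).
``subacute_ischemia``
    Smaller, shallower wedge hypodensity mimicking early demarcation
    (subtle finding; default -10 HU).
``lacunar_dwm``
    Small deep-white-matter sphere (clinical criterion: defects > 15 mm
    diameter; default radius 9 mm, -15 HU).
``hvs``
    Hyperdense-vessel sign: a thin high-density tube near the skull base
    standing in for an occluding thrombus in a proximal artery
    (default +40 HU, sized so tube HU exceeds 1.2x contralateral brain HU
    on the noise-free phantom).

Phantoms are generated directly in template space (identity registration
ground truth); a rigid perturbation for registration testing is applied
separately via :mod:`ctriage.registration`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import BinaryMask, Volume, compute_brain_mask, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "LESION_KINDS",
    "DEFAULT_TISSUE_HU",
    "make_normal_phantom",
    "inject_lesion",
    "default_lesion_spec",
    "make_cohort",
]

#: Conventional CT attenuation of the modelled compartments (HU).
DEFAULT_TISSUE_HU = {
    "air": -1000.0,
    "skull": 800.0,
    "brain_white": 25.0,
    "brain_grey": 38.0,
    "ventricle": 8.0,
}

#: Integer codes in the tissue label map.
TISSUE_LABELS = {"air": 0, "skull": 1, "brain_grey": 2, "brain_white": 3, "ventricle": 4}

LESION_KINDS = ("chronic_ischemia", "subacute_ischemia", "lacunar_dwm", "hvs")

#: Signed HU offsets per lesion class: chronic obvious, subacute subtle.
DEFAULT_LESION_DELTA_HU = {
    "chronic_ischemia": -20.0,
    "subacute_ischemia": -10.0,
    "lacunar_dwm": -15.0,
    "hvs": +40.0,
}

#: Characteristic size (mm) per lesion class: wedge chord, sphere radius,
#: tube length.  Chosen once from typical imaging appearance.
DEFAULT_LESION_SIZE_MM = {
    "chronic_ischemia": 25.0,
    "subacute_ischemia": 20.0,
    "lacunar_dwm": 9.0,
    "hvs": 40.0,
}

#: Default lesion centers as fractions of the brain bounding box.
DEFAULT_LESION_CENTER_FRAC = {
    "chronic_ischemia": (0.75, 0.65, 0.60),
    "subacute_ischemia": (0.25, 0.60, 0.55),
    "lacunar_dwm": (0.40, 0.45, 0.55),
    "hvs": (0.60, 0.50, 0.25),
}

HVS_TUBE_RADIUS_MM = 3.5


class PhantomSpecError(ValueError):
    """Raised when a phantom or lesion specification is invalid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a normal head phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    noise_sd_hu: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_hu < 0:
            raise PhantomSpecError("noise_sd_hu must be >= 0")
        missing = set(DEFAULT_TISSUE_HU) - set(self.tissue_hu)
        if missing:
            raise PhantomSpecError(f"tissue_hu missing compartments: {sorted(missing)}")
        if not all(np.isfinite(list(self.tissue_hu.values()))):
            raise PhantomSpecError("tissue HU means must be finite")
        if min(self.grid_shape) < 16:
            raise PhantomSpecError(
                f"grid {self.grid_shape} too small to contain the skull ellipsoid"
            )


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one injected lesion.

    ``center_frac`` positions the lesion inside the brain bounding box;
    ``size_mm`` is the class's characteristic size (wedge chord at the
    cortex, sphere radius, or tube length); ``delta_hu`` is the signed HU
    offset (negative for the ischemic classes, positive for hvs).
    """

    kind: str
    center_frac: tuple[float, float, float] = (0.5, 0.5, 0.5)
    size_mm: float = 10.0
    delta_hu: float = -15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise PhantomSpecError(f"unknown lesion kind {self.kind!r}; one of {LESION_KINDS}")
        if self.size_mm <= 0:
            raise PhantomSpecError("size_mm must be > 0")
        if self.kind == "hvs":
            if self.delta_hu <= 0:
                raise PhantomSpecError("hvs lesions must be hyperdense (delta_hu > 0)")
        elif self.delta_hu >= 0 and self.delta_hu != 0.0:
            raise PhantomSpecError(f"{self.kind} lesions must be hypodense (delta_hu < 0)")


def default_lesion_spec(kind: str, seed: int = 0) -> LesionSpec:
    """The study-default lesion of a given class."""
    return LesionSpec(
        kind=kind,
        center_frac=DEFAULT_LESION_CENTER_FRAC[kind],
        size_mm=DEFAULT_LESION_SIZE_MM[kind],
        delta_hu=DEFAULT_LESION_DELTA_HU[kind],
        seed=seed,
    )


def _head_geometry(shape: tuple[int, int, int]):
    """Voxel-index coordinate grids and ellipsoid semi-axes (voxels)."""
    idx = np.indices(shape).astype(np.float64)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    # Semi-axes as fractions of the half-extent: outer skull, inner skull
    # (= brain surface), grey/white boundary, lateral-ventricle pair.
    half = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    outer = half * np.array([0.88, 0.92, 0.80])
    inner = outer - 2.0  # ~2-voxel calvarium
    gw = inner * 0.82  # grey rind outside, white core inside
    vent = inner * np.array([0.10, 0.28, 0.14])
    return idx, center, outer, inner, gw, vent


def _inside_ellipsoid(idx, center, semi) -> np.ndarray:
    d = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d <= 1.0


def make_normal_phantom(spec: PhantomSpec) -> tuple[Volume, np.ndarray]:
    """Generate a normal head phantom and its tissue label map.

    Deterministic given ``spec.seed``.  With ``noise_sd_hu == 0`` every
    voxel equals its compartment's mean HU exactly.
    """
    shape = tuple(spec.grid_shape)
    idx, center, outer, inner, gw, vent = _head_geometry(shape)
    if np.any(inner <= 2) or np.any(vent < 1):
        raise PhantomSpecError(f"grid {shape} too small for the head geometry")

    labels = np.full(shape, TISSUE_LABELS["air"], dtype=np.uint8)
    labels[_inside_ellipsoid(idx, center, outer)] = TISSUE_LABELS["skull"]
    brain = _inside_ellipsoid(idx, center, inner)
    labels[brain] = TISSUE_LABELS["brain_grey"]
    labels[_inside_ellipsoid(idx, center, gw)] = TISSUE_LABELS["brain_white"]
    # paired lateral ventricles: offset off the midline and slightly posterior
    for side in (-1.0, +1.0):
        vc = center + np.array([side * 0.22 * inner[0], 0.08 * inner[1], 0.05 * inner[2]])
        labels[_inside_ellipsoid(idx, vc, vent)] = TISSUE_LABELS["ventricle"]

    hu = np.empty(shape, dtype=np.float64)
    for name, code in TISSUE_LABELS.items():
        hu[labels == code] = spec.tissue_hu[name]
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=shape)
    return Volume(hu, spacing=spec.spacing_mm), labels


def _brain_region(labels: np.ndarray) -> np.ndarray:
    return (
        (labels == TISSUE_LABELS["brain_grey"])
        | (labels == TISSUE_LABELS["brain_white"])
        | (labels == TISSUE_LABELS["ventricle"])
    )


def _lesion_mask(v: Volume, labels: np.ndarray, lesion: LesionSpec) -> np.ndarray:
    """Boolean lesion region in voxel space (before feathering)."""
    brain = _brain_region(labels)
    if not brain.any():
        raise PhantomSpecError("phantom has no brain compartment")
    nz = np.array(np.nonzero(brain))
    bb_lo, bb_hi = nz.min(axis=1), nz.max(axis=1)
    center_vox = bb_lo + np.asarray(lesion.center_frac) * (bb_hi - bb_lo)
    spacing = v.spacing
    idx = np.indices(v.shape).astype(np.float64)
    # mm offsets from lesion center
    d_mm = [(idx[a] - center_vox[a]) * spacing[a] for a in range(3)]
    dist_mm = np.sqrt(sum(d * d for d in d_mm))

    if lesion.kind == "lacunar_dwm":
        region = dist_mm <= lesion.size_mm
    elif lesion.kind in ("chronic_ischemia", "subacute_ischemia"):
        # Wedge: cone sector with apex at the brain centroid, axis through
        # the requested cortical point, spanning ~size_mm at the cortex and
        # covering the outer half of the radial extent.
        centroid = nz.mean(axis=1)
        axis_mm = (center_vox - centroid) * spacing
        axis_len = np.linalg.norm(axis_mm)
        if axis_len < 1e-6:
            raise PhantomSpecError("wedge lesion center coincides with brain centroid")
        axis_mm = axis_mm / axis_len
        r_mm = [(idx[a] - centroid[a]) * spacing[a] for a in range(3)]
        r_len = np.sqrt(sum(r * r for r in r_mm))
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_angle = sum(r_mm[a] * axis_mm[a] for a in range(3)) / np.maximum(r_len, 1e-9)
        half_angle = np.arcsin(min(0.95, lesion.size_mm / (2.0 * axis_len)))
        region = brain & (cos_angle >= np.cos(half_angle)) & (r_len >= 0.5 * axis_len)
    elif lesion.kind == "hvs":
        # Tube of length size_mm along the second axis near the skull base.
        along = d_mm[1]
        radial = np.sqrt(d_mm[0] ** 2 + d_mm[2] ** 2)
        region = (np.abs(along) <= lesion.size_mm / 2.0) & (radial <= HVS_TUBE_RADIUS_MM)
    else:  # pragma: no cover - guarded by LesionSpec
        raise PhantomSpecError(f"unknown lesion kind {lesion.kind!r}")

    region = region & brain
    if not region.any():
        raise PhantomSpecError(
            f"{lesion.kind} lesion at {lesion.center_frac} falls outside the brain"
        )
    return region


def inject_lesion(
    v: Volume, labels: np.ndarray, lesion: LesionSpec
) -> tuple[Volume, BinaryMask]:
    """Add a lesion to a phantom; returns the modified volume and the exact
    ground-truth mask.  The input volume is unchanged.

    ``delta_hu`` is applied fully inside the mask and at half amplitude on
    the 1-voxel boundary ring outside it (feathering), so injected edges are
    not perfectly sharp.
    """
    from scipy import ndimage

    region = _lesion_mask(v, labels, lesion)
    out = v.values.copy()
    if lesion.delta_hu != 0.0:
        feather = ndimage.binary_dilation(region, structure=np.ones((3, 3, 3), bool))
        feather &= ~region
        feather &= _brain_region(labels)
        out[region] += lesion.delta_hu
        out[feather] += 0.5 * lesion.delta_hu
    return v.with_values(out), BinaryMask.like(v, region)


def _subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_cohort(
    n_train_normal: int,
    n_test_normal: int,
    n_test_lesion_per_kind: dict[str, int],
    spec: PhantomSpec,
    seed: int,
    out_dir: str | os.PathLike,
    n_val_normal: int = 0,
    n_val_lesion_per_kind: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Simulate a study cohort on disk and return its manifest.

    Splits mirror the study design: normal training scans for atlas fitting,
    an optional mixed validation split for threshold calibration, and a test
    split of normals plus the four lesion classes.  Per-subject seeds are
    derived deterministically from the master seed, so the same call
    reproduces a byte-identical cohort.

    The manifest CSV (``manifest.csv`` in ``out_dir``) has columns
    ``scan_path, subject_id, truth_label, lesion_mask_path, split, lesion_kind``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    subject = 0

    def emit(split: str, kind: str | None) -> None:
        nonlocal subject
        sseed = _subject_seed(seed, subject)
        sid = f"sub-{subject:04d}"
        vol, labels = make_normal_phantom(replace(spec, seed=sseed))
        mask_path = ""
        if kind is None:
            truth = "normal"
        else:
            truth = "pathological"
            vol, mask = inject_lesion(vol, labels, default_lesion_spec(kind, seed=sseed))
            mask_path = str(out / f"{sid}_lesion.nii.gz")
            write_mask(mask, mask_path)
        scan_path = str(out / f"{sid}.nii.gz")
        write_volume(vol, scan_path)
        rows.append(
            {
                "scan_path": scan_path,
                "subject_id": sid,
                "truth_label": truth,
                "lesion_mask_path": mask_path,
                "split": split,
                "lesion_kind": kind or "normal",
            }
        )
        subject += 1

    for _ in range(n_train_normal):
        emit("train", None)
    for _ in range(n_val_normal):
        emit("validation", None)
    for kind, count in sorted((n_val_lesion_per_kind or {}).items()):
        for _ in range(count):
            emit("validation", kind)
    for _ in range(n_test_normal):
        emit("test", None)
    for kind, count in sorted(n_test_lesion_per_kind.items()):
        for _ in range(count):
            emit("test", kind)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def phantom_brain_mask(labels: np.ndarray, ref: Volume) -> BinaryMask:
    """Ground-truth brain mask from a tissue label map (oracle for
    :func:`ctriage.volume.compute_brain_mask` on noise-free phantoms)."""
    return BinaryMask.like(ref, _brain_region(labels))
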