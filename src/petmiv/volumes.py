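"""Grid-aware volume containers and NIfTI-1 I/O.

All analysis happens on a single voxel grid (PET space).  Volumes carry
their spacing and origin but are never resampled: combining two volumes
whose grids disagree is an error, not a silent interpolation.  The axis
convention is ``data[i, j, k]`` with the physical center of voxel
``(i, j, k)`` at ``origin + index * spacing`` (axes i→x, j→y, k→z; in the
synthetic phantoms z increases toward the lung apex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeError",
    "VolumeLoadError",
    "GridMismatchError",
    "ScalarVolume",
    "MaskVolume",
    "InjectionRecord",
    "F18_HALF_LIFE_MIN",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "require_same_grid",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: Tolerance (mm) within which two grids' spacings are considered equal.
SPACING_TOL_MM = 1e-3


class VolumeError(ValueError):
    """Invalid volume content or metadata."""


class VolumeLoadError(VolumeError):
    """A file could not be loaded as a valid 3D volume."""


class GridMismatchError(VolumeError):
    """Two volumes do not live on the same voxel grid."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise VolumeError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing


@dataclass(frozen=True)
class ScalarVolume:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    data
        3D array of finite reals.  Units are arbitrary activity units for
        non-attenuation-corrected PET, kBq/mL for calibrated activity,
        dimensionless for parametric (reference-normalized) images.
    spacing
        Per-axis voxel edge length in mm, all strictly positive.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise VolumeError(f"expected a 3D volume, got {data.ndim} dimension(s)")
        n_bad = int(np.size(data) - np.count_nonzero(np.isfinite(data)))
        if n_bad:
            raise VolumeError(f"volume contains {n_bad} non-finite voxel(s)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (= product of spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        """Same grid, new voxel values."""
        return replace(self, data=data)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class MaskVolume:
    """A binary region on a regular grid (lung field, reference area, VOI...)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"expected a 3D mask, got {data.ndim} dimension(s)")
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise VolumeError(f"mask values must be 0/1, found {uniq[:10]}")
        object.__setattr__(self, "data", data.astype(np.uint8))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_cm3

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass(frozen=True)
class InjectionRecord:
    """Tracer injection bookkeeping used only for SUV scaling.

    Attributes
    ----------
    injected_activity_mbq
        Administered activity at injection time, MBq.
    body_weight_kg
        Patient body weight, kg.
    injection_to_scan_min
        Uptake interval between injection and scan start, minutes.
    half_life_min
        Isotope physical half-life, minutes (default F-18).
    """

    injected_activity_mbq: float
    body_weight_kg: float
    injection_to_scan_min: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self):
        for name in ("injected_activity_mbq", "body_weight_kg", "half_life_min"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise VolumeError(f"{name} must be strictly positive, got {v}")
        if not (np.isfinite(self.injection_to_scan_min) and self.injection_to_scan_min >= 0):
            raise VolumeError("injection_to_scan_min must be nonnegative")

    @property
    def decay_corrected_dose_kbq(self) -> float:
        """Injected dose decayed to scan time, in kBq."""
        decay = 2.0 ** (-self.injection_to_scan_min / self.half_life_min)
        return self.injected_activity_mbq * 1000.0 * decay


def require_same_grid(a, b, what: str = "volumes") -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share one grid."""
    if a.shape != b.shape:
        raise GridMismatchError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    da = np.asarray(a.spacing) - np.asarray(b.spacing)
    if np.abs(da).max() > SPACING_TOL_MM:
        raise GridMismatchError(
            f"{what}: spacing mismatch {a.spacing} vs {b.spacing} "
            f"(tolerance {SPACING_TOL_MM} mm)"
        )


def _load_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeLoadError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeLoadError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return np.asarray(data, dtype=np.float64), spacing, origin


def read_volume(path) -> ScalarVolume:
    """Read a NIfTI-1 file as a :class:`ScalarVolume`.

    Raises
    ------
    VolumeLoadError
        If the file is missing, not 3D, or contains non-finite voxels
        (the error message reports how many voxels are affected).
    """
    data, spacing, origin = _load_nifti(path)
    n_bad = int(np.size(data) - np.count_nonzero(np.isfinite(data)))
    if n_bad:
        raise VolumeLoadError(f"{path}: {n_bad} non-finite voxel(s) in image data")
    try:
        return ScalarVolume(data, spacing, origin)
    except VolumeError as exc:
        raise VolumeLoadError(f"{path}: {exc}") from exc


def write_volume(volume: ScalarVolume | MaskVolume, path) -> None:
    """Write a volume as NIfTI-1, preserving spacing and origin."""
    data = volume.data
    if isinstance(volume, MaskVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path, reference_grid: ScalarVolume | MaskVolume) -> MaskVolume:
    """Read a NIfTI-1 mask and check it against a reference grid.

    Any nonzero voxel is coerced to 1; a warning is emitted when values
    other than {0, 1} are present (0/255 exports are common).  Shape must
    match the reference exactly and spacing must agree within 1e-3 mm.
    """
    data, spacing, origin = _load_nifti(path)
    n_bad = int(np.size(data) - np.count_nonzero(np.isfinite(data)))
    if n_bad:
        raise VolumeLoadError(f"{path}: {n_bad} non-finite voxel(s) in mask data")
    uniq = np.unique(data)
    if not np.isin(uniq, (0, 1)).all():
        warnings.warn(
            f"{path}: mask values {uniq[:10].tolist()} are not 0/1; "
            "binarizing (any nonzero -> 1)",
            UserWarning,
            stacklevel=2,
        )
    mask = MaskVolume((data != 0).astype(np.uint8), spacing, origin)
    require_same_grid(mask, reference_grid, what=f"mask {path} vs reference grid")
    return mask


# Masks and scalar volumes share one on-disk representation.
write_mask = write_volume
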