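"""3D volume container, NIfTI input/output, and Gaussian pre-smoothing.

Conventions used throughout the package:

* Voxel indices are 0-based; world coordinates are millimetres, obtained from
  the NIfTI voxel-to-world affine.
* Tissue classes are ordered ``(GM, WM, CSF, other)`` everywhere (probability
  arrays, priors, cluster statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import LoadError

#: Canonical tissue-class ordering shared by priors, probabilities and stats.
CLASS_NAMES = ("GM", "WM", "CSF", "other")

#: FWHM -> standard deviation conversion for a Gaussian, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.data, dtype=np.float64)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


@dataclass
class TissuePriorSet:
    """Four aligned tissue probability volumes, class order ``CLASS_NAMES``.

    ``priors`` has shape ``(nx, ny, nz, 4)``; values lie in [0, 1] and sum to
    one at every voxel (renormalized on construction).
    """

    priors: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        p = np.asarray(self.priors, dtype=np.float64)
        if p.ndim != 4 or p.shape[3] != 4:
            raise ValueError("priors must have shape (nx, ny, nz, 4)")
        if np.any(~np.isfinite(p)):
            raise LoadError("priors contain non-finite values")
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise LoadError("prior values must lie in [0, 1]")
        p = np.clip(p, 0.0, 1.0)
        total = p.sum(axis=3, keepdims=True)
        # Voxels with no prior mass default to the "other" class.
        empty = total[..., 0] <= 1e-12
        p[empty] = (0.0, 0.0, 0.0, 1.0)
        total[empty[..., None]] = 1.0
        self.priors = p / total
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.priors.shape[:3]

    def class_volume(self, k: int) -> Volume:
        return Volume(self.priors[..., k], self.affine)


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI volume, preserving header spacing and affine.

    Raises :class:`LoadError` on missing files, non-3D images, and NaN/Inf
    voxels (the error message names the offending file).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise LoadError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise LoadError(f"expected 3D volume, got {data.ndim}D in {path}")
    if np.issubdtype(data.dtype, np.floating) and np.any(~np.isfinite(data)):
        raise LoadError(f"volume {path} contains NaN or Inf voxels")
    return Volume(data, np.asarray(img.affine))


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; round-trips bit-identically via read_volume."""
    path = Path(path)
    if not path.parent.exists():
        raise LoadError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(v.data), v.affine)
    img.header.set_data_dtype(v.data.dtype)
    nib.save(img, str(path))


def read_priors(path: str | Path) -> TissuePriorSet:
    """Read a tissue-prior set stored as one 4D NIfTI (class as 4th axis)."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 4:
        raise LoadError(
            f"expected a 4D prior image with 4 classes, got shape {data.shape} in {path}"
        )
    return TissuePriorSet(data.astype(np.float64), np.asarray(img.affine))


def read_priors_split(paths: Sequence[str | Path]) -> TissuePriorSet:
    """Read a prior set from four 3D files in ``CLASS_NAMES`` order."""
    if len(paths) != 4:
        raise LoadError("expected exactly four prior files (GM, WM, CSF, other)")
    vols = [read_volume(p) for p in paths]
    for v in vols[1:]:
        if v.shape != vols[0].shape:
            raise LoadError("prior volumes do not share a grid")
    stack = np.stack([v.astype_float() for v in vols], axis=3)
    return TissuePriorSet(stack, vols[0].affine)


def write_priors(priors: TissuePriorSet, path: str | Path) -> None:
    img = nib.Nifti1Image(priors.priors.astype(np.float32), priors.affine)
    nib.save(img, str(Path(path)))


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with the kernel width given in mm FWHM.

    Per-axis sigma (in voxels) is ``fwhm / (2 sqrt(2 ln 2)) / spacing``;
    boundaries are handled by reflection so that interior-supported mass is
    conserved. ``fwhm_mm = 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return v.copy()
    sigmas = [fwhm_mm / FWHM_TO_SIGMA / s for s in v.spacing]
    smoothed = ndimage.gaussian_filter(v.astype_float(), sigma=sigmas, mode="reflect")
    return Volume(smoothed, v.affine.copy())
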