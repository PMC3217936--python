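"""Volume input/output and the in-scope CSF preprocessing filter.

Volumes are NIfTI-1 files handled through nibabel. The affine is carried
opaquely from input to every output; the voxel grid is addressed with 0-based
indices and all millimetre sizes elsewhere in the package are converted to
voxels with :func:`mm_to_voxels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityVolume",
    "BrainMask",
    "read_volume",
    "write_volume",
    "hysteresis_csf_filter",
    "mm_to_voxels",
]

#: 3x3x3 structuring element for 26-connectivity.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 3x3x3 structuring element for 6-connectivity (face neighbours).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class IntensityVolume:
    """A 3D scalar image on a voxel grid with millimetre spacing.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    spacing:
        Per-axis voxel size in mm, strictly positive.
    affine:
        4x4 voxel-to-world matrix, carried opaquely.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 8:
            raise ValueError(f"all dimensions must be >= 8, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BrainMask:
    """Binary brain (or hemisphere) mask on the same grid as its volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError("mask is empty")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def mm_to_voxels(size_mm: float, spacing: float) -> int:
    """Convert a millimetre size to voxels: round(size/spacing), minimum 1."""
    return max(1, int(round(size_mm / spacing)))


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a 3D NIfTI-1 volume.

    Spacing comes from the header zooms. A warning is emitted for strongly
    anisotropic grids (max/min spacing ratio > 1.5); the pipeline assumes a
    near-isotropic ~1 mm grid such as produced by super-resolution
    reconstruction of orthogonal fast spin-echo stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if max(spacing) / min(spacing) > 1.5:
        warnings.warn(
            f"strongly anisotropic spacing {spacing}; the method assumes a "
            "near-isotropic grid (resample upstream)",
            stacklevel=2,
        )
    return IntensityVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing,
                           affine=np.asarray(img.affine))


def write_volume(vol, path: str | Path) -> None:
    """Write an IntensityVolume, BrainMask or FeatureField as NIfTI-1.

    Masks are written as 0/1 uint8; scalar fields keep their sign and dtype
    (float64). Re-reading restores data and spacing exactly.
    """
    path = Path(path)
    data = np.asarray(vol.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float64)
    affine = np.asarray(getattr(vol, "affine", np.eye(4)))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def hysteresis_csf_filter(
    vol: IntensityVolume, mask: BrainMask, low: float, high: float
) -> BrainMask:
    """Remove bright CSF from a brain mask by hysteresis thresholding.

    In T2w infant images CSF is the brightest compartment; voxels >= ``high``
    seed the removal, and any voxel >= ``low`` that is 26-connected to a seed
    (through voxels >= ``low``) is removed as well. Thresholds are in the
    volume's intensity units and are chosen per subject.

    Returns a new mask, always a subset of the input mask.
    """
    if low > high:
        raise ValueError(f"low threshold must be <= high ({low} > {high})")
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: {vol.shape} vs {mask.shape}")
    candidate = vol.data >= low
    seeds = vol.data >= high
    labels, n = ndimage.label(candidate, structure=STRUCT_26)
    if n == 0:
        return BrainMask(mask.data.copy(), spacing=mask.spacing, affine=mask.affine)
    seeded = np.zeros(n + 1, dtype=bool)
    seeded[np.unique(labels[seeds])] = True
    seeded[0] = False
    removed = seeded[labels]
    return BrainMask(mask.data & ~removed, spacing=mask.spacing, affine=mask.affine)
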