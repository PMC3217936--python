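"""Quantitative validation instruments.

Three measures are provided, matching how grey-white segmentations are
commonly appraised: the Dice overlap between two white-matter masks, the
voxelwise distance between an automatic and a reference interface (surface
reconstruction error), and frequency distributions of distances from sulcal
landmarks to a segmentation, compared across segmentations with the Pearson
correlation of the histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from gwseg.surface_model import DigitalRegion
from gwseg.volume_io import BrainMask

__all__ = [
    "LandmarkSet",
    "DistanceDistribution",
    "SurfaceDistanceResult",
    "dice_coefficient",
    "surface_distance_map",
    "landmark_distance_distribution",
    "distribution_correlation",
    "write_landmarks",
    "read_landmarks",
]


@dataclass
class LandmarkSet:
    """Points on a sulcal sheet with their unit normals (voxel coordinates)."""

    points: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if self.points.shape != self.normals.shape or self.points.shape[1] != 3:
            raise ValueError("points and normals must both be (K, 3)")
        norms = np.linalg.norm(self.normals, axis=1)
        if self.points.shape[0] == 0:
            raise ValueError("landmark set is empty")
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class DistanceDistribution:
    """Normalized histogram of landmark-to-segmentation distances (mm)."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.frequencies.shape[0] != self.bin_edges.shape[0] - 1:
            raise ValueError("frequencies must have len(bin_edges) - 1 entries")
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")


@dataclass
class SurfaceDistanceResult:
    distances: np.ndarray  # mm, one per boundary voxel of the automatic surface
    mean: float
    sd: float


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BrainMask):
        return mask.data
    if isinstance(mask, DigitalRegion):
        return mask.voxels
    return np.asarray(mask).astype(bool)


def dice_coefficient(a, m) -> float:
    """Dice overlap 2|A∩M| / (|A| + |M|) between two masks."""
    a = _as_bool(a)
    m = _as_bool(m)
    if a.shape != m.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {m.shape}")
    na = int(a.sum())
    nm = int(m.sum())
    if na == 0 and nm == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & m).sum()) / (na + nm)


def surface_distance_map(
    auto: DigitalRegion, manual: DigitalRegion, spacing=None, symmetric: bool = False
) -> SurfaceDistanceResult:
    """Distance (mm) from each boundary voxel of ``auto`` to the ``manual`` surface.

    The reconstruction error is the mean ± sd of the Euclidean distance,
    evaluated via the distance transform of the reference boundary. With
    ``symmetric=True`` distances in both directions are pooled.
    """
    spacing = tuple(spacing) if spacing is not None else auto.spacing
    a_bnd = auto.boundary_voxel_mask()
    m_bnd = manual.boundary_voxel_mask()
    if not a_bnd.any() or not m_bnd.any():
        raise ValueError("empty boundary")
    dt_m = ndimage.distance_transform_edt(~m_bnd, sampling=spacing)
    dists = dt_m[a_bnd]
    if symmetric:
        dt_a = ndimage.distance_transform_edt(~a_bnd, sampling=spacing)
        dists = np.concatenate([dists, dt_a[m_bnd]])
    return SurfaceDistanceResult(dists, float(dists.mean()), float(dists.std()))


def landmark_distance_distribution(
    landmarks: LandmarkSet,
    seg_boundary: DigitalRegion,
    max_dist: float = 15.0,
    bin_width: float = 0.5,
    spacing=None,
    method: str = "normal",
) -> DistanceDistribution:
    """Distribution of distances from sulcal landmarks to a segmentation surface.

    With ``method="normal"`` each landmark is probed along ± its normal in
    steps of half the minimum voxel size until the segmentation boundary is
    hit; landmarks with no hit within ``max_dist`` fall into the last
    (overflow) bin, producing the heavy tails seen where folds widen. With
    ``method="nearest"`` the unconstrained nearest boundary voxel is used.
    """
    spacing = tuple(spacing) if spacing is not None else seg_boundary.spacing
    bnd = seg_boundary.boundary_voxel_mask()
    if not bnd.any():
        raise ValueError("empty boundary")
    sp = np.asarray(spacing, dtype=float)
    pts = landmarks.points
    if method == "nearest":
        dt = ndimage.distance_transform_edt(~bnd, sampling=spacing)
        idx = np.clip(np.round(pts).astype(int), 0, np.array(bnd.shape) - 1)
        dists = dt[idx[:, 0], idx[:, 1], idx[:, 2]]
    elif method == "normal":
        step = 0.5 * float(min(spacing))
        n_steps = int(np.ceil(max_dist / step))
        dists = np.full(len(landmarks), max_dist, dtype=float)
        shape = np.array(bnd.shape)
        for i in range(len(landmarks)):
            p = pts[i]
            nrm = landmarks.normals[i]
            for k in range(n_steps + 1):
                t = k * step
                hit = False
                for sgn in (1.0, -1.0):
                    q = p + sgn * t * nrm / sp  # mm step expressed in voxels
                    qi = np.round(q).astype(int)
                    if np.all(qi >= 0) and np.all(qi < shape) and bnd[qi[0], qi[1], qi[2]]:
                        hit = True
                        break
                if hit:
                    dists[i] = t
                    break
    else:
        raise ValueError(f"unknown method {method!r}")
    dists = np.minimum(dists, max_dist)
    edges = np.arange(0.0, max_dist + bin_width + 1e-9, bin_width)
    counts, _ = np.histogram(np.clip(dists, 0, edges[-1] - 1e-9), bins=edges)
    freq = counts / counts.sum()
    return DistanceDistribution(edges, freq, n_samples=len(landmarks))


def distribution_correlation(d1: DistanceDistribution, d2: DistanceDistribution) -> float:
    """Pearson correlation between two distance-frequency distributions."""
    if d1.bin_edges.shape != d2.bin_edges.shape or not np.allclose(d1.bin_edges, d2.bin_edges):
        raise ValueError("distributions must share identical binning")
    f1, f2 = d1.frequencies, d2.frequencies
    if f1.std() == 0 or f2.std() == 0:
        raise ValueError("zero-variance distribution")
    return float(np.corrcoef(f1, f2)[0, 1])


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write landmarks as TSV with columns x, y, z, nx, ny, nz (voxel coords)."""
    df = pd.DataFrame(
        np.hstack([landmarks.points, landmarks.normals]),
        columns=["x", "y", "z", "nx", "ny", "nz"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_landmarks(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path, sep="\t")
    return LandmarkSet(df[["x", "y", "z"]].to_numpy(), df[["nx", "ny", "nz"]].to_numpy())
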