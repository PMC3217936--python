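"""Digital regions and their topology machinery.

A segmented object is a :class:`DigitalRegion`: a set of voxels whose
"surface" is the closed set of exposed facets between region and complement.
This module provides the neighbour counts and the local homotopy (simple
point) test that the deformable surfaces rely on, an Euler characteristic to
verify spherical topology, and a marching-cubes mesh extraction for
rendering/export.

Connectivity convention of the homotopy test: by default the growing region
(set S of region neighbours) uses 6-connectivity and the background (set B)
26-connectivity. This is the pairing consistent with the cubical-complex
boundary realization used by :func:`euler_characteristic`: under it, growing a
region by accepted additions provably keeps the complement's boundary a
topological sphere. The classic swapped pair (region 26, background 6) is
available via ``region_connectivity=26``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from gwseg._kernels import simple_point_local

__all__ = [
    "DigitalRegion",
    "count_region_neighbors",
    "is_homotopic_addition",
    "euler_characteristic",
    "extract_interface_mesh",
]


@dataclass
class DigitalRegion:
    """A voxel set together with its boundary facets.

    The boundary is defined implicitly: every 6-neighbour facet with exactly
    one side inside the region. It is recomputable from ``voxels`` at any
    time, so only the membership array is stored.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("DigitalRegion requires a 3D boolean array")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def size(self) -> int:
        return int(self.voxels.sum())

    def face_adjacent_pairs(self) -> int:
        """Number of in-region voxel pairs sharing a facet."""
        v = self.voxels
        return int(sum((v[ax_slice] & v[ax_slice_next]).sum()
                       for ax_slice, ax_slice_next in (
                           ((slice(None, -1), slice(None), slice(None)),
                            (slice(1, None), slice(None), slice(None))),
                           ((slice(None), slice(None, -1), slice(None)),
                            (slice(None), slice(1, None), slice(None))),
                           ((slice(None), slice(None), slice(None, -1)),
                            (slice(None), slice(None), slice(1, None))),
                       )))

    def boundary_facet_count(self) -> int:
        """Number of exposed facets: 6*|region| - 2*(face-adjacent pairs)."""
        return 6 * self.size - 2 * self.face_adjacent_pairs()

    def boundary_facets(self) -> np.ndarray:
        """Exposed facets as an (M, 4) int array (x, y, z, face id).

        Face ids 0..5 encode -x, +x, -y, +y, -z, +z of the in-region voxel.
        Facets on the grid border are exposed (complement assumed outside).
        """
        v = np.pad(self.voxels, 1)
        core = v[1:-1, 1:-1, 1:-1]
        rows = []
        shifts = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        for face_id, (dx, dy, dz) in enumerate(shifts):
            nb = v[1 + dx:v.shape[0] - 1 + dx,
                   1 + dy:v.shape[1] - 1 + dy,
                   1 + dz:v.shape[2] - 1 + dz]
            xs, ys, zs = np.nonzero(core & ~nb)
            rows.append(np.stack([xs, ys, zs, np.full_like(xs, face_id)], axis=1))
        return np.concatenate(rows, axis=0)

    def boundary_voxel_mask(self) -> np.ndarray:
        """Region voxels exposing at least one facet."""
        v = np.pad(self.voxels, 1)
        inner = (
            v[:-2, 1:-1, 1:-1] & v[2:, 1:-1, 1:-1]
            & v[1:-1, :-2, 1:-1] & v[1:-1, 2:, 1:-1]
            & v[1:-1, 1:-1, :-2] & v[1:-1, 1:-1, 2:]
        )
        return self.voxels & ~inner


def _local_cube(voxels: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """3x3x3 occupancy around target; cells outside the grid count as background."""
    occ = np.zeros((3, 3, 3), dtype=bool)
    x, y, z = target
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                px, py, pz = x + dx, y + dy, z + dz
                if (0 <= px < voxels.shape[0] and 0 <= py < voxels.shape[1]
                        and 0 <= pz < voxels.shape[2]):
                    occ[dx + 1, dy + 1, dz + 1] = voxels[px, py, pz]
    return occ


def _check_target(voxels: np.ndarray, target) -> tuple[int, int, int]:
    target = tuple(int(t) for t in target)
    if len(target) != 3 or not all(0 <= t < s for t, s in zip(target, voxels.shape)):
        raise IndexError(f"target {target} outside grid {voxels.shape}")
    return target


def count_region_neighbors(region: DigitalRegion, target) -> int:
    """Number of 26-neighbours of ``target`` inside the region (0..26).

    ``target`` must not itself belong to the region.
    """
    target = _check_target(region.voxels, target)
    if region.voxels[target]:
        raise ValueError(f"target {target} already in region")
    occ = _local_cube(region.voxels, target)
    occ[1, 1, 1] = False
    return int(occ.sum())


def is_homotopic_addition(region: DigitalRegion, target, region_connectivity: int = 6) -> bool:
    """True iff adding ``target`` to the region preserves its topology.

    Local simple-point test: the region neighbours S and the background
    neighbours B of the target must each form one and only one connected
    component, counted with the topological numbers of the chosen
    connectivity pair. The 6-connected side is counted in the geodesic
    18-neighbourhood (components must touch a face neighbour), the
    26-connected side in the full 26-neighbourhood. Cells outside the grid
    count as background.
    """
    if region_connectivity not in (6, 26):
        raise ValueError("region_connectivity must be 6 or 26")
    target = _check_target(region.voxels, target)
    if region.voxels[target]:
        raise ValueError(f"target {target} already in region")
    occ = _local_cube(region.voxels, target)
    return bool(simple_point_local(occ, region_connectivity == 6))


def euler_characteristic(region: DigitalRegion | np.ndarray) -> int:
    """Euler characteristic of the region's boundary surface.

    Computed from the cubical complex of the solid: chi(boundary) =
    2*(V - E + F - C) with vertices, edges, faces and cubes of the voxel
    complex. A ball gives 2, a solid torus 0. The region must not touch the
    grid border (pad first).
    """
    vox = region.voxels if isinstance(region, DigitalRegion) else np.asarray(region, bool)
    if not vox.any():
        raise ValueError("empty region")
    if (vox[0].any() or vox[-1].any() or vox[:, 0].any() or vox[:, -1].any()
            or vox[:, :, 0].any() or vox[:, :, -1].any()):
        raise ValueError("region touches grid border; pad first")
    p = np.pad(vox, 1)
    c = int(vox.sum())
    pairs = (
        int((vox[:-1] & vox[1:]).sum())
        + int((vox[:, :-1] & vox[:, 1:]).sum())
        + int((vox[:, :, :-1] & vox[:, :, 1:]).sum())
    )
    f = 6 * c - pairs
    v = int((p[:-1, :-1, :-1] | p[1:, :-1, :-1] | p[:-1, 1:, :-1] | p[1:, 1:, :-1]
             | p[:-1, :-1, 1:] | p[1:, :-1, 1:] | p[:-1, 1:, 1:] | p[1:, 1:, 1:]).sum())
    e_x = int((p[1:-1, :-1, :-1] | p[1:-1, 1:, :-1]
               | p[1:-1, :-1, 1:] | p[1:-1, 1:, 1:]).sum())
    e_y = int((p[:-1, 1:-1, :-1] | p[1:, 1:-1, :-1]
               | p[:-1, 1:-1, 1:] | p[1:, 1:-1, 1:]).sum())
    e_z = int((p[:-1, :-1, 1:-1] | p[1:, :-1, 1:-1]
               | p[:-1, 1:, 1:-1] | p[1:, 1:, 1:-1]).sum())
    return 2 * (v - (e_x + e_y + e_z) + f - c)


def extract_interface_mesh(region: DigitalRegion, spacing=None) -> trimesh.Trimesh:
    """Triangulated surface of the region boundary, vertices in mm.

    Marching cubes on the (padded) membership array at level 0.5; the result
    is a closed, watertight mesh suitable for PLY export and rendering.
    """
    if region.size == 0:
        raise ValueError("empty region")
    spacing = tuple(spacing) if spacing is not None else region.spacing
    padded = np.pad(region.voxels, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)
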