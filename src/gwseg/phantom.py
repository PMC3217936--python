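"""Synthetic infant-T2w phantoms with analytic ground truth.

The phantom is a folded-sheet geometry: the grey-white interface is the
height-field sheet

    z(x, y) = z0 + A * sin(2*pi*x / lambda) * sin(2*pi*y / lambda)   (mm)

with white matter filling the space below the sheet, a cortical ribbon of
constant thickness coating it, and CSF outside. The T2w intensity ordering of
the unmyelinated infant brain is emulated: CSF brightest, white matter bright,
cortex dark. A smooth multiplicative bias field and additive Gaussian noise
are applied on top; ground-truth masks come from the noise-free geometry, so
every downstream stage can be scored exactly. An optional box where the
WM-GM intensity difference is scaled down mimics the regional contrast loss
caused by early myelination of primary cortices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from gwseg.evaluation import LandmarkSet
from gwseg.volume_io import STRUCT_6, BrainMask, IntensityVolume

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "phantom_suite",
           "multiplicative_bias_field"]

#: sampling step of the sulcal-fundus landmark sheets (mm)
LANDMARK_SPACING_MM = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    intensities is the (wm, gm, csf) mean triple in arbitrary units with
    wm > gm and csf > gm (T2w ordering). contrast_loss_region is an optional
    voxel box ((x0, x1), (y0, y1), (z0, z1)) inside which the WM intensity is
    pulled toward GM by contrast_loss_scale (maturation mimic).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ribbon_thickness: float = 3.0  # mm
    fold_amplitude: float = 5.0  # mm
    fold_wavelength: float = 24.0  # mm
    intensities: tuple[float, float, float] = (160.0, 90.0, 220.0)  # (wm, gm, csf)
    noise_sd: float = 8.0
    bias_strength: float = 0.15
    contrast_loss_region: tuple | None = None
    #: residual fraction of the WM-GM intensity difference inside the loss
    #: box; advanced myelination makes central-region contrast nearly vanish
    contrast_loss_scale: float = 0.2
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        wm, gm, csf = self.intensities
        if not (wm > gm and csf > gm):
            raise ValueError("T2w ordering requires wm > gm and csf > gm")
        if self.ribbon_thickness < 2 * min(self.spacing):
            raise ValueError("ribbon_thickness must be >= 2 * min(spacing)")
        if not (0 <= self.bias_strength < 1):
            raise ValueError("bias_strength must be in [0, 1)")
        if any(s <= 0 for s in self.spacing) or any(d < 8 for d in self.shape):
            raise ValueError("invalid grid")


@dataclass
class PhantomTruth:
    """A phantom volume plus everything needed to score a segmentation."""

    volume: IntensityVolume
    brain_mask: BrainMask
    wm_mask: BrainMask
    inner_interface: np.ndarray  # bool: boundary voxels of wm_mask
    landmarks: LandmarkSet
    bias: np.ndarray  # the multiplicative field actually applied
    spec: PhantomSpec


def multiplicative_bias_field(shape, spacing, strength, centers=None) -> np.ndarray:
    """Smooth multiplicative bias: normalized sum of broad Gaussians in [1-b, 1+b]."""
    if strength == 0:
        return np.ones(shape)
    if centers is None:
        centers = [(0.30, 0.35, 0.65), (0.70, 0.60, 0.35), (0.50, 0.85, 0.70)]
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    sigma = 0.4 * extent.max()
    g = np.zeros(shape)
    for c in centers:
        c_mm = np.asarray(c) * extent
        r2 = sum((grid - cc) ** 2 for grid, cc in zip(grids, c_mm))
        g += np.exp(-r2 / (2 * sigma**2))
    g -= g.mean()
    g /= np.abs(g).max()
    return 1.0 + strength * g


def _fold_height(spec: PhantomSpec, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    z0 = 0.5 * spec.shape[2] * spec.spacing[2]
    lam = spec.fold_wavelength
    return z0 + spec.fold_amplitude * np.sin(2 * np.pi * x_mm / lam) * np.sin(
        2 * np.pi * y_mm / lam
    )


def _fundus_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Sample the sulcal-fundus analog: vertical sheets along the trough lines
    of the interface, probed along the x axis (analytically known normals)."""
    sx, sy, sz = spec.spacing
    lam = spec.fold_wavelength
    ext = [n * s for n, s in zip(spec.shape, spec.spacing)]
    z0 = 0.5 * ext[2]
    pts, nrm = [], []
    if spec.fold_amplitude == 0:
        # flat slab: landmarks on the interface plane itself, probing along z
        for x in np.arange(LANDMARK_SPACING_MM, ext[0] - 1, LANDMARK_SPACING_MM):
            for y in np.arange(LANDMARK_SPACING_MM, ext[1] - 1, LANDMARK_SPACING_MM):
                pts.append((x / sx, y / sy, z0 / sz))
                nrm.append((0.0, 0.0, 1.0))
        return LandmarkSet(np.array(pts), np.array(nrm))
    # trough lines of the sheet: sin(2 pi x / lam) = -1 where sin(2 pi y / lam) > 0
    k = 0
    while True:
        x_f = lam * (0.75 + k)
        k += 1
        if x_f >= ext[0] - 1:
            break
        if x_f < 1:
            continue
        for y in np.arange(1.0, ext[1] - 1, LANDMARK_SPACING_MM):
            s_y = np.sin(2 * np.pi * y / lam)
            if s_y <= 0.3:
                continue
            z_fundus = z0 - spec.fold_amplitude * s_y
            z_crest = z0 + spec.fold_amplitude * s_y
            for z in np.arange(z_fundus + 1.0, z_crest - 0.5, LANDMARK_SPACING_MM):
                if not (1 <= z < ext[2] - 1):
                    continue
                pts.append((x_f / sx, y / sy, z / sz))
                nrm.append((1.0, 0.0, 0.0))
    return LandmarkSet(np.array(pts), np.array(nrm))


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate the phantom volume and its ground truth, deterministically."""
    sx, sy, sz = spec.spacing
    x_mm = np.arange(spec.shape[0])[:, None, None] * sx
    y_mm = np.arange(spec.shape[1])[None, :, None] * sy
    z_mm = np.arange(spec.shape[2])[None, None, :] * sz
    height = _fold_height(spec, x_mm, y_mm)

    wm = np.broadcast_to(z_mm, spec.shape) < height
    wm = np.ascontiguousarray(wm)
    # the WM compartment must be strictly interior so the cortical ribbon can
    # wrap it completely (as it does a hemisphere): inset by ribbon + rim
    margin = spec.ribbon_thickness + 2.0 * max(spec.spacing)
    for ax, s in enumerate(spec.spacing):
        k = max(1, int(np.ceil(margin / s)))
        sl = [slice(None)] * 3
        sl[ax] = slice(0, k)
        wm[tuple(sl)] = False
        sl[ax] = slice(-k, None)
        wm[tuple(sl)] = False
    if not wm.any():
        raise ValueError("geometry leaves zero WM voxels")

    dist_to_wm = ndimage.distance_transform_edt(~wm, sampling=spec.spacing)
    gm = (dist_to_wm > 0) & (dist_to_wm <= spec.ribbon_thickness + 1e-9)
    brain = ndimage.binary_dilation(wm | gm, structure=STRUCT_6)
    brain[0, :, :] = brain[-1, :, :] = False
    brain[:, 0, :] = brain[:, -1, :] = False
    brain[:, :, 0] = brain[:, :, -1] = False
    gm &= brain

    wm_i, gm_i, csf_i = spec.intensities
    vol = np.full(spec.shape, csf_i, dtype=np.float64)
    vol[gm] = gm_i
    vol[wm] = wm_i
    if spec.contrast_loss_region is not None:
        (x0, x1), (y0, y1), (z0b, z1b) = spec.contrast_loss_region
        box = np.zeros(spec.shape, dtype=bool)
        box[x0:x1, y0:y1, z0b:z1b] = True
        vol[wm & box] = gm_i + (wm_i - gm_i) * spec.contrast_loss_scale

    bias = multiplicative_bias_field(spec.shape, spec.spacing, spec.bias_strength)
    vol = vol * bias
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, spec.shape)

    interface = wm & ~ndimage.binary_erosion(wm, structure=STRUCT_6, border_value=1)

    return PhantomTruth(
        volume=IntensityVolume(vol, spacing=spec.spacing),
        brain_mask=BrainMask(brain, spacing=spec.spacing),
        wm_mask=BrainMask(wm, spacing=spec.spacing),
        inner_interface=interface,
        landmarks=_fundus_landmarks(spec),
        bias=bias,
        spec=spec,
    )


def phantom_suite(seed: int | None = None) -> list[PhantomSpec]:
    """The fixed three-phantom evaluation suite.

    (a) "young": high grey-white contrast, as in the first post-natal weeks;
    (b) "old": same geometry with a central box of strongly reduced WM-GM
        contrast, mimicking the advanced maturation of primary cortices;
    (c) "narrow": fold wavelength close to twice the ribbon thickness,
        stressing partial-volume behaviour in narrow gyri.

    ``seed`` (optional) re-seeds the noise of all three phantoms.
    """
    specs = [
        PhantomSpec(name="young", seed=101),
        # the loss box hugs the folded interface band, as maturation first
        # erodes contrast in the cortex of primary areas, not deep WM
        PhantomSpec(
            name="old",
            contrast_loss_region=((28, 68), (28, 68), (40, 60)),
            contrast_loss_scale=0.2,
            seed=202,
        ),
        PhantomSpec(
            name="narrow",
            ribbon_thickness=2.5,
            fold_amplitude=3.0,
            fold_wavelength=6.0,
            seed=303,
        ),
    ]
    if seed is not None:
        specs = [dataclasses.replace(s, seed=(int(seed) + i) % 2**31)
                 for i, s in enumerate(specs)]
    return specs
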