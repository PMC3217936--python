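"""Signed feature field separating white matter from cortex.

Three detectors are combined. Directional dark top hats (closing minus image)
respond to the thin dark cortical ribbon of T2w infant images; directional
bright top hats (image minus opening) respond to thin bright white-matter
structure; the rectified negative mean curvature of isointensity surfaces
(MC^WM) traces the gyral ridge lines of white matter, which persist even where
maturation has erased the intensity contrast. Each detector probes the image
with square structuring elements in 9 plane orientations (3 axis-aligned + 6
bisecting) and takes the maximum across orientations, which makes the response
approximately isotropic. All detectors are local differential measurements and
are therefore largely insensitive to slow intensity inhomogeneity.

After normalization (sigmoidal for top hats, linear for curvature) the field

    f = (w_wm * TH^WM + w_mc * MC^WM - w_gm * TH^GM) / (w_gm + w_wm + w_mc)

is positive in white matter and negative in cortex. The deformation thresholds
are derived per volume as F^WM = 12% of the highest and F^GM = 8% of the
lowest feature value inside the brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.special import expit
from skimage import filters

from gwseg.volume_io import BrainMask, IntensityVolume

__all__ = [
    "StructuringPlane",
    "FeatureField",
    "FeatureParams",
    "directional_tophat",
    "tophat_gm",
    "tophat_wm",
    "mean_curvature_isointensity",
    "normalize_sigmoid",
    "normalize_linear",
    "combine_feature_field",
    "build_feature_field",
]

# unit normals of the 9 probing planes: axis-aligned + bisecting, with an
# in-plane orthonormal basis (u, v) used to rasterize the square footprint
_SQ2 = 1.0 / np.sqrt(2.0)
_ORIENTATIONS: list[tuple[tuple, tuple, tuple]] = [
    ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    ((0, 1, 0), (1, 0, 0), (0, 0, 1)),
    ((0, 0, 1), (1, 0, 0), (0, 1, 0)),
    ((_SQ2, _SQ2, 0), (_SQ2, -_SQ2, 0), (0, 0, 1)),
    ((_SQ2, -_SQ2, 0), (_SQ2, _SQ2, 0), (0, 0, 1)),
    ((_SQ2, 0, _SQ2), (_SQ2, 0, -_SQ2), (0, 1, 0)),
    ((_SQ2, 0, -_SQ2), (_SQ2, 0, _SQ2), (0, 1, 0)),
    ((0, _SQ2, _SQ2), (0, _SQ2, -_SQ2), (1, 0, 0)),
    ((0, _SQ2, -_SQ2), (0, _SQ2, _SQ2), (1, 0, 0)),
]

N_ORIENTATIONS = len(_ORIENTATIONS)


@dataclass(frozen=True)
class StructuringPlane:
    """A flat square structuring element of side ``side_mm`` in one of the 9
    plane orientations (index 0..8)."""

    orientation: int
    side_mm: float

    def __post_init__(self) -> None:
        if not 0 <= self.orientation < N_ORIENTATIONS:
            raise ValueError(f"orientation index must be in 0..8, got {self.orientation}")
        if self.side_mm <= 0:
            raise ValueError("side_mm must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.asarray(_ORIENTATIONS[self.orientation][0])

    def footprint_offsets(self, spacing) -> np.ndarray:
        """Voxel offsets of the discretized square (symmetric about center)."""
        _, u, v = _ORIENTATIONS[self.orientation]
        u = np.asarray(u)
        v = np.asarray(v)
        sp = np.asarray(spacing, dtype=float)
        step = float(sp.min()) / 2.0
        k = int(np.floor((self.side_mm / 2.0) / step))
        samples = np.arange(-k, k + 1) * step
        pts = samples[:, None, None] * u + samples[None, :, None] * v
        offs = np.round(pts.reshape(-1, 3) / sp).astype(int)
        offs = np.unique(offs, axis=0)
        assert len(offs) > 0
        # symmetric by construction: samples and rounding are odd-symmetric
        return offs

    def footprint(self, spacing) -> np.ndarray:
        """Boolean footprint array with odd dimensions, centered."""
        offs = self.footprint_offsets(spacing)
        r = np.abs(offs).max(axis=0)
        fp = np.zeros(2 * r + 1, dtype=bool)
        fp[offs[:, 0] + r[0], offs[:, 1] + r[1], offs[:, 2] + r[2]] = True
        return fp


@dataclass
class FeatureField:
    """Signed scalar field in [-1, 1]: WM positive, cortex negative."""

    data: np.ndarray
    f_gm: float  # negative threshold bounding confident cortex
    f_wm: float  # positive threshold bounding confident white matter
    spacing: tuple[float, float, float]
    mask: np.ndarray
    components: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.f_gm < 0 < self.f_wm:
            raise ValueError(f"need F^GM < 0 < F^WM, got {self.f_gm}, {self.f_wm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature field contains non-finite values")


@dataclass(frozen=True)
class FeatureParams:
    """Tunables of the feature field (sizes in mm)."""

    gm_sizes: tuple[float, ...] = (2.0, 4.0)
    wm_sizes: tuple[float, ...] = (4.0, 7.0, 14.0)
    gm_size_weights: tuple[float, ...] | None = None  # uniform when None
    wm_size_weights: tuple[float, ...] | None = None
    #: (w_gm, w_wm, w_mc); the curvature ridges get extra weight because they
    #: are the only detector carrying signal inside featureless deep WM, where
    #: the noise residues of the two opposing top hats cancel on average
    weights: tuple[float, float, float] = (1.0, 1.0, 1.5)
    presmooth_sd: float = 1.0  # mm, curvature pre-smoothing
    pct_wm: float = 0.12  # F^WM as fraction of the highest feature value
    pct_gm: float = 0.08  # F^GM as fraction of the lowest feature value
    sigmoid_center: float | None = None  # None: Otsu split of positive responses
    sigmoid_slope: float | None = None  # None: quarter of the Otsu class-mean gap
    mc_clip_percentile: float = 99.5
    grad_floor_scale: float = 1e-3  # of masked intensity range, per mm
    component_median_size: int = 3  # voxels; edge-preserving denoising of the top hats
    mc_smooth_sd: float = 1.0  # mm; spatial pooling of the speckly ridge map


def directional_tophat(
    vol: IntensityVolume, element: StructuringPlane, polarity: str
) -> np.ndarray:
    """Grey-scale top hat with one directional square element.

    ``polarity="dark"`` returns Closing(I; e) - I (responds to dark structure
    thinner than the element, i.e. cortex in T2w); ``polarity="bright"``
    returns I - Opening(I; e). Boundaries use replicate padding. The result is
    nonnegative everywhere.
    """
    fp = element.footprint(vol.spacing)
    if any(fs > vs for fs, vs in zip(fp.shape, vol.shape)):
        raise ValueError(f"element {fp.shape} larger than volume {vol.shape}")
    data = np.asarray(vol.data, dtype=np.float64)
    if polarity == "dark":
        closed = ndimage.grey_erosion(
            ndimage.grey_dilation(data, footprint=fp, mode="nearest"),
            footprint=fp, mode="nearest",
        )
        residue = closed - data
    elif polarity == "bright":
        opened = ndimage.grey_dilation(
            ndimage.grey_erosion(data, footprint=fp, mode="nearest"),
            footprint=fp, mode="nearest",
        )
        residue = data - opened
    else:
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    # replicate padding makes closing/opening non-adjunct at the border, so
    # small negative residues can appear there; the top hat is nonnegative
    return np.maximum(residue, 0.0)


def _multiscale_tophat(vol, mask, sizes, size_weights, polarity) -> np.ndarray:
    """Max over the 9 orientations, weighted average over element sizes."""
    if size_weights is None:
        size_weights = np.full(len(sizes), 1.0 / len(sizes))
    else:
        size_weights = np.asarray(size_weights, dtype=float)
        size_weights = size_weights / size_weights.sum()
    out = np.zeros(vol.shape, dtype=np.float64)
    for s, w in zip(sizes, size_weights):
        best = np.zeros(vol.shape, dtype=np.float64)
        for ori in range(N_ORIENTATIONS):
            th = directional_tophat(vol, StructuringPlane(ori, s), polarity)
            np.maximum(best, th, out=best)
        out += w * best
    out[~_mask_data(mask, vol)] = 0.0
    return out


def _mask_data(mask, vol) -> np.ndarray:
    if mask is None:
        return np.ones(vol.shape, dtype=bool)
    m = mask.data if isinstance(mask, BrainMask) else np.asarray(mask, bool)
    if m.shape != vol.shape:
        raise ValueError("mask shape mismatch")
    return m


def tophat_gm(vol: IntensityVolume, mask=None, params: FeatureParams = FeatureParams()):
    """Cortical-ribbon detector: dark top hats, sides 2 and 4 mm."""
    return _multiscale_tophat(vol, mask, params.gm_sizes, params.gm_size_weights, "dark")


def tophat_wm(vol: IntensityVolume, mask=None, params: FeatureParams = FeatureParams()):
    """Thin bright white-matter detector: bright top hats, sides 4, 7, 14 mm."""
    return _multiscale_tophat(vol, mask, params.wm_sizes, params.wm_size_weights, "bright")


def mean_curvature_isointensity(
    vol: IntensityVolume,
    mask=None,
    presmooth_sd: float = 1.0,
    grad_floor_scale: float = 1e-3,
    clip_percentile: float = 99.5,
) -> np.ndarray:
    """Rectified ridge response MC^WM from isointensity-surface mean curvature.

    The image is Gaussian pre-smoothed (sd in mm); the mean curvature H of the
    implicit level set through each voxel is computed from first and second
    derivatives (half the divergence of the unit gradient, outward normal
    along +grad I, so bright WM crests have H < 0). The response is
    MC^WM = max(0, -H), clipped at a robust upper percentile; it is zeroed
    where the gradient magnitude falls below a floor, since the curvature is
    singular at the very crest. Units: 1/mm.
    """
    if presmooth_sd < 0:
        raise ValueError("presmooth_sd must be >= 0")
    m = _mask_data(mask, vol)
    sp = np.asarray(vol.spacing, dtype=float)
    data = np.asarray(vol.data, dtype=np.float64)
    if presmooth_sd > 0:
        data = ndimage.gaussian_filter(data, sigma=presmooth_sd / sp, mode="nearest")
    gx, gy, gz = np.gradient(data, *sp)
    gxx, gxy, gxz = np.gradient(gx, *sp)
    _, gyy, gyz = np.gradient(gy, *sp)
    gzz = np.gradient(gz, *sp)[2]
    g2 = gx**2 + gy**2 + gz**2
    num = (
        gx**2 * (gyy + gzz)
        + gy**2 * (gxx + gzz)
        + gz**2 * (gxx + gyy)
        - 2.0 * (gx * gy * gxy + gx * gz * gxz + gy * gz * gyz)
    )
    if not np.all(np.isfinite(num)):
        raise ValueError("non-finite derivatives; input needs smoothing")
    rng = np.ptp(data[m]) if m.any() else np.ptp(data)
    floor = grad_floor_scale * rng  # intensity units per mm
    g = np.sqrt(g2)
    ok = g > floor
    h = np.zeros_like(data)
    h[ok] = num[ok] / (2.0 * g[ok] ** 3)
    mc = np.maximum(0.0, -h)
    mc[~m] = 0.0
    pos = mc[m & (mc > 0)]
    if pos.size:
        mc = np.minimum(mc, np.percentile(pos, clip_percentile))
    return mc


def normalize_sigmoid(field: np.ndarray, center=None, slope=None, mask=None) -> np.ndarray:
    """Monotone logistic normalization of a detector response into [0, 1].

    Top-hat responses inside a brain volume are bimodal: a large hump of
    small noise-driven residues plus a tail of genuine structure. The default
    center is therefore the Otsu threshold of the strictly positive masked
    responses — the valley between noise and signal — and the default slope a
    quarter of the separation between the two class means, so that the noise
    hump is compressed toward 0 and the structural tail saturates toward 1
    ("levelling off" the more specific detectors). After the logistic map the
    masked values are affinely rescaled onto [0, 1]; large explicit slopes
    therefore approach plain linear normalization.
    """
    field = np.asarray(field, dtype=np.float64)
    m = np.ones(field.shape, bool) if mask is None else np.asarray(
        mask.data if isinstance(mask, BrainMask) else mask, bool)
    vals = field[m]
    pos = vals[vals > 0]
    ref = pos if pos.size else vals
    if center is None or slope is None:
        try:
            thr = float(filters.threshold_otsu(ref))
            lo_mean = float(ref[ref <= thr].mean())
            hi_mean = float(ref[ref > thr].mean())
        except ValueError:  # degenerate (constant) response
            thr = float(np.median(ref))
            lo_mean, hi_mean = thr, thr
        if center is None:
            center = thr
        if slope is None:
            slope = max((hi_mean - lo_mean) / 4.0, 1e-12)
    if slope <= 0:
        raise ValueError("slope must be positive")
    y = expit((field - center) / slope)
    ymin, ymax = y[m].min(), y[m].max()
    if ymax - ymin <= 0:
        out = np.zeros_like(y)
    else:
        out = (y - ymin) / (ymax - ymin)
    out[~m] = 0.0
    return np.clip(out, 0.0, 1.0)


def normalize_linear(field: np.ndarray, mask=None) -> np.ndarray:
    """Affine rescaling of the masked values onto [0, 1]."""
    field = np.asarray(field, dtype=np.float64)
    m = np.ones(field.shape, bool) if mask is None else np.asarray(
        mask.data if isinstance(mask, BrainMask) else mask, bool)
    vals = field[m]
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 0:
        raise ValueError("constant field: zero range inside mask")
    out = (field - lo) / (hi - lo)
    out[~m] = 0.0
    return np.clip(out, 0.0, 1.0)


def combine_feature_field(
    th_gm: np.ndarray,
    th_wm: np.ndarray,
    mc_wm: np.ndarray,
    mask,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    spacing=(1.0, 1.0, 1.0),
    pct_wm: float = 0.12,
    pct_gm: float = 0.08,
    components: dict | None = None,
) -> FeatureField:
    """Weighted combination of the normalized detections into the signed field.

    f = (w_wm*TH^WM + w_mc*MC^WM - w_gm*TH^GM) / (w_gm + w_wm + w_mc), clipped
    to [-1, 1] and zeroed outside the mask. Thresholds: F^WM = pct_wm * max f,
    F^GM = pct_gm * min f over the mask.
    """
    w_gm, w_wm, w_mc = (float(w) for w in weights)
    if w_gm <= 0 or (w_wm + w_mc) <= 0 or w_wm < 0 or w_mc < 0:
        raise ValueError("weights must be positive (w_gm and w_wm + w_mc each > 0)")
    m = np.asarray(mask.data if isinstance(mask, BrainMask) else mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    f = (w_wm * th_wm + w_mc * mc_wm - w_gm * th_gm) / (w_gm + w_wm + w_mc)
    f = np.clip(f, -1.0, 1.0)
    f[~m] = 0.0
    fmax = float(f[m].max())
    fmin = float(f[m].min())
    if fmax <= 0 or fmin >= 0:
        raise ValueError("degenerate feature range: cannot derive F^GM < 0 < F^WM")
    return FeatureField(
        data=f,
        f_gm=pct_gm * fmin,
        f_wm=pct_wm * fmax,
        spacing=tuple(float(s) for s in spacing),
        mask=m,
        components=components or {},
    )


def build_feature_field(
    vol: IntensityVolume,
    mask: BrainMask,
    params: FeatureParams = FeatureParams(),
    keep_components: bool = False,
) -> FeatureField:
    """Full feature-field pipeline: top hats + curvature, normalized, combined."""
    th_gm_raw = tophat_gm(vol, mask, params)
    th_wm_raw = tophat_wm(vol, mask, params)
    mc_raw = mean_curvature_isointensity(
        vol, mask, params.presmooth_sd, params.grad_floor_scale, params.mc_clip_percentile
    )
    th_gm_n = normalize_sigmoid(th_gm_raw, params.sigmoid_center, params.sigmoid_slope, mask)
    th_wm_n = normalize_sigmoid(th_wm_raw, params.sigmoid_center, params.sigmoid_slope, mask)
    mc_n = normalize_linear(mc_raw, mask)
    if params.component_median_size > 1:
        # an edge-preserving median suppresses the voxelwise top-hat noise
        # residue in featureless white matter without displacing the sharp
        # GM/WM transitions (a Gaussian here drags the zero crossing of the
        # combined field about a voxel into the white matter)
        k = params.component_median_size
        th_gm_n = ndimage.median_filter(th_gm_n, size=k)
        th_wm_n = ndimage.median_filter(th_wm_n, size=k)
    if params.mc_smooth_sd > 0:
        # the rectified curvature response is speckly by nature (it rides on
        # noise isophotes in homogeneous tissue); Gaussian pooling turns it
        # into a smooth WM-interior prior, and since the cortex response is
        # near zero the bleed across the interface is negligible
        mc_n = ndimage.gaussian_filter(mc_n, params.mc_smooth_sd / np.asarray(vol.spacing))
    components = (
        {"th_gm": th_gm_n, "th_wm": th_wm_n, "mc_wm": mc_n} if keep_components else None
    )
    return combine_feature_field(
        th_gm_n, th_wm_n, mc_n, mask,
        weights=params.weights, spacing=vol.spacing,
        pct_wm=params.pct_wm, pct_gm=params.pct_gm, components=components,
    )
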