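"""Coupled homotopic deformation of two digital surfaces.

Two regions are initialised on each side of the grey-white interface: the
inner region (white-matter side, from a feature-field threshold) and the outer
region (the complement of the brain bounding box, whose boundary is the box).
Both fronts then grow toward each other across the signed feature field f.

Energy model: every candidate addition changes U = U_D + U_R by

    dU = -f * sigma + beta * (26 - 2 n)        sigma = +1 inner, -1 outer

where n is the number of 26-neighbours already in the growing region (Ising
regularization on order-two cliques: isolated additions cost, well supported
ones gain) and beta > 0 the coupling. Minimization is ICM-like: sequential
lexicographic sweeps, additions only.

Round 1 moves the surfaces close to each other in confident territory only
(inner where f > F^WM, outer where f < F^GM, both requiring dU < 0). Round 2
drives the final convergence with the potential-to-move scheduler: every
candidate carries a potential P (initially P0) decremented each sweep by
P0 * (S / S_high), with the speed S read from the per-surface speed tables;
the move triggers when P reaches zero. The inner surface only moves on energy
decrease; the outer surface creeps at S_verylow even when dU >= 0 so that it
crosses residual CSF, and every outer move must pass the homotopy (simple
point) test, which keeps the outer surface sphere-equivalent throughout.
Propagation stops where the fronts meet; those voxels form the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from gwseg import _kernels as K
from gwseg.feature_field import FeatureField, FeatureParams, build_feature_field
from gwseg.surface_model import DigitalRegion, euler_characteristic
from gwseg.volume_io import STRUCT_26, BrainMask, IntensityVolume

__all__ = [
    "SpeedParams",
    "DeformationState",
    "SegmentationResult",
    "delta_energy",
    "speed_inner",
    "speed_outer",
    "init_surfaces",
    "run_round_one",
    "run_round_two",
    "segment_white_matter",
]

_PAD = 2  # work-grid margin around the mask bounding box


@dataclass(frozen=True)
class SpeedParams:
    """Speeds and regularization thresholds of the two fronts.

    The ratios S_high/S_low and S_low/S_verylow set the distinct timescales of
    confident vs hesitant propagation; N is the neighbour-count threshold above
    which even adverse-contrast moves are allowed (regularization), N_I_min and
    N_O_min the support demanded at the confident end of the weak-contrast
    band. beta_scale expresses the Ising coupling as a fraction of the feature
    magnitude.
    """

    s_high: float = 1.0
    s_low: float = 0.25
    s_verylow: float = 0.05
    p0: float = 1.0
    n_reg: int = 22
    n_inner_min: int = 9
    n_outer_min: int = 9
    beta_scale: float = 0.005

    def __post_init__(self) -> None:
        if not (self.s_high > self.s_low > self.s_verylow > 0):
            raise ValueError("need S_high > S_low > S_verylow > 0")
        if not (0 < self.n_inner_min < self.n_reg <= 26):
            raise ValueError("need 0 < N_I_min < N <= 26")
        if not (0 < self.n_outer_min < self.n_reg <= 26):
            raise ValueError("need 0 < N_O_min < N <= 26")
        if self.p0 <= 0 or self.beta_scale < 0:
            raise ValueError("p0 must be > 0 and beta_scale >= 0")

    @property
    def quiet_sweeps(self) -> int:
        """Sweeps without change after which round 2 has provably converged
        (the slowest positive speed needs ceil(S_high/S_verylow) sweeps)."""
        return int(math.ceil(self.s_high / self.s_verylow)) + 1


@dataclass
class DeformationState:
    """Work-grid bookkeeping of the coupled deformation.

    The work grid is the brain-mask bounding box padded by a fixed margin;
    label array values follow gwseg._kernels (0 unclaimed, 1 inner, 2 outer,
    3 interface). ``offset`` maps work-grid indices to original-volume ones.
    """

    state: np.ndarray  # uint8 labels
    f: np.ndarray  # feature values on the work grid
    domain: np.ndarray  # bool, growable voxels (the bounding box)
    p_in: np.ndarray
    p_out: np.ndarray
    offset: tuple[int, int, int]
    orig_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    params: SpeedParams
    f_gm: float
    f_wm: float
    beta: float
    sweeps: int = 0
    u_inner: float = 0.0  # cumulative energy change of inner additions
    u_outer: float = 0.0
    history: list = dc_field(default_factory=list)

    def _to_original(self, label: int) -> np.ndarray:
        """Map a work-grid label mask back onto the original volume grid.

        The padding shell may extend past the original borders; only the
        overlapping part is reported."""
        out = np.zeros(self.orig_shape, dtype=bool)
        sel = self.state == label
        src, dst = [], []
        for ax in range(3):
            o = self.offset[ax]
            s0 = max(0, -o)
            s1 = min(self.state.shape[ax], self.orig_shape[ax] - o)
            src.append(slice(s0, s1))
            dst.append(slice(s0 + o, s1 + o))
        out[tuple(dst)] = sel[tuple(src)]
        return out

    def inner_mask(self) -> np.ndarray:
        return self._to_original(K.INNER)

    def outer_mask(self) -> np.ndarray:
        return self._to_original(K.OUTER)

    def interface_mask(self) -> np.ndarray:
        return self._to_original(K.INTERFACE)

    def outer_complement_euler(self) -> int:
        """Euler characteristic of the boundary of everything not yet claimed
        by the outer region (2 = sphere-equivalent, held by the homotopy
        constraint)."""
        return euler_characteristic(self.state != K.OUTER)


def delta_energy(state: DeformationState, which: str, target, f_value=None) -> float:
    """Energy change of adding ``target`` (original-volume coords) to a front."""
    if which not in ("inner", "outer"):
        raise ValueError("which must be 'inner' or 'outer'")
    x, y, z = (int(t) - o for t, o in zip(target, state.offset))
    lab = state.state[x, y, z]
    if lab in (K.INNER, K.OUTER):
        raise ValueError(f"target {tuple(target)} already claimed")
    fv = float(state.f[x, y, z]) if f_value is None else float(f_value)
    region_label = K.INNER if which == "inner" else K.OUTER
    sigma = 1.0 if which == "inner" else -1.0
    n = K._count26(state.state, x, y, z, region_label)
    return -fv * sigma + state.beta * (26.0 - 2.0 * n)


def speed_inner(f: float, n: int, field: FeatureField, params: SpeedParams) -> float:
    """Inner-front speed for feature value f and neighbour count n."""
    return float(K.speed_inner_kernel(
        float(f), float(n), field.f_gm, field.f_wm,
        params.s_high, params.s_low, params.n_reg, params.n_inner_min,
    ))


def speed_outer(f: float, n: int, field: FeatureField, params: SpeedParams) -> float:
    """Outer-front speed; strictly positive for every (f, n)."""
    return float(K.speed_outer_kernel(
        float(f), float(n), field.f_gm, field.f_wm,
        params.s_high, params.s_low, params.s_verylow,
        params.n_reg, params.n_outer_min,
    ))


def _bbox(mask: np.ndarray):
    xs, ys, zs = np.nonzero(mask)
    return (xs.min(), xs.max() + 1), (ys.min(), ys.max() + 1), (zs.min(), zs.max() + 1)


def _largest_component_area(f, thresh, candidates):
    """Largest 26-connected component of {f >= thresh} among candidate voxels
    (cavities filled, so the initial surface is closed) and its boundary facet
    count. The threshold is inclusive: regions where no local detector fires
    at all (f exactly 0, e.g. deep inside a homogeneous WM body) still belong
    to the white-matter side."""
    lab, n = ndimage.label((f >= thresh) & candidates, structure=STRUCT_26)
    if n == 0:
        return None, 0
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    comp = ndimage.binary_fill_holes(lab == sizes.argmax())
    return comp, DigitalRegion(comp).boundary_facet_count()


def init_surfaces(
    field: FeatureField,
    mask: BrainMask,
    target_area: int | None = None,
    params: SpeedParams = SpeedParams(),
) -> DeformationState:
    """Initialise the coupled fronts.

    The outer region is the complement of the brain bounding box (its boundary
    is the box, a topological sphere). The inner region is the largest
    26-connected component of {f_s > t} with its cavities filled, where f_s is
    a smoothed copy of the feature field (thresholding the raw field selects a
    noise sponge whose facet area is meaningless). By default t -> 0+: the
    initial region is the whole positive body of the smoothed field, a rough
    fit of the final interface that hands the inner front the white-matter
    bulk, whose interior carries no local feature signal. When an explicit
    ``target_area`` is given, t is found by bisection so that the component's
    boundary facet count comes within 10% of it.
    """
    m = mask.data
    f_full = field.data
    (x0, x1), (y0, y1), (z0, z1) = _bbox(m)
    shape = (x1 - x0 + 2 * _PAD, y1 - y0 + 2 * _PAD, z1 - z0 + 2 * _PAD)
    offset = (x0 - _PAD, y0 - _PAD, z0 - _PAD)

    f_work = np.zeros(shape, dtype=np.float64)
    f_work[_PAD:_PAD + x1 - x0, _PAD:_PAD + y1 - y0, _PAD:_PAD + z1 - z0] = \
        f_full[x0:x1, y0:y1, z0:z1]
    domain = np.zeros(shape, dtype=bool)
    domain[_PAD:_PAD + x1 - x0, _PAD:_PAD + y1 - y0, _PAD:_PAD + z1 - z0] = True

    state = np.full(shape, K.OUTER, dtype=np.uint8)
    state[domain] = K.UNCLAIMED

    # inner initialisation threshold on a despeckled field: the median
    # suppresses isolated noise voxels without displacing the boundary of the
    # positive body (a Gaussian shrinks it by several voxels near the strong
    # negative cortex response)
    f_init = ndimage.median_filter(f_work, size=3)
    mask_work = np.zeros(shape, dtype=bool)
    mask_work[_PAD:_PAD + x1 - x0, _PAD:_PAD + y1 - y0, _PAD:_PAD + z1 - z0] = \
        m[x0:x1, y0:y1, z0:z1]
    fmax = float(f_init[domain].max())
    comp_lo, area_lo = _largest_component_area(f_init, 0.0, mask_work)
    if comp_lo is None:
        raise ValueError("no white matter found: feature field has no positive component")
    best, best_area = comp_lo, area_lo
    if target_area is not None:
        lo, hi = 0.0, fmax
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            comp, area = _largest_component_area(f_init, mid, mask_work)
            if comp is None:
                hi = mid
                continue
            if abs(area - target_area) < abs(best_area - target_area):
                best, best_area = comp, area
            if abs(area - target_area) <= 0.10 * target_area:
                break
            if area > target_area:
                lo = mid  # raise threshold to shrink the component
            else:
                hi = mid
    state[best & domain] = K.INNER

    fmask = f_work[domain]
    beta = params.beta_scale * float(np.abs(fmask).max()) if fmask.size else 0.0
    return DeformationState(
        state=state,
        f=f_work,
        domain=domain,
        p_in=np.full(shape, params.p0, dtype=np.float64),
        p_out=np.full(shape, params.p0, dtype=np.float64),
        offset=offset,
        orig_shape=m.shape,
        spacing=mask.spacing,
        params=params,
        f_gm=field.f_gm,
        f_wm=field.f_wm,
        beta=beta,
    )


def run_round_one(state: DeformationState, on_sweep=None) -> DeformationState:
    """Round 1: confident approach. Inner inflates where f > F^WM, outer
    deflates where f < F^GM, both on energy decrease only, skipping voxels in
    conflict (adjacent to the other front); outer moves stay homotopic."""
    while True:
        a_in, du_in = K.sweep_round1_inner(state.state, state.f, state.domain,
                                           state.f_wm, state.beta)
        a_out, du_out = K.sweep_round1_outer(state.state, state.f, state.domain,
                                             state.f_gm, state.beta)
        state.sweeps += 1
        state.u_inner += du_in
        state.u_outer += du_out
        state.history.append(("round1", a_in, a_out, du_in, du_out))
        if on_sweep is not None:
            on_sweep(state)
        if a_in + a_out == 0:
            return state


def run_round_two(state: DeformationState, on_sweep=None, max_sweeps: int = 20000
                  ) -> DeformationState:
    """Round 2: speed-coupled convergence with the potential scheduler.

    Terminates when no front can change for a full quiet period (long enough
    for the slowest positive speed to trigger) or nothing is left unclaimed;
    remaining unclaimed voxels — where the fronts met — become the interface.
    """
    p = state.params
    quiet = 0
    for _ in range(max_sweeps):
        c_in, a_in, du_in = K.sweep_round2_inner(
            state.state, state.f, state.domain, state.p_in, state.p_out,
            state.f_gm, state.f_wm, p.s_high, p.s_low,
            p.n_reg, p.n_inner_min, p.p0, state.beta,
        )
        c_out, a_out, du_out = K.sweep_round2_outer(
            state.state, state.f, state.domain, state.p_in, state.p_out,
            state.f_gm, state.f_wm, p.s_high, p.s_low, p.s_verylow,
            p.n_reg, p.n_outer_min, p.p0, state.beta,
        )
        state.sweeps += 1
        state.u_inner += du_in
        state.u_outer += du_out
        state.history.append(("round2", c_in + a_in, c_out + a_out, du_in, du_out))
        if on_sweep is not None:
            on_sweep(state)
        quiet = quiet + 1 if (c_in + c_out) == 0 else 0
        unclaimed = state.domain & (state.state == K.UNCLAIMED)
        if not unclaimed.any() or quiet >= p.quiet_sweeps:
            break
    _finalize_unclaimed(state)
    return state


def _finalize_unclaimed(state: DeformationState) -> None:
    """Resolve voxels no front could claim.

    Where the fronts met, the remaining candidates are the interface. A
    leftover pocket that only one front ever reached (frozen inner candidates
    enclosed by the inner region, homotopy-blocked outer cavities) was never
    contested and is absorbed by the enclosing region.
    """
    unclaimed = state.domain & (state.state == K.UNCLAIMED)
    if not unclaimed.any():
        return
    labels, n = ndimage.label(unclaimed, structure=ndimage.generate_binary_structure(3, 1))
    dil = ndimage.generate_binary_structure(3, 1)
    for comp_label in range(1, n + 1):
        comp = labels == comp_label
        border = ndimage.binary_dilation(comp, structure=dil) & ~comp
        touch_in = bool((state.state[border] == K.INNER).any())
        touch_out = bool((state.state[border] == K.OUTER).any())
        if touch_in and touch_out:
            state.state[comp] = K.INTERFACE
        elif touch_in:
            state.state[comp] = K.INNER
        elif touch_out:
            state.state[comp] = K.OUTER
        else:
            state.state[comp] = K.INTERFACE


@dataclass
class SegmentationResult:
    wm_mask: BrainMask
    interface: DigitalRegion  # boundary voxels of the converged WM region
    field: FeatureField
    state: DeformationState


def segment_white_matter(
    vol: IntensityVolume,
    mask: BrainMask,
    feature_params: FeatureParams = FeatureParams(),
    speed_params: SpeedParams = SpeedParams(),
    target_area: int | None = None,
    field: FeatureField | None = None,
    on_sweep=None,
) -> SegmentationResult:
    """End-to-end segmentation: feature field, initialisation, rounds 1 and 2.

    Returns the converged inner region as the white-matter mask (interface
    voxels join it where f >= 0) and its exposed boundary voxels as the
    grey-white interface. Fully deterministic for identical inputs: sweeps
    visit voxels in fixed lexicographic order.
    """
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if field is None:
        field = build_feature_field(vol, mask, feature_params)
    st = init_surfaces(field, mask, target_area=target_area, params=speed_params)
    run_round_one(st, on_sweep=on_sweep)
    run_round_two(st, on_sweep=on_sweep)
    wm = st.inner_mask() | (st.interface_mask() & (field.data >= 0))
    wm_region = DigitalRegion(wm, spacing=vol.spacing)
    interface = DigitalRegion(wm_region.boundary_voxel_mask(), spacing=vol.spacing)
    return SegmentationResult(
        wm_mask=BrainMask(wm, spacing=mask.spacing, affine=mask.affine),
        interface=interface,
        field=field,
        state=st,
    )
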