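"""Numba kernels for digital-topology tests and front-propagation sweeps.

Everything here operates on plain ndarrays so the public modules can stay
array-in / array-out. State labels used by the deformation sweeps:

    0 = unclaimed, 1 = inner region (WM side), 2 = outer region (GM/CSF side),
    3 = interface (fronts met).
"""

from __future__ import annotations

import numpy as np
from numba import njit

UNCLAIMED = 0
INNER = 1
OUTER = 2
INTERFACE = 3

#: trigger tolerance for the potential-to-move countdown (guards float error
#: so that k decrements of P0/k trigger in exactly k sweeps)
P_EPS = 1e-9


@njit(cache=False)
def _n_components_26(occ, want):
    """Number of 26-connected components of the cells equal to ``want`` in
    the 26-neighbourhood of the target (occ[1,1,1] excluded)."""
    visited = np.zeros((3, 3, 3), dtype=np.uint8)
    stack = np.empty((27, 3), dtype=np.int64)
    ncomp = 0
    for sx in range(3):
        for sy in range(3):
            for sz in range(3):
                if sx == 1 and sy == 1 and sz == 1:
                    continue
                if visited[sx, sy, sz] or occ[sx, sy, sz] != want:
                    continue
                ncomp += 1
                top = 0
                stack[top, 0] = sx
                stack[top, 1] = sy
                stack[top, 2] = sz
                top += 1
                visited[sx, sy, sz] = 1
                while top > 0:
                    top -= 1
                    cx = stack[top, 0]
                    cy = stack[top, 1]
                    cz = stack[top, 2]
                    for dx in range(-1, 2):
                        for dy in range(-1, 2):
                            for dz in range(-1, 2):
                                if dx == 0 and dy == 0 and dz == 0:
                                    continue
                                nx = cx + dx
                                ny = cy + dy
                                nz = cz + dz
                                if nx < 0 or nx > 2 or ny < 0 or ny > 2 or nz < 0 or nz > 2:
                                    continue
                                if nx == 1 and ny == 1 and nz == 1:
                                    continue
                                if visited[nx, ny, nz] or occ[nx, ny, nz] != want:
                                    continue
                                visited[nx, ny, nz] = 1
                                stack[top, 0] = nx
                                stack[top, 1] = ny
                                stack[top, 2] = nz
                                top += 1
    return ncomp


@njit(cache=False)
def _n_components_6_geodesic(occ, want):
    """Number of 6-connected components of the cells equal to ``want`` that
    are 6-adjacent to the target, counted in its 18-neighbourhood (the
    geodesic neighbourhood of the 6-connected side of a (26, 6) / (6, 26)
    connectivity pair: corner cells are excluded and components must contain
    a face neighbour)."""
    visited = np.zeros((3, 3, 3), dtype=np.uint8)
    stack = np.empty((27, 3), dtype=np.int64)
    ncomp = 0
    # seed floods only from the 6 face neighbours
    for seed in range(6):
        if seed == 0:
            sx, sy, sz = 0, 1, 1
        elif seed == 1:
            sx, sy, sz = 2, 1, 1
        elif seed == 2:
            sx, sy, sz = 1, 0, 1
        elif seed == 3:
            sx, sy, sz = 1, 2, 1
        elif seed == 4:
            sx, sy, sz = 1, 1, 0
        else:
            sx, sy, sz = 1, 1, 2
        if visited[sx, sy, sz] or occ[sx, sy, sz] != want:
            continue
        ncomp += 1
        top = 0
        stack[top, 0] = sx
        stack[top, 1] = sy
        stack[top, 2] = sz
        top += 1
        visited[sx, sy, sz] = 1
        while top > 0:
            top -= 1
            cx = stack[top, 0]
            cy = stack[top, 1]
            cz = stack[top, 2]
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    for dz in range(-1, 2):
                        if abs(dx) + abs(dy) + abs(dz) != 1:
                            continue
                        nx = cx + dx
                        ny = cy + dy
                        nz = cz + dz
                        if nx < 0 or nx > 2 or ny < 0 or ny > 2 or nz < 0 or nz > 2:
                            continue
                        if nx == 1 and ny == 1 and nz == 1:
                            continue
                        # stay inside the 18-neighbourhood (no corner cells)
                        if abs(nx - 1) + abs(ny - 1) + abs(nz - 1) > 2:
                            continue
                        if visited[nx, ny, nz] or occ[nx, ny, nz] != want:
                            continue
                        visited[nx, ny, nz] = 1
                        stack[top, 0] = nx
                        stack[top, 1] = ny
                        stack[top, 2] = nz
                        top += 1
    return ncomp


@njit(cache=False)
def simple_point_local(occ, region_conn6=True):
    """Homotopy (simple point) test on a 3x3x3 neighbourhood.

    occ[1,1,1] is the candidate target and is ignored. True cells form S (the
    region), False cells form B (background). The addition preserves topology
    iff S and B each reduce to one and only one connected set around the
    target, counted with the standard topological numbers of a consistent
    connectivity pair: with ``region_conn6`` (default) the region is
    6-connected (one 6-component of S in the 18-neighbourhood touching a face
    neighbour) and the background 26-connected (one 26-component of B in the
    26-neighbourhood); with ``region_conn6=False`` the roles are swapped —
    the (26, 6) pair.
    """
    if region_conn6:
        return _n_components_6_geodesic(occ, True) == 1 and _n_components_26(occ, False) == 1
    return _n_components_26(occ, True) == 1 and _n_components_6_geodesic(occ, False) == 1


@njit(cache=False)
def _simple_in_state(state, x, y, z, label, region_conn6=True):
    occ = np.zeros((3, 3, 3), dtype=np.bool_)
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                occ[dx + 1, dy + 1, dz + 1] = state[x + dx, y + dy, z + dz] == label
    return simple_point_local(occ, region_conn6)


@njit(cache=False)
def _count26(state, x, y, z, label):
    n = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                if state[x + dx, y + dy, z + dz] == label:
                    n += 1
    return n


@njit(cache=False)
def _adjacent6(state, x, y, z, label):
    return (
        state[x - 1, y, z] == label
        or state[x + 1, y, z] == label
        or state[x, y - 1, z] == label
        or state[x, y + 1, z] == label
        or state[x, y, z - 1] == label
        or state[x, y, z + 1] == label
    )


@njit(cache=False)
def speed_inner_kernel(f, n, f_gm, f_wm, s_high, s_low, n_reg, n_inner_min):
    """Inner-surface speed table: fast in confident WM, frozen in confident GM
    unless heavily supported, interpolated in the weak-contrast band.

    The neighbour gate N_I(f) demands extra support only where the evidence
    actually opposes the move: it equals N_I_min on the WM-leaning half of the
    band (f >= 0) and ramps linearly up to N at F^GM, so that a flat front
    (n = 9) keeps advancing through weakly positive territory but needs a
    concave, well-supported configuration to absorb negative-f voxels.
    """
    if f > f_wm:
        return s_high
    if f < f_gm:
        if n > n_reg:
            return s_low
        return 0.0
    if f >= 0.0:
        n_i = float(n_inner_min)
    else:
        n_i = n_inner_min + (n_reg - n_inner_min) * (f / f_gm)
    if n < n_i:
        return 0.0
    t = (f - f_gm) / (f_wm - f_gm)
    return s_low + (s_high - s_low) * t


@njit(cache=False)
def speed_outer_kernel(f, n, f_gm, f_wm, s_high, s_low, s_verylow, n_reg, n_outer_min):
    """Outer-surface speed table: fast in confident GM, very slow (but never
    zero) in confident WM, interpolated in the weak-contrast band (mirror
    image of the inner table, with S_verylow instead of a full stop below the
    neighbour gate N_O(f))."""
    if f < f_gm:
        return s_high
    if f > f_wm:
        if n > n_reg:
            return s_low
        return s_verylow
    if f <= 0.0:
        n_o = float(n_outer_min)
    else:
        n_o = n_outer_min + (n_reg - n_outer_min) * (f / f_wm)
    if n < n_o or f >= 0.0:
        # no supporting grey-matter evidence: only the residual-CSF creep
        return s_verylow
    return s_verylow + (s_high - s_verylow) * (f / f_gm)


@njit(cache=False)
def sweep_round1_inner(state, f, domain, f_wm, beta):
    """One lexicographic ICM sweep of round-1 inner inflation.

    Adds unclaimed domain voxels with f > F^WM that touch the inner front,
    are not in conflict with the outer front, and decrease the energy.
    Returns (voxels added, summed energy change).
    """
    added = 0
    du_sum = 0.0
    nx, ny, nz = state.shape
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                if state[x, y, z] != UNCLAIMED or not domain[x, y, z]:
                    continue
                if f[x, y, z] <= f_wm:
                    continue
                if not _adjacent6(state, x, y, z, INNER):
                    continue
                if _adjacent6(state, x, y, z, OUTER):
                    continue
                n = _count26(state, x, y, z, INNER)
                du = -f[x, y, z] + beta * (26.0 - 2.0 * n)
                if du < 0.0:
                    state[x, y, z] = INNER
                    added += 1
                    du_sum += du
    return added, du_sum


@njit(cache=False)
def sweep_round1_outer(state, f, domain, f_gm, beta):
    """One lexicographic ICM sweep of round-1 outer deflation.

    Adds unclaimed domain voxels with f < F^GM touching the outer front,
    not in conflict with the inner front, energy-decreasing, and passing the
    homotopy test so that the outer region's topology never changes.
    """
    added = 0
    du_sum = 0.0
    nx, ny, nz = state.shape
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                if state[x, y, z] != UNCLAIMED or not domain[x, y, z]:
                    continue
                if f[x, y, z] >= f_gm:
                    continue
                if not _adjacent6(state, x, y, z, OUTER):
                    continue
                if _adjacent6(state, x, y, z, INNER):
                    continue
                n = _count26(state, x, y, z, OUTER)
                du = f[x, y, z] + beta * (26.0 - 2.0 * n)
                if du < 0.0 and _simple_in_state(state, x, y, z, OUTER):
                    state[x, y, z] = OUTER
                    added += 1
                    du_sum += du
    return added, du_sum


@njit(cache=False)
def sweep_round2_inner(
    state, f, domain, p_in, p_out,
    f_gm, f_wm, s_high, s_low, n_reg, n_inner_min, p0, beta,
):
    """One round-2 sweep of the inner front with the potential scheduler.

    A candidate facing both fronts is frozen as interface. Otherwise its
    potential decreases by P0*(S/S_high); it joins the inner region when the
    potential reaches zero, provided the move decreases the energy (strict
    for the inner surface). The potential of a location is reset to P0 when
    it propagates (it starts fresh as a new candidate); between sweeps it
    simply keeps counting down. Returns (changes, additions, energy sum).
    """
    changed = 0
    added = 0
    du_sum = 0.0
    nx, ny, nz = state.shape
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                if state[x, y, z] != UNCLAIMED or not domain[x, y, z]:
                    continue
                if not _adjacent6(state, x, y, z, INNER):
                    continue
                if _adjacent6(state, x, y, z, OUTER):
                    state[x, y, z] = INTERFACE
                    changed += 1
                    continue
                fv = f[x, y, z]
                n = _count26(state, x, y, z, INNER)
                s = speed_inner_kernel(fv, n, f_gm, f_wm, s_high, s_low, n_reg, n_inner_min)
                if s <= 0.0:
                    continue
                du = -fv + beta * (26.0 - 2.0 * n)
                if du >= 0.0:
                    continue
                p_in[x, y, z] -= p0 * s / s_high
                if p_in[x, y, z] <= P_EPS:
                    state[x, y, z] = INNER
                    changed += 1
                    added += 1
                    du_sum += du
    return changed, added, du_sum


@njit(cache=False)
def sweep_round2_outer(
    state, f, domain, p_in, p_out,
    f_gm, f_wm, s_high, s_low, s_verylow, n_reg, n_outer_min, p0, beta,
):
    """One round-2 sweep of the outer front.

    The outer surface always has strictly positive speed; when the move would
    not decrease the energy it creeps at S_verylow (to cross residual CSF).
    Moves must pass the homotopy test; blocked candidates retry next sweep.
    """
    changed = 0
    added = 0
    du_sum = 0.0
    nx, ny, nz = state.shape
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                if state[x, y, z] != UNCLAIMED or not domain[x, y, z]:
                    continue
                if not _adjacent6(state, x, y, z, OUTER):
                    continue
                if _adjacent6(state, x, y, z, INNER):
                    state[x, y, z] = INTERFACE
                    changed += 1
                    continue
                fv = f[x, y, z]
                n = _count26(state, x, y, z, OUTER)
                du = fv + beta * (26.0 - 2.0 * n)
                if du < 0.0:
                    s = speed_outer_kernel(
                        fv, n, f_gm, f_wm, s_high, s_low, s_verylow, n_reg, n_outer_min
                    )
                else:
                    s = s_verylow
                p_out[x, y, z] -= p0 * s / s_high
                if p_out[x, y, z] <= P_EPS:
                    if _simple_in_state(state, x, y, z, OUTER):
                        state[x, y, z] = OUTER
                        changed += 1
                        added += 1
                        du_sum += du
                    else:
                        p_out[x, y, z] = 0.0
    return changed, added, du_sum
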