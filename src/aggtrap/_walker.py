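"""Numba kernels for the target-search walker.

Geometry queries use flat uniform cell lists: for each cubic cell of a grid
covering the nucleus bounding cube, ``build_cell_lists`` stores the indices
of every sphere that intersects the cell, so a walker needs exactly one
cell lookup per tick for the target-hit test and one for the
inside-aggregate test.

Randomness comes from an inline xorshift64* generator (seeded per batch via
splitmix64), which is deterministic across platforms and much cheaper than
a library RNG in this inner loop.  Two exact shortcuts keep the kernels
fast without changing the walk's law: in accept mode the run of frozen
ticks inside an obstacle is drawn directly from the geometric distribution,
and the target-hit test is skipped while the walker is inside an obstacle
(targets are placed outside obstacles, so a hit there is impossible).
"""

import numpy as np
from numba import njit

__all__ = ["build_cell_lists", "run_walkers"]

_U64 = np.uint64
_MULT = _U64(0x2545F4914F6CDD1D)  # xorshift64* output multiplier
_SM_GAMMA = _U64(0x9E3779B97F4A7C15)
_DOUBLE_NORM = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def build_cell_lists(centers, radius, R, cell):
    """CSR cell lists of spheres intersecting each grid cell.

    Grid covers [-R, R]^3 with cubic cells of side ``cell``.  Returns
    (start, items, cell, ncell): sphere indices for flat cell c are
    items[start[c]:start[c+1]].
    """
    ncell = int(np.ceil(2.0 * R / cell))
    n = centers.shape[0]
    counts = np.zeros(ncell * ncell * ncell, dtype=np.int64)
    start = np.zeros(ncell * ncell * ncell + 1, dtype=np.int64)
    items = np.empty(0, dtype=np.int64)
    cursor = np.empty(0, dtype=np.int64)
    for pass_id in range(2):
        if pass_id == 1:
            for c in range(ncell * ncell * ncell):
                start[c + 1] = start[c] + counts[c]
            items = np.empty(start[-1], dtype=np.int64)
            cursor = start[:-1].copy()
        for i in range(n):
            cx, cy, cz = centers[i, 0], centers[i, 1], centers[i, 2]
            i0 = max(int((cx - radius + R) // cell), 0)
            i1 = min(int((cx + radius + R) // cell), ncell - 1)
            j0 = max(int((cy - radius + R) // cell), 0)
            j1 = min(int((cy + radius + R) // cell), ncell - 1)
            k0 = max(int((cz - radius + R) // cell), 0)
            k1 = min(int((cz + radius + R) // cell), ncell - 1)
            for ii in range(i0, i1 + 1):
                x0 = ii * cell - R
                dx = max(x0 - cx, 0.0, cx - (x0 + cell))
                for jj in range(j0, j1 + 1):
                    y0 = jj * cell - R
                    dy = max(y0 - cy, 0.0, cy - (y0 + cell))
                    for kk in range(k0, k1 + 1):
                        z0 = kk * cell - R
                        dz = max(z0 - cz, 0.0, cz - (z0 + cell))
                        if dx * dx + dy * dy + dz * dz <= radius * radius:
                            c = (ii * ncell + jj) * ncell + kk
                            if pass_id == 0:
                                counts[c] += 1
                            else:
                                items[cursor[c]] = i
                                cursor[c] += 1
    return start, items, float(cell), ncell


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + _SM_GAMMA) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _xs_next(s):
    s ^= s >> _U64(12)
    s ^= (s << _U64(25)) & _U64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> _U64(27)
    return s


@njit(cache=True, inline="always")
def _to_unit(s):
    return float(((s * _MULT) & _U64(0xFFFFFFFFFFFFFFFF)) >> _U64(11)) * _DOUBLE_NORM


@njit(cache=True, inline="always")
def _hit_sphere(x, y, z, centers, radius, start, items, R, cell, ncell):
    i = int((x + R) // cell)
    j = int((y + R) // cell)
    k = int((z + R) // cell)
    if i < 0:
        i = 0
    elif i >= ncell:
        i = ncell - 1
    if j < 0:
        j = 0
    elif j >= ncell:
        j = ncell - 1
    if k < 0:
        k = 0
    elif k >= ncell:
        k = ncell - 1
    c = (i * ncell + j) * ncell + k
    r2 = radius * radius
    for idx in range(start[c], start[c + 1]):
        t = items[idx]
        dx = x - centers[t, 0]
        dy = y - centers[t, 1]
        dz = z - centers[t, 2]
        if dx * dx + dy * dy + dz * dz <= r2:
            return True
    return False


@njit(cache=True)
def run_walkers(
    n_sims,
    seed,
    R,
    target_centers,
    target_radius,
    agg_centers,
    agg_radius,
    t_start,
    t_items,
    t_cell,
    t_ncell,
    a_start,
    a_items,
    a_cell,
    a_ncell,
    slowdown,
    speed_mode,
    step_cap,
):
    """First-passage tick counts for ``n_sims`` independent walkers.

    Each walker starts uniformly in the aggregate-free space, takes
    unit-length steps in uniformly random 3D directions (step length
    ``1/slowdown`` inside aggregates in speed mode; in accept mode the
    move executes with probability ``1/slowdown`` instead), rejects moves
    that would exit the nucleus sphere (the tick still counts), and stops
    as soon as its position lies within ``target_radius`` of any target
    center.  Returns -1 for walkers that exceed ``step_cap``.
    """
    out = np.empty(n_sims, dtype=np.int64)
    has_aggs = agg_centers.shape[0] > 0
    R2 = R * R
    inv_slow = 1.0 / slowdown
    ell_in = inv_slow if speed_mode else 1.0
    # geometric run length of frozen ticks: log(u)/log(1-p)
    log1mp = np.log(1.0 - inv_slow) if (not speed_mode and slowdown > 1.0) else 0.0
    rng = _splitmix64(_U64(seed))
    for sim in range(n_sims):
        rng = _splitmix64(rng)
        s = rng if rng != _U64(0) else _U64(0x1234567887654321)
        # uniform start in the free (non-aggregate) space
        while True:
            s = _xs_next(s)
            x = (2.0 * _to_unit(s) - 1.0) * R
            s = _xs_next(s)
            y = (2.0 * _to_unit(s) - 1.0) * R
            s = _xs_next(s)
            z = (2.0 * _to_unit(s) - 1.0) * R
            if x * x + y * y + z * z > R2:
                continue
            if has_aggs and _hit_sphere(
                x, y, z, agg_centers, agg_radius, a_start, a_items, R, a_cell, a_ncell
            ):
                continue
            break
        n = 0
        capped = False
        inside = False  # start is in free space by construction
        while True:
            if not inside and _hit_sphere(
                x, y, z, target_centers, target_radius, t_start, t_items, R, t_cell, t_ncell
            ):
                break
            if n >= step_cap:
                capped = True
                break
            ell = 1.0
            if inside:
                if speed_mode:
                    ell = ell_in
                elif slowdown > 1.0:
                    # frozen ticks before the next executed move
                    s = _xs_next(s)
                    u = _to_unit(s)
                    if u <= 0.0:
                        u = _DOUBLE_NORM
                    n += int(np.log(u) / log1mp)  # 0,1,2,... rejected ticks
                    if n >= step_cap:
                        capped = True
                        break
            # uniform direction via Marsaglia rejection on the unit disk
            while True:
                s = _xs_next(s)
                u = 2.0 * _to_unit(s) - 1.0
                s = _xs_next(s)
                v = 2.0 * _to_unit(s) - 1.0
                d2 = u * u + v * v
                if d2 < 1.0:
                    break
            f = 2.0 * np.sqrt(1.0 - d2)
            nx = x + ell * u * f
            ny = y + ell * v * f
            nz = z + ell * (1.0 - 2.0 * d2)
            if nx * nx + ny * ny + nz * nz <= R2:
                x = nx
                y = ny
                z = nz
                inside = has_aggs and _hit_sphere(
                    x, y, z, agg_centers, agg_radius, a_start, a_items, R, a_cell, a_ncell
                )
            n += 1
        out[sim] = -1 if capped else n
    return out
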