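"""Independent brute-force implementations used as test oracles.

``naive_walk`` re-implements the target-search walk rules directly in
vectorized numpy, sharing no code (and no RNG) with the production numba
engine: unit steps in uniform 3D directions, nucleus-boundary rejection,
slowdown inside aggregate spheres either as step length 1/s ("speed") or
as move-acceptance probability 1/s ("accept"), termination on first
arrival within the target radius.
"""

import numpy as np


def naive_walk(
    geom,
    n_walkers: int,
    slowdown: float,
    mode: str,
    rng: np.random.Generator,
    max_steps: int = 10_000_000,
    record_inside: bool = False,
):
    """First-passage tick counts (and optional inside-aggregate tick counts)."""
    R = geom.nucleus_radius
    tc = geom.target_centers
    rt2 = geom.target_radius**2
    ac = geom.aggregate_centers
    ra2 = geom.aggregate_radius**2 if len(ac) else 0.0

    def inside_agg(p):
        if len(ac) == 0:
            return np.zeros(len(p), dtype=bool)
        d2 = ((p[:, None, :] - ac[None, :, :]) ** 2).sum(axis=2)
        return (d2 <= ra2).any(axis=1)

    def at_target(p):
        d2 = ((p[:, None, :] - tc[None, :, :]) ** 2).sum(axis=2)
        return (d2 <= rt2).any(axis=1)

    # uniform starts in free space
    pos = np.empty((0, 3))
    while len(pos) < n_walkers:
        cand = rng.uniform(-R, R, size=(2 * n_walkers, 3))
        cand = cand[(cand**2).sum(axis=1) <= R * R]
        cand = cand[~inside_agg(cand)]
        pos = np.vstack([pos, cand])
    pos = pos[:n_walkers]

    steps = np.zeros(n_walkers, dtype=np.int64)
    inside_ticks = np.zeros(n_walkers, dtype=np.int64)
    active = ~at_target(pos)
    n_ticks = 0
    while active.any():
        n_ticks += 1
        if n_ticks > max_steps:
            raise RuntimeError("oracle exceeded max_steps")
        p = pos[active]
        k = len(p)
        ins = inside_agg(p)
        if record_inside:
            ii = np.zeros(n_walkers, dtype=bool)
            ii[np.nonzero(active)[0]] = ins
            inside_ticks[ii] += 1
        # isotropic unit directions
        v = rng.normal(size=(k, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ell = np.ones(k)
        move = np.ones(k, dtype=bool)
        if slowdown > 1.0 and ins.any():
            if mode == "speed":
                ell[ins] = 1.0 / slowdown
            else:
                move[ins] = rng.uniform(size=int(ins.sum())) < 1.0 / slowdown
        new = p + (ell * move)[:, None] * v
        out = (new**2).sum(axis=1) > R * R
        new[out] = p[out]
        pos[active] = new
        steps[active] += 1
        hit = at_target(new)
        idx = np.nonzero(active)[0]
        active[idx[hit]] = False
    if record_inside:
        return steps, inside_ticks
    return steps
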