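"""3D first-passage target-search simulation with slow-diffusion obstacles.

A point-like transcription factor performs a unit-step random walk inside a
spherical nucleus that contains two kinds of spheres: small *target* sites
(cognate binding loci) and larger *aggregate* obstacles (decoy traps).  The
walk terminates on first arrival at any target; the recorded observable is
the number of walking ticks (first-passage time in step units).  Inside an
aggregate the walker's motion is slowed ``slowdown_factor``-fold.  The
headline statistic is the *fold of delay*: the mean first-passage time
normalized to a matched aggregate-free control.

Two slowdown mechanics are provided (``slowdown_mode``):

``"accept"`` (default)
    Moves proposed from inside an aggregate are executed with probability
    ``1/slowdown_factor`` (a time-change of the embedded unit-step walk).
    This inflates the walker's dwell time inside obstacles exactly
    ``slowdown_factor``-fold, so the fold of delay approaches
    ``1 + (slowdown_factor - 1) * VR / (1 - VR)`` for small volume ratios
    and is insensitive to obstacle size at fixed volume ratio.  Dwell
    statistics are well defined and replicate means converge quickly.

``"speed"``
    The step length inside aggregates is reduced to ``1/slowdown_factor``
    spatial units, i.e. the literal walking speed is cut by the slowdown
    factor.  The embedded walk then spends ``slowdown_factor**2`` more
    moves inside obstacles (its occupancy follows the inverse local
    diffusivity), so the fold of delay scales like
    ``1 + c * slowdown_factor**2 * VR`` and per-walk step counts are
    heavily right-tailed (deep obstacle excursions).  Kept as a
    sensitivity-analysis variant of the same rule set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._walker import build_cell_lists, run_walkers

__all__ = [
    "SearchSimConfig",
    "NucleusGeometry",
    "SearchSimResult",
    "PackingError",
    "StepCapError",
    "build_geometry",
    "simulate_search",
    "run_walks",
    "run_condition",
    "fold_of_delay",
    "sweep",
    "volume_ratio",
    "diameter_for_volume_ratio",
    "n_aggregates_for_volume_ratio",
]


class PackingError(RuntimeError):
    """Raised when non-overlapping obstacle placement fails (packing too dense)."""


class StepCapError(RuntimeError):
    """Raised when a walker exceeds the configured step cap without reaching a target."""


@dataclass(frozen=True)
class SearchSimConfig:
    """Parameters of one simulated nuclear search condition.

    Lengths are in abstract spatial units; the nucleus is a sphere of
    diameter ``nucleus_diameter`` (default 400).  ``n_targets`` binding
    sites of diameter ``target_diameter`` (default 5000 sites of diameter
    2) and ``n_aggregates`` obstacle spheres of diameter
    ``aggregate_diameter`` are placed uniformly at random, obstacles
    mutually non-overlapping and targets restricted to the obstacle-free
    space.
    """

    n_aggregates: int = 0
    aggregate_diameter: float = 20.0
    nucleus_diameter: float = 400.0
    n_targets: int = 5000
    target_diameter: float = 2.0
    slowdown_factor: float = 100.0
    slowdown_mode: str = "accept"
    n_simulations: int = 2000
    n_geometries: int = 20
    step_cap: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_diameter <= 0 or self.target_diameter <= 0:
            raise ValueError("diameters must be positive")
        if self.n_aggregates > 0 and self.aggregate_diameter <= 0:
            raise ValueError("aggregate_diameter must be positive")
        if self.slowdown_factor < 1:
            raise ValueError("slowdown_factor must be >= 1")
        if self.slowdown_mode not in ("speed", "accept"):
            raise ValueError("slowdown_mode must be 'speed' or 'accept'")
        if self.n_targets < 1 or self.n_simulations < 1 or self.n_geometries < 1:
            raise ValueError("counts must be positive")
        if self.n_aggregates > 0 and self.aggregate_diameter >= self.nucleus_diameter:
            raise ValueError("aggregates must fit inside the nucleus")
        if self.volume_ratio >= 0.5:
            raise ValueError(
                f"aggregate volume ratio {self.volume_ratio:.2f} >= 0.5; packing rejected"
            )

    @property
    def nucleus_radius(self) -> float:
        return self.nucleus_diameter / 2.0

    @property
    def volume_ratio(self) -> float:
        """Total aggregate volume divided by nucleus volume (VR)."""
        return volume_ratio(
            self.n_aggregates, self.aggregate_diameter, self.nucleus_diameter
        )

    def replace(self, **kw) -> "SearchSimConfig":
        return dataclasses.replace(self, **kw)


def volume_ratio(n_aggregates: int, aggregate_diameter: float, nucleus_diameter: float) -> float:
    """VR = N * (D/2)^3 / (R_nucleus)^3."""
    if n_aggregates == 0:
        return 0.0
    return n_aggregates * (aggregate_diameter / nucleus_diameter) ** 3


def diameter_for_volume_ratio(vr: float, n_aggregates: int, nucleus_diameter: float = 400.0) -> float:
    """Aggregate diameter giving volume ratio ``vr`` with ``n_aggregates`` spheres."""
    return nucleus_diameter * (vr / n_aggregates) ** (1.0 / 3.0)


def n_aggregates_for_volume_ratio(vr: float, aggregate_diameter: float, nucleus_diameter: float = 400.0) -> int:
    """Number of aggregates of a given diameter closest to volume ratio ``vr``."""
    return int(round(vr * (nucleus_diameter / aggregate_diameter) ** 3))


@dataclass
class NucleusGeometry:
    """One realization of the simulator's world: nucleus + obstacles + targets."""

    nucleus_radius: float
    aggregate_centers: np.ndarray  # (N, 3)
    aggregate_radius: float
    target_centers: np.ndarray  # (n_targets, 3)
    target_radius: float

    @property
    def n_aggregates(self) -> int:
        return len(self.aggregate_centers)

    def contains_point_in_aggregate(self, p: np.ndarray) -> bool:
        if self.n_aggregates == 0:
            return False
        d2 = np.sum((self.aggregate_centers - p) ** 2, axis=1)
        return bool(np.any(d2 <= self.aggregate_radius**2))


def _sample_in_sphere(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    """Uniform points in a sphere of given radius (rejection from the cube)."""
    out = np.empty((0, 3))
    while len(out) < n:
        cand = rng.uniform(-radius, radius, size=(max(2 * (n - len(out)), 16), 3))
        cand = cand[np.sum(cand**2, axis=1) <= radius**2]
        out = np.vstack([out, cand])
    return out[:n]


def build_geometry(cfg: SearchSimConfig, rng: np.random.Generator) -> NucleusGeometry:
    """Place aggregates then targets by rejection sampling.

    Aggregates are mutually non-overlapping and fully interior to the
    nucleus; targets are fully interior and excluded from aggregates
    ("the remaining space").  Raises :class:`PackingError` if a
    non-overlapping configuration cannot be found in a bounded number of
    attempts.
    """
    R = cfg.nucleus_radius
    r_a = cfg.aggregate_diameter / 2.0
    r_t = cfg.target_diameter / 2.0

    centers = np.empty((cfg.n_aggregates, 3))
    n_placed = 0
    attempts = 0
    max_attempts = 1000 * max(cfg.n_aggregates, 1)
    while n_placed < cfg.n_aggregates:
        if attempts >= max_attempts:
            raise PackingError(
                f"failed to place {cfg.n_aggregates} aggregates of diameter "
                f"{cfg.aggregate_diameter} after {attempts} attempts (VR={cfg.volume_ratio:.3f})"
            )
        cand = _sample_in_sphere(rng, R - r_a, 1)[0]
        attempts += 1
        if n_placed:
            d2 = np.sum((centers[:n_placed] - cand) ** 2, axis=1)
            if np.any(d2 < (2 * r_a) ** 2):
                continue
        centers[n_placed] = cand
        n_placed += 1

    targets = np.empty((cfg.n_targets, 3))
    n_placed = 0
    min_d2 = (r_a + r_t) ** 2
    while n_placed < cfg.n_targets:
        cand = _sample_in_sphere(rng, R - r_t, cfg.n_targets - n_placed)
        if cfg.n_aggregates:
            keep = np.ones(len(cand), dtype=bool)
            for c in centers:
                keep &= np.sum((cand - c) ** 2, axis=1) >= min_d2
            cand = cand[keep]
        k = len(cand)
        targets[n_placed : n_placed + k] = cand
        n_placed += k

    return NucleusGeometry(
        nucleus_radius=R,
        aggregate_centers=centers,
        aggregate_radius=r_a,
        target_centers=targets,
        target_radius=r_t,
    )


def _grids_for(geom: NucleusGeometry):
    R = geom.nucleus_radius
    # Targets: fine grid whose cells list every target sphere intersecting the
    # cell cube, so the hit test needs a single cell lookup per tick.
    cell_t = max(4.0 * geom.target_radius, R / 64.0)
    tg = build_cell_lists(geom.target_centers, geom.target_radius, R, cell_t)
    if geom.n_aggregates:
        cell_a = max(geom.aggregate_radius, R / 16.0)
        ag = build_cell_lists(geom.aggregate_centers, geom.aggregate_radius, R, cell_a)
    else:
        empty = np.zeros((0, 3))
        ag = build_cell_lists(empty, 1.0, R, R)
    return tg, ag


def _run_geometry(
    geom: NucleusGeometry, cfg: SearchSimConfig, n_sims: int, kernel_seed: int
) -> np.ndarray:
    (t_start, t_items, t_cell, t_ncell), (a_start, a_items, a_cell, a_ncell) = _grids_for(geom)
    steps = run_walkers(
        n_sims,
        int(kernel_seed),
        geom.nucleus_radius,
        np.ascontiguousarray(geom.target_centers),
        geom.target_radius,
        np.ascontiguousarray(geom.aggregate_centers),
        geom.aggregate_radius,
        t_start,
        t_items,
        t_cell,
        t_ncell,
        a_start,
        a_items,
        a_cell,
        a_ncell,
        float(cfg.slowdown_factor),
        cfg.slowdown_mode == "speed",
        int(cfg.step_cap),
    )
    if np.any(steps < 0):
        raise StepCapError(
            f"{int(np.sum(steps < 0))} walker(s) exceeded step cap {cfg.step_cap}"
        )
    return steps


def simulate_search(
    geom: NucleusGeometry, cfg: SearchSimConfig, rng: np.random.Generator
) -> int:
    """Run a single first-passage walk in ``geom``; return the tick count."""
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    return int(_run_geometry(geom, cfg, 1, kernel_seed)[0])


def run_walks(
    geom: NucleusGeometry, cfg: SearchSimConfig, n_sims: int, seed: int
) -> np.ndarray:
    """Per-simulation first-passage tick counts on one fixed geometry."""
    return _run_geometry(geom, cfg, n_sims, seed)


def run_condition(cfg: SearchSimConfig) -> np.ndarray:
    """Per-simulation first-passage step counts for one condition.

    ``cfg.n_simulations`` walks are distributed over ``cfg.n_geometries``
    independently sampled nucleus realizations; all randomness derives from
    ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    geom_ss, walk_ss = ss.spawn(2)
    geom_seeds = geom_ss.spawn(cfg.n_geometries)
    walk_seeds = walk_ss.generate_state(cfg.n_geometries) % (2**31 - 1)
    per_geom = np.full(cfg.n_geometries, cfg.n_simulations // cfg.n_geometries)
    per_geom[: cfg.n_simulations % cfg.n_geometries] += 1
    out = []
    for gs, ks, n in zip(geom_seeds, walk_seeds, per_geom):
        if n == 0:
            continue
        geom = build_geometry(cfg, np.random.default_rng(gs))
        out.append(_run_geometry(geom, cfg, int(n), int(ks)))
    return np.concatenate(out)


@dataclass
class SearchSimResult:
    """Fold of delay for one condition versus its aggregate-free control."""

    n_aggregates: int
    aggregate_diameter: float
    volume_ratio: float
    mean_steps: float
    se_steps: float
    control_mean_steps: float
    control_se_steps: float
    fold_of_delay: float
    fold_ci_low: float
    fold_ci_high: float
    n_simulations: int
    seed: int
    steps: np.ndarray = field(repr=False)
    control_steps: np.ndarray = field(repr=False)

    def to_row(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_aggregates",
                "aggregate_diameter",
                "volume_ratio",
                "mean_steps",
                "se_steps",
                "control_mean_steps",
                "control_se_steps",
                "fold_of_delay",
                "fold_ci_low",
                "fold_ci_high",
                "n_simulations",
                "seed",
            )
        }
        return d


def _bootstrap_fold(
    steps: np.ndarray, control: np.ndarray, seed: int, n_boot: int = 1000
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    na, nb = len(steps), len(control)
    folds = np.empty(n_boot)
    for i in range(n_boot):
        a = steps[rng.integers(0, na, na)].mean()
        b = control[rng.integers(0, nb, nb)].mean()
        folds[i] = a / b
    return float(np.quantile(folds, 0.025)), float(np.quantile(folds, 0.975))


def fold_of_delay(cfg: SearchSimConfig, control_steps: np.ndarray | None = None) -> SearchSimResult:
    """Mean first-passage steps normalized to a matched aggregate-free control.

    The control regenerates geometry (targets only, N=0) under the same
    seed protocol and identical non-aggregate parameters.  A precomputed
    ``control_steps`` array may be passed to share one control across a
    family of conditions.
    """
    steps = run_condition(cfg)
    if control_steps is None:
        control_steps = run_condition(cfg.replace(n_aggregates=0))
    mean, cmean = steps.mean(), control_steps.mean()
    se = steps.std(ddof=1) / np.sqrt(len(steps))
    cse = control_steps.std(ddof=1) / np.sqrt(len(control_steps))
    lo, hi = _bootstrap_fold(steps, control_steps, seed=cfg.seed + 12345)
    return SearchSimResult(
        n_aggregates=cfg.n_aggregates,
        aggregate_diameter=cfg.aggregate_diameter,
        volume_ratio=cfg.volume_ratio,
        mean_steps=float(mean),
        se_steps=float(se),
        control_mean_steps=float(cmean),
        control_se_steps=float(cse),
        fold_of_delay=float(mean / cmean),
        fold_ci_low=lo,
        fold_ci_high=hi,
        n_simulations=len(steps),
        seed=cfg.seed,
        steps=steps,
        control_steps=control_steps,
    )


def sweep(configs: Sequence[SearchSimConfig], share_controls: bool = True) -> pd.DataFrame:
    """Run a family of conditions; returns one row per condition.

    With ``share_controls`` (default), conditions that share all
    non-aggregate parameters and seed reuse a single aggregate-free control
    run.
    """
    controls: dict[tuple, np.ndarray] = {}
    rows = []
    for cfg in configs:
        key = (
            cfg.nucleus_diameter,
            cfg.n_targets,
            cfg.target_diameter,
            cfg.n_simulations,
            cfg.n_geometries,
            cfg.seed,
        )
        ctrl = controls.get(key) if share_controls else None
        res = fold_of_delay(cfg, control_steps=ctrl)
        if share_controls:
            controls[key] = res.control_steps
        rows.append(res.to_row())
    return pd.DataFrame(rows)
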