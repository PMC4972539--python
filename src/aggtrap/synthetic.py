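"""Synthetic single-molecule and imaging data with known ground truth.

Generators for every input the analysis stages consume:

* plain Brownian trajectory tables (fixtures for MSD / translocation /
  angle analyses),
* photoactivation localization streams in which a tracked protein
  occupies three dynamic states — fast diffusion, transient clustering
  with a ~10–20 s episode lifetime, and permanent immobilization inside
  stable aggregate regions,
* two-channel aggregate images in which a second channel is enriched at
  (recruitment) or depleted from (exclusion) the aggregate disks,
* single-exponential FRAP recovery curves.

Coordinates are continuous micrometres with the origin at the image
corner; frames are 0-based; default frame interval 20 ms.  Identical
seed and parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThreeStateModel",
    "FrapModel",
    "gen_brownian_tracks",
    "gen_three_state_stream",
    "gen_aggregate_images",
    "gen_frap_curve",
]

STATE_FAST = "fast"
STATE_CLUSTER = "cluster"
STATE_AGGREGATE = "aggregate"


@dataclass(frozen=True)
class ThreeStateModel:
    """Parameters of the three-state localization-stream generator.

    ``aggregate_regions`` are disks ``(cx_um, cy_um, r_um)`` that
    immobilize any molecule entering them (absorbing — stable aggregates
    show essentially no molecular exchange on imaging timescales) and,
    with ``aggregate_loc_rate > 0``, emit their own immobile detections
    uniformly over the acquisition.  ``cluster_sites`` are points at which
    one transient clustering episode occurs; during an episode the site
    emits molecules that diffuse slowly within ``cluster_radius`` and
    disperse when the episode ends.
    """

    d_fast: float = 3.0  # µm²/s, free state
    d_cluster: float = 0.1  # µm²/s, inside dynamic clusters
    cluster_lifetime_mean: float = 15.0  # s, exponential episode mean
    aggregate_regions: tuple[tuple[float, float, float], ...] = ()
    frame_interval: float = 0.02  # s
    localization_error_sd: float = 0.03  # µm
    n_frames: int = 3000
    activation_rate: float = 0.5  # expected new free molecules per frame
    seed: int = 0
    # additional knobs (package choices, not externally prescribed)
    field_size: float = 10.0  # µm, square field of view
    bleach_prob: float = 0.05  # per-frame photobleaching probability
    cluster_sites: tuple[tuple[float, float], ...] = ()
    cluster_radius: float = 0.1  # µm
    cluster_loc_rate: float = 1.0  # new molecules per frame during an episode
    aggregate_loc_rate: float = 0.0  # detections per frame per region
    cluster_episode_duration: float | None = None  # fixed duration override (s)

    def __post_init__(self) -> None:
        if not (self.d_fast > self.d_cluster >= 0):
            raise ValueError("require d_fast > d_cluster >= 0")
        if self.cluster_lifetime_mean <= 0 or self.frame_interval <= 0:
            raise ValueError("cluster_lifetime_mean and frame_interval must be positive")
        if self.n_frames < 1 or self.activation_rate < 0:
            raise ValueError("n_frames >= 1 and activation_rate >= 0 required")
        if not 0 < self.bleach_prob <= 1:
            raise ValueError("bleach_prob must be in (0, 1]")


@dataclass(frozen=True)
class FrapModel:
    """Ground truth for one synthetic FRAP recovery curve."""

    plateau: float = 1.0
    tau: float = 10.0  # s
    noise_sd: float = 0.0
    sample_times: tuple[float, ...] = tuple(np.arange(0.0, 40.0, 0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if np.any(np.diff(np.asarray(self.sample_times)) <= 0):
            raise ValueError("sample_times must be strictly increasing")


def gen_brownian_tracks(
    d: float,
    n_tracks: int,
    n_steps: int,
    frame_interval: float = 0.02,
    localization_error_sd: float = 0.03,
    seed: int = 0,
    field_size: float = 10.0,
) -> pd.DataFrame:
    """Pure-Brownian 2D trajectories as a tidy table.

    Each track has ``n_steps + 1`` points; per-axis step variance is
    ``2 * d * frame_interval`` and independent Gaussian localization error
    of SD ``localization_error_sd`` is added to every reported point.
    Columns: ``track_id, frame, x_um, y_um``.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    if n_tracks < 1 or n_steps < 2:
        raise ValueError("need n_tracks >= 1 and n_steps >= 2")
    rng = np.random.default_rng(seed)
    n_pts = n_steps + 1
    starts = rng.uniform(0.0, field_size, size=(n_tracks, 1, 2))
    steps = rng.normal(
        0.0, np.sqrt(2.0 * d * frame_interval), size=(n_tracks, n_steps, 2)
    )
    pos = np.concatenate([starts, starts + np.cumsum(steps, axis=1)], axis=1)
    if localization_error_sd > 0:
        pos = pos + rng.normal(0.0, localization_error_sd, size=pos.shape)
    return pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n_tracks), n_pts),
            "frame": np.tile(np.arange(n_pts), n_tracks),
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
        }
    )


def _in_any_region(
    x: np.ndarray, y: np.ndarray, regions: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    hit = np.zeros(len(x), dtype=bool)
    for cx, cy, r in regions:
        hit |= (x - cx) ** 2 + (y - cy) ** 2 <= r * r
    return hit


def gen_three_state_stream(model: ThreeStateModel) -> tuple[pd.DataFrame, dict]:
    """Simulate a photoactivation localization stream with ground truth.

    Returns ``(locs, truth)``: ``locs`` has columns
    ``frame, x_um, y_um, intensity, state_label, molecule_id`` (reported
    positions include localization error; ``state_label`` is the
    ground-truth dynamic state of the molecule in that frame), and
    ``truth`` carries the cluster-episode table
    (``site, x_um, y_um, start_s, duration_s``) plus the per-molecule true
    positions needed by linking benchmarks.
    """
    rng = np.random.default_rng(model.seed)
    dt = model.frame_interval
    step_fast = np.sqrt(2.0 * model.d_fast * dt)
    step_cluster = np.sqrt(2.0 * model.d_cluster * dt)

    episodes = []
    for i, (sx, sy) in enumerate(model.cluster_sites):
        duration = (
            model.cluster_episode_duration
            if model.cluster_episode_duration is not None
            else rng.exponential(model.cluster_lifetime_mean)
        )
        t_total = model.n_frames * dt
        start = rng.uniform(0.0, max(t_total - duration, 0.0) * 0.8)
        episodes.append(
            {"site": i, "x_um": sx, "y_um": sy, "start_s": start, "duration_s": duration}
        )
    episodes_df = pd.DataFrame(
        episodes, columns=["site", "x_um", "y_um", "start_s", "duration_s"]
    )

    # active molecule state (object columns kept small: plain ndarrays)
    mol_x: list[float] = []
    mol_y: list[float] = []
    mol_state: list[str] = []
    mol_site: list[int] = []
    mol_id: list[int] = []
    next_id = 0

    rec_frame: list[np.ndarray] = []
    rec_x: list[np.ndarray] = []
    rec_y: list[np.ndarray] = []
    rec_state: list[list[str]] = []
    rec_id: list[np.ndarray] = []

    for f in range(model.n_frames):
        t = f * dt
        # photoactivation of free molecules, uniform over the field
        n_new = rng.poisson(model.activation_rate)
        for _ in range(n_new):
            x, y = rng.uniform(0.0, model.field_size, size=2)
            state = (
                STATE_AGGREGATE
                if _in_any_region(np.array([x]), np.array([y]), model.aggregate_regions)[0]
                else STATE_FAST
            )
            mol_x.append(x)
            mol_y.append(y)
            mol_state.append(state)
            mol_site.append(-1)
            mol_id.append(next_id)
            next_id += 1
        # cluster-site activations during active episodes
        for ep in episodes:
            if ep["start_s"] <= t < ep["start_s"] + ep["duration_s"]:
                for _ in range(rng.poisson(model.cluster_loc_rate)):
                    ang = rng.uniform(0.0, 2.0 * np.pi)
                    rad = model.cluster_radius * np.sqrt(rng.uniform())
                    mol_x.append(ep["x_um"] + rad * np.cos(ang))
                    mol_y.append(ep["y_um"] + rad * np.sin(ang))
                    mol_state.append(STATE_CLUSTER)
                    mol_site.append(int(ep["site"]))
                    mol_id.append(next_id)
                    next_id += 1
        # immobile detections intrinsic to stable aggregates
        for cx, cy, r in model.aggregate_regions:
            for _ in range(rng.poisson(model.aggregate_loc_rate)):
                ang = rng.uniform(0.0, 2.0 * np.pi)
                rad = r * np.sqrt(rng.uniform())
                mol_x.append(cx + rad * np.cos(ang))
                mol_y.append(cy + rad * np.sin(ang))
                mol_state.append(STATE_AGGREGATE)
                mol_site.append(-1)
                mol_id.append(next_id)
                next_id += 1

        if mol_x:
            x = np.array(mol_x)
            y = np.array(mol_y)
            states = np.array(mol_state, dtype=object)
            sites = np.array(mol_site)
            ids = np.array(mol_id)

            rec_frame.append(np.full(len(x), f))
            rec_x.append(x.copy())
            rec_y.append(y.copy())
            rec_state.append(list(states))
            rec_id.append(ids.copy())

            # diffusion step by state
            fast = states == STATE_FAST
            clus = states == STATE_CLUSTER
            x[fast] += rng.normal(0.0, step_fast, fast.sum())
            y[fast] += rng.normal(0.0, step_fast, fast.sum())
            if clus.any():
                x[clus] += rng.normal(0.0, step_cluster, clus.sum())
                y[clus] += rng.normal(0.0, step_cluster, clus.sum())
                # confine cluster members to their site
                for i in np.nonzero(clus)[0]:
                    ep = episodes[sites[i]]
                    dx, dy = x[i] - ep["x_um"], y[i] - ep["y_um"]
                    rr = np.hypot(dx, dy)
                    if rr > model.cluster_radius:
                        x[i] = ep["x_um"] + dx / rr * model.cluster_radius
                        y[i] = ep["y_um"] + dy / rr * model.cluster_radius
            # cluster disassembly at episode end -> members become fast
            for i in np.nonzero(clus)[0]:
                ep = episodes[sites[i]]
                if (f + 1) * dt >= ep["start_s"] + ep["duration_s"]:
                    states[i] = STATE_FAST
                    sites[i] = -1
            # entering an aggregate region is absorbing
            mobile = states != STATE_AGGREGATE
            if model.aggregate_regions and mobile.any():
                entered = mobile & _in_any_region(x, y, model.aggregate_regions)
                states[entered] = STATE_AGGREGATE
            # photobleaching
            survive = rng.uniform(size=len(x)) > model.bleach_prob
            mol_x = list(x[survive])
            mol_y = list(y[survive])
            mol_state = list(states[survive])
            mol_site = list(sites[survive])
            mol_id = list(ids[survive])

    if rec_frame:
        frame = np.concatenate(rec_frame)
        true_x = np.concatenate(rec_x)
        true_y = np.concatenate(rec_y)
        state = np.concatenate([np.array(s, dtype=object) for s in rec_state])
        mid = np.concatenate(rec_id)
    else:
        frame = np.empty(0, dtype=int)
        true_x = true_y = np.empty(0)
        state = np.empty(0, dtype=object)
        mid = np.empty(0, dtype=int)

    err = model.localization_error_sd
    locs = pd.DataFrame(
        {
            "frame": frame,
            "x_um": true_x + (rng.normal(0.0, err, len(true_x)) if err > 0 else 0.0),
            "y_um": true_y + (rng.normal(0.0, err, len(true_y)) if err > 0 else 0.0),
            "intensity": rng.normal(1000.0, 100.0, len(true_x)),
            "state_label": state.astype(str) if len(state) else state,
            "molecule_id": mid,
        }
    )
    truth = {
        "episodes": episodes_df,
        "true_x": true_x,
        "true_y": true_y,
    }
    return locs, truth


def gen_aggregate_images(
    n_regions: int,
    enrichment: float,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    radius_range: tuple[float, float] = (10.0, 25.0),
    amplitude: float = 200.0,
    ch2_level: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    edge_softness: float = 0.15,
) -> tuple[np.ndarray, list[dict]]:
    """Two-channel image with disk-like aggregates and a known contrast.

    Channel 1 carries bright soft-edged aggregate disks of varying radii
    on a dim background.  Channel 2 carries a uniform level that is scaled
    by ``(1 + enrichment)`` inside the aggregates: ``enrichment < 0``
    models exclusion (chromatin-like), ``> 0`` recruitment
    (trapped-factor-like), ``0`` indifference.  Returns the
    ``(2, H, W)`` float stack and the region annotations
    ``[{"cx_px", "cy_px", "r_px"}, ...]`` whose radii span twice the
    aggregate radius (aggregate plus surround), ready for size-normalized
    radial analysis.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not -1.0 <= enrichment:
        raise ValueError("enrichment must be >= -1")
    h, w = image_size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    regions: list[dict] = []
    profile = np.zeros((h, w))
    attempts = 0
    while len(regions) < n_regions:
        attempts += 1
        if attempts > 1000 * n_regions:
            raise RuntimeError("could not place non-overlapping regions; reduce n_regions")
        r = rng.uniform(*radius_range)
        r_reg = 2.0 * r
        cx = rng.uniform(r_reg + 2, w - r_reg - 2)
        cy = rng.uniform(r_reg + 2, h - r_reg - 2)
        if any(
            np.hypot(cx - q["cx_px"], cy - q["cy_px"]) < r_reg + q["r_px"] + 2
            for q in regions
        ):
            continue
        d = np.hypot(xx - cx, yy - cy)
        profile += 0.5 * (1.0 + np.tanh((r - d) / (edge_softness * r)))
        regions.append({"cx_px": float(cx), "cy_px": float(cy), "r_px": float(r_reg)})
    profile = np.clip(profile, 0.0, 1.0)

    ch1 = background + amplitude * profile
    ch2 = background + ch2_level * (1.0 + enrichment * profile)
    stack = np.stack([ch1, ch2])
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack, regions


def gen_frap_curve(model: FrapModel) -> pd.DataFrame:
    """Synthetic FRAP table ``(time_s, intensity)``.

    ``intensity(t) = plateau * (1 - exp(-t/tau)) + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(model.seed)
    t = np.asarray(model.sample_times, dtype=float)
    y = model.plateau * (1.0 - np.exp(-t / model.tau))
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd, size=len(t))
    return pd.DataFrame({"time_s": t, "intensity": y})
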