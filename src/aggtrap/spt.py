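"""Per-track diffusion estimation and kinematic statistics.

Mean-square-displacement (MSD) curves are time-averaged over all ordered
point pairs at each lag; the diffusion coefficient is the slope of the
first few MSD lags over lag time divided by 4 (2D imaging), gated by the
regression R².  Also provided: log-scale diffusion histograms,
adjacent-frame translocation histograms, three-point jump-angle
distributions, and splitting of track sets by a binary aggregate mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MsdCurve",
    "DiffusionEstimate",
    "AggregateMask",
    "compute_msd",
    "fit_diffusion",
    "estimate_tracks",
    "diffusion_histogram",
    "translocations",
    "translocation_histogram",
    "jump_angles",
    "angle_histogram",
    "split_tracks_by_mask",
    "mask_from_regions",
]

MIN_TRACK_POINTS = 5  # minimum consecutive frames for a diffusion estimate


@dataclass(frozen=True)
class MsdCurve:
    track_id: int
    lags: np.ndarray  # frame counts, 1..max_lag
    msd: np.ndarray  # µm² per lag
    n_pairs: np.ndarray  # displacement pairs averaged per lag


@dataclass(frozen=True)
class DiffusionEstimate:
    track_id: int
    d: float  # µm²/s (slope/4, clipped at 0); NaN if not estimable
    r_squared: float
    accepted: bool
    n_points: int


@dataclass(frozen=True)
class AggregateMask:
    """Binary raster marking aggregate area, in the trajectory coordinate frame.

    ``mask[i, j]`` covers the half-open pixel
    ``[j, j+1) x [i, i+1)`` in pixel units, i.e. µm coordinates divided by
    ``pixel_size_um``.
    """

    mask: np.ndarray  # bool, (H, W)
    pixel_size_um: float

    def contains(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        j = np.floor(np.asarray(x_um) / self.pixel_size_um).astype(int)
        i = np.floor(np.asarray(y_um) / self.pixel_size_um).astype(int)
        h, w = self.mask.shape
        ok = (i >= 0) & (i < h) & (j >= 0) & (j < w)
        out = np.zeros(len(ok), dtype=bool)
        out[ok] = self.mask[i[ok], j[ok]]
        return out


def mask_from_regions(
    regions, field_size_um: float, pixel_size_um: float
) -> AggregateMask:
    """Rasterize disk regions ``(cx_um, cy_um, r_um)`` into an AggregateMask."""
    n = int(np.ceil(field_size_um / pixel_size_um))
    yy, xx = (np.mgrid[0:n, 0:n] + 0.5) * pixel_size_um
    m = np.zeros((n, n), dtype=bool)
    for cx, cy, r in regions:
        m |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return AggregateMask(mask=m, pixel_size_um=pixel_size_um)


def _track_xy(track: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = track.sort_values("frame")
    return t["frame"].to_numpy().astype(int), t[["x_um", "y_um"]].to_numpy()


def compute_msd(track: pd.DataFrame, max_lag: int = 4) -> MsdCurve:
    """Time-averaged MSD of one track for lags 1..max_lag (frames).

    All ordered pairs of points whose frame numbers differ by exactly the
    lag contribute; lags beyond the track span are truncated.
    """
    frames, xy = _track_xy(track)
    if len(frames) < 2:
        raise ValueError("track must have at least 2 points")
    span = frames[-1] - frames[0]
    max_lag = int(min(max_lag, span))
    pos = {f: p for f, p in zip(frames, xy)}
    lags, msds, npairs = [], [], []
    for k in range(1, max_lag + 1):
        sq = [
            np.sum((pos[f + k] - pos[f]) ** 2)
            for f in frames
            if f + k in pos
        ]
        lags.append(k)
        msds.append(float(np.mean(sq)) if sq else np.nan)
        npairs.append(len(sq))
    tid = int(track["track_id"].iloc[0]) if "track_id" in track.columns else -1
    return MsdCurve(
        track_id=tid,
        lags=np.array(lags),
        msd=np.array(msds),
        n_pairs=np.array(npairs),
    )


def fit_diffusion(
    msd: MsdCurve,
    frame_interval: float,
    n_fit_lags: int = 4,
    r2_threshold: float = 0.8,
    n_points: int | None = None,
) -> DiffusionEstimate:
    """Diffusion coefficient from an ordinary least-squares MSD fit.

    The first ``n_fit_lags`` lags of the MSD are regressed against lag
    time (free intercept, absorbing static localization error);
    ``d = slope / 4`` for 2D data, clipped at 0.  The estimate is accepted
    only if the regression R² reaches ``r2_threshold`` (0.8 by default,
    0.9 for stricter figure-grade gating) and the track had at least
    5 points.
    """
    usable = ~np.isnan(msd.msd) & (msd.n_pairs > 0)
    lags = msd.lags[usable][:n_fit_lags]
    vals = msd.msd[usable][:n_fit_lags]
    npts = n_points if n_points is not None else int(np.max(msd.n_pairs) + 1)
    if len(lags) < 2 or npts < MIN_TRACK_POINTS:
        return DiffusionEstimate(msd.track_id, float("nan"), float("nan"), False, npts)
    t = lags * frame_interval
    res = stats.linregress(t, vals)
    r2 = float(res.rvalue**2)
    d = max(float(res.slope) / 4.0, 0.0)
    return DiffusionEstimate(
        track_id=msd.track_id,
        d=d,
        r_squared=r2,
        accepted=bool(r2 >= r2_threshold),
        n_points=npts,
    )


def estimate_tracks(
    tracks: pd.DataFrame,
    frame_interval: float,
    n_fit_lags: int = 4,
    r2_threshold: float = 0.8,
    min_points: int = MIN_TRACK_POINTS,
) -> pd.DataFrame:
    """Per-track diffusion estimates for a whole trajectory table.

    Tracks shorter than ``min_points`` are skipped.  Returns columns
    ``track_id, d, r_squared, accepted, n_points``.
    """
    rows = []
    for tid, tr in tracks.groupby("track_id"):
        if len(tr) < min_points:
            continue
        est = fit_diffusion(
            compute_msd(tr, max_lag=n_fit_lags),
            frame_interval,
            n_fit_lags=n_fit_lags,
            r2_threshold=r2_threshold,
            n_points=len(tr),
        )
        rows.append(
            {
                "track_id": tid,
                "d": est.d,
                "r_squared": est.r_squared,
                "accepted": est.accepted,
                "n_points": est.n_points,
            }
        )
    return pd.DataFrame(
        rows, columns=["track_id", "d", "r_squared", "accepted", "n_points"]
    )


def diffusion_histogram(
    estimates: pd.DataFrame, bin_edges: np.ndarray | None = None
) -> pd.DataFrame:
    """Density histogram of accepted diffusion coefficients on a log10 axis.

    ``bin_edges`` are log10(µm²/s) edges (default -3..1.5 in 0.25 steps).
    Density is normalized to sum to 1 over occupied bins; zero-valued
    estimates cannot be placed on a log axis and are excluded.
    """
    if bin_edges is None:
        bin_edges = np.arange(-3.0, 1.75, 0.25)
    if len(estimates) == 0:
        return pd.DataFrame({"log10_d": [], "count": [], "density": []})
    d = estimates.loc[estimates["accepted"] & (estimates["d"] > 0), "d"].to_numpy()
    counts, edges = np.histogram(np.log10(d), bins=bin_edges)
    density = counts / counts.sum() if counts.sum() else counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"log10_d": centers, "count": counts, "density": density})


def translocations(tracks: pd.DataFrame) -> np.ndarray:
    """All adjacent-frame Euclidean displacements (µm), pooled across tracks."""
    out = []
    for _, tr in tracks.groupby("track_id"):
        frames, xy = _track_xy(tr)
        adj = np.diff(frames) == 1
        steps = np.diff(xy, axis=0)[adj]
        if len(steps):
            out.append(np.hypot(steps[:, 0], steps[:, 1]))
    return np.concatenate(out) if out else np.empty(0)


def translocation_histogram(
    tracks: pd.DataFrame, bin_edges: np.ndarray | None = None
) -> pd.DataFrame:
    """Binned density of adjacent-frame translocation distances."""
    dist = translocations(tracks)
    if bin_edges is None:
        hi = float(np.quantile(dist, 0.999)) if len(dist) else 1.0
        bin_edges = np.linspace(0.0, max(hi, 1e-3), 51)
    counts, edges = np.histogram(dist, bins=bin_edges)
    density = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame(
        {"distance_um": 0.5 * (edges[:-1] + edges[1:]), "count": counts, "density": density}
    )


def jump_angles(tracks: pd.DataFrame, min_jump: float = 0.04) -> np.ndarray:
    """Three-point jump angles in degrees, pooled across tracks.

    For consecutive points p1, p2, p3 the angle between (p2 - p1) and
    (p3 - p2) is 0° for straight continuation and 180° for a reversal.
    Triples with either jump shorter than ``min_jump`` (default 40 nm)
    are excluded so localization error does not dominate the geometry.
    """
    out = []
    for _, tr in tracks.groupby("track_id"):
        frames, xy = _track_xy(tr)
        if len(xy) < 3:
            continue
        v = np.diff(xy, axis=0)
        adj = np.diff(frames) == 1
        norms = np.hypot(v[:, 0], v[:, 1])
        a, b = v[:-1], v[1:]
        na, nb = norms[:-1], norms[1:]
        good = adj[:-1] & adj[1:] & (na >= min_jump) & (nb >= min_jump)
        if not good.any():
            continue
        cosang = np.sum(a[good] * b[good], axis=1) / (na[good] * nb[good])
        out.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.concatenate(out) if out else np.empty(0)


def angle_histogram(angles: np.ndarray, n_bins: int = 18) -> pd.DataFrame:
    """Rose-histogram bins of jump angles over [0°, 180°]."""
    counts, edges = np.histogram(angles, bins=n_bins, range=(0.0, 180.0))
    density = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame(
        {"angle_deg": 0.5 * (edges[:-1] + edges[1:]), "count": counts, "density": density}
    )


def split_tracks_by_mask(
    tracks: pd.DataFrame, mask: AggregateMask
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition tracks into (in_aggregate, out_of_aggregate) sets.

    A track is *in* if at least one of its localizations falls on a
    mask-true pixel; the partition is exhaustive and exclusive.
    """
    if len(tracks) == 0:
        return tracks.copy(), tracks.copy()
    hit = mask.contains(tracks["x_um"].to_numpy(), tracks["y_um"].to_numpy())
    in_ids = set(tracks.loc[hit, "track_id"].unique())
    is_in = tracks["track_id"].isin(in_ids)
    return (
        tracks[is_in].reset_index(drop=True),
        tracks[~is_in].reset_index(drop=True),
    )
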