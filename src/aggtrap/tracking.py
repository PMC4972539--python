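"""Minimal deterministic trajectory linking for localization tables.

Greedy nearest-neighbour frame-to-frame linking: candidate links between
open track ends and new-frame localizations are sorted globally by
distance and assigned greedily, links beyond the distance budget are
rejected, gaps of up to ``max_gap_frames`` missed frames are closed, and
tracks shorter than ``min_track_length`` are dropped.  Adequate at the
sparse densities of single-particle-tracking photoactivation streams; no
motion model and no multi-hypothesis reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LinkingConfig", "link_tracks"]


@dataclass(frozen=True)
class LinkingConfig:
    """Linking budget.

    ``max_link_distance`` is the allowed displacement per frame interval
    (a link across a gap of ``g`` missed frames may span
    ``(g + 1) * max_link_distance``).  A sensible default for a free
    diffusion coefficient ``d`` and frame interval ``dt`` is
    ``3 * sqrt(4 * d * dt)``.
    """

    max_link_distance: float = 1.5  # µm per frame interval
    max_gap_frames: int = 0
    min_track_length: int = 2  # points

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.max_gap_frames < 0 or self.min_track_length < 1:
            raise ValueError("max_gap_frames >= 0 and min_track_length >= 1 required")


def link_tracks(localizations: pd.DataFrame, cfg: LinkingConfig) -> pd.DataFrame:
    """Link a localization table into trajectories.

    Input columns: ``frame, x_um, y_um`` (extra columns are carried
    through).  Output adds a ``track_id`` column and is sorted by
    ``(track_id, frame)``.  Every localization is used at most once; the
    result is independent of the input row order (rows are canonically
    sorted by ``(frame, x_um, y_um)`` first, with equal-distance ties
    broken by that canonical order).
    """
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(localizations.columns):
        raise ValueError(f"localizations must have columns {sorted(required)}")
    if len(localizations) == 0:
        out = localizations.copy()
        out["track_id"] = pd.Series([], dtype=int)
        return out
    frames = localizations["frame"].to_numpy()
    if np.any(frames < 0) or not np.allclose(frames, np.round(frames)):
        raise ValueError("frames must be non-negative integers")

    df = (
        localizations.sort_values(["frame", "x_um", "y_um"], kind="mergesort")
        .reset_index(drop=True)
    )
    frame = df["frame"].to_numpy().astype(int)
    xy = df[["x_um", "y_um"]].to_numpy()

    n = len(df)
    track_of = np.full(n, -1, dtype=int)
    # open track ends: row index of the last localization of each track
    end_row: list[int] = []
    next_track = 0

    for f in np.unique(frame):
        rows = np.nonzero(frame == f)[0]
        # candidate ends: last point within the allowed gap
        cand_ends = [
            e for e in end_row if 1 <= f - frame[e] <= cfg.max_gap_frames + 1
        ]
        pairs = []
        for e in cand_ends:
            gap = f - frame[e]
            budget = cfg.max_link_distance * gap
            d = np.hypot(xy[rows, 0] - xy[e, 0], xy[rows, 1] - xy[e, 1])
            ok = np.nonzero(d <= budget)[0]
            for j in ok:
                pairs.append((d[j], e, rows[j]))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_ends: set[int] = set()
        used_rows: set[int] = set()
        for d, e, r in pairs:
            if e in used_ends or r in used_rows:
                continue
            used_ends.add(e)
            used_rows.add(r)
            track_of[r] = track_of[e]
            end_row[end_row.index(e)] = r
        for r in rows:
            if r not in used_rows:
                track_of[r] = next_track
                next_track += 1
                end_row.append(r)
        # prune ends that can no longer link (beyond any future gap budget)
        end_row = [e for e in end_row if f - frame[e] <= cfg.max_gap_frames]

    df["track_id"] = track_of
    lengths = df.groupby("track_id")["frame"].transform("size")
    df = df[lengths >= cfg.min_track_length].copy()
    # renumber tracks consecutively in order of first appearance
    first = df.groupby("track_id")["frame"].transform("min")
    order = (
        df[["track_id"]]
        .assign(first=first)
        .drop_duplicates("track_id")
        .sort_values(["first", "track_id"])["track_id"]
        .to_numpy()
    )
    remap = {t: i for i, t in enumerate(order)}
    df["track_id"] = df["track_id"].map(remap)
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)
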