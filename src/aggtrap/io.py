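"""Readers and writers for the package's table, image and config formats.

Tables are plain CSV (localizations: ``frame,x_um,y_um,intensity[,state_label]``;
trajectories: ``track_id,frame,x_um,y_um``; FRAP curves: ``time_s,intensity``).
Images are multi-page TIFF, channel-major.  Regions are JSON lists of disk
dicts.  Configs are YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_table",
    "write_table",
    "read_image",
    "write_image",
    "read_regions",
    "write_regions",
    "read_config",
]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    """Read a channel-major TIFF stack as float array."""
    return tifffile.imread(path).astype(float)


def write_image(stack: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_regions(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def write_regions(regions: list[dict], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(regions, fh, indent=1)


def read_config(path) -> dict:
    """Read a YAML (or JSON — YAML superset) mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
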