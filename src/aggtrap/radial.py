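"""Size-normalized radial intensity analysis of two-channel images.

Aggregate-containing regions of different sizes are rescaled to a common
100-pixel diameter, averaged pixelwise across regions (and cells), and
summarized as a center-to-periphery mean-intensity curve per circular
pixel increment for both channels.  A channel excluded from aggregates
(chromatin-like) yields a profile that mirrors the aggregate channel; a
recruited channel parallels it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = [
    "RadialProfile",
    "RegionClippedError",
    "normalize_region",
    "average_maps",
    "radial_profile",
    "analyze_regions",
    "center_periphery_contrast",
    "classify_enrichment",
]

PATCH_DIAMETER = 100  # px, common size of rescaled regions


class RegionClippedError(ValueError):
    """Raised when a region's bounding square is not fully inside the image."""


@dataclass(frozen=True)
class RadialProfile:
    """Center-to-periphery mean intensity per channel.

    ``radii`` are normalized bin centers in [0, 1] (0 = center C,
    1 = periphery P, one bin per circular pixel increment);
    ``mean_intensity`` has shape ``(n_channels, n_bins)``.
    """

    radii: np.ndarray
    mean_intensity: np.ndarray
    n_regions: int

    def channel(self, c: int) -> np.ndarray:
        return self.mean_intensity[c]

    def to_frame(self) -> pd.DataFrame:
        data = {"radius_norm": self.radii}
        for c in range(self.mean_intensity.shape[0]):
            data[f"ch{c + 1}_mean"] = self.mean_intensity[c]
        df = pd.DataFrame(data)
        df["n_regions"] = self.n_regions
        return df


def normalize_region(image: np.ndarray, region: dict) -> np.ndarray:
    """Crop a region's bounding square and rescale it to 100x100 px.

    ``image`` is a ``(n_channels, H, W)`` stack; ``region`` is
    ``{"cx_px", "cy_px", "r_px"}``.  Bilinear interpolation preserves
    intensity values up to resampling.  Raises
    :class:`RegionClippedError` for regions touching the image border.
    """
    if image.ndim != 3:
        raise ValueError("image must be a (n_channels, H, W) stack")
    _, h, w = image.shape
    cx, cy, r = region["cx_px"], region["cy_px"], region["r_px"]
    x0, x1 = int(round(cx - r)), int(round(cx + r))
    y0, y1 = int(round(cy - r)), int(round(cy + r))
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise RegionClippedError(
            f"region ({cx:.1f}, {cy:.1f}, r={r:.1f}) clipped by image border"
        )
    crop = image[:, y0:y1, x0:x1]
    out = np.empty((image.shape[0], PATCH_DIAMETER, PATCH_DIAMETER))
    for c in range(image.shape[0]):
        out[c] = resize(
            crop[c],
            (PATCH_DIAMETER, PATCH_DIAMETER),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        )
    return out


def average_maps(patches: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise arithmetic mean of size-normalized patches."""
    if len(patches) == 0:
        raise ValueError("no patches to average")
    return np.mean(np.stack(patches), axis=0)


def _radial_bins() -> tuple[np.ndarray, np.ndarray]:
    half = PATCH_DIAMETER // 2
    c = (PATCH_DIAMETER - 1) / 2.0
    yy, xx = np.mgrid[0:PATCH_DIAMETER, 0:PATCH_DIAMETER]
    dist = np.hypot(xx - c, yy - c)
    bin_of = np.floor(dist).astype(int)
    bin_of[dist >= half] = -1  # corner pixels beyond the inscribed disk
    return bin_of, np.arange(half)


def radial_profile(mean_map: np.ndarray, n_regions: int = 1) -> RadialProfile:
    """Center-to-periphery curve of a (possibly averaged) patch stack.

    Bin ``r`` holds the mean over pixels whose center distance from the
    patch center lies in ``[r, r+1)`` px; corner pixels outside the
    inscribed disk are excluded.  Radii are reported normalized to [0, 1].
    """
    if mean_map.ndim == 2:
        mean_map = mean_map[None]
    if mean_map.shape[-2:] != (PATCH_DIAMETER, PATCH_DIAMETER):
        raise ValueError(f"expected {PATCH_DIAMETER}x{PATCH_DIAMETER} patches")
    bin_of, bins = _radial_bins()
    half = PATCH_DIAMETER // 2
    prof = np.empty((mean_map.shape[0], half))
    for c in range(mean_map.shape[0]):
        ch = mean_map[c]
        for r in bins:
            prof[c, r] = ch[bin_of == r].mean()
    return RadialProfile(
        radii=(bins + 0.5) / half, mean_intensity=prof, n_regions=n_regions
    )


def analyze_regions(image: np.ndarray, regions: Sequence[dict]) -> tuple[RadialProfile, np.ndarray]:
    """Full pipeline: normalize each region, average, take radial profiles.

    Regions clipped by the image border are rejected (skipped); at least
    one usable region is required.  Returns the profile and the averaged
    ``(n_channels, 100, 100)`` map.
    """
    patches = []
    for reg in regions:
        try:
            patches.append(normalize_region(image, reg))
        except RegionClippedError:
            continue
    if not patches:
        raise ValueError("no usable (unclipped) regions")
    mean_map = average_maps(patches)
    return radial_profile(mean_map, n_regions=len(patches)), mean_map


def center_periphery_contrast(profile: RadialProfile, channel: int = 1, frac: float = 0.2) -> float:
    """Mean intensity of the innermost minus the outermost ``frac`` of bins."""
    n = max(int(len(profile.radii) * frac), 1)
    ch = profile.channel(channel)
    return float(ch[:n].mean() - ch[-n:].mean())


def classify_enrichment(
    profile: RadialProfile, channel: int = 1, rel_tol: float = 0.02
) -> str:
    """"recruitment", "exclusion" or "flat" from the channel's contrast sign.

    The contrast is compared against ``rel_tol`` times the channel's mean
    level to absorb noise.
    """
    contrast = center_periphery_contrast(profile, channel)
    scale = float(np.abs(profile.channel(channel)).mean()) or 1.0
    if contrast > rel_tol * scale:
        return "recruitment"
    if contrast < -rel_tol * scale:
        return "exclusion"
    return "flat"
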