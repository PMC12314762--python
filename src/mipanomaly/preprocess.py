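"""Subtraction-MIP preprocessing: volume reduction, bilateral split, scaling.

A dynamic contrast-enhanced exam is reduced to one 2D image: the
pre-contrast volume is subtracted from the first post-contrast volume,
negative differences are clipped to zero (subtraction MIPs visualize
enhancement; negatives are noise or motion), and a maximum-intensity
projection is taken along the chosen axis. The bilateral projection is then
split at the midline into two single-breast images in one canonical
orientation so a single model serves both lateralities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class BilateralMip:
    pixels: np.ndarray          # (H, W)
    midline_column: int | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("BilateralMip pixels must be 2D")
        w = self.pixels.shape[1]
        if self.midline_column is None:
            self.midline_column = w // 2
        if not 0 < self.midline_column < w:
            raise ValueError(f"midline_column {self.midline_column} outside (0, {w})")


def subtraction_mip(pre: np.ndarray, post: np.ndarray, projection_axis: int = 0) -> BilateralMip:
    """Clipped post-minus-pre subtraction followed by a max projection."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"volume shapes differ: {pre.shape} vs {post.shape}")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise ValueError("volumes must be finite")
    if not -pre.ndim <= projection_axis < pre.ndim:
        raise ValueError(f"projection axis {projection_axis} out of range for ndim {pre.ndim}")
    sub = np.clip(post - pre, 0.0, None)
    return BilateralMip(sub.max(axis=projection_axis))


def split_bilateral(mip: BilateralMip) -> tuple[np.ndarray, np.ndarray]:
    """Split at the midline; the right half is mirrored into canonical
    orientation so both outputs present the chest wall on the same side."""
    px = mip.pixels
    if px.shape[1] < 2:
        raise ValueError("bilateral MIP must be at least 2 columns wide")
    mid = mip.midline_column
    left = px[:, :mid]
    right = px[:, mid:][:, ::-1]
    return left, right


def join_bilateral(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Inverse of split_bilateral (un-mirror the right half, concatenate)."""
    return np.concatenate([left, right[:, ::-1]], axis=1)


def normalize_and_resize(pixels: np.ndarray, target_h: int, target_w: int,
                         clip_quantiles: tuple[float, float] = (0.0, 0.995)) -> np.ndarray:
    """Quantile-clip, min-max scale to [0, 1], bilinearly resample.

    The resampling grid maps output corners onto input corners, so corner
    values are preserved exactly on upsampling. A constant input yields an
    all-zero output rather than a division blow-up.
    """
    x = np.asarray(pixels, dtype=float)
    if x.size == 0:
        raise ValueError("empty image")
    qlo, qhi = np.quantile(x, clip_quantiles[0]), np.quantile(x, clip_quantiles[1])
    x = np.clip(x, qlo, qhi)
    span = x.max() - x.min()
    x = (x - x.min()) / span if span > 0 else np.zeros_like(x)
    h, w = x.shape
    if (h, w) != (target_h, target_w):
        rr = np.linspace(0.0, h - 1.0, target_h) if target_h > 1 else np.array([(h - 1) / 2.0])
        cc = np.linspace(0.0, w - 1.0, target_w) if target_w > 1 else np.array([(w - 1) / 2.0])
        grid = np.meshgrid(rr, cc, indexing="ij")
        x = ndimage.map_coordinates(x, grid, order=1, mode="nearest")
    return np.clip(x, 0.0, 1.0)
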