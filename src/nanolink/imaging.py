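"""Two-channel colocalization analysis: the pixelwise product map.

Mixing of two orthogonally-binding nanostar species (A tagged green, B
tagged red) is quantified by multiplying the normalized channel
intensities pixel by pixel: I_y(i, j) = I_r(i, j) * I_g(i, j). Bright
product pixels mark regions occupied by both species, i.e.
interpenetration; fully demixed samples give <I_y> ~ 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class ChannelImage:
    """Single-channel image normalized to [0, 1]."""

    data: np.ndarray
    label: str = ""
    pixel_size: float | None = None  # micrometres, optional

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("channel image must be 2-D")
        if self.data.min() < 0 or self.data.max() > 1 + 1e-12:
            raise ValueError("channel image must be normalized to [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def load_channel(path: str | Path, label: str = "", method: str = "percentile-99.9") -> ChannelImage:
    """Read a TIFF/PNG image and normalize it into a ChannelImage."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(Path(path)), dtype=float)
    if raw.ndim == 3:  # collapse RGB(A) to intensity
        raw = raw[..., :3].mean(axis=-1)
    return normalize_channel(raw, method=method, label=label)


def normalize_channel(
    raw: np.ndarray,
    method: str = "percentile-99.9",
    label: str = "",
    background: float = 0.0,
) -> ChannelImage:
    """Normalize a raw intensity image to [0, 1].

    ``method`` is either ``max`` (divide by the maximum) or
    ``percentile-99.9`` (divide by the 99.9th percentile, robust to hot
    pixels; values above it are clipped to 1). An optional flat
    ``background`` offset is subtracted first.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty image")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    raw = np.maximum(raw - background, 0.0)
    if method == "max":
        ref = raw.max()
    elif method.startswith("percentile-"):
        ref = np.percentile(raw, float(method.split("-", 1)[1]))
    else:
        raise ValueError(f"unknown normalization method '{method}'")
    if ref <= 0:
        raise ValueError("image is all zero; cannot normalize")
    return ChannelImage(np.clip(raw / ref, 0.0, 1.0), label=label)


def yellow_map(red: ChannelImage, green: ChannelImage) -> tuple[np.ndarray, float, float]:
    """Pixel-by-pixel product map I_y = I_r * I_g with mean and s.d.

    Returns (map, <I_y>, s.d. across pixels). Symmetric in its arguments.
    """
    if red.shape != green.shape:
        raise ValueError(f"channel shapes differ: {red.shape} vs {green.shape}")
    product = red.data * green.data
    return product, float(product.mean()), float(product.std())


def batch_yellow(pairs: list[tuple[ChannelImage, ChannelImage]]) -> dict:
    """<I_y> over a batch of image pairs, with the s.d. across images."""
    if not pairs:
        raise ValueError("empty batch")
    means = np.array([yellow_map(r, g)[1] for r, g in pairs])
    return {
        "mean": float(means.mean()),
        "sd_across_images": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        "per_image": means,
    }
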