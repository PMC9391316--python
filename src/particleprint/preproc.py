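"""Standardization of variable-size particle crops into fixed CNN inputs.

Crops arrive at whatever size the particle dictated.  The network expects a
fixed ``target x target`` grid (default 32), reached without any rescaling
so spatial resolution is preserved: smaller images are centered inside a
constant-intensity border (the training-set mean by default), larger ones
are center-cropped.  Pixel intensities are then z-scored with the training
set's pooled mean and standard deviation; the statistics are frozen at
training time and reused unchanged for validation and test images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic import ParticleImage

__all__ = [
    "NormalizationStats",
    "compute_normalization",
    "standardize_size",
    "normalize",
    "denormalize",
    "prepare_batch",
]

TARGET_SIZE = 32


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled pixel mean and (population) standard deviation of a training set."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    def to_dict(self) -> dict:
        return {"mean": float(self.mean), "sd": float(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(mean=float(d["mean"]), sd=float(d["sd"]))


def compute_normalization(training_images: Iterable[ParticleImage]) -> NormalizationStats:
    """Pool every pixel of every training image; population mean and sd.

    Raises if the collection is empty or has zero pixel variance (a
    degenerate, constant-intensity training set cannot be z-scored).
    """
    arrays = [img.pixels.ravel() for img in training_images]
    if not arrays:
        raise ValueError("compute_normalization: empty training collection")
    pooled = np.concatenate(arrays)
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=0))
    if sd == 0.0:
        raise ValueError(
            "compute_normalization: training pixels are constant "
            f"(all equal to {mean}); standard deviation is zero"
        )
    return NormalizationStats(mean=mean, sd=sd)


def _axis_slices(n: int, target: int) -> tuple[slice, slice]:
    """Source and destination slices for one axis.

    For padding, the content is centered with any odd leftover pixel going
    to the bottom/right; for cropping, the kept window is centered with any
    odd leftover removed from the bottom/right.  (Convention fixed so tests
    can be bit-exact; either choice is equally defensible.)
    """
    if n < target:
        before = (target - n) // 2
        return slice(0, n), slice(before, before + n)
    start = (n - target) // 2
    return slice(start, start + target), slice(0, target)


def standardize_size(image: ParticleImage, target: int = TARGET_SIZE,
                     fill: float = 0.0) -> ParticleImage:
    """Pad and/or crop to exactly ``target x target`` without rescaling.

    ``fill`` is the border intensity for padded regions — conventionally the
    training-set mean pixel intensity (a plain black border works nearly as
    well).  The two axes are handled independently, so a tall narrow crop
    can be cropped vertically while padded horizontally.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    px = image.pixels
    out = np.full((target, target), float(fill), dtype=float)
    src_r, dst_r = _axis_slices(px.shape[0], target)
    src_c, dst_c = _axis_slices(px.shape[1], target)
    out[dst_r, dst_c] = px[src_r, src_c]
    return ParticleImage(out, id=image.id, label=image.label)


def normalize(image: ParticleImage, stats: NormalizationStats,
              target: int = TARGET_SIZE) -> ParticleImage:
    """Z-score a size-standardized image with frozen training statistics."""
    if image.pixels.shape != (target, target):
        raise ValueError(
            f"normalize expects a {target}x{target} image, got {image.pixels.shape}"
        )
    out = (image.pixels - stats.mean) / stats.sd
    return ParticleImage(out, id=image.id, label=image.label)


def denormalize(image: ParticleImage, stats: NormalizationStats) -> ParticleImage:
    """Inverse of :func:`normalize` (round-trips to ~1e-16)."""
    return ParticleImage(image.pixels * stats.sd + stats.mean,
                         id=image.id, label=image.label)


def prepare_batch(images: Sequence[ParticleImage], stats: NormalizationStats,
                  target: int = TARGET_SIZE) -> np.ndarray:
    """Standardize + normalize a list of crops into an (N, 1, T, T) tensor."""
    out = np.empty((len(images), 1, target, target), dtype=float)
    for i, img in enumerate(images):
        std = standardize_size(img, target=target, fill=stats.mean)
        out[i, 0] = (std.pixels - stats.mean) / stats.sd
    return out
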