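"""Short-edge resize, center crop and channel standardisation.

The chain reduces a large histopathology scene (nominally 2304x1728) to a
square network input: the short edge is scaled to ``short_edge`` with the
long edge following proportionally (floor rounding, so 2304x1728 at 512
gives 682x512), a ``crop_size`` square is cut from the center, pixel values
are scaled to [0, 1] and standardised per channel.

Conventions: arrays are (H, W, C) with a 0-based, half-open, row-major
index grid; interpolation is bilinear. The long-edge floor rounding and the
``floor((dim - size) / 2)`` crop offset are part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .exceptions import ConfigError, DataError

__all__ = [
    "PreprocessConfig",
    "resize_short_edge",
    "center_crop",
    "normalize_standardize",
    "preprocess",
    "STRATEGIES",
]

#: published resize/crop strategies, name -> (short_edge, crop_size)
STRATEGIES = {
    "256-224": (256, 224),
    "384-336": (384, 336),
    "512-448": (512, 448),
    "640-560": (640, 560),
}


@dataclass(frozen=True)
class PreprocessConfig:
    """Resize/crop/standardisation settings.

    ``channel_mean`` / ``channel_std`` default to None, meaning "compute from
    the training split of the active dataset" (the estimator does this per
    fold); explicit constants may be supplied instead.
    """

    short_edge: int = 512
    crop_size: int = 448
    channel_mean: tuple[float, float, float] | None = None
    channel_std: tuple[float, float, float] | None = None
    interpolation: str = "bilinear"

    def __post_init__(self):
        if self.short_edge < 1 or self.crop_size < 1:
            raise ConfigError("short_edge and crop_size must be >= 1")
        if self.crop_size > self.short_edge:
            raise ConfigError(
                f"crop_size ({self.crop_size}) must not exceed short_edge "
                f"({self.short_edge})")
        if self.interpolation != "bilinear":
            raise ConfigError(f"unsupported interpolation {self.interpolation!r}")
        if self.channel_std is not None and any(s <= 0 for s in self.channel_std):
            raise ConfigError("channel_std components must be positive")

    @classmethod
    def from_strategy(cls, name: str, **kw) -> "PreprocessConfig":
        if name not in STRATEGIES:
            raise ConfigError(f"unknown strategy {name!r}; choose from {sorted(STRATEGIES)}")
        se, cs = STRATEGIES[name]
        return cls(short_edge=se, crop_size=cs, **kw)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DataError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    return image


def resize_short_edge(image: np.ndarray, target: int) -> np.ndarray:
    """Scale so min(H', W') == target; the long edge is floor-scaled."""
    image = _check_rgb(image)
    if target < 1:
        raise ConfigError("target must be >= 1")
    h, w = image.shape[:2]
    if min(h, w) == target:
        return image
    if h <= w:
        nh, nw = target, (w * target) // h
    else:
        nh, nw = (h * target) // w, target
    pil = Image.fromarray(np.ascontiguousarray(image.astype(np.uint8)))
    return np.asarray(pil.resize((nw, nh), Image.BILINEAR))


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    """Central ``size`` x ``size`` window; no padding is ever applied."""
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if size > h or size > w:
        raise DataError(
            f"crop size {size} exceeds image dimensions {h}x{w} (no padding)")
    top, left = (h - size) // 2, (w - size) // 2
    return image[top : top + size, left : left + size]


def normalize_standardize(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Scale to [0, 1] then standardise per channel: (p/255 - mean) / std."""
    image = _check_rgb(image).astype(np.float32) / 255.0
    mean = np.asarray(cfg.channel_mean if cfg.channel_mean is not None
                      else (0.0, 0.0, 0.0), dtype=np.float32)
    std = np.asarray(cfg.channel_std if cfg.channel_std is not None
                     else (1.0, 1.0, 1.0), dtype=np.float32)
    return (image - mean) / std


def preprocess(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: resize -> center crop -> normalise/standardise."""
    cfg = cfg or PreprocessConfig()
    resized = resize_short_edge(image, cfg.short_edge)
    cropped = center_crop(resized, cfg.crop_size)
    return normalize_standardize(cropped, cfg)


def channel_stats(images: np.ndarray):
    """Per-channel mean/std of a (N, H, W, 3) uint8 stack on the [0,1] scale."""
    x = np.asarray(images, dtype=np.float64) / 255.0
    mean = x.mean(axis=(0, 1, 2))
    std = x.std(axis=(0, 1, 2))
    std = np.where(std < 1e-6, 1.0, std)
    return tuple(float(v) for v in mean), tuple(float(v) for v in std)
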