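"""Artificial-RGB construction and resizing of grayscale ultrasound images.

Object detectors pre-trained on natural RGB photographs expect three input
channels.  A grayscale B-mode ultrasound image is lifted into that space by
stacking three views of itself: the original image, an unsharp-masked
(sharpened) version and a contrast-limited adaptive histogram-equalized
(CLAHE) version.  The stack is the "artificial RGB" image fed to detectors;
channel 1 is always the unmodified input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, filters, transform

from .boxes import ImageSize

__all__ = [
    "PreprocessConfig",
    "sharpen",
    "contrast_enhance",
    "to_artificial_rgb",
    "resize_image",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter parameters for the artificial-RGB channels.

    ``sharpen_radius`` (px) and ``sharpen_amount`` drive the unsharp mask;
    ``clahe_clip`` and ``clahe_tile`` drive adaptive histogram equalization.
    """

    sharpen_radius: float = 2.0
    sharpen_amount: float = 1.0
    clahe_clip: float = 0.01
    clahe_tile: int = 8

    def __post_init__(self) -> None:
        if self.sharpen_radius <= 0:
            raise ValueError("sharpen_radius must be > 0")
        if self.sharpen_amount < 0:
            raise ValueError("sharpen_amount must be >= 0")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")
        if self.clahe_tile < 1:
            raise ValueError("clahe_tile must be >= 1")


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("grayscale values must lie in [0, 255]")
    return img


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def sharpen(img: np.ndarray, radius: float = 2.0, amount: float = 1.0) -> np.ndarray:
    """Unsharp mask: original + amount x (original − Gaussian blur), clipped."""
    img = _check_gray(img)
    out = filters.unsharp_mask(
        img.astype(float), radius=radius, amount=amount, preserve_range=True
    )
    return _to_uint8(out)


def contrast_enhance(
    img: np.ndarray, clip_limit: float = 0.01, tile: int = 8
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, back on [0, 255]."""
    img = _check_gray(img)
    if img.max() == img.min():
        return img.astype(np.uint8).copy()  # no contrast to stretch
    out = exposure.equalize_adapthist(
        img.astype(np.uint8), kernel_size=tile_kernel(img.shape, tile), clip_limit=clip_limit
    )
    return _to_uint8(out * 255.0)


def tile_kernel(shape: tuple[int, int], tile: int) -> tuple[int, int]:
    """Kernel size dividing the image into roughly ``tile`` x ``tile`` blocks."""
    return (max(1, shape[0] // tile), max(1, shape[1] // tile))


def to_artificial_rgb(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Stack (original, sharpened, contrast-enhanced) as an (H, W, 3) uint8 image."""
    config = config or PreprocessConfig()
    img = _check_gray(img).astype(np.uint8)
    return np.dstack(
        [
            img,
            sharpen(img, radius=config.sharpen_radius, amount=config.sharpen_amount),
            contrast_enhance(img, clip_limit=config.clahe_clip, tile=config.clahe_tile),
        ]
    )


def resize_image(img: np.ndarray, to: ImageSize) -> np.ndarray:
    """Bilinear resize of a grayscale or 3-channel image to ``to`` (uint8 out)."""
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise ValueError("expected a 2-D grayscale or (H, W, C) image")
    if img.shape[:2] == (to.height, to.width):
        return img.astype(np.uint8).copy()
    target = (to.height, to.width) + img.shape[2:]
    out = transform.resize(
        img.astype(float), target, order=1, preserve_range=True, anti_aliasing=False
    )
    return _to_uint8(out)
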