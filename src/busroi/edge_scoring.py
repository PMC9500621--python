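"""Edge-map scoring of candidate tumor ROIs.

An edge map is a per-pixel edge-strength image (here typically produced by a
learned edge detector and consumed as an 8-bit grayscale image).  A candidate
ROI is scored by two indicators computed over the pixels it encloses:

* ``S`` — the *edge mass*: the sum of normalized edge intensities inside the
  box.  S rewards boxes that cover the tumor boundary.
* ``D`` — the *edge density*: the fraction of box pixels that exceed an
  adaptive binarization threshold.  D penalizes boxes that dilute the
  boundary with empty background.

The combined score is ``SD = S * D``; among candidate boxes the one with the
highest SD both covers the boundary and stays tight around it.  The
binarization threshold is found by intermode thresholding: the 256-bin
intensity histogram is smoothed with a 3-bin moving average until exactly two
local maxima remain and the threshold is the midpoint of the two modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .boxes import Box, ImageSize

__all__ = [
    "EdgeMap",
    "BinaryEdgeMap",
    "RoiScore",
    "normalize_edge_map",
    "intermode_threshold",
    "intermode_threshold_info",
    "binarize_edge_map",
    "indicator_S",
    "indicator_D",
    "score_roi",
]

logger = logging.getLogger(__name__)

#: Default cap on intermode smoothing passes before falling back.
DEFAULT_MAX_ITERATIONS = 10_000


@dataclass(frozen=True)
class EdgeMap:
    """Normalized edge-strength image with values in [0, 1], indexed (row, col)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("edge map must be a non-empty 2-D grid")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("edge map values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> ImageSize:
        return ImageSize(width=self.values.shape[1], height=self.values.shape[0])


@dataclass(frozen=True)
class BinaryEdgeMap:
    """0/1 mask of high-edge-intensity pixels plus the threshold that made it."""

    values: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("binary edge map must be a non-empty 2-D grid")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("binary edge map may contain only 0 and 1")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def size(self) -> ImageSize:
        return ImageSize(width=self.values.shape[1], height=self.values.shape[0])


@dataclass(frozen=True)
class RoiScore:
    """The (S, D, SD) indicator triple for one candidate box.

    ``SD`` is always the product of the stored S and D; it is derived at
    construction and kept at full float precision (reports round it).
    """

    S: float
    D: float
    SD: float = field(init=False)

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError(f"S must be non-negative, got {self.S}")
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"D must lie in [0, 1], got {self.D}")
        object.__setattr__(self, "SD", self.S * self.D)


def normalize_edge_map(raw: np.ndarray) -> EdgeMap:
    """Normalize an 8-bit edge image to [0, 1] by dividing by 255."""
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.size == 0:
        raise ValueError("raw edge image must be a non-empty 2-D grid")
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("raw edge image values must lie in [0, 255]")
    return EdgeMap(raw.astype(float) / 255.0)


def _smooth3(hist: np.ndarray) -> np.ndarray:
    # 3-bin moving average with replicated edges.
    padded = np.concatenate(([hist[0]], hist, [hist[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(hist: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; edge bins compare to one neighbor."""
    n = len(hist)
    left = np.concatenate(([-np.inf], hist[:-1]))
    right = np.concatenate((hist[1:], [-np.inf]))
    return np.nonzero((hist > left) & (hist > right))[0] if n > 1 else np.array([0])


def intermode_threshold_info(
    em: EdgeMap, max_iterations: int = DEFAULT_MAX_ITERATIONS
) -> tuple[float, bool]:
    """Like :func:`intermode_threshold`, also reporting whether the histogram-mean
    fallback was used (True) instead of a genuine intermode threshold."""
    intensities = np.clip(np.rint(em.values * 255.0), 0, 255).astype(np.int64)
    hist = np.bincount(intensities.ravel(), minlength=256).astype(float)

    fallback = float(np.average(np.arange(256), weights=hist)) / 255.0

    smoothed = hist
    for _ in range(max_iterations):
        peaks = _local_maxima(smoothed)
        if len(peaks) == 2:
            return float(peaks[0] + peaks[1]) / 2.0 / 255.0, False
        if len(peaks) < 2:
            logger.warning(
                "intermode threshold: histogram is unimodal; "
                "falling back to histogram mean %.4f",
                fallback,
            )
            return fallback, True
        smoothed = _smooth3(smoothed)

    peaks = _local_maxima(smoothed)
    if len(peaks) == 2:
        return float(peaks[0] + peaks[1]) / 2.0 / 255.0, False
    logger.warning(
        "intermode threshold: bimodality not reached within %d iterations; "
        "falling back to histogram mean %.4f",
        max_iterations,
        fallback,
    )
    return fallback, True


def intermode_threshold(
    em: EdgeMap, max_iterations: int = DEFAULT_MAX_ITERATIONS
) -> float:
    """Adaptive intermode threshold of an edge map, on the [0, 1] scale.

    The histogram of the rescaled (x255) intensities is smoothed with a 3-bin
    moving average until exactly two local maxima remain; the threshold is the
    midpoint of the two mode bins mapped back to [0, 1].  If the histogram is
    (or collapses to) unimodal, or bimodality is not reached within
    ``max_iterations`` passes, the histogram mean is returned instead and a
    warning is logged.
    """
    return intermode_threshold_info(em, max_iterations=max_iterations)[0]


def binarize_edge_map(em: EdgeMap, threshold: float) -> BinaryEdgeMap:
    """Mark pixels strictly above ``threshold`` as 1, others 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return BinaryEdgeMap(
        values=(em.values > threshold).astype(np.uint8), threshold_used=threshold
    )


def _check_in_frame(size: ImageSize, roi: Box) -> None:
    if not roi.within(size):
        raise ValueError(
            f"ROI {roi} extends beyond the {size.width}x{size.height} frame"
        )


def indicator_S(em: EdgeMap, roi: Box) -> float:
    """Edge mass: sum of normalized edge intensities inside the box."""
    _check_in_frame(em.size, roi)
    window = em.values[roi.y_min : roi.y_max + 1, roi.x_min : roi.x_max + 1]
    return float(window.sum())


def indicator_D(bem: BinaryEdgeMap, roi: Box) -> float:
    """Edge density: fraction of box pixels set in the binarized map."""
    _check_in_frame(bem.size, roi)
    window = bem.values[roi.y_min : roi.y_max + 1, roi.x_min : roi.x_max + 1]
    return float(window.sum()) / roi.area


def score_roi(em: EdgeMap, bem: BinaryEdgeMap, roi: Box) -> RoiScore:
    """Compute the (S, D, SD) score of one candidate box."""
    if em.size != bem.size:
        raise ValueError(
            f"edge map ({em.size.width}x{em.size.height}) and binary edge map "
            f"({bem.size.width}x{bem.size.height}) differ in size"
        )
    return RoiScore(S=indicator_S(em, roi), D=indicator_D(bem, roi))
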