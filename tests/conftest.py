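"""Shared fixtures: brute-force pixel-level oracles and random-box helpers.

The oracles deliberately avoid the package's arithmetic: boxes are rasterized
onto boolean masks and pixels are counted, so any agreement with the fast
implementations is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from busroi.boxes import Box


def rasterize(b: Box, height: int, width: int) -> np.ndarray:
    """Boolean mask of the pixels a box covers (independent of Box methods)."""
    mask = np.zeros((height, width), dtype=bool)
    for y in range(height):
        for x in range(width):
            if b.x_min <= x <= b.x_max and b.y_min <= y <= b.y_max:
                mask[y, x] = True
    return mask


@pytest.fixture(scope="session")
def mask_oracle():
    """Callable (box, H, W) -> boolean pixel mask, by exhaustive rasterization."""
    return rasterize


@pytest.fixture(scope="session")
def random_box():
    """Callable (rng, H, W) -> a uniformly random valid box inside an HxW frame."""

    def _draw(rng: np.random.Generator, height: int, width: int) -> Box:
        x1, x2 = sorted(rng.integers(0, width, size=2).tolist())
        y1, y2 = sorted(rng.integers(0, height, size=2).tolist())
        return Box(int(x1), int(y1), int(x2), int(y2))

    return _draw
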