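"""Edge-based selection of the best candidate ROI.

Each available candidate box is scored against the image's edge map with the
(S, D, SD) indicators and the candidate with the highest SD wins.  Detectors
that produced no box for the image are simply skipped; ties are broken by the
configured candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .boxes import Box
from .edge_scoring import (
    DEFAULT_MAX_ITERATIONS,
    BinaryEdgeMap,
    EdgeMap,
    RoiScore,
    binarize_edge_map,
    intermode_threshold,
    score_roi,
)

__all__ = ["CandidateSet", "SelectionResult", "select_roi", "argmax_sd"]


@dataclass
class CandidateSet:
    """Per-image mapping from detector name to an optional box.

    ``entries`` preserves insertion order, which doubles as the tie-breaking
    order during selection.  ``None`` marks a detector that failed to produce
    a box for this image.
    """

    image_id: str
    entries: dict[str, Optional[Box]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = dict(self.entries)

    def present(self) -> dict[str, Box]:
        """The sub-mapping of detectors that did produce a box."""
        return {name: b for name, b in self.entries.items() if b is not None}


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of edge-based selection for one image."""

    selected_model: Optional[str]
    selected_box: Optional[Box]
    scores: Mapping[str, RoiScore]
    threshold: Optional[float] = None


def argmax_sd(scores: Mapping[str, RoiScore]) -> Optional[str]:
    """Name of the highest-SD entry; first-listed wins ties; None if empty."""
    best_name = None
    best_sd = -1.0
    for name, score in scores.items():
        if score.SD > best_sd:
            best_name, best_sd = name, score.SD
    return best_name


def select_roi(
    em: EdgeMap,
    candidates: CandidateSet,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    bem: Optional[BinaryEdgeMap] = None,
) -> SelectionResult:
    """Score every present candidate box and return the SD-argmax.

    The edge map is binarized once per image (intermode threshold) before the
    candidate loop; pass a precomputed ``bem`` to reuse an existing
    binarization.  When every detector failed, the result carries no box and
    counts as a detection failure downstream.
    """
    present = candidates.present()
    for name, box in present.items():
        if not box.within(em.size):
            raise ValueError(
                f"candidate {name!r} of image {candidates.image_id!r}: "
                f"box {box} exceeds the {em.size.width}x{em.size.height} frame"
            )
    if bem is None:
        threshold = intermode_threshold(em, max_iterations=max_iterations)
        bem = binarize_edge_map(em, threshold)
    scores = {name: score_roi(em, bem, box) for name, box in present.items()}
    winner = argmax_sd(scores)
    return SelectionResult(
        selected_model=winner,
        selected_box=present[winner] if winner is not None else None,
        scores=scores,
        threshold=bem.threshold_used,
    )
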