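"""Baseline methods that fuse several detectors' boxes into one ROI.

Three combiners are provided: *average* (mean of upper-left and lower-right
corners), *union* (smallest box enclosing all boxes) and *intersection*
(largest box common to all boxes).  Detectors that failed to produce a box
are excluded before combining; if none remain — or the intersection is
empty — the combiner reports no ROI, which downstream evaluation counts as a
detection failure.
"""

from __future__ import annotations

from typing import Optional

from .boxes import Box, _round_half_away, enclose, intersect
from .selection import CandidateSet

__all__ = ["combine_average", "combine_union", "combine_intersection", "COMBINERS"]


def combine_average(candidates: CandidateSet) -> Optional[Box]:
    """Box whose corners are the mean of the present boxes' corners."""
    present = list(candidates.present().values())
    if not present:
        return None
    n = len(present)
    return Box(
        _round_half_away(sum(b.x_min for b in present) / n),
        _round_half_away(sum(b.y_min for b in present) / n),
        _round_half_away(sum(b.x_max for b in present) / n),
        _round_half_away(sum(b.y_max for b in present) / n),
    )


def combine_union(candidates: CandidateSet) -> Optional[Box]:
    """Smallest box enclosing every present box."""
    present = list(candidates.present().values())
    if not present:
        return None
    return enclose(present)


def combine_intersection(candidates: CandidateSet) -> Optional[Box]:
    """Largest box contained in every present box; None when empty."""
    present = list(candidates.present().values())
    if not present:
        return None
    result: Optional[Box] = present[0]
    for b in present[1:]:
        result = intersect(result, b)
        if result is None:
            return None
    return result


COMBINERS = {
    "average": combine_average,
    "union": combine_union,
    "intersection": combine_intersection,
}
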