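"""Axis-aligned bounding-box arithmetic and pairwise overlap indicators.

Boxes use a continuous, 0-based, half-open convention: a box covers
``[x_min, x_max) x [y_min, y_max)`` so that ``area = (x_max - x_min) *
(y_max - y_min)`` and areas compose exactly under tiling.

Five pairwise indicators are provided:

``iou``
    intersection over union — the standard overlap measure.
``giou``
    generalized IoU: IoU penalized by the slack of the smallest
    enclosing box, ``iou - (A_c - union) / A_c``.
``diou``
    distance IoU: IoU penalized by the normalized squared center
    distance, ``iou - rho^2 / c^2`` where ``c`` is the enclosing-box
    diagonal.
``iob``
    intersection over the *smaller* box's area — close to 1 whenever
    the smaller box lies (almost) inside the bigger one, regardless of
    how different the two areas are.
``bou``
    the *bigger* box's area over the union — close to 1 when the union
    nearly coincides with the bigger box, i.e. near-containment.

IOB and BOU together discriminate a repeated detection of the same
object (a clipped fragment inside a whole-object box) from two distinct
overlapping objects, which plain IoU cannot do when the two areas
differ by an order of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional


class DegenerateBoxError(ValueError):
    """Raised when a ratio indicator is undefined for degenerate input."""


@dataclass(frozen=True)
class Box:
    """An axis-aligned rectangle in pixel coordinates.

    Parameters
    ----------
    x_min, y_min, x_max, y_max
        Corner coordinates; ``x_max >= x_min`` and ``y_max >= y_min``.
    score
        Optional detector confidence in ``[0, 1]``.
    label
        Optional class label.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"invalid box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translate(self, dx: float, dy: float) -> "Box":
        """Return a copy shifted by ``(dx, dy)``; score/label preserved."""
        return Box(
            self.x_min + dx,
            self.y_min + dy,
            self.x_max + dx,
            self.y_max + dy,
            score=self.score,
            label=self.label,
        )

    def clip(self, x_min: float, y_min: float, x_max: float, y_max: float) -> "Box":
        """Return the intersection of this box with a clipping window.

        Degenerate (zero-area) results are allowed; callers that cannot
        handle them should filter on ``area``.
        """
        return Box(
            min(max(self.x_min, x_min), x_max),
            min(max(self.y_min, y_min), y_max),
            max(min(self.x_max, x_max), x_min),
            max(min(self.y_max, y_max), y_min),
            score=self.score,
            label=self.label,
        )

    def corner_key(self) -> tuple[float, float, float, float]:
        """Lexicographic corner tuple, used as a deterministic tie-break."""
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class OverlapGeometry:
    """Shared derived quantities for a pair of boxes.

    ``enclosing_area`` is the area of the smallest axis-aligned box
    containing both inputs; ``center_dist_sq`` is the squared Euclidean
    distance between the two centers; ``enclosing_diag_sq`` the squared
    diagonal of the enclosing box.
    """

    inter_area: float
    union_area: float
    area_a: float
    area_b: float
    enclosing_area: float
    center_dist_sq: float
    enclosing_diag_sq: float


def overlap_geometry(a: Box, b: Box) -> OverlapGeometry:
    """Compute all pairwise overlap quantities for two boxes."""
    ix_min = max(a.x_min, b.x_min)
    iy_min = max(a.y_min, b.y_min)
    ix_max = min(a.x_max, b.x_max)
    iy_max = min(a.y_max, b.y_max)
    iw = max(0.0, ix_max - ix_min)
    ih = max(0.0, iy_max - iy_min)
    inter = iw * ih

    area_a = a.area
    area_b = b.area
    union = area_a + area_b - inter

    ex_min = min(a.x_min, b.x_min)
    ey_min = min(a.y_min, b.y_min)
    ex_max = max(a.x_max, b.x_max)
    ey_max = max(a.y_max, b.y_max)
    ew = ex_max - ex_min
    eh = ey_max - ey_min

    ca = a.center
    cb = b.center
    rho_sq = (ca[0] - cb[0]) ** 2 + (ca[1] - cb[1]) ** 2

    return OverlapGeometry(
        inter_area=inter,
        union_area=union,
        area_a=area_a,
        area_b=area_b,
        enclosing_area=ew * eh,
        center_dist_sq=rho_sq,
        enclosing_diag_sq=ew * ew + eh * eh,
    )


def iou(a: Box, b: Box) -> float:
    """Intersection over union; 1 iff identical, 0 iff disjoint."""
    g = overlap_geometry(a, b)
    if g.union_area <= 0.0:
        raise DegenerateBoxError("IOU undefined: both boxes have zero area")
    return g.inter_area / g.union_area


def giou(a: Box, b: Box) -> float:
    """Generalized IoU: ``iou - (A_c - union) / A_c``; in ``(-1, 1]``."""
    g = overlap_geometry(a, b)
    if g.union_area <= 0.0 or g.enclosing_area <= 0.0:
        raise DegenerateBoxError("GIOU undefined: degenerate box pair")
    return g.inter_area / g.union_area - (g.enclosing_area - g.union_area) / g.enclosing_area


def diou(a: Box, b: Box) -> float:
    """Distance IoU: ``iou - rho^2 / c^2``; in ``(-1, 1]``."""
    g = overlap_geometry(a, b)
    if g.enclosing_diag_sq <= 0.0:
        raise DegenerateBoxError("DIOU undefined: coincident degenerate boxes")
    iou_term = g.inter_area / g.union_area if g.union_area > 0.0 else 0.0
    if g.union_area <= 0.0:
        raise DegenerateBoxError("DIOU undefined: both boxes have zero area")
    return iou_term - g.center_dist_sq / g.enclosing_diag_sq


def _smaller_bigger_area(a: Box, b: Box) -> tuple[float, float]:
    # Equal areas: designate by lexicographic corner order; the returned
    # values are unaffected, this only fixes which box counts as smaller.
    if a.area < b.area or (a.area == b.area and a.corner_key() <= b.corner_key()):
        return a.area, b.area
    return b.area, a.area


def iob(a: Box, b: Box) -> float:
    """Intersection over the smaller box's area.

    Equals 1 iff the smaller box lies entirely inside the bigger one.
    """
    smaller, _ = _smaller_bigger_area(a, b)
    if smaller <= 0.0:
        raise DegenerateBoxError("IOB undefined: smaller box has zero area")
    return overlap_geometry(a, b).inter_area / smaller


def bou(a: Box, b: Box) -> float:
    """Bigger box's area over the union.

    Equals 1 iff the union coincides with the bigger box, i.e. the
    smaller box is contained in it.
    """
    g = overlap_geometry(a, b)
    if g.union_area <= 0.0:
        raise DegenerateBoxError("BOU undefined: both boxes have zero area")
    _, bigger = _smaller_bigger_area(a, b)
    return bigger / g.union_area
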