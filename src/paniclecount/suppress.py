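"""Removal of repeated detections among merged, globally-mapped boxes.

When overlapping tiles are detected independently, the same panicle is
often reported twice: once whole, once as a fragment clipped by a tile
edge.  The two boxes then differ greatly in area, so their IoU is low
and classical NMS keeps both.  The containment-based rule implemented
here removes a pair's smaller box whenever

    IOB > iob_threshold  AND  BOU > bou_threshold

i.e. when the smaller box lies (nearly) inside the bigger one *and* the
union is (nearly) the bigger box — the signature of a repeated
detection rather than two distinct, partially overlapping panicles.

Greedy NMS with IoU/GIoU/DIoU metrics is provided as a baseline, plus a
brute-force fixed-point dedup used as an independent test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .boxgeom import Box, bou, diou, giou, iob, iou

VALID_METHODS = ("iob_bou", "nms_iou", "nms_giou", "nms_diou")

_NMS_METRIC: dict[str, Callable[[Box, Box], float]] = {
    "nms_iou": iou,
    "nms_giou": giou,
    "nms_diou": diou,
}


class SuppressionConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SuppressionConfig:
    """Which duplicate-removal rule to apply and its thresholds.

    The containment rule fires only when *both* the IOB and BOU
    thresholds are strictly exceeded; NMS suppresses a box when its
    metric with an already-kept box strictly exceeds ``nms_threshold``.
    """

    method: str = "iob_bou"
    iob_threshold: float = 0.8
    bou_threshold: float = 0.8
    nms_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise SuppressionConfigError(
                f"method {self.method!r} not in {VALID_METHODS}"
            )
        if not (0.0 <= self.iob_threshold <= 1.0):
            raise SuppressionConfigError("iob_threshold outside [0, 1]")
        if not (0.0 <= self.bou_threshold <= 1.0):
            raise SuppressionConfigError("bou_threshold outside [0, 1]")
        if not (-1.0 <= self.nms_threshold <= 1.0):
            raise SuppressionConfigError("nms_threshold outside [-1, 1]")


def _area_rank_key(box: Box) -> tuple:
    # Largest area first; exact area ties broken by corner lexicographic
    # order (the lexicographically smaller corner counts as the
    # "smaller" box, so it ranks later and is the one removed).
    return (-box.area, tuple(-v for v in box.corner_key()))


def _score_rank_key(box: Box) -> tuple[float, float, tuple[float, float, float, float]]:
    score = box.score if box.score is not None else -1.0
    return (-score, -box.area, box.corner_key())


def _violates(a: Box, b: Box, cfg: SuppressionConfig) -> bool:
    """True when the pair triggers the containment duplicate rule."""
    if min(a.area, b.area) <= 0.0:
        return False
    return iob(a, b) > cfg.iob_threshold and bou(a, b) > cfg.bou_threshold


def remove_repeats_iob_bou(
    boxes: Sequence[Box], cfg: SuppressionConfig | None = None
) -> list[Box]:
    """Remove repeated detections with the IOB/BOU containment rule.

    Candidate pairs are resolved largest-area-first: each box, visited
    in descending area, removes every remaining smaller box that
    violates the rule with it.  For every retained pair, NOT
    (iob > iob_threshold AND bou > bou_threshold).  Input order is
    preserved in the output; boxes are removed, never altered.
    """
    if cfg is None:
        cfg = SuppressionConfig()
    order = sorted(range(len(boxes)), key=lambda i: _area_rank_key(boxes[i]))
    alive = [True] * len(boxes)
    for pos, i in enumerate(order):
        if not alive[i]:
            continue
        for j in order[pos + 1 :]:
            if alive[j] and _violates(boxes[i], boxes[j], cfg):
                alive[j] = False
    return [b for b, keep in zip(boxes, alive) if keep]


def nms(boxes: Sequence[Box], cfg: SuppressionConfig) -> list[Box]:
    """Greedy non-maximum suppression with the metric named by ``cfg.method``.

    Boxes are visited in descending score (descending area when scores
    are absent or tie); a kept box suppresses any remaining box whose
    metric with it strictly exceeds ``cfg.nms_threshold``.  Output
    preserves input order.
    """
    if cfg.method not in _NMS_METRIC:
        raise SuppressionConfigError(f"{cfg.method!r} is not an NMS method")
    metric = _NMS_METRIC[cfg.method]
    order = sorted(range(len(boxes)), key=lambda i: _score_rank_key(boxes[i]))
    alive = [True] * len(boxes)
    for pos, i in enumerate(order):
        if not alive[i]:
            continue
        for j in order[pos + 1 :]:
            if not alive[j]:
                continue
            a, b = boxes[i], boxes[j]
            if max(a.area, b.area) <= 0.0:
                continue
            if metric(a, b) > cfg.nms_threshold:
                alive[j] = False
    return [b for b, keep in zip(boxes, alive) if keep]


def suppress(boxes: Sequence[Box], cfg: SuppressionConfig) -> list[Box]:
    """Dispatch to the configured duplicate-removal rule."""
    if cfg.method == "iob_bou":
        return remove_repeats_iob_bou(boxes, cfg)
    return nms(boxes, cfg)


def brute_force_dedup(
    boxes: Sequence[Box], cfg: SuppressionConfig | None = None
) -> list[Box]:
    """Fixed-point reference implementation of the IOB/BOU rule.

    Repeatedly rescans ALL remaining pairs, resolves the violating pair
    whose surviving (bigger) box ranks first under the canonical
    largest-area-first order by removing its smaller box, and stops when
    no violating pair remains.  Resolution order matters for chains
    (big contains medium, medium contains small, but big does not
    contain small), so the canonical order is part of the rule, not an
    implementation detail.  Intended as a test oracle for small inputs
    (roughly n <= 25); quadratic per sweep.
    """
    if cfg is None:
        cfg = SuppressionConfig()
    kept = list(boxes)
    while True:
        violating: list[tuple] = []
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                if _violates(a, b, cfg):
                    # orient the pair as (bigger, smaller)
                    if (a.area, a.corner_key()) < (b.area, b.corner_key()):
                        big_idx, small_idx = j, i
                    else:
                        big_idx, small_idx = i, j
                    big, small = kept[big_idx], kept[small_idx]
                    violating.append(
                        (_area_rank_key(big), _area_rank_key(small), small_idx)
                    )
        if not violating:
            return kept
        violating.sort()
        kept.pop(violating[0][2])
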