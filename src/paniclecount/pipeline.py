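"""End-to-end detect-and-count over large images.

Stages: plan an overlapping tiling of the image, crop the tiles, run a
pluggable detector on each tile, translate the tile-local boxes into the
global frame, remove repeated detections (the same object reported from
several overlapping tiles), and count the survivors.

The detector is any object with a ``detect(tile, origin) -> list[Box]``
method returning boxes in the tile's own pixel coordinates: any internal
resizing to the model's input size must be inverted before returning, so
the geometric pipeline stays independent of the model backend.  The tile
origin is passed for provenance; raster-only detectors may ignore it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .boxgeom import Box
from .io import box_to_record
from .suppress import SuppressionConfig, suppress
from .tiler import TilePlan, crop_tiles, plan_tiles, to_global


@runtime_checkable
class Detector(Protocol):
    """Contract for per-tile detectors."""

    def detect(self, tile: np.ndarray, origin: tuple[int, int]) -> list[Box]:
        """Return boxes in tile-local pixel coordinates, scores in [0,1]."""
        ...


class DetectionError(RuntimeError):
    """A detector failed on a tile; carries the tile context."""


@dataclass(frozen=True)
class PipelineResult:
    """Final detections for one image, in the global frame."""

    image_id: str
    boxes: tuple[Box, ...]
    tile_plan: TilePlan
    provenance: dict

    @property
    def count(self) -> int:
        return len(self.boxes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_id": self.image_id,
                "count": self.count,
                "boxes": [box_to_record(b) for b in self.boxes],
                "tile_plan": json.loads(self.tile_plan.to_json()),
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )


def detect_tiles(
    detector: Detector, tiles: Sequence[np.ndarray], plan: TilePlan
) -> list[list[Box]]:
    """Run the detector on every tile; one box list per tile.

    A detector exception on any tile aborts the run with the tile index
    and origin attached, so a partial result is never silently returned.
    """
    if len(tiles) != plan.n_tiles:
        raise DetectionError(
            f"{len(tiles)} tiles given but plan has {plan.n_tiles}"
        )
    results: list[list[Box]] = []
    for idx, (tile, origin) in enumerate(zip(tiles, plan.origins)):
        try:
            results.append(list(detector.detect(tile, origin)))
        except Exception as exc:  # noqa: BLE001 - context then re-raise
            raise DetectionError(
                f"detector failed on tile {idx} at origin {origin}: {exc}"
            ) from exc
    return results


def merge_detections(
    per_tile: Sequence[Sequence[Box]], plan: TilePlan
) -> list[Box]:
    """Map tile-local boxes to the global frame and concatenate.

    No deduplication happens here: an object seen in two overlapping
    tiles yields two (near-)identical global boxes by design.
    """
    if len(per_tile) != plan.n_tiles:
        raise DetectionError(
            f"{len(per_tile)} box lists given but plan has {plan.n_tiles}"
        )
    merged: list[Box] = []
    for boxes, origin in zip(per_tile, plan.origins):
        merged.extend(to_global(b, origin) for b in boxes)
    return merged


def count_panicles(
    image: np.ndarray,
    detector: Detector,
    image_id: str = "image",
    tile_w: int = 1056,
    tile_h: int = 1056,
    stride: int = 756,
    suppression: SuppressionConfig | None = None,
) -> PipelineResult:
    """Full chain: plan, crop, detect, merge, suppress, count.

    Merged boxes are clipped to the image bounds before suppression
    (clamped edge tiles cannot produce out-of-image boxes, but detector
    adapters might); zero-area boxes left after clipping are dropped.
    """
    if suppression is None:
        suppression = SuppressionConfig()
    h, w = image.shape[:2]
    plan = plan_tiles(w, h, tile_w, tile_h, stride)
    tiles = crop_tiles(image, plan)
    per_tile = detect_tiles(detector, tiles, plan)
    merged = merge_detections(per_tile, plan)
    merged = [b for b in (m.clip(0, 0, w, h) for m in merged) if b.area > 0]
    kept = suppress(merged, suppression)
    provenance = {
        "tile_w": tile_w,
        "tile_h": tile_h,
        "stride": stride,
        "suppression": {
            "method": suppression.method,
            "iob_threshold": suppression.iob_threshold,
            "bou_threshold": suppression.bou_threshold,
            "nms_threshold": suppression.nms_threshold,
        },
        "n_tiles": plan.n_tiles,
        "n_merged": len(merged),
    }
    return PipelineResult(
        image_id=image_id,
        boxes=tuple(kept),
        tile_plan=plan,
        provenance=provenance,
    )
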