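"""Seeded synthetic field scenes and an oracle detector.

Real panicle imagery cannot ship with the package, so tests and demos
run on generated scenes: elliptical textured blobs ("panicles") on a
noisy green-brown background, with tight ground-truth bounding boxes
and a binary foreground mask.  Blob sizes are bimodal by default —
a small mode (30-60 px) and a large mode (150-290 px) — because the
large size disparity between a whole detection and a tile-clipped
fragment is exactly what separates the IOB/BOU duplicate rule from
IoU-based NMS.  The large mode stays below the 300 px tile overlap of
the default tiling geometry (1056 px tiles, 756 px stride) so that
every object fits whole in at least one tile.

The oracle detector replays ground truth per tile instead of running a
neural network: an object fully inside a tile is reported as its exact
box (optionally jittered); an object cut by a tile edge is reported as
the clipped fragment, reproducing the central hazard of overlapping
tiling — the same panicle reported whole in one tile and as a small
fragment in a neighbour.  Configurable drop and spurious rates simulate
false negatives and false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .boxgeom import Box
from .tiler import TilePlan

MAX_PLACEMENT_TRIES = 200


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed within bounds."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``overlap_fraction`` is the share of objects deliberately placed
    touching a previously placed object, emulating occluded panicle
    clusters; the rest are placed without constraint (and may still
    overlap by chance at high density).
    """

    width: int = 2000
    height: int = 1500
    n_objects: int = 40
    size_range_small: tuple[int, int] = (30, 60)
    size_range_large: tuple[int, int] = (150, 290)
    large_fraction: float = 0.5
    overlap_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.size_range_small, self.size_range_large):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction outside [0, 1]")


@dataclass(frozen=True)
class OracleNoise:
    """Noise model of the oracle detector.

    ``drop_rate`` removes each would-be detection independently
    (simulated false negatives); ``spurious_rate`` is the Poisson mean
    of extra background boxes per tile (false positives); ``jitter_px``
    perturbs each corner uniformly in ``[-jitter_px, +jitter_px]``;
    ``emit_fragments`` controls whether objects cut by a tile edge are
    reported as their clipped fragments.
    """

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    jitter_px: float = 0.0
    emit_fragments: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.drop_rate <= 1.0):
            raise ValueError("drop_rate outside [0, 1]")
        if self.spurious_rate < 0 or self.jitter_px < 0:
            raise ValueError("rates must be non-negative")


# A placed object whose bounding box is this deeply contained in an
# earlier object's box would be annotated as a single panicle by a human
# rater, so the generator rejects it and the ground truth stays free of
# indistinguishable duplicates.
_CONTAINMENT_IOB = 0.7
_CONTAINMENT_BOU = 0.7


def _ellipse_bbox(cx, cy, rx, ry, angle) -> Box:
    """Tight axis-aligned bounding box of a rotated ellipse."""
    hw = float(np.hypot(rx * np.cos(angle), ry * np.sin(angle)))
    hh = float(np.hypot(rx * np.sin(angle), ry * np.cos(angle)))
    return Box(cx - hw, cy - hh, cx + hw, cy + hh)


def _place_ellipses(spec: SceneSpec, rng: np.random.Generator) -> list[tuple]:
    """Choose (cx, cy, rx, ry, angle) for each object, within bounds.

    Placements whose bounding box is near-contained in (or near-contains)
    an existing object's box are rejected and retried.
    """
    from .boxgeom import bou as _bou, iob as _iob

    placed: list[tuple] = []
    bboxes: list[Box] = []
    for k in range(spec.n_objects):
        if rng.random() < spec.large_fraction:
            lo, hi = spec.size_range_large
        else:
            lo, hi = spec.size_range_small
        # box side in [lo, hi]; ellipse semi-axes fill the box
        w = rng.uniform(lo, hi)
        h = rng.uniform(lo, hi)
        rx, ry = w / 2.0, h / 2.0
        touch = placed and rng.random() < spec.overlap_fraction
        for attempt in range(MAX_PLACEMENT_TRIES):
            # fall back to unconstrained placement if touching fails
            if touch and attempt < MAX_PLACEMENT_TRIES // 2:
                base = placed[rng.integers(len(placed))]
                cx = base[0] + rng.uniform(-base[2] - rx, base[2] + rx)
                cy = base[1] + rng.uniform(-base[3] - ry, base[3] + ry)
            else:
                cx = rng.uniform(rx, spec.width - rx)
                cy = rng.uniform(ry, spec.height - ry)
            if not (rx <= cx <= spec.width - rx and ry <= cy <= spec.height - ry):
                continue
            angle = rng.uniform(0, np.pi)
            bb = _ellipse_bbox(cx, cy, rx, ry, angle)
            if any(
                _iob(bb, other) > _CONTAINMENT_IOB
                and _bou(bb, other) > _CONTAINMENT_BOU
                for other in bboxes
            ):
                continue
            placed.append((cx, cy, rx, ry, angle))
            bboxes.append(bb)
            break
        else:
            raise PlacementError(
                f"could not place object {k} within bounds after "
                f"{MAX_PLACEMENT_TRIES} tries"
            )
    return placed


def _ellipse_support(
    cx: float, cy: float, rx: float, ry: float, angle: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates (rows, cols) inside a rotated ellipse."""
    h, w = shape
    x0 = max(0, int(np.floor(cx - max(rx, ry))))
    x1 = min(w, int(np.ceil(cx + max(rx, ry))) + 1)
    y0 = max(0, int(np.floor(cy - max(rx, ry))))
    y1 = min(h, int(np.ceil(cy + max(rx, ry))) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    inside = u * u + v * v <= 1.0
    return yy[inside], xx[inside]


def generate_scene(
    spec: SceneSpec,
) -> tuple[np.ndarray, list[Box], np.ndarray]:
    """Render a synthetic scene.

    Returns ``(image, gt_boxes, mask)``: an RGB uint8 array of shape
    ``(height, width, 3)``, the tight half-open bounding boxes of the
    rendered blobs, and a boolean foreground mask (union of blob
    supports).  Identical specs (including seed) produce identical
    arrays and box lists.
    """
    rng = np.random.default_rng(spec.seed)

    # muddy-green background with per-pixel noise
    image = np.empty((spec.height, spec.width, 3), dtype=np.float32)
    base = np.array([62.0, 92.0, 48.0], dtype=np.float32)
    noise = rng.normal(0.0, 12.0, size=(spec.height, spec.width, 1)).astype(np.float32)
    image[:] = base + noise

    mask = np.zeros((spec.height, spec.width), dtype=bool)
    gt: list[Box] = []

    for cx, cy, rx, ry, angle in _place_ellipses(spec, rng):
        rows, cols = _ellipse_support(cx, cy, rx, ry, angle, mask.shape)
        if rows.size == 0:
            continue
        # straw-yellow blob with grainy texture, loosely panicle-like
        tint = rng.uniform(0.85, 1.15)
        color = np.array([205.0, 185.0, 110.0], dtype=np.float32) * tint
        grain = rng.normal(0.0, 18.0, size=(rows.size, 1)).astype(np.float32)
        image[rows, cols] = color + grain
        mask[rows, cols] = True
        gt.append(
            Box(
                float(cols.min()),
                float(rows.min()),
                float(cols.max() + 1),
                float(rows.max() + 1),
                label="panicle",
            )
        )

    return np.clip(image, 0, 255).astype(np.uint8), gt, mask


def _tile_seed(seed: int, origin: tuple[int, int]) -> int:
    """Deterministic per-tile stream, independent of call order."""
    return (seed * 1_000_003 + origin[0] * 9176 + origin[1]) % (2**31 - 1)


def oracle_detect(
    gt: Sequence[Box],
    tile_origin: tuple[int, int],
    tile_size: tuple[int, int],
    noise: OracleNoise | None = None,
    seed: int = 0,
) -> list[Box]:
    """Replay ground truth as tile-local detections.

    For each ground-truth box (global frame) intersecting the tile: if
    it lies fully inside, emit the tile-local box; if it is cut by a
    tile edge and ``noise.emit_fragments``, emit the clipped fragment.
    Jitter, drops and spurious boxes are applied from a per-tile seeded
    stream, so detections are deterministic per (seed, origin).
    """
    if noise is None:
        noise = OracleNoise()
    ox, oy = tile_origin
    tw, th = tile_size
    rng = np.random.default_rng(_tile_seed(seed, tile_origin))
    out: list[Box] = []
    for g in gt:
        clipped = g.clip(ox, oy, ox + tw, oy + th)
        if clipped.area <= 0.0:
            continue
        whole = clipped.area == g.area
        if not whole and not noise.emit_fragments:
            continue
        if noise.drop_rate > 0.0 and rng.random() < noise.drop_rate:
            continue
        local = clipped.translate(-ox, -oy)
        coords = [local.x_min, local.y_min, local.x_max, local.y_max]
        if noise.jitter_px > 0.0:
            coords = list(coords + rng.uniform(-noise.jitter_px, noise.jitter_px, 4))
            coords[0] = min(max(coords[0], 0.0), tw)
            coords[1] = min(max(coords[1], 0.0), th)
            coords[2] = min(max(coords[2], coords[0]), tw)
            coords[3] = min(max(coords[3], coords[1]), th)
        out.append(
            Box(*coords, score=0.95 if whole else 0.6, label=g.label)
        )
    if noise.spurious_rate > 0.0:
        for _ in range(rng.poisson(noise.spurious_rate)):
            w = rng.uniform(20, 80)
            h = rng.uniform(20, 80)
            x = rng.uniform(0, tw - w)
            y = rng.uniform(0, th - h)
            out.append(Box(x, y, x + w, y + h, score=0.3, label="spurious"))
    return out


class OracleDetector:
    """Detector-contract adapter around :func:`oracle_detect`.

    Holds the scene's global ground truth and, when asked to detect a
    tile, replays the boxes intersecting that tile in tile-local
    coordinates.  Deterministic for fixed ground truth, noise and seed.
    """

    def __init__(
        self,
        gt: Sequence[Box],
        noise: OracleNoise | None = None,
        seed: int = 0,
    ) -> None:
        self.gt = list(gt)
        self.noise = noise if noise is not None else OracleNoise()
        self.seed = seed

    def detect(
        self, tile: np.ndarray, origin: tuple[int, int]
    ) -> list[Box]:
        th, tw = tile.shape[:2]
        return oracle_detect(
            self.gt, origin, (tw, th), noise=self.noise, seed=self.seed
        )
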