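"""Overlapping sliding-window tiling of large images.

A very large field image (e.g. 6000 x 4000 px) is cut into fixed-size
sub-images on a regular grid with a stride smaller than the tile side,
so that consecutive tiles overlap by ``tile - stride`` pixels.  The
overlap is sized to the largest expected object so any object whose
sides do not exceed ``tile - stride`` appears *whole* in at least one
tile.  The last tile along each axis is clamped to the image boundary
rather than padded, so no pixels are ever fabricated; clamping can only
enlarge the final overlap, which strengthens the whole-object
guarantee.

Default geometry (1056 px tiles, 756 px stride) splits a 6000 x 4000
image into an 8 x 5 grid of 40 tiles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxgeom import Box

DEFAULT_TILE = 1056
DEFAULT_STRIDE = 756


class TilingError(ValueError):
    """Raised for geometrically impossible tiling requests."""


@dataclass(frozen=True)
class TilePlan:
    """An ordered, row-major list of tile origins covering an image."""

    image_w: int
    image_h: int
    tile_w: int
    tile_h: int
    stride: int
    origins: tuple[tuple[int, int], ...]

    @property
    def n_tiles(self) -> int:
        return len(self.origins)

    def to_json(self) -> str:
        """Serialize the plan (for provenance logging)."""
        return json.dumps(
            {
                "image_w": self.image_w,
                "image_h": self.image_h,
                "tile_w": self.tile_w,
                "tile_h": self.tile_h,
                "stride": self.stride,
                "origins": [list(o) for o in self.origins],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TilePlan":
        d = json.loads(text)
        return cls(
            image_w=d["image_w"],
            image_h=d["image_h"],
            tile_w=d["tile_w"],
            tile_h=d["tile_h"],
            stride=d["stride"],
            origins=tuple((int(x), int(y)) for x, y in d["origins"]),
        )


def _axis_origins(length: int, tile: int, stride: int) -> list[int]:
    """Origins 0, stride, ... with the last clamped to ``length - tile``."""
    n = math.ceil((length - tile) / stride) + 1
    origins = [min(i * stride, length - tile) for i in range(n)]
    # Clamping can make the final two origins coincide when stride
    # exactly divides length - tile; deduplicate while keeping order.
    out: list[int] = []
    for o in origins:
        if not out or o != out[-1]:
            out.append(o)
    return out


def plan_tiles(
    image_w: int,
    image_h: int,
    tile_w: int = DEFAULT_TILE,
    tile_h: int = DEFAULT_TILE,
    stride: int = DEFAULT_STRIDE,
) -> TilePlan:
    """Plan an overlapping row-major tiling of an ``image_w x image_h`` image.

    Per axis the number of tiles is ``ceil((L - tile) / stride) + 1``;
    origins advance by ``stride`` with the final origin clamped to
    ``L - tile``.

    Raises
    ------
    TilingError
        If the tile exceeds the image on either axis, or the stride is
        not in ``(0, min(tile_w, tile_h)]``.
    """
    if tile_w > image_w or tile_h > image_h:
        raise TilingError(
            f"tile {tile_w}x{tile_h} larger than image {image_w}x{image_h}"
        )
    if stride <= 0 or stride > min(tile_w, tile_h):
        raise TilingError(f"stride {stride} outside (0, {min(tile_w, tile_h)}]")

    xs = _axis_origins(image_w, tile_w, stride)
    ys = _axis_origins(image_h, tile_h, stride)
    origins = tuple((x, y) for y in ys for x in xs)
    return TilePlan(image_w, image_h, tile_w, tile_h, stride, origins)


def crop_tiles(image: np.ndarray, plan: TilePlan) -> list[np.ndarray]:
    """Extract the planned sub-images as pixel copies (no resampling).

    ``image`` is a ``(H, W)`` or ``(H, W, C)`` array whose dimensions
    must match the plan.
    """
    h, w = image.shape[:2]
    if w != plan.image_w or h != plan.image_h:
        raise TilingError(
            f"image {w}x{h} does not match plan {plan.image_w}x{plan.image_h}"
        )
    return [
        image[y : y + plan.tile_h, x : x + plan.tile_w].copy()
        for x, y in plan.origins
    ]


def to_global(box: Box, origin: tuple[int, int]) -> Box:
    """Map a tile-local box to global image coordinates."""
    return box.translate(origin[0], origin[1])


def to_local(box: Box, origin: tuple[int, int]) -> Box:
    """Map a global box into the local frame of a tile at ``origin``."""
    return box.translate(-origin[0], -origin[1])
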