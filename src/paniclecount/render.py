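"""Overlay rendering of detection results onto images."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .boxgeom import Box

COLORS = {"kept": (0, 255, 0), "removed": (255, 0, 0), "gt": (255, 255, 255)}


def draw_boxes(
    image: np.ndarray,
    kept: Sequence[Box] = (),
    removed: Sequence[Box] = (),
    gt: Sequence[Box] = (),
    width: int = 3,
) -> Image.Image:
    """Draw box overlays: green = kept detections, red = removed
    duplicates, white = ground truth."""
    img = Image.fromarray(image).convert("RGB")
    draw = ImageDraw.Draw(img)
    for group, color in (
        (gt, COLORS["gt"]),
        (removed, COLORS["removed"]),
        (kept, COLORS["kept"]),
    ):
        for b in group:
            draw.rectangle(
                [b.x_min, b.y_min, max(b.x_max - 1, b.x_min), max(b.y_max - 1, b.y_min)],
                outline=color,
                width=width,
            )
    return img


def save_overlay(path: str | Path, image: np.ndarray, **groups) -> None:
    draw_boxes(image, **groups).save(str(path))
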