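"""Reading and writing boxes: Pascal-VOC XML (LabelImg dialect) and JSON.

The VOC dialect written by LabelImg stores one XML file per image with
``object/bndbox`` elements holding integer ``xmin/ymin/xmax/ymax``.
LabelImg coordinates are 1-based inclusive; internally boxes are
0-based half-open, so reading subtracts 1 from the minima and writing
adds it back.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from lxml import etree

from .boxgeom import Box


def read_voc_xml(path: str | Path) -> list[Box]:
    """Read LabelImg-style VOC annotations as 0-based half-open boxes."""
    tree = etree.parse(str(path))
    boxes: list[Box] = []
    for obj in tree.findall(".//object"):
        name_el = obj.find("name")
        label = name_el.text if name_el is not None else None
        bnd = obj.find("bndbox")
        if bnd is None:
            continue
        xmin = float(bnd.findtext("xmin"))
        ymin = float(bnd.findtext("ymin"))
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        boxes.append(Box(xmin - 1.0, ymin - 1.0, xmax, ymax, label=label))
    return boxes


def write_voc_xml(
    path: str | Path,
    boxes: Sequence[Box],
    image_name: str = "image",
    image_size: tuple[int, int] | None = None,
) -> None:
    """Write boxes as a LabelImg-style VOC XML file."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = image_name
    if image_size is not None:
        size = etree.SubElement(root, "size")
        etree.SubElement(size, "width").text = str(image_size[0])
        etree.SubElement(size, "height").text = str(image_size[1])
        etree.SubElement(size, "depth").text = "3"
    for b in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label or "panicle"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(b.x_min)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(b.y_min)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(b.x_max)))
        etree.SubElement(bnd, "ymax").text = str(int(round(b.y_max)))
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=False)
    )


def box_to_record(box: Box) -> dict:
    rec = {
        "x_min": box.x_min,
        "y_min": box.y_min,
        "x_max": box.x_max,
        "y_max": box.y_max,
    }
    if box.score is not None:
        rec["score"] = box.score
    if box.label is not None:
        rec["label"] = box.label
    return rec


def record_to_box(rec: dict) -> Box:
    return Box(
        rec["x_min"],
        rec["y_min"],
        rec["x_max"],
        rec["y_max"],
        score=rec.get("score"),
        label=rec.get("label"),
    )


def read_boxes_json(path: str | Path) -> list[Box]:
    data = json.loads(Path(path).read_text())
    records = data["boxes"] if isinstance(data, dict) else data
    return [record_to_box(r) for r in records]


def write_boxes_json(path: str | Path, boxes: Sequence[Box]) -> None:
    Path(path).write_text(
        json.dumps({"boxes": [box_to_record(b) for b in boxes]}, indent=2)
        + "\n"
    )


def read_ground_truth(path: str | Path) -> list[Box]:
    """Read ground truth from VOC XML or JSON, by file extension."""
    p = Path(path)
    if p.suffix.lower() == ".xml":
        return read_voc_xml(p)
    if p.suffix.lower() == ".json":
        return read_boxes_json(p)
    raise ValueError(f"unsupported annotation format: {p.suffix}")
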