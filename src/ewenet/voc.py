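"""Pascal VOC XML annotation I/O (LabelImg dialect), splitting, frame sampling.

On disk, VOC stores 1-based inclusive corner coordinates; internally the
package works with 0-based, half-open continuous pixel coordinates.  The
converters in this module are the only place that offset is applied.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import BoundingBox, to_center

__all__ = [
    "VocObject",
    "Annotation",
    "SplitSpec",
    "read_voc",
    "write_voc",
    "split_dataset",
    "sample_frames",
]

DEFAULT_CLASS = "mounting"


@dataclass(frozen=True)
class VocObject:
    """One annotated object: class name, 0-based corner box, difficult flag."""

    class_name: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    difficult: bool = False

    def __post_init__(self) -> None:
        if not self.xmin < self.xmax or not self.ymin < self.ymax:
            raise ValueError(
                f"corner order violated: ({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )

    def box(self) -> BoundingBox:
        return to_center((self.xmin, self.ymin, self.xmax, self.ymax))


@dataclass
class Annotation:
    """All annotations for one image."""

    image_path: str
    image_size: tuple[int, int]  # (w, h)
    objects: list[VocObject] = field(default_factory=list)

    def boxes(self) -> list[BoundingBox]:
        return [o.box() for o in self.objects]


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios (must sum to 1) and the shuffling seed."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError(f"ratios must be positive, got {self.ratios}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {self.ratios}")


def _req(node: ET.Element, tag: str, path: str) -> ET.Element:
    child = node.find(tag)
    if child is None:
        raise ValueError(f"{path}: missing <{tag}> element")
    return child


def _num(node: ET.Element, tag: str, path: str) -> float:
    child = _req(node, tag, path)
    try:
        return float(child.text)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValueError(f"{path}: non-numeric <{tag}> value {child.text!r}") from None


def read_voc(path: str | Path) -> Annotation:
    """Parse a LabelImg-style VOC XML file.

    Corner coordinates are converted from the 1-based inclusive on-disk
    convention to 0-based half-open pixels and clipped to the image bounds.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    size = _req(root, "size", str(path))
    w = int(_num(size, "width", str(path)))
    h = int(_num(size, "height", str(path)))
    if w <= 0 or h <= 0:
        raise ValueError(f"{path}: non-positive image size {w}x{h}")
    fname_node = root.find("filename")
    fname = fname_node.text if fname_node is not None and fname_node.text else path.stem

    objects: list[VocObject] = []
    for obj in root.iter("object"):
        name = _req(obj, "name", str(path)).text or DEFAULT_CLASS
        bnd = _req(obj, "bndbox", str(path))
        xmin = _num(bnd, "xmin", str(path)) - 1.0
        ymin = _num(bnd, "ymin", str(path)) - 1.0
        xmax = _num(bnd, "xmax", str(path))
        ymax = _num(bnd, "ymax", str(path))
        if xmin >= xmax or ymin >= ymax:
            raise ValueError(f"{path}: degenerate bndbox ({xmin+1},{ymin+1},{xmax},{ymax})")
        diff_node = obj.find("difficult")
        difficult = bool(int(diff_node.text)) if diff_node is not None and diff_node.text else False
        objects.append(
            VocObject(
                class_name=name,
                xmin=max(0.0, xmin),
                ymin=max(0.0, ymin),
                xmax=min(float(w), xmax),
                ymax=min(float(h), ymax),
                difficult=difficult,
            )
        )
    return Annotation(image_path=fname, image_size=(w, h), objects=objects)


def write_voc(ann: Annotation, path: str | Path) -> None:
    """Serialise an Annotation back to LabelImg-style XML (1-based corners)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = ann.image_path
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.image_size[0])
    ET.SubElement(size, "height").text = str(ann.image_size[1])
    ET.SubElement(size, "depth").text = "3"
    for obj in ann.objects:
        o = ET.SubElement(root, "object")
        ET.SubElement(o, "name").text = obj.class_name
        ET.SubElement(o, "pose").text = "Unspecified"
        ET.SubElement(o, "truncated").text = "0"
        ET.SubElement(o, "difficult").text = str(int(obj.difficult))
        b = ET.SubElement(o, "bndbox")
        ET.SubElement(b, "xmin").text = _fmt(obj.xmin + 1.0)
        ET.SubElement(b, "ymin").text = _fmt(obj.ymin + 1.0)
        ET.SubElement(b, "xmax").text = _fmt(obj.xmax)
        ET.SubElement(b, "ymax").text = _fmt(obj.ymax)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def split_dataset(
    items: Sequence, spec: SplitSpec = SplitSpec()
) -> tuple[list, list, list]:
    """Randomly partition items into train/val/test by the spec ratios.

    Subset sizes are ``round(n * ratio)`` with any remainder folded into
    the training set, e.g. 5600 items at 7:2:1 give 3920/1120/560.  The
    shuffle is deterministic per seed and the three parts are disjoint
    with union equal to the input.
    """
    n = len(items)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    n_val = round(n * spec.ratios[1])
    n_test = round(n * spec.ratios[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("ratios produce a negative subset size")
    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [items[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def sample_frames(frame_indices: Sequence[int], stride: int) -> list[int]:
    """Keep one frame every ``stride`` frames, starting with the first."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return list(frame_indices[::stride])
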