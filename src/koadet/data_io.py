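"""Dataset I/O: VOC-XML and CSV annotations, 8-bit grayscale images,
stratified 8:2 splitting, and runtime augmentation.

Annotations label each box with one of the five Kellgren-Lawrence grades
K0..K4 (serialized as "KL0".."KL4"; "K0".."K4" accepted as aliases).
VOC XML stores 1-based inclusive pixel indices; on read the minima are
shifted by -1 into the package's continuous top-left-origin convention,
and on write the inverse shift is applied.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import GRADE_NAMES, NUM_GRADES
from .geometry import Box

__all__ = ["ImageSample", "DatasetSplit", "grade_to_index", "index_to_grade",
           "read_voc_xml", "write_voc_xml", "read_annotations_csv",
           "write_annotations_csv", "read_image", "write_image",
           "stratified_split", "augment", "load_dataset"]

_ALIASES = {name: i for i, name in enumerate(GRADE_NAMES)}
_ALIASES.update({f"K{i}": i for i in range(NUM_GRADES)})


def grade_to_index(name: str) -> int:
    try:
        return _ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown class label {name!r}; permitted: "
            f"{sorted(_ALIASES)}") from None


def index_to_grade(i: int) -> str:
    return GRADE_NAMES[i]


@dataclass
class ImageSample:
    """One grayscale radiograph with its (box, grade) annotations."""

    image_id: str
    pixels: np.ndarray                       # (H, W) uint8
    annotations: list[tuple[Box, int]] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be a 2-D uint8 raster")
        h, w = self.pixels.shape
        for box, grade in self.annotations:
            if not (0 <= box.x_min and box.x_max <= w
                    and 0 <= box.y_min and box.y_max <= h):
                raise ValueError(
                    f"annotation {box.as_tuple()} outside {w}x{h} image")
            if not 0 <= grade < NUM_GRADES:
                raise ValueError(f"grade index {grade} out of range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DatasetSplit:
    train: list
    test: list
    train_counts: dict[int, int]
    test_counts: dict[int, int]


# ---------------------------------------------------------------------------
# VOC XML
# ---------------------------------------------------------------------------

def _num(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def write_voc_xml(path: str | Path, sample: ImageSample) -> None:
    h, w = sample.shape
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{sample.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "1"
    for box, grade in sample.annotations:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = index_to_grade(grade)
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _num(box.x_min + 1)
        ET.SubElement(bnd, "ymin").text = _num(box.y_min + 1)
        ET.SubElement(bnd, "xmax").text = _num(box.x_max)
        ET.SubElement(bnd, "ymax").text = _num(box.y_max)
    ET.indent(tree := ET.ElementTree(root))
    tree.write(path, encoding="unicode")


def read_voc_xml(path: str | Path) -> list[tuple[Box, int]]:
    """Parse VOC object boxes, shifting 1-based minima to the continuous
    convention; unknown class names are rejected with the permitted list."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise ValueError(f"malformed VOC XML at {path}: {e}") from None
    annotations = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        grade = grade_to_index(name)
        bnd = obj.find("bndbox")
        vals = {k: float(bnd.findtext(k)) for k in ("xmin", "ymin", "xmax", "ymax")}
        annotations.append(
            (Box(vals["xmin"] - 1, vals["ymin"] - 1, vals["xmax"], vals["ymax"]),
             grade))
    return annotations


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

CSV_HEADER = ["filename", "x_min", "y_min", "x_max", "y_max", "label"]


def write_annotations_csv(path: str | Path,
                          samples: list[ImageSample]) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(CSV_HEADER)
        for s in samples:
            for box, grade in s.annotations:
                writer.writerow([f"{s.image_id}.png", _num(box.x_min),
                                 _num(box.y_min), _num(box.x_max),
                                 _num(box.y_max), index_to_grade(grade)])


def read_annotations_csv(path: str | Path) -> dict[str, list[tuple[Box, int]]]:
    """Rows aggregated by filename (insertion order preserved)."""
    out: dict[str, list[tuple[Box, int]]] = {}
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        if header != CSV_HEADER:
            raise ValueError(f"bad CSV header {header}; expected {CSV_HEADER}")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            fname, *coords, label = row
            try:
                x1, y1, x2, y2 = map(float, coords)
            except ValueError:
                raise ValueError(
                    f"non-numeric coordinate on row {row_no} of {path}") from None
            out.setdefault(fname, []).append((Box(x1, y1, x2, y2),
                                              grade_to_index(label)))
    return out


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(path)


def load_dataset(directory: str | Path) -> list[ImageSample]:
    """Read every image with a sibling VOC XML from a dataset directory."""
    directory = Path(directory)
    samples = []
    for img_path in sorted(directory.glob("*.png")) + sorted(directory.glob("*.jpg")):
        xml_path = img_path.with_suffix(".xml")
        anns = read_voc_xml(xml_path) if xml_path.exists() else []
        samples.append(ImageSample(img_path.stem, read_image(img_path), anns))
    return samples


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def stratified_split(items, ratio: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Per-class split: floor(ratio * n) to train, remainder to test.

    `items` is either a mapping {class: count} or a sequence of
    (identifier, class) pairs / ImageSamples (class = grade of the first
    annotation). Selection order within a class is a seeded shuffle, so the
    same seed reproduces membership and any seed reproduces the counts.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("split ratio must lie in (0, 1)")
    if isinstance(items, dict):
        pairs = [(f"{cls}_{i}", cls) for cls, n in items.items()
                 for i in range(n)]
    else:
        pairs = []
        for it in items:
            if isinstance(it, ImageSample):
                if not it.annotations:
                    raise ValueError(f"sample {it.image_id} has no annotations")
                pairs.append((it.image_id, it.annotations[0][1]))
            else:
                pairs.append(tuple(it))
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for ident, cls in pairs:
        by_class.setdefault(cls, []).append(ident)
    train, test = [], []
    train_counts, test_counts = {}, {}
    for cls in sorted(by_class, key=str):
        members = by_class[cls]
        order = rng.permutation(len(members))
        n_train = int(np.floor(ratio * len(members)))
        chosen = [members[i] for i in order]
        train.extend(chosen[:n_train])
        test.extend(chosen[n_train:])
        train_counts[cls] = n_train
        test_counts[cls] = len(members) - n_train
    return DatasetSplit(train, test, train_counts, test_counts)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _hflip(sample: ImageSample) -> ImageSample:
    h, w = sample.shape
    boxes = [(Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max), g)
             for b, g in sample.annotations]
    return ImageSample(sample.image_id, sample.pixels[:, ::-1].copy(), boxes)


def _rotate(sample: ImageSample, theta_deg: float) -> ImageSample:
    h, w = sample.shape
    rotated = ndimage.rotate(sample.pixels, theta_deg, reshape=False,
                             order=1, mode="nearest").astype(np.uint8)
    # ndimage.rotate(theta) moves content by +theta in (x right, y down)
    # screen coordinates when theta is negated in the (row, col) plane;
    # map each box to the axis-aligned hull of its rotated corners.
    t = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    boxes = []
    for b, g in sample.annotations:
        corners = np.array([[b.x_min, b.y_min], [b.x_max, b.y_min],
                            [b.x_min, b.y_max], [b.x_max, b.y_max]])
        moved = (corners - (cx, cy)) @ rot.T + (cx, cy)
        x1, y1 = moved.min(axis=0)
        x2, y2 = moved.max(axis=0)
        boxes.append((Box(max(x1, 0.0), max(y1, 0.0),
                          min(x2, float(w)), min(y2, float(h))), g))
    return ImageSample(sample.image_id, rotated, boxes)


def _random_crop(sample: ImageSample, rng: np.random.Generator,
                 min_scale: float = 0.7, tries: int = 10) -> ImageSample:
    h, w = sample.shape
    for _ in range(tries):
        s = rng.uniform(min_scale, 1.0)
        ch, cw = int(round(h * s)), int(round(w * s))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        boxes = []
        for b, g in sample.annotations:
            mx, my = b.center
            if left <= mx < left + cw and top <= my < top + ch:
                boxes.append((Box(max(b.x_min - left, 0.0),
                                  max(b.y_min - top, 0.0),
                                  min(b.x_max - left, float(cw)),
                                  min(b.y_max - top, float(ch))), g))
        if boxes or not sample.annotations:
            pix = sample.pixels[top:top + ch, left:left + cw].copy()
            return ImageSample(sample.image_id, pix, boxes)
    return sample


def augment(sample: ImageSample, ops: tuple[str, ...], seed: int,
            max_rotation: float = 15.0) -> ImageSample:
    """Apply a random subset of {hflip, rotate, random_crop}, deterministic
    under a fixed seed; boxes track the pixels and stay inside the frame."""
    allowed = {"hflip", "rotate", "random_crop"}
    unknown = set(ops) - allowed
    if unknown:
        raise ValueError(f"unknown augmentation ops {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = sample
    if "hflip" in ops and rng.random() < 0.5:
        out = _hflip(out)
    if "rotate" in ops:
        out = _rotate(out, float(rng.uniform(-max_rotation, max_rotation)))
    if "random_crop" in ops:
        out = _random_crop(out, rng)
    return out
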