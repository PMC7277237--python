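"""Segmentation-annotation I/O and raster/vector conversion.

The package works on per-tooth binary masks of the six mandibular molars
(FDI 36-38 left, 46-48 right). Annotations arrive either as single-channel
8-bit label-map PNGs (index 0 = background, indices 1-6 mapped to FDI codes
by a label table) or as LabelMe-style polygon JSON. Everything downstream
uses one fixed raster convention: x rightward, y downward, 0-based indices,
coordinates refer to pixel centers.

Rasterization rule: a pixel is foreground iff its center lies inside or on
the annotation polygon.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon
from skimage import measure

from .errors import (
    AnnotationError,
    EmptyMaskError,
    GeometryError,
    UnknownLabelError,
)

__all__ = [
    "BinaryMask",
    "Position",
    "Side",
    "ToothLabel",
    "LandmarkPair",
    "ToothInstance",
    "Scene",
    "read_label_map",
    "write_label_map",
    "read_labelme",
    "write_labelme",
    "parse_label_table",
    "polygon_to_mask",
    "mask_to_polygon",
    "mask_to_boundary",
    "write_angle_csv",
    "read_angle_csv",
    "ANGLE_CSV_COLUMNS",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class Position(str, Enum):
    """Molar position along the arch: first, second, third (wisdom) molar."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


#: FDI two-digit codes of the mandibular molars.
_FDI_TABLE: dict[int, tuple[Position, Side]] = {
    36: (Position.M1, Side.LEFT),
    37: (Position.M2, Side.LEFT),
    38: (Position.M3, Side.LEFT),
    46: (Position.M1, Side.RIGHT),
    47: (Position.M2, Side.RIGHT),
    48: (Position.M3, Side.RIGHT),
}


@dataclass(frozen=True)
class BinaryMask:
    """2D boolean raster of one tooth instance (rows = y, cols = x)."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={px.ndim}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def area(self) -> int:
        """Foreground pixel count."""
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass(frozen=True)
class ToothLabel:
    """Identity of one mandibular molar: position, jaw side, FDI code."""

    position: Position
    side: Side
    fdi_code: int

    def __post_init__(self):
        expected = _FDI_TABLE.get(self.fdi_code)
        if expected is None:
            raise UnknownLabelError(
                f"FDI code {self.fdi_code} is not a mandibular molar "
                f"(expected one of {sorted(_FDI_TABLE)})"
            )
        if expected != (self.position, self.side):
            raise AnnotationError(
                f"FDI code {self.fdi_code} inconsistent with "
                f"({self.position.value}, {self.side.value})"
            )

    @classmethod
    def from_fdi(cls, fdi_code: int) -> "ToothLabel":
        try:
            position, side = _FDI_TABLE[int(fdi_code)]
        except (KeyError, ValueError) as exc:
            raise UnknownLabelError(
                f"cannot parse FDI code {fdi_code!r} as a mandibular molar"
            ) from exc
        return cls(position=position, side=side, fdi_code=int(fdi_code))


@dataclass(frozen=True)
class LandmarkPair:
    """Occlusal-surface midpoint and pulp-chamber floor, image coordinates.

    For mandibular teeth the occlusal surface lies above the pulp floor, so
    ``occlusal_midpoint`` must have the smaller y.
    """

    occlusal_midpoint: tuple[float, float]
    pulp_floor: tuple[float, float]

    def __post_init__(self):
        if not self.occlusal_midpoint[1] < self.pulp_floor[1]:
            raise ValueError(
                "occlusal midpoint must lie above the pulp floor "
                f"(y {self.occlusal_midpoint[1]} !< {self.pulp_floor[1]})"
            )


@dataclass(frozen=True)
class ToothInstance:
    """One segmented molar: label + mask + optional landmarks."""

    label: ToothLabel
    mask: BinaryMask
    landmarks: LandmarkPair | None = None
    source_image_id: str = ""

    def __post_init__(self):
        if self.mask.is_empty():
            raise EmptyMaskError(
                f"tooth instance {self.label.fdi_code} has an empty mask"
            )


@dataclass
class Scene:
    """All molar instances annotated on one panoramic image (0-6 teeth)."""

    image_id: str
    instances: list[ToothInstance] = field(default_factory=list)
    image_height: int = 0
    image_width: int = 0

    def __post_init__(self):
        codes = [inst.label.fdi_code for inst in self.instances]
        if len(codes) != len(set(codes)):
            raise AnnotationError(
                f"scene {self.image_id!r} has duplicate FDI codes: {codes}"
            )

    def get(self, fdi_code: int) -> ToothInstance | None:
        for inst in self.instances:
            if inst.label.fdi_code == fdi_code:
                return inst
        return None


# ---------------------------------------------------------------------------
# Raster <-> vector conversion
# ---------------------------------------------------------------------------


def rasterize_geometry(geom, height: int, width: int) -> BinaryMask:
    """Rasterize a shapely geometry by the pixel-center-inclusion rule.

    Pixel (r, c) is foreground iff the point (x=c, y=r) lies inside or on
    the geometry. Accepts Polygon or MultiPolygon (the latter arises from
    noisy phantom contours repaired with ``make_valid``).
    """
    pixels = np.zeros((height, width), dtype=bool)
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(width - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(height - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        return BinaryMask(pixels)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.intersects_xy(geom, xx.ravel(), yy.ravel())
    pixels[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(len(rows), len(cols))
    return BinaryMask(pixels)


def polygon_to_mask(
    points: Sequence[tuple[float, float]], height: int, width: int
) -> BinaryMask:
    """Rasterize a simple polygon onto a ``height`` x ``width`` grid.

    Parameters
    ----------
    points
        Polygon vertices as (x, y) pairs, >= 3, in drawing order. The
        polygon may be non-convex but must be simple (non-self-intersecting,
        non-degenerate).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError(f"polygon needs >= 3 (x, y) points, got {points!r}")
    poly = Polygon(pts)
    if not poly.is_valid or poly.area == 0:
        raise GeometryError(
            "polygon is not simple (self-intersecting or degenerate): "
            + shapely.is_valid_reason(poly)
        )
    return rasterize_geometry(poly, height, width)


def mask_to_polygon(mask: BinaryMask) -> np.ndarray:
    """Extract the mask's outer contour as sub-pixel (x, y) coordinates.

    Uses marching squares at level 0.5 on the binary raster; when the mask
    has several connected components the longest closed contour is returned.
    """
    if mask.is_empty():
        raise EmptyMaskError("cannot extract a contour from an empty mask")
    padded = np.pad(mask.pixels.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    longest = max(contours, key=len)
    # contour is (row, col) in the padded frame; convert to (x, y) unpadded
    return np.column_stack([longest[:, 1] - 1.0, longest[:, 0] - 1.0])


def mask_to_boundary(mask: BinaryMask) -> np.ndarray:
    """Boundary pixels of a mask as an (n, 2) array of (x, y) coordinates.

    A foreground pixel is boundary iff at least one of its 4-neighbors is
    background; the image border counts as background.
    """
    if mask.is_empty():
        raise EmptyMaskError("cannot extract the boundary of an empty mask")
    fg = mask.pixels
    padded = np.pad(fg, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    rows, cols = np.nonzero(fg & ~interior)
    return np.column_stack([cols, rows]).astype(float)


# ---------------------------------------------------------------------------
# Label-map PNG I/O
# ---------------------------------------------------------------------------


def parse_label_table(source: str | Path) -> dict[int, int]:
    """Parse an index-to-FDI label table.

    Accepts a path to (or the text of) a simple ``key=value`` file, e.g.::

        1=36
        2=37

    Blank lines and ``#`` comments are ignored.
    """
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    table: dict[int, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            key, value = line.split("=")
            table[int(key.strip())] = int(value.strip())
        except ValueError as exc:
            raise AnnotationError(
                f"bad label-table line {lineno}: {raw!r}"
            ) from exc
    return table


def read_label_map(path: str | Path, label_table: Mapping[int, int]) -> Scene:
    """Read a single-channel 8-bit label-map PNG into a Scene.

    Index 0 is background; every other index present must appear in
    ``label_table`` (index -> FDI code).
    """
    path = Path(path)
    with Image.open(path) as img:
        if img.mode not in ("L", "P"):
            raise AnnotationError(
                f"label map must be single-channel 8-bit, got mode {img.mode!r}"
            )
        arr = np.asarray(img.convert("L") if img.mode == "P" else img)
    indices = [int(i) for i in np.unique(arr) if i != 0]
    instances = []
    for idx in indices:
        if idx not in label_table:
            raise UnknownLabelError(f"unknown label index {idx} in {path.name}")
        instances.append(
            ToothInstance(
                label=ToothLabel.from_fdi(label_table[idx]),
                mask=BinaryMask(arr == idx),
                source_image_id=path.stem,
            )
        )
    return Scene(
        image_id=path.stem,
        instances=instances,
        image_height=arr.shape[0],
        image_width=arr.shape[1],
    )


def write_label_map(
    scene: Scene, path: str | Path, label_table: Mapping[int, int]
) -> None:
    """Write a Scene as an 8-bit label-map PNG (inverse of read_label_map).

    ``label_table`` maps index -> FDI code; masks must be pairwise disjoint.
    """
    fdi_to_index = {fdi: idx for idx, fdi in label_table.items()}
    arr = np.zeros((scene.image_height, scene.image_width), dtype=np.uint8)
    for inst in scene.instances:
        fdi = inst.label.fdi_code
        if fdi not in fdi_to_index:
            raise UnknownLabelError(f"no label index assigned to FDI {fdi}")
        px = inst.mask.pixels
        if (arr[px] != 0).any():
            raise AnnotationError(
                f"instance {fdi} overlaps a previously written mask"
            )
        arr[px] = fdi_to_index[fdi]
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


# ---------------------------------------------------------------------------
# LabelMe-style JSON I/O
# ---------------------------------------------------------------------------


def read_labelme(path: str | Path) -> Scene:
    """Read a LabelMe-style polygon annotation file into a Scene.

    Expected JSON keys: ``imageHeight``, ``imageWidth``, ``shapes``; each
    shape carries ``label`` (FDI code as text), ``points`` and
    ``shape_type == "polygon"``. When polygons overlap, later shapes win
    per-pixel (LabelMe files are ordered) and a warning is issued.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    try:
        height = int(data["imageHeight"])
        width = int(data["imageWidth"])
        shapes = data["shapes"]
    except KeyError as exc:
        raise AnnotationError(f"missing top-level key {exc} in {path.name}")

    masks: list[tuple[ToothLabel, np.ndarray]] = []
    for i, shape in enumerate(shapes):
        stype = shape.get("shape_type", "polygon")
        if stype != "polygon":
            raise AnnotationError(
                f"unsupported shape_type {stype!r} in shape {i} of {path.name}"
            )
        label = ToothLabel.from_fdi(shape["label"])
        mask = polygon_to_mask(shape["points"], height, width)
        masks.append((label, mask.pixels.copy()))

    # later shapes win per-pixel
    for j in range(len(masks)):
        for k in range(j + 1, len(masks)):
            overlap = masks[j][1] & masks[k][1]
            if overlap.any():
                warnings.warn(
                    f"shapes {masks[j][0].fdi_code} and {masks[k][0].fdi_code} "
                    f"overlap on {int(overlap.sum())} px; later shape wins",
                    stacklevel=2,
                )
                masks[j][1][overlap] = False

    instances = [
        ToothInstance(label=label, mask=BinaryMask(px), source_image_id=path.stem)
        for label, px in masks
        if px.any()
    ]
    return Scene(
        image_id=path.stem,
        instances=instances,
        image_height=height,
        image_width=width,
    )


def write_labelme(scene: Scene, path: str | Path) -> None:
    """Write a Scene as LabelMe-style JSON (polygon per instance)."""
    shapes = []
    for inst in scene.instances:
        contour = mask_to_polygon(inst.mask)
        shapes.append(
            {
                "label": str(inst.label.fdi_code),
                "points": [[float(x), float(y)] for x, y in contour],
                "shape_type": "polygon",
            }
        )
    payload = {
        "imageHeight": scene.image_height,
        "imageWidth": scene.image_width,
        "imagePath": f"{scene.image_id}.png",
        "shapes": shapes,
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Angle CSV
# ---------------------------------------------------------------------------

ANGLE_CSV_COLUMNS = [
    "image_id",
    "fdi",
    "position",
    "side",
    "angle_signed_deg",
    "angle_magnitude_deg",
    "n_iterations",
    "converged",
]


def write_angle_csv(records: Iterable[Mapping], path: str | Path) -> None:
    """Write per-tooth angle rows as CSV (UTF-8, '.' decimals, header row).

    Float angles round-trip through :func:`read_angle_csv` to 1e-6.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=ANGLE_CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            row = dict(rec)
            for key in ("angle_signed_deg", "angle_magnitude_deg"):
                if key in row and row[key] is not None:
                    row[key] = f"{float(row[key]):.9g}"
            writer.writerow({k: row.get(k, "") for k in ANGLE_CSV_COLUMNS})


def read_angle_csv(path: str | Path) -> pd.DataFrame:
    """Read an angle CSV written by :func:`write_angle_csv`.

    Lines starting with ``#`` (reproducibility headers written by the CLI)
    are skipped.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(ANGLE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"angle CSV {path} missing columns {sorted(missing)}")
    return df
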