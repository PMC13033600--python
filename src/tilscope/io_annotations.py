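"""Raster images, binary masks and QuPath-dialect GeoJSON annotations.

Coordinate convention: 0-based pixel units, x rightward, y downward,
half-open pixel space — identical to QuPath's image space, so polygons and
points import without any axis flip.  Class labels come from the closed
vocabulary {tissue, tumor, necrosis, hemorrhage} for polygons and
{lymphocyte} for points; unknown labels are preserved verbatim (a warning
is emitted) so expert files never silently lose data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

POLYGON_CLASSES = ("tissue", "tumor", "necrosis", "hemorrhage")
POINT_CLASSES = ("lymphocyte",)

__all__ = [
    "RasterImage",
    "BinaryMask",
    "AnnotationSet",
    "read_annotation_file",
    "write_annotation_file",
    "rasterize_polygons",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
]


@dataclass
class RasterImage:
    """8-bit RGB pixel grid with optional physical-scale metadata.

    mpp is microns per pixel; magnification is the nominal objective power
    of the scan (e.g. 20 for a 20x scan).
    """

    pixels: np.ndarray
    mpp: float | None = None
    magnification: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 RGB array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("image must be at least 2x2")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if self.mpp is not None and not self.mpp > 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Single-channel {0,1} grid with the downsample factor vs its source."""

    grid: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if self.grid.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        if not self.scale >= 1:
            raise ValueError("scale must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def area(self) -> int:
        return int(self.grid.sum())


@dataclass
class AnnotationSet:
    """Polygons and points with class labels, in source-image pixels."""

    polygons: list[tuple[str, np.ndarray]] = field(default_factory=list)
    points: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.polygons = [(str(c), np.asarray(v, dtype=np.float64))
                         for c, v in self.polygons]
        for c, v in self.polygons:
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise ValueError(f"polygon '{c}' needs >= 3 (x, y) vertices")
            if not np.isfinite(v).all() or (v < 0).any():
                raise ValueError(f"polygon '{c}' has non-finite or negative coords")
        self.points = [(str(c), float(x), float(y)) for c, x, y in self.points]
        for c, x, y in self.points:
            if not (np.isfinite(x) and np.isfinite(y)) or x < 0 or y < 0:
                raise ValueError(f"point '{c}' has non-finite or negative coords")

    def polygons_of(self, label: str) -> list[np.ndarray]:
        return [v for c, v in self.polygons if c == label]

    def points_of(self, label: str) -> list[tuple[float, float]]:
        return [(x, y) for c, x, y in self.points if c == label]

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        if len(self.polygons) != len(other.polygons) or self.points != other.points:
            return False
        return all(
            ca == cb and np.array_equal(va, vb)
            for (ca, va), (cb, vb) in zip(self.polygons, other.polygons)
        )


class AnnotationParseError(ValueError):
    pass


class UnsupportedGeometryError(ValueError):
    pass


def _known_labels():
    return set(POLYGON_CLASSES) | set(POINT_CLASSES)


def read_annotation_file(path) -> AnnotationSet:
    """Read a QuPath-dialect GeoJSON FeatureCollection.

    The class label is taken from ``feature.properties.classification.name``
    (falling back to ``properties.name``). Polygon exteriors only; Point
    and MultiPolygon geometries are supported, anything else raises.
    """
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise AnnotationParseError(
            f"malformed JSON in {path} at byte offset {e.pos}: {e.msg}"
        ) from e
    feats = doc.get("features", [])
    polygons: list = []
    points: list = []
    known = _known_labels()
    for feat in feats:
        props = feat.get("properties", {}) or {}
        cls = props.get("classification", {})
        label = (cls.get("name") if isinstance(cls, dict) else None) or \
            props.get("name") or "unclassified"
        if label not in known:
            warnings.warn(f"unknown annotation class '{label}' preserved verbatim")
        geom = feat.get("geometry", {}) or {}
        gtype = geom.get("type")
        coords = geom.get("coordinates")
        if gtype == "Polygon":
            polygons.append((label, np.asarray(coords[0], dtype=np.float64)))
        elif gtype == "MultiPolygon":
            for poly in coords:
                polygons.append((label, np.asarray(poly[0], dtype=np.float64)))
        elif gtype == "Point":
            points.append((label, float(coords[0]), float(coords[1])))
        else:
            raise UnsupportedGeometryError(
                f"unsupported geometry type {gtype!r} in {path}"
            )
    return AnnotationSet(polygons=polygons, points=points)


def write_annotation_file(ann: AnnotationSet, path) -> None:
    """Write QuPath-dialect GeoJSON: polygons first, then points, each in
    insertion order."""
    feats = []
    for label, verts in ann.polygons:
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": [np.asarray(verts, dtype=float).tolist()]},
            "properties": {"objectType": "annotation",
                           "classification": {"name": label}},
        })
    for label, x, y in ann.points:
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {"objectType": "annotation",
                           "classification": {"name": label}},
        })
    doc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(doc, indent=1))


def _points_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd ray-casting test, vectorised over query points."""
    inside = np.zeros(px.shape, dtype=bool)
    v = np.asarray(verts, dtype=np.float64)
    if np.array_equal(v[0], v[-1]):
        v = v[:-1]
    n = len(v)
    for i in range(n):
        x0, y0 = v[i]
        x1, y1 = v[(i + 1) % n]
        crosses = (y0 > py) != (y1 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < np.where(crosses, xint, np.inf))
    return inside


def rasterize_polygons(ann: AnnotationSet, label: str, shape: tuple[int, int],
                       scale: float = 1.0) -> BinaryMask:
    """Rasterize all polygons of one class into an HxW {0,1} mask.

    A pixel (r, c) of the output is foreground iff its center, mapped to
    parent-image coordinates ((c + 0.5) * scale, (r + 0.5) * scale), lies
    inside any polygon of the class under the even-odd rule.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    grid = np.zeros((h, w), dtype=np.uint8)
    polys = ann.polygons_of(label)
    if not polys:
        return BinaryMask(grid, scale=scale)
    cy, cx = np.mgrid[0:h, 0:w]
    px = (cx + 0.5) * scale
    py = (cy + 0.5) * scale
    for verts in polys:
        grid |= _points_in_polygon(px, py, verts).astype(np.uint8)
    return BinaryMask(grid, scale=scale)


def read_image(path) -> RasterImage:
    """Read an 8-bit RGB PNG or TIFF; other bit depths are rejected."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = np.asarray(Image.open(p))
    if arr.dtype != np.uint8:
        raise ValueError(
            f"unsupported bit depth: {arr.dtype} (expected 8-bit) in {path}"
        )
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RasterImage(pixels=arr.copy())


def write_image(image: RasterImage, path) -> None:
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, image.pixels)
    else:
        Image.fromarray(image.pixels).save(p)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as single-channel 8-bit PNG with values {0, 255}."""
    Image.fromarray((mask.grid * 255).astype(np.uint8)).save(Path(path))


def read_mask(path, scale: float = 1.0) -> BinaryMask:
    arr = np.asarray(Image.open(Path(path)))
    if arr.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth: {arr.dtype} (expected 8-bit)")
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask((arr > 127).astype(np.uint8), scale=scale)
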