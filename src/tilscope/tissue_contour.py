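"""Deterministic tissue-region segmentation of low-resolution thumbnails.

The stage runs two parallel channels on a 2.5x-equivalent thumbnail and
intersects them:

* edge channel — grayscale -> Roberts cross gradient magnitude -> Otsu
  binarisation -> 3x iterated morphological closing with the 3x3 disc
  (the 5-pixel cross);
* colour channel — HSV gate keeping pink/purple H&E hues
  (H 18-180 on the 0-180 half-degree scale, S 9-255, V 0-255), followed
  by a radius-4 (9x9) median filter.

The logical AND of the two channels is the tissue mask; outer contours of
its connected components are exported as polygons in source coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure as skmeasure
from skimage import transform as sktransform

from .io_annotations import AnnotationSet, BinaryMask, RasterImage

__all__ = [
    "ContourConfig",
    "make_thumbnail",
    "to_grayscale",
    "roberts_edges",
    "otsu_threshold",
    "close_mask",
    "hsv_tissue_gate",
    "segment_tissue",
]

# 3x3 "circular" structuring element: the discrete disc of radius 1,
# i.e. the 5-pixel cross.
CROSS_3X3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ContourConfig:
    target_magnification: float = 2.5
    close_iterations: int = 3
    hsv_low: tuple[float, float, float] = (18.0, 9.0, 0.0)
    hsv_high: tuple[float, float, float] = (180.0, 255.0, 255.0)
    median_radius: int = 4
    min_area: int = 0  # small-fragment suppression, off by default
    structuring_element: np.ndarray = field(default_factory=lambda: CROSS_3X3.copy())

    def __post_init__(self):
        if any(lo > hi for lo, hi in zip(self.hsv_low, self.hsv_high)):
            raise ValueError("hsv_low must be <= hsv_high componentwise")
        if self.close_iterations < 1 or self.median_radius < 1:
            raise ValueError("iterations and radius must be >= 1")


def make_thumbnail(image: RasterImage, cfg: ContourConfig | None = None,
                   factor: float | None = None) -> tuple[RasterImage, float]:
    """Downsample to the target magnification by area averaging.

    Returns the thumbnail and the scale factor (source px per thumbnail px).
    The factor is magnification / target (e.g. 20x -> 2.5x gives 8), or an
    explicit `factor` when the image carries no magnification.
    """
    cfg = cfg or ContourConfig()
    if factor is None:
        if image.magnification is None:
            raise ValueError("image has no magnification; pass an explicit factor")
        factor = image.magnification / cfg.target_magnification
    if factor < 1:
        raise ValueError("cannot upsample to the target magnification")
    if factor == 1:
        return RasterImage(image.pixels.copy(), mpp=image.mpp,
                           magnification=image.magnification), 1.0
    h, w = image.shape
    th, tw = max(int(round(h / factor)), 1), max(int(round(w / factor)), 1)
    thumb = sktransform.resize(image.pixels.astype(np.float64), (th, tw),
                               order=1, anti_aliasing=True)
    thumb = np.clip(np.round(thumb), 0, 255).astype(np.uint8)
    mpp = image.mpp * factor if image.mpp else None
    return RasterImage(thumb, mpp=mpp, magnification=cfg.target_magnification), float(factor)


def to_grayscale(image: RasterImage) -> np.ndarray:
    """Luma grayscale (ITU-R 601 weights), 8-bit."""
    px = image.pixels.astype(np.float64)
    gray = 0.299 * px[:, :, 0] + 0.587 * px[:, :, 1] + 0.114 * px[:, :, 2]
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def roberts_edges(gray: np.ndarray) -> np.ndarray:
    """Roberts cross gradient magnitude (L2 of the two 2x2 responses).

    Response at (r, c) uses the 2x2 window anchored there; the last row and
    column (incomplete windows) respond zero.  Clipped to [0, 255].
    """
    if gray.ndim != 2:
        raise ValueError("roberts_edges expects a single-channel image")
    g = gray.astype(np.float64)
    d1 = np.zeros_like(g)
    d2 = np.zeros_like(g)
    d1[:-1, :-1] = g[:-1, :-1] - g[1:, 1:]
    d2[:-1, :-1] = g[:-1, 1:] - g[1:, :-1]
    mag = np.sqrt(d1 * d1 + d2 * d2)
    return np.clip(np.round(mag), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> tuple[int, BinaryMask]:
    """Otsu's threshold over the 256-bin histogram; mask = (pixel > t).

    The returned threshold maximises the between-class variance; ties are
    broken toward the smallest threshold.
    """
    if gray.ndim != 2:
        raise ValueError("otsu_threshold expects a single-channel image")
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    total = hist.sum()
    p = hist / total
    omega = np.cumsum(p)                       # class-0 weight for t = 0..255
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    t = int(np.argmax(sigma_b))
    return t, BinaryMask((gray > t).astype(np.uint8))


def close_mask(mask: BinaryMask, cfg: ContourConfig | None = None) -> BinaryMask:
    """Iterated morphological closing: n dilations then n erosions with the
    3x3 cross.  Extensive (output superset of input) and monotone."""
    cfg = cfg or ContourConfig()
    n = cfg.close_iterations
    se = cfg.structuring_element
    # pad so the dilation can expand past the frame before eroding back;
    # this realises the closing on the infinite grid, which is extensive
    g = np.pad(mask.grid.astype(bool), 2 * n)
    d = ndimage.binary_dilation(g, structure=se, iterations=n)
    e = ndimage.binary_erosion(d, structure=se, iterations=n)
    out = e[2 * n:-2 * n, 2 * n:-2 * n]
    return BinaryMask(out.astype(np.uint8), scale=mask.scale)


def rgb_to_hsv_cv(pixels: np.ndarray) -> np.ndarray:
    """RGB -> HSV with H on the 0-180 half-degree scale, S and V on 0-255."""
    hsv = skcolor.rgb2hsv(pixels)
    out = np.empty_like(hsv)
    out[:, :, 0] = hsv[:, :, 0] * 180.0
    out[:, :, 1] = hsv[:, :, 1] * 255.0
    out[:, :, 2] = hsv[:, :, 2] * 255.0
    return out


def hsv_tissue_gate(image: RasterImage, cfg: ContourConfig | None = None) -> BinaryMask:
    """Componentwise HSV range gate followed by a radius-4 median filter."""
    cfg = cfg or ContourConfig()
    hsv = rgb_to_hsv_cv(image.pixels)
    lo = np.asarray(cfg.hsv_low)
    hi = np.asarray(cfg.hsv_high)
    gate = ((hsv >= lo) & (hsv <= hi)).all(axis=2).astype(np.uint8)
    k = 2 * cfg.median_radius + 1
    gate = ndimage.median_filter(gate, size=k, mode="nearest")
    return BinaryMask(gate)


def _outer_contours(mask: np.ndarray, scale: float) -> list[np.ndarray]:
    """One outer polygon per connected component, in source coordinates."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    polys = []
    for i in range(1, n + 1):
        comp = ndimage.binary_fill_holes(labels == i)
        padded = np.pad(comp.astype(float), 1)
        contours = skmeasure.find_contours(padded, 0.5)
        if not contours:
            continue
        c = max(contours, key=len) - 1.0  # undo pad; rows, cols
        verts = np.column_stack([c[:, 1], c[:, 0]]) * scale  # (x, y)
        verts = np.clip(verts, 0, None)
        if len(verts) >= 3:
            polys.append(verts)
    return polys


def segment_tissue(image: RasterImage, cfg: ContourConfig | None = None,
                   factor: float | None = None
                   ) -> tuple[BinaryMask, AnnotationSet]:
    """Full tissue-contour stage: edge channel AND colour channel.

    Returns the thumbnail-resolution mask (scale recorded) and the outer
    contour polygons of its components, upscaled to source coordinates.
    """
    cfg = cfg or ContourConfig()
    thumb, scale = make_thumbnail(image, cfg, factor=factor)
    gray = to_grayscale(thumb)
    edges = roberts_edges(gray)
    try:
        _, edge_mask = otsu_threshold(edges)
    except ValueError:  # perfectly flat thumbnail: no edges at all
        edge_mask = BinaryMask(np.zeros(thumb.shape, dtype=np.uint8))
    closed = close_mask(edge_mask, cfg)
    gate = hsv_tissue_gate(thumb, cfg)
    grid = closed.grid & gate.grid
    if cfg.min_area > 0:
        labels, n = ndimage.label(grid, structure=np.ones((3, 3)))
        sizes = np.bincount(labels.ravel())
        keep = sizes >= cfg.min_area
        keep[0] = False
        grid = keep[labels].astype(np.uint8)
    if not grid.any():
        warnings.warn("tissue segmentation produced an empty mask")
    mask = BinaryMask(grid, scale=scale)
    polys = _outer_contours(grid, scale)
    ann = AnnotationSet(polygons=[("tissue", p) for p in polys])
    return mask, ann
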