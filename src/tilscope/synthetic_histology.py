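"""Seeded synthetic H&E-like scenes with exact ground truth.

Scenes emulate the ingredients a desk-scale histology pipeline needs:
a near-white glass background, pink stromal tissue with visible texture,
darker purple tumor-parenchyma blobs with stronger nuclear texture, and
small dark-blue near-circular lymphocytes scattered through the stroma at
a controllable density.  Every scene carries its exact truth (tissue mask,
parenchyma mask, lymphocyte centers), so segmentation and detection stages
can be scored without any external slides.

The module also implements the preprocessing recipe used around those
scenes: Gaussian/median denoising, the flip/rotate/crop/HSV augmentation
family, slide-level train/val/test splitting, and nearest-neighbour
inpainting of masked-out regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import draw as skdraw
from skimage import transform as sktransform

from .io_annotations import BinaryMask, RasterImage

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "AugmentConfig",
    "generate_scene",
    "denoise",
    "augment",
    "split_slides",
    "inpaint_missing",
]

# Base colours (RGB). Stroma is a mid pink, parenchyma a darker purple,
# lymphocytes a dark blue-violet; all chosen to sit inside the HSV tissue
# gate (hue >= 36 deg, saturation >= 9/255) used by the contour stage.
_STROMA_RGB = np.array([231.0, 161.0, 201.0])
_PARENCHYMA_RGB = np.array([152.0, 96.0, 172.0])
_LYMPHOCYTE_RGB = np.array([48.0, 44.0, 118.0])
_STROMA_NOISE_SD = 26.0
_PARENCHYMA_NOISE_SD = 31.0
_BACKGROUND_RANGE = (245, 255)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    lymphocyte_density is the expected number of cells per mm^2 of stroma;
    tumor_fraction is the target fraction of tissue covered by parenchyma;
    tissue_fraction the target fraction of the frame covered by tissue.
    stain_fade in [0, 1] blends the stains toward white (faded sections).
    """

    width: int = 256
    height: int = 256
    n_tissue_blobs: int = 2
    tissue_fraction: float = 0.5
    tumor_fraction: float = 0.35
    lymphocyte_density: float = 300.0
    mpp: float = 2.0
    magnification: float = 2.5
    stain_fade: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8x8 pixels")
        if self.n_tissue_blobs < 0 or self.lymphocyte_density < 0:
            raise ValueError("counts and densities must be >= 0")
        for name in ("tissue_fraction", "tumor_fraction", "stain_fade"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tumor_fraction > 0.95:
            raise ValueError(
                "tumor_fraction > 0.95 leaves no stroma to host lymphocytes"
            )
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")


@dataclass
class SyntheticScene:
    image: RasterImage
    tissue_truth: BinaryMask
    parenchyma_truth: BinaryMask
    lymphocyte_truth: list[tuple[float, float]]
    density_realized: float
    lymphocyte_radii: list[float] | None = None
    spec: SceneSpec | None = None

    def __post_init__(self):
        t, p = self.tissue_truth.grid, self.parenchyma_truth.grid
        if (p & ~t).any():
            raise ValueError("parenchyma truth must be a subset of tissue truth")
        for x, y in self.lymphocyte_truth:
            r, c = int(y), int(x)
            if not (t[r, c] == 1 and p[r, c] == 0):
                raise ValueError("lymphocyte center outside stroma")

    @property
    def stroma_truth(self) -> BinaryMask:
        return BinaryMask(self.tissue_truth.grid & (1 - self.parenchyma_truth.grid))


def _blob_mask(shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray,
               wobble: np.ndarray) -> np.ndarray:
    """Union of star-convex blobs: r(theta) = R * (1 + sum_k a_k cos(k theta + phi_k))."""
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    theta = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
    for (cy, cx), r0, (amps, phases) in zip(centers, radii, wobble):
        r = r0 * (1.0 + sum(a * np.cos((k + 2) * theta + p)
                            for k, (a, p) in enumerate(zip(amps, phases))))
        r = np.clip(r, 1.0, None)
        rr, cc = skdraw.polygon(cy + r * np.sin(theta), cx + r * np.cos(theta),
                                shape=(h, w))
        mask[rr, cc] = 1
    return mask


def _fit_fraction(shape, centers, base_radii, wobble, target: float,
                  within: np.ndarray | None = None) -> np.ndarray:
    """Binary-search a global radius multiplier so the blob-union area hits
    `target` (fraction of the frame, or of `within` when given)."""
    denom = within.sum() if within is not None else shape[0] * shape[1]
    if target <= 0 or denom == 0:
        return np.zeros(shape, dtype=np.uint8)
    lo, hi = 0.05, 8.0
    best = None
    for _ in range(22):
        mid = 0.5 * (lo + hi)
        m = _blob_mask(shape, centers, base_radii * mid, wobble)
        if within is not None:
            m = m & within
        frac = m.sum() / denom
        best = m
        if frac < target:
            lo = mid
        else:
            hi = mid
    return best


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene deterministically from ``spec.seed``.

    The realized lymphocyte count is Poisson with mean
    density x stromal area (mm^2); centers are uniform over stroma.
    """
    h, w = spec.height, spec.width
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_geom, rng_tex, rng_par, rng_lym, rng_bg = (
        np.random.default_rng(s) for s in streams
    )

    # --- geometry: tissue blobs scaled to the target frame fraction
    n_blobs = max(spec.n_tissue_blobs, 0)
    if n_blobs and spec.tissue_fraction > 0:
        margin = 0.12 * min(h, w)
        centers = np.column_stack([
            rng_geom.uniform(margin, h - margin, n_blobs),
            rng_geom.uniform(margin, w - margin, n_blobs),
        ])
        base_radii = rng_geom.uniform(0.6, 1.0, n_blobs) * min(h, w) * 0.25
        wobble = [(rng_geom.uniform(0.03, 0.10, 3), rng_geom.uniform(0, 2 * np.pi, 3))
                  for _ in range(n_blobs)]
        tissue = _fit_fraction((h, w), centers, base_radii, wobble,
                               spec.tissue_fraction)
    else:
        tissue = np.zeros((h, w), dtype=np.uint8)

    # --- parenchyma blobs inside tissue, scaled to tumor_fraction of tissue
    if tissue.any() and spec.tumor_fraction > 0:
        ys, xs = np.nonzero(tissue)
        k = max(1, n_blobs * 2)
        pick = rng_par.integers(0, len(ys), k)
        pcenters = np.column_stack([ys[pick], xs[pick]]).astype(float)
        pradii = rng_par.uniform(0.4, 0.8, k) * min(h, w) * 0.18
        pwobble = [(rng_par.uniform(0.05, 0.14, 3), rng_par.uniform(0, 2 * np.pi, 3))
                   for _ in range(k)]
        parenchyma = _fit_fraction((h, w), pcenters, pradii, pwobble,
                                   spec.tumor_fraction, within=tissue)
    else:
        parenchyma = np.zeros((h, w), dtype=np.uint8)
    stroma = tissue & (1 - parenchyma)

    # --- lymphocytes: Poisson count over stromal area
    px_area_mm2 = (spec.mpp / 1000.0) ** 2
    stroma_mm2 = stroma.sum() * px_area_mm2
    centers_xy: list[tuple[float, float]] = []
    if spec.lymphocyte_density > 0 and stroma_mm2 > 0:
        n_cells = int(rng_lym.poisson(spec.lymphocyte_density * stroma_mm2))
        if n_cells:
            ys, xs = np.nonzero(stroma)
            pick = rng_lym.integers(0, len(ys), n_cells)
            jitter = rng_lym.uniform(0.0, 1.0, (n_cells, 2))
            for (r, c), (jy, jx) in zip(zip(ys[pick], xs[pick]), jitter):
                centers_xy.append((float(c) + jx * 0.999, float(r) + jy * 0.999))
    density_realized = len(centers_xy) / stroma_mm2 if stroma_mm2 > 0 else 0.0

    # --- render
    # glass is optically flat: one near-white level per scene with faint
    # sensor noise, against strongly textured stained tissue
    img = np.empty((h, w, 3))
    img[:] = float(rng_bg.integers(_BACKGROUND_RANGE[0], _BACKGROUND_RANGE[1] + 1))
    img[tissue == 1] = _STROMA_RGB
    img[parenchyma == 1] = _PARENCHYMA_RGB
    noise = rng_tex.normal(0.0, 1.0, (h, w, 3))
    sd = np.where(parenchyma[:, :, None] == 1, _PARENCHYMA_NOISE_SD,
                  np.where(tissue[:, :, None] == 1, _STROMA_NOISE_SD, 0.8))
    img += noise * sd

    yy, xx = np.mgrid[0:h, 0:w]
    radii_px: list[float] = []
    for x, y in centers_xy:
        diam_um = rng_lym.uniform(6.0, 10.0)
        rad_px = max(0.5 * diam_um / spec.mpp, 1.2)
        radii_px.append(rad_px)
        r0, r1 = max(int(y - rad_px) - 1, 0), min(int(y + rad_px) + 2, h)
        c0, c1 = max(int(x - rad_px) - 1, 0), min(int(x + rad_px) + 2, w)
        d2 = (yy[r0:r1, c0:c1] + 0.5 - y) ** 2 + (xx[r0:r1, c0:c1] + 0.5 - x) ** 2
        disc = d2 <= rad_px ** 2
        img[r0:r1, c0:c1][disc] = _LYMPHOCYTE_RGB + rng_lym.normal(0, 6, 3)

    if spec.stain_fade > 0:
        img = img * (1.0 - 0.6 * spec.stain_fade) + 255.0 * 0.6 * spec.stain_fade
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return SyntheticScene(
        image=RasterImage(img, mpp=spec.mpp, magnification=spec.magnification),
        tissue_truth=BinaryMask(tissue),
        parenchyma_truth=BinaryMask(parenchyma),
        lymphocyte_truth=centers_xy,
        density_realized=density_realized,
        lymphocyte_radii=radii_px,
        spec=replace(spec),
    )


def denoise(image: RasterImage, method: str = "gaussian", radius: int = 1) -> RasterImage:
    """Channelwise Gaussian (sigma = radius) or median ((2r+1) window) filter."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    px = image.pixels.astype(np.float64)
    if method == "gaussian":
        out = np.stack([ndimage.gaussian_filter(px[:, :, c], sigma=radius,
                                                mode="nearest")
                        for c in range(3)], axis=-1)
    elif method == "median":
        out = np.stack([ndimage.median_filter(image.pixels[:, :, c],
                                              size=2 * radius + 1, mode="nearest")
                        for c in range(3)], axis=-1)
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return RasterImage(np.clip(np.round(out), 0, 255).astype(np.uint8),
                       mpp=image.mpp, magnification=image.magnification)


@dataclass
class AugmentConfig:
    """Flip/rotate/crop/HSV-jitter recipe.

    Hue jitter is a fraction of the full hue circle; saturation and value
    jitters are multiplicative half-ranges (e.g. 0.15 means factors drawn
    uniformly from [0.85, 1.15]).  Crop area fraction is drawn uniformly in
    crop_range and the crop is resized back to the input shape.
    """

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rot90: float = 0.5
    crop_range: tuple[float, float] = (0.85, 1.00)
    hue_jitter: float = 0.10
    sat_jitter: float = 0.15
    val_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("p_hflip", "p_vflip", "p_rot90"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.crop_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_range must satisfy 0 < lo <= hi <= 1")


def draw_augment_params(cfg: "AugmentConfig") -> dict:
    """One seeded draw of all augmentation parameters.

    Exposed so the sampled values (e.g. the crop-area fraction) can be
    audited; ``augment`` consumes exactly this draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    return {
        "hflip": bool(rng.uniform() < cfg.p_hflip),
        "vflip": bool(rng.uniform() < cfg.p_vflip),
        "k_rot": int(rng.integers(1, 4)) if rng.uniform() < cfg.p_rot90 else 0,
        "crop_area": float(rng.uniform(cfg.crop_range[0], cfg.crop_range[1])),
        "hue_shift": float(rng.uniform(-cfg.hue_jitter, cfg.hue_jitter)),
        "sat_factor": 1.0 + float(rng.uniform(-cfg.sat_jitter, cfg.sat_jitter)),
        "val_factor": 1.0 + float(rng.uniform(-cfg.val_jitter, cfg.val_jitter)),
        "_rng": rng,
    }


def _apply_geometry(arr: np.ndarray, hflip: bool, vflip: bool,
                    k_rot: int) -> np.ndarray:
    if hflip:
        arr = arr[:, ::-1]
    if vflip:
        arr = arr[::-1, :]
    if k_rot:
        arr = np.rot90(arr, k_rot)
    return arr


def augment(image: RasterImage, masks: list[BinaryMask],
            points: np.ndarray, cfg: AugmentConfig
            ) -> tuple[RasterImage, list[BinaryMask], np.ndarray]:
    """Apply one seeded augmentation draw identically to image, masks and
    (x, y) points.  Points whose centers leave the crop window are dropped;
    all others are mapped analytically."""
    h, w = image.shape
    px = image.pixels
    grids = [m.grid for m in masks]
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2).copy()

    draw = draw_augment_params(cfg)
    rng = draw.pop("_rng")
    hflip, vflip, k_rot = draw["hflip"], draw["vflip"], draw["k_rot"]
    area = draw["crop_area"]
    hue_d, sat_f, val_f = draw["hue_shift"], draw["sat_factor"], draw["val_factor"]

    # geometric flips / rotations (points follow analytically)
    px = _apply_geometry(px, hflip, vflip, k_rot)
    grids = [_apply_geometry(g, hflip, vflip, k_rot) for g in grids]
    if hflip:
        pts[:, 0] = w - pts[:, 0]
    if vflip:
        pts[:, 1] = h - pts[:, 1]
    for _ in range(k_rot):  # rot90 CCW on arrays: (x, y) -> (y, W - x); frame swaps
        pts = np.column_stack([pts[:, 1], w - pts[:, 0]])
        h, w = w, h

    # crop + resize back
    if area < 1.0:
        side = np.sqrt(area)
        ch, cw = max(int(round(h * side)), 1), max(int(round(w * side)), 1)
        if ch < 2 or cw < 2:
            raise ValueError("crop would drop below 2x2 pixels")
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        keep = ((pts[:, 0] >= c0) & (pts[:, 0] < c0 + cw) &
                (pts[:, 1] >= r0) & (pts[:, 1] < r0 + ch))
        pts = pts[keep]
        pts[:, 0] = (pts[:, 0] - c0) * (w / cw)
        pts[:, 1] = (pts[:, 1] - r0) * (h / ch)
        px = sktransform.resize(px[r0:r0 + ch, c0:c0 + cw].astype(np.float64),
                                (h, w), order=1, anti_aliasing=False)
        px = np.clip(np.round(px), 0, 255).astype(np.uint8)
        grids = [sktransform.resize(g[r0:r0 + ch, c0:c0 + cw], (h, w), order=0,
                                    preserve_range=True,
                                    anti_aliasing=False).astype(np.uint8)
                 for g in grids]

    # HSV jitter
    if hue_d != 0.0 or sat_f != 1.0 or val_f != 1.0:
        hsv = skcolor.rgb2hsv(px)
        hsv[:, :, 0] = (hsv[:, :, 0] + hue_d) % 1.0
        hsv[:, :, 1] = np.clip(hsv[:, :, 1] * sat_f, 0, 1)
        hsv[:, :, 2] = np.clip(hsv[:, :, 2] * val_f, 0, 1)
        px = np.clip(np.round(skcolor.hsv2rgb(hsv) * 255), 0, 255).astype(np.uint8)

    out_img = RasterImage(px, mpp=image.mpp, magnification=image.magnification)
    out_masks = [BinaryMask(g, scale=m.scale) for g, m in zip(grids, masks)]
    return out_img, out_masks, pts


def split_slides(slide_ids: list, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 seed: int = 0) -> tuple[list, list, list]:
    """Slide-level shuffle split.  Validation and test sizes are the rounded
    targets (at least 1 each); the remainder goes to training."""
    ids = list(slide_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate slide ids")
    if len(ids) < 3:
        raise ValueError("need at least 3 slide ids")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    n_val = max(1, int(np.floor(n * fractions[1] + 0.5)))
    n_test = max(1, int(np.floor(n * fractions[2] + 0.5)))
    if n_val + n_test >= n:
        raise ValueError("fractions leave no training slides")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    train = shuffled[: n - n_val - n_test]
    val = shuffled[n - n_val - n_test: n - n_test]
    test = shuffled[n - n_test:]
    return train, val, test


def inpaint_missing(image: RasterImage, missing: BinaryMask) -> RasterImage:
    """Fill missing pixels with their nearest valid neighbour's value."""
    if missing.grid.shape != image.shape:
        raise ValueError("mask shape must match image")
    if not missing.grid.any():
        return RasterImage(image.pixels.copy(), mpp=image.mpp,
                           magnification=image.magnification)
    _, (ir, ic) = ndimage.distance_transform_edt(missing.grid == 1,
                                                 return_indices=True)
    filled = image.pixels[ir, ic]
    return RasterImage(filled, mpp=image.mpp, magnification=image.magnification)
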