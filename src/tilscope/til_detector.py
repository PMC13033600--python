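"""Compact single-stage anchor-based lymphocyte detector.

A small convolutional backbone feeds a feature pyramid with top-down and
bottom-up aggregation; decoupled classification and regression heads
predict at three scales (P3-P5, strides 8/16/32) from per-scale anchor
priors sized to lymphocyte diameters.  Training composes binary
cross-entropy for the classification branch, binary cross-entropy for the
objectness branch, and Complete-IoU loss for box regression:

    L_CIoU = 1 - IoU + rho^2(b, b_gt) / c^2 + alpha * v

with v the aspect-consistency term (4/pi^2)(arctan(w_gt/h_gt) -
arctan(w/h))^2 and alpha = v / ((1 - IoU) + v).  Post-processing applies a
confidence threshold, greedy non-maximum suppression, and stromal gating
(boxes whose center falls outside the stroma mask are discarded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .eval_metrics import ConfusionCounts, box_iou, confusion_metrics
from .io_annotations import BinaryMask, RasterImage
from .nn import Tensor, concat, xarctan, xclip, xlog, xmaximum, xminimum

__all__ = [
    "DetectionBox",
    "CIoUTerms",
    "DetTrainConfig",
    "ciou_loss",
    "nms",
    "build_detector",
    "Detector",
    "assign_targets",
    "detection_loss",
    "train_detector",
    "detect_tils",
    "lymphocyte_boxes",
]


@dataclass
class DetectionBox:
    """Axis-aligned half-open box with confidence, for one candidate cell."""

    x0: float
    y0: float
    x1: float
    y1: float
    confidence: float
    cls: str = "lymphocyte"

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("box must have positive extent")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must lie in (0, 1)")

    @property
    def box(self):
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def center(self):
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))


@dataclass
class CIoUTerms:
    iou: float
    rho2: float
    c2: float
    v: float
    alpha_ciou: float


# Anchor priors sized to lymphocyte diameters (6-12 um) over the
# magnifications the detector is run at (mpp 0.25-1.0, i.e. 10x-40x):
# P3/P4 carry the cell-sized priors; P5 priors cover only large
# aggregates so that isolated cells never assign there.
_DEF_ANCHORS = (
    ((8.0, 8.0), (12.0, 12.0), (16.0, 16.0)),       # P3, stride 8
    ((20.0, 20.0), (28.0, 28.0), (38.0, 38.0)),     # P4, stride 16
    ((84.0, 84.0), (108.0, 108.0), (136.0, 136.0)),  # P5, stride 32
)
_STRIDES = (8, 16, 32)


@dataclass
class DetTrainConfig:
    input_size: int = 640
    batch_size: int = 8
    lr0: float = 1e-2
    weight_decay: float = 5e-4
    momentum: float = 0.937
    max_epochs: int = 250
    t_max: int | None = None  # cosine period; defaults to max_epochs
    anchors: tuple = _DEF_ANCHORS
    conf_threshold: float = 0.25
    nms_iou: float = 0.45
    base_channels: int = 8
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 5.0)  # cls, obj, box
    obj_pos_weight: float = 32.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.conf_threshold < 1.0 and 0.0 < self.nms_iou < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        for scale in self.anchors:
            for aw, ah in scale:
                if aw <= 0 or ah <= 0:
                    raise ValueError("anchors must be positive")

    @property
    def effective_t_max(self) -> int:
        return self.t_max if self.t_max is not None else self.max_epochs


# --------------------------------------------------------------------------
# CIoU and NMS
# --------------------------------------------------------------------------

def _ciou_core(px0, py0, px1, py1, gx0, gy0, gx1, gy1):
    """Batched/scalar CIoU; works on numbers, arrays or Tensors."""
    pw, ph = px1 - px0, py1 - py0
    gw, gh = gx1 - gx0, gy1 - gy0
    iw = xmaximum(xminimum(px1, gx1) - xmaximum(px0, gx0), 0.0)
    ih = xmaximum(xminimum(py1, gy1) - xmaximum(py0, gy0), 0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    iou = inter / union
    rho2 = ((px0 + px1 - gx0 - gx1) * 0.5) ** 2 + ((py0 + py1 - gy0 - gy1) * 0.5) ** 2
    ew = xmaximum(px1, gx1) - xminimum(px0, gx0)
    eh = xmaximum(py1, gy1) - xminimum(py0, gy0)
    c2 = ew * ew + eh * eh
    v = (4.0 / math.pi ** 2) * (xarctan(gw / gh) - xarctan(pw / ph)) ** 2
    if isinstance(v, Tensor):  # alpha is treated as a constant weight
        iou_v, v_v = iou.data, v.data
        alpha = v_v / ((1.0 - iou_v) + v_v + 1e-12)
    else:
        alpha = v / ((1.0 - iou) + v) if (1.0 - iou) + v > 0 else 0.0
    loss = 1.0 - iou + rho2 / c2 + alpha * v
    return loss, iou, rho2, c2, v, alpha


def ciou_loss(pred, gt) -> tuple[float, CIoUTerms]:
    """Complete-IoU loss between two boxes, with the audit terms."""
    pb = pred.box if isinstance(pred, DetectionBox) else tuple(pred)
    gb = gt.box if isinstance(gt, DetectionBox) else tuple(gt)
    for b in (pb, gb):
        if b[2] - b[0] <= 0 or b[3] - b[1] <= 0:
            raise ValueError(f"degenerate (zero-area) box: {b}")
    loss, iou, rho2, c2, v, alpha = _ciou_core(*pb, *gb)
    return float(loss), CIoUTerms(iou=float(iou), rho2=float(rho2),
                                  c2=float(c2), v=float(v),
                                  alpha_ciou=float(alpha))


def nms(boxes: list[DetectionBox], iou_threshold: float) -> list[DetectionBox]:
    """Greedy NMS: sort by confidence descending (ties by earlier index),
    keep, suppress any remaining box with IoU >= threshold vs a kept box."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept: list[int] = []
    for i in order:
        if all(box_iou(boxes[i].box, boxes[j].box) < iou_threshold for j in kept):
            kept.append(i)
    return [boxes[i] for i in kept]


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

class _CBR(nn.Module):
    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class _Head(nn.Module):
    """Decoupled per-scale head: separate classification and regression
    branches; objectness comes off the regression branch."""

    def __init__(self, cin, n_anchors, rng=None):
        self.cls_stem = _CBR(cin, cin, 3, rng=rng)
        self.reg_stem = _CBR(cin, cin, 3, rng=rng)
        self.cls_out = nn.Conv2d(cin, n_anchors, 1, rng=rng)
        self.reg_out = nn.Conv2d(cin, n_anchors * 4, 1, rng=rng)
        self.obj_out = nn.Conv2d(cin, n_anchors, 1, rng=rng)

    def __call__(self, x):
        c = self.cls_stem(x)
        r = self.reg_stem(x)
        return self.reg_out(r), self.obj_out(r), self.cls_out(c)


class Detector(nn.Module):
    """Compact backbone + FPN/PAN neck + decoupled heads at strides 8/16/32."""

    def __init__(self, cfg: DetTrainConfig):
        self.cfg = cfg
        w = cfg.base_channels
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        n = 4 * w
        self.stem = _CBR(3, w, 3, rng=rng)
        self.down1 = _CBR(w, 2 * w, 3, stride=2, rng=rng)       # /2
        self.down2 = _CBR(2 * w, 3 * w, 3, stride=2, rng=rng)   # /4
        self.down3 = _CBR(3 * w, 4 * w, 3, stride=2, rng=rng)   # /8  -> C3
        self.block3 = _CBR(4 * w, 4 * w, 3, rng=rng)
        self.down4 = _CBR(4 * w, 6 * w, 3, stride=2, rng=rng)   # /16 -> C4
        self.block4 = _CBR(6 * w, 6 * w, 3, rng=rng)
        self.down5 = _CBR(6 * w, 8 * w, 3, stride=2, rng=rng)   # /32 -> C5
        self.block5 = _CBR(8 * w, 8 * w, 3, rng=rng)
        # top-down
        self.lat5 = _CBR(8 * w, n, 1, rng=rng)
        self.td4 = _CBR(n + 6 * w, n, 3, rng=rng)
        self.td3 = _CBR(n + 4 * w, n, 3, rng=rng)
        # bottom-up
        self.bu4 = _CBR(n + n, n, 3, rng=rng)
        self.bu5 = _CBR(n + n, n, 3, rng=rng)
        self.heads = [_Head(n, len(a), rng=rng) for a in cfg.anchors]
        self.strides = _STRIDES

    def __call__(self, x: Tensor):
        h = self.stem(x)
        h = self.down1(h)
        h = self.down2(h)
        c3 = self.block3(self.down3(h))
        c4 = self.block4(self.down4(c3))
        c5 = self.block5(self.down5(c4))
        p5 = self.lat5(c5)
        p4 = self.td4(concat([p5.upsample_to(c4.shape[2], c4.shape[3]), c4]))
        p3 = self.td3(concat([p4.upsample_to(c3.shape[2], c3.shape[3]), c3]))
        n3 = p3
        n4 = self.bu4(concat([n3.maxpool2(), p4]))
        n5 = self.bu5(concat([n4.maxpool2(), p5]))
        return [head(f) for head, f in zip(self.heads, (n3, n4, n5))]


def build_detector(cfg: DetTrainConfig | None = None) -> Detector:
    return Detector(cfg or DetTrainConfig())


# --------------------------------------------------------------------------
# target assignment and loss
# --------------------------------------------------------------------------

def assign_targets(gt_boxes, anchors, grid_shapes, strides=_STRIDES,
                   frame_shape=None, ratio_limit: float = 4.0,
                   expand_neighbors: bool = False):
    """Anchor assignment by size ratio at the cell containing the gt center.

    Returns (obj_targets, assignments): obj_targets is a list of (A, H, W)
    arrays per scale; assignments is a list of
    (scale, anchor, gy, gx, gt_box) tuples.  A gt is assigned to every
    anchor whose width and height ratios vs the gt are within
    [1/ratio_limit, ratio_limit]; a gt matching no anchor falls back to
    the single best-ratio anchor so every in-frame gt gets at least one.

    With ``expand_neighbors`` (used during training) the two side cells
    nearest the sub-cell center offset are assigned as additional
    positives with the same box target; the bounded decode lets them
    regress onto the object, so duplicates merge in NMS instead of
    surviving as badly-localised near-misses.
    """
    obj_targets = [np.zeros((len(a), h, w)) for a, (h, w) in zip(anchors, grid_shapes)]
    assignments = []
    for gt in gt_boxes:
        x0, y0, x1, y1 = gt
        gw, gh = x1 - x0, y1 - y0
        cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        if frame_shape is not None:
            fh, fw = frame_shape
            if not (0 <= cx < fw and 0 <= cy < fh):
                warnings.warn(f"ground-truth box centered outside frame skipped: {gt}")
                continue
        matches, best = [], None
        for si, (scale_anchors, stride, (hg, wg)) in enumerate(
                zip(anchors, strides, grid_shapes)):
            gx = min(int(cx // stride), wg - 1)
            gy = min(int(cy // stride), hg - 1)
            for ai, (aw, ah) in enumerate(scale_anchors):
                r = max(aw / gw, gw / aw, ah / gh, gh / ah)
                cand = (si, ai, gy, gx)
                if best is None or r < best[0]:
                    best = (r, cand)
                if r <= ratio_limit:
                    matches.append(cand)
        if not matches:
            matches = [best[1]]
        if expand_neighbors:
            extra = []
            for si, ai, gy, gx in matches:
                stride = strides[si]
                hg, wg = grid_shapes[si]
                fx = cx / stride - gx
                fy = cy / stride - gy
                nx = gx + (1 if fx >= 0.5 else -1)
                ny = gy + (1 if fy >= 0.5 else -1)
                if 0 <= nx < wg:
                    extra.append((si, ai, gy, nx))
                if 0 <= ny < hg:
                    extra.append((si, ai, ny, gx))
            matches = matches + extra
        for si, ai, gy, gx in matches:
            if obj_targets[si][ai, gy, gx] == 1.0:
                continue
            obj_targets[si][ai, gy, gx] = 1.0
            assignments.append((si, ai, gy, gx, tuple(gt)))
    return obj_targets, assignments


def _bce(p, t):
    """Elementwise BCE with clipped probabilities; p Tensor or array."""
    pc = xclip(p, 1e-7, 1.0 - 1e-7)
    return -(t * xlog(pc) + (1.0 - t) * xlog(1.0 - pc))


def _decode_assigned(preds, assignments, anchors, strides):
    """Decode predicted boxes (Tensor, M x 4 as x0 y0 x1 y1) at the
    assigned anchors of a single image's prediction."""
    per_scale = {}
    for m, (si, ai, gy, gx, gt) in enumerate(assignments):
        per_scale.setdefault(si, []).append((m, ai, gy, gx, gt))
    decoded, gts = [], []
    for si, items in sorted(per_scale.items()):
        reg, _, _ = preds[si]
        _, ch, hg, wg = reg.shape
        a = ch // 4
        reg5 = reg.reshape(1, a, 4, hg, wg)
        ms, ais, gys, gxs = (np.array([it[j] for it in items]) for j in range(4))
        idx = (np.zeros(len(items), dtype=int)[:, None],
               ais[:, None], np.arange(4)[None, :], gys[:, None], gxs[:, None])
        t = reg5.gather(idx)  # (M, 4): tx, ty, tw, th
        aw = np.array([anchors[si][ai][0] for ai in ais])
        ah = np.array([anchors[si][ai][1] for ai in ais])
        s = strides[si]
        tx = t.gather((slice(None), np.array([0]))).reshape(-1)
        ty = t.gather((slice(None), np.array([1]))).reshape(-1)
        tw = t.gather((slice(None), np.array([2]))).reshape(-1)
        th = t.gather((slice(None), np.array([3]))).reshape(-1)
        # bounded decode: center offset in (-0.5, 1.5) cells so neighbours
        # can regress onto the object; size in (0, 4) anchor units
        cx = (tx.sigmoid() * 2.0 - 0.5 + gxs) * s
        cy = (ty.sigmoid() * 2.0 - 0.5 + gys) * s
        bw = ((tw.sigmoid() * 2.0) ** 2 * aw).maximum(0.5)
        bh = ((th.sigmoid() * 2.0) ** 2 * ah).maximum(0.5)
        decoded.append((cx - bw * 0.5, cy - bh * 0.5, cx + bw * 0.5, cy + bh * 0.5))
        gts.extend(it[4] for it in items)
    return decoded, gts


def detection_loss(preds, obj_targets, assignments, anchors=_DEF_ANCHORS,
                   strides=_STRIDES, weights=(1.0, 1.0, 1.0),
                   obj_pos_weight: float = 32.0):
    """Composite loss: cls BCE + obj BCE + CIoU, unit weights by default.

    ``preds`` is a single image's per-scale list of (reg, obj, cls) raw
    maps (each (1, ., H, W)); the box term averages over assigned anchors
    only.  Returns (total, cls_bce, obj_bce, box_ciou) as Tensors.
    """
    w_cls, w_obj, w_box = weights
    obj_all, obj_flags, cls_terms = [], [], []
    for si, (reg, obj, cls) in enumerate(preds):
        t = obj_targets[si][None]
        obj_all.append(_bce(obj.sigmoid(), (t == 1.0).astype(float)).reshape(-1))
        obj_flags.append(t.reshape(-1))
        mask = t == 1.0  # single class: cls target equals objectness target
        if mask.sum() > 0:
            sel = np.nonzero(mask.reshape(cls.shape))
            cls_terms.append(_bce(cls.gather(sel).sigmoid(), 1.0).reshape(-1))
    obj_vec = concat(obj_all, axis=0)
    tflags = np.concatenate(obj_flags)
    # positive anchors are rare (a handful among hundreds); weight them up
    # so objectness learns both classes, keeping per-negative pressure
    wv = np.where(tflags == 1.0, float(obj_pos_weight), 1.0)
    obj_bce = (obj_vec * wv).sum() / float(wv.sum())
    cls_bce = (concat(cls_terms, axis=0).mean() if cls_terms
               else Tensor(np.zeros(())))
    if assignments:
        decoded, gts = _decode_assigned(preds, assignments, anchors, strides)
        losses = []
        off = 0
        for (px0, py0, px1, py1) in decoded:
            m = px0.shape[0]
            g = np.asarray(gts[off:off + m], dtype=np.float64)
            loss, *_ = _ciou_core(px0, py0, px1, py1,
                                  g[:, 0], g[:, 1], g[:, 2], g[:, 3])
            losses.append(loss.reshape(-1))
            off += m
        box_ciou = concat(losses, axis=0).mean()
    else:
        box_ciou = Tensor(np.zeros(()))
    total = w_cls * cls_bce + w_obj * obj_bce + w_box * box_ciou
    return total, cls_bce, obj_bce, box_ciou


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _decode_all(preds, anchors, strides, conf_threshold):
    """Numpy decode of every anchor above the confidence threshold."""
    out = []
    for si, (reg, obj, cls) in enumerate(preds):
        reg_d = reg.data if isinstance(reg, Tensor) else reg
        obj_d = obj.data if isinstance(obj, Tensor) else obj
        cls_d = cls.data if isinstance(cls, Tensor) else cls
        _, ch, hg, wg = reg_d.shape
        a = ch // 4
        reg5 = reg_d.reshape(a, 4, hg, wg)
        p_obj = 1.0 / (1.0 + np.exp(-obj_d[0]))
        p_cls = 1.0 / (1.0 + np.exp(-cls_d[0]))
        conf = p_obj * p_cls
        sel = np.nonzero(conf >= conf_threshold)
        s = strides[si]
        for ai, gy, gx in zip(*sel):
            tx, ty, tw, th = reg5[ai, :, gy, gx]
            aw, ah = anchors[si][ai]
            cx = (2.0 / (1.0 + np.exp(-tx)) - 0.5 + gx) * s
            cy = (2.0 / (1.0 + np.exp(-ty)) - 0.5 + gy) * s
            bw = max(aw * (2.0 / (1.0 + np.exp(-tw))) ** 2, 0.5)
            bh = max(ah * (2.0 / (1.0 + np.exp(-th))) ** 2, 0.5)
            c = min(max(float(conf[ai, gy, gx]), 1e-6), 1.0 - 1e-6)
            out.append(DetectionBox(cx - bw / 2, cy - bh / 2,
                                    cx + bw / 2, cy + bh / 2, c))
    return out


def detect_tils(model: Detector, image: RasterImage,
                stroma_mask: BinaryMask | None, cfg: DetTrainConfig | None = None,
                tile: int | None = None, overlap: int = 32) -> list[DetectionBox]:
    """Tiled detection with global NMS and stromal gating.

    Boxes are decoded per tile, shifted to global coordinates, filtered at
    cfg.conf_threshold, merged with one global NMS pass, and finally gated
    by the stroma mask (a box is kept iff its center pixel is stromal)."""
    cfg = cfg or (model.cfg if hasattr(model, "cfg") else DetTrainConfig())
    tile = tile or cfg.input_size
    h, w = image.shape
    img01 = image.pixels.astype(np.float64) / 255.0
    model.set_training(False)
    step = max(tile - overlap, 1)
    raw: list[DetectionBox] = []
    r = 0
    while True:
        r0 = min(r, max(h - tile, 0))
        c = 0
        while True:
            c0 = min(c, max(w - tile, 0))
            patch = img01[r0:r0 + tile, c0:c0 + tile]
            preds = model(Tensor(patch.transpose(2, 0, 1)[None]))
            for b in _decode_all(preds, cfg.anchors, model.strides,
                                 cfg.conf_threshold):
                raw.append(DetectionBox(b.x0 + c0, b.y0 + r0, b.x1 + c0,
                                        b.y1 + r0, b.confidence))
            if c0 + tile >= w:
                break
            c += step
        if r0 + tile >= h:
            break
        r += step
    kept = nms(raw, cfg.nms_iou)
    if stroma_mask is None:
        return kept
    sg, sc = stroma_mask.grid, stroma_mask.scale
    out = []
    for b in kept:
        cx, cy = b.center
        mr = min(int(cy / sc), sg.shape[0] - 1)
        mc = min(int(cx / sc), sg.shape[1] - 1)
        if mr >= 0 and mc >= 0 and sg[mr, mc] == 1:
            out.append(b)
    return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def lymphocyte_boxes(scene) -> list[tuple[float, float, float, float]]:
    """Ground-truth boxes from a synthetic scene: each center dilated to
    the extent of its drawn disc (fallback radius 4 um when unknown)."""
    radii = getattr(scene, "lymphocyte_radii", None)
    mpp = scene.image.mpp or 1.0
    boxes = []
    for i, (x, y) in enumerate(scene.lymphocyte_truth):
        r = radii[i] if radii else max(4.0 / mpp, 1.5)
        boxes.append((x - r, y - r, x + r, y + r))
    return boxes


def train_detector(scenes, cfg: DetTrainConfig | None = None,
                   val_scenes=None, model: Detector | None = None):
    """Train the detector on synthetic scenes; returns (model, history).

    ``scenes`` are SyntheticScene objects or (RasterImage, boxes) pairs.
    SGD with momentum/weight decay and a cosine-annealed learning rate;
    per-epoch validation precision/recall/F1 at IoU 0.5 are recorded and
    the best-F1 checkpoint is restored at the end.
    """
    cfg = cfg or DetTrainConfig()

    def unpack(s):
        if hasattr(s, "image") and hasattr(s, "lymphocyte_truth"):
            return s.image, lymphocyte_boxes(s)
        img, boxes = s
        return img, [tuple(b) for b in boxes]

    data = [unpack(s) for s in scenes]
    if not data:
        raise ValueError("empty training dataset")
    if val_scenes is None:
        n_val = max(1, len(data) * 15 // 100)
        if len(data) <= n_val:
            raise ValueError("not enough scenes to hold out a validation set")
        val, data = data[-n_val:], data[:-n_val]
    else:
        val = [unpack(s) for s in val_scenes]

    if model is None:
        model = build_detector(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)

    def grids_for(shape):
        h, w = shape
        return [((h + s - 1) // s, (w + s - 1) // s) for s in model.strides]

    history = []
    best = {"f1": -1.0, "state": None, "epoch": -1}
    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(cfg.lr0, epoch, cfg.effective_t_max)
        model.set_training(True)
        order = rng.permutation(len(data))
        ep = {"total": [], "cls": [], "obj": [], "box": []}
        for i in order:
            img, boxes = data[i]
            x = Tensor(img.pixels.astype(np.float64).transpose(2, 0, 1)[None] / 255.0)
            preds = model(x)
            grid_shapes = [(p[0].shape[2], p[0].shape[3]) for p in preds]
            obj_t, assigns = assign_targets(boxes, cfg.anchors, grid_shapes,
                                            model.strides, frame_shape=img.shape,
                                            expand_neighbors=True)
            opt.zero_grad()
            total, cls_l, obj_l, box_l = detection_loss(
                preds, obj_t, assigns, cfg.anchors, model.strides,
                cfg.loss_weights, cfg.obj_pos_weight)
            total.backward()
            opt.step()
            ep["total"].append(total.item())
            ep["cls"].append(float(cls_l.data))
            ep["obj"].append(float(obj_l.data))
            ep["box"].append(float(box_l.data))

        tp = fp = fn = 0
        model.set_training(False)
        for img, boxes in val:
            dets = detect_tils(model, img, None, cfg, tile=max(img.shape))
            from .eval_metrics import match_detections
            labels, miss = match_detections(dets, boxes, 0.5)
            tp += sum(labels)
            fp += len(labels) - sum(labels)
            fn += miss
        rep = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn))
        rec = {"epoch": epoch, "lr": opt.lr,
               "train_loss": float(np.mean(ep["total"])),
               "cls_loss": float(np.mean(ep["cls"])),
               "obj_loss": float(np.mean(ep["obj"])),
               "box_loss": float(np.mean(ep["box"])),
               "val_precision": rep.precision, "val_recall": rep.recall,
               "val_f1": rep.f1}
        history.append(rec)
        f1 = rep.f1 if rep.f1 is not None else -1.0
        if f1 > best["f1"]:
            best = {"f1": f1, "epoch": epoch,
                    "state": [a.copy() for a in model.state_arrays()]}
    if best["state"] is not None:
        model.load_state_arrays(best["state"])
    model.set_training(False)
    return model, history
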