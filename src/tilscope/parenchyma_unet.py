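"""Lightweight nested-U tumor-parenchyma segmentation.

The model is the small nested-U configuration (U2-Net-P): six
encoder/decoder stages of residual U-blocks (RSUs) that mix standard and
dilated 3x3 convolutions, each block itself a small U-net with an input
residual, plus one side output per decoder stage fused by a 1x1
convolution into the final sigmoid map.  The default configuration
(mid 16, out 64 channels) has 1.13 M trainable parameters.

Training uses the composite loss

    L_total = alpha * L_WBCE + beta * L_Dice

with a weighted binary cross-entropy (positive-class weight ``w``) and a
smoothed Dice loss (``eps = 1e-6``), AdamW (lr 1e-4, betas 0.9/0.999,
eps 1e-8), cosine-annealed learning rate (T_max 50), and early stopping on
validation Dice (patience 20).  Inference resamples the input to a
5x-objective-equivalent resolution (2.0 um/px), tiles it with overlap,
averages probabilities on the overlaps and thresholds at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .eval_metrics import ConfusionCounts, confusion_metrics, dice_coefficient
from .io_annotations import BinaryMask, RasterImage
from .nn import Tensor, concat, xclip, xlog, xsum

__all__ = [
    "SegLossConfig",
    "SegTrainConfig",
    "SegPrediction",
    "wbce_loss",
    "dice_loss",
    "total_loss",
    "U2NetP",
    "build_u2netp",
    "train_segmenter",
    "predict_parenchyma",
]

# 5x objective magnification corresponds to ~2.0 microns per pixel
TARGET_MPP_5X = 2.0


@dataclass
class SegLossConfig:
    """alpha/beta weight the WBCE and Dice terms; w is the positive-class
    weight inside the WBCE; eps_dice smooths the Dice ratio."""

    alpha: float = 1.0
    beta: float = 1.0
    w: float = 1.0
    eps_dice: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise ValueError("alpha, beta must be >= 0 and not both zero")
        if self.w <= 0 or self.eps_dice <= 0:
            raise ValueError("w and eps_dice must be positive")


@dataclass
class SegTrainConfig:
    patch_size: int = 640
    batch_size: int = 16
    lr0: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    eps_opt: float = 1e-8
    weight_decay: float = 0.0
    t_max: int = 50
    max_epochs: int = 300
    patience: int = 20
    side_loss_weight: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if min(self.patch_size, self.batch_size, self.t_max, self.max_epochs) <= 0:
            raise ValueError("all sizes must be positive")


@dataclass
class SegPrediction:
    prob: np.ndarray
    mask: BinaryMask
    threshold: float = 0.5


_CLIP = 1e-7


def wbce_loss(pred, target, w: float = 1.0):
    """Weighted binary cross-entropy, mean over all pixels.

    Accepts numpy arrays or autodiff Tensors; predictions are clipped to
    [1e-7, 1 - 1e-7] before the logs.
    """
    p = xclip(pred, _CLIP, 1.0 - _CLIP)
    y = target.grid if isinstance(target, BinaryMask) else target
    y = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    n = y.size
    ll = w * y * xlog(p) + (1.0 - y) * xlog(1.0 - p)
    return -(xsum(ll) / float(n))


def dice_loss(pred, target, eps_dice: float = 1e-6):
    """1 - (2 sum(y p) + eps) / (sum(y) + sum(p) + eps)."""
    y = target.grid if isinstance(target, BinaryMask) else target
    y = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    inter = xsum(pred * y)
    denom = xsum(pred) + float(y.sum())
    return 1.0 - (2.0 * inter + eps_dice) / (denom + eps_dice)


def total_loss(pred, target, cfg: SegLossConfig | None = None):
    cfg = cfg or SegLossConfig()
    return (cfg.alpha * wbce_loss(pred, target, cfg.w)
            + cfg.beta * dice_loss(pred, target, cfg.eps_dice))


# --------------------------------------------------------------------------
# architecture
# --------------------------------------------------------------------------

class _REBNCONV(nn.Module):
    """3x3 (possibly dilated) conv + batch norm + ReLU."""

    def __init__(self, cin, cout, dirate=1, rng=None):
        self.conv = nn.Conv2d(cin, cout, 3, dilation=dirate, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class _RSU(nn.Module):
    """Residual U-block of the given height (7, 6, 5 or 4 levels)."""

    def __init__(self, height, cin, mid, cout, rng=None):
        self.height = height
        self.convin = _REBNCONV(cin, cout, 1, rng)
        self.enc = [_REBNCONV(cout, mid, 1, rng)]
        self.enc += [_REBNCONV(mid, mid, 1, rng) for _ in range(height - 2)]
        self.enc.append(_REBNCONV(mid, mid, 2, rng))  # dilated bottom
        self.dec = [_REBNCONV(2 * mid, mid, 1, rng) for _ in range(height - 2)]
        self.dec.append(_REBNCONV(2 * mid, cout, 1, rng))

    def __call__(self, x):
        hxin = self.convin(x)
        feats = [self.enc[0](hxin)]
        h = feats[0]
        for conv in self.enc[1:-1]:
            h = conv(h.maxpool2())
            feats.append(h)
        h = self.enc[-1](feats[-1])  # dilated, same resolution as deepest
        for i, conv in enumerate(self.dec):
            skip = feats[-(i + 1)]
            h = conv(concat([h, skip], axis=1))
            if i < len(self.dec) - 1:
                tgt = feats[-(i + 2)]
                h = h.upsample_to(tgt.shape[2], tgt.shape[3])
        return h + hxin


class _RSU4F(nn.Module):
    """Dilation-only residual U-block (no resolution change)."""

    def __init__(self, cin, mid, cout, rng=None):
        self.convin = _REBNCONV(cin, cout, 1, rng)
        self.conv1 = _REBNCONV(cout, mid, 1, rng)
        self.conv2 = _REBNCONV(mid, mid, 2, rng)
        self.conv3 = _REBNCONV(mid, mid, 4, rng)
        self.conv4 = _REBNCONV(mid, mid, 8, rng)
        self.conv3d = _REBNCONV(2 * mid, mid, 4, rng)
        self.conv2d = _REBNCONV(2 * mid, mid, 2, rng)
        self.conv1d = _REBNCONV(2 * mid, cout, 1, rng)

    def __call__(self, x):
        hxin = self.convin(x)
        h1 = self.conv1(hxin)
        h2 = self.conv2(h1)
        h3 = self.conv3(h2)
        h4 = self.conv4(h3)
        d3 = self.conv3d(concat([h4, h3], axis=1))
        d2 = self.conv2d(concat([d3, h2], axis=1))
        d1 = self.conv1d(concat([d2, h1], axis=1))
        return d1 + hxin


class U2NetP(nn.Module):
    """Six-stage nested-U with side outputs and 1x1 fusion.

    ``attention_fusion`` enables a parameter-free gate that reweights the
    side maps by a softmax over their global mean activations before the
    fusion convolution; it adds no trainable parameters.
    """

    def __init__(self, in_channels=3, out_channels=1, mid_ch=16, out_ch=64,
                 seed=0, attention_fusion=True):
        self.arch = dict(in_channels=in_channels, out_channels=out_channels,
                         mid_ch=mid_ch, out_ch=out_ch, seed=seed,
                         attention_fusion=attention_fusion)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        m, c = mid_ch, out_ch
        self.stage1 = _RSU(7, in_channels, m, c, rng)
        self.stage2 = _RSU(6, c, m, c, rng)
        self.stage3 = _RSU(5, c, m, c, rng)
        self.stage4 = _RSU(4, c, m, c, rng)
        self.stage5 = _RSU4F(c, m, c, rng)
        self.stage6 = _RSU4F(c, m, c, rng)
        self.stage5d = _RSU4F(2 * c, m, c, rng)
        self.stage4d = _RSU(4, 2 * c, m, c, rng)
        self.stage3d = _RSU(5, 2 * c, m, c, rng)
        self.stage2d = _RSU(6, 2 * c, m, c, rng)
        self.stage1d = _RSU(7, 2 * c, m, c, rng)
        self.sides = [nn.Conv2d(c, out_channels, 3, rng=rng) for _ in range(6)]
        self.outconv = nn.Conv2d(6 * out_channels, out_channels, 1, rng=rng)
        self.attention_fusion = attention_fusion

    def __call__(self, x: Tensor):
        """Returns (fused sigmoid map, list of 6 side sigmoid maps)."""
        h, w = x.shape[2], x.shape[3]
        e1 = self.stage1(x)
        e2 = self.stage2(e1.maxpool2())
        e3 = self.stage3(e2.maxpool2())
        e4 = self.stage4(e3.maxpool2())
        e5 = self.stage5(e4.maxpool2())
        e6 = self.stage6(e5.maxpool2())
        d5 = self.stage5d(concat([e6.upsample_to(e5.shape[2], e5.shape[3]), e5]))
        d4 = self.stage4d(concat([d5.upsample_to(e4.shape[2], e4.shape[3]), e4]))
        d3 = self.stage3d(concat([d4.upsample_to(e3.shape[2], e3.shape[3]), e3]))
        d2 = self.stage2d(concat([d3.upsample_to(e2.shape[2], e2.shape[3]), e2]))
        d1 = self.stage1d(concat([d2.upsample_to(e1.shape[2], e1.shape[3]), e1]))
        logits = [side(d).upsample_to(h, w)
                  for side, d in zip(self.sides, (d1, d2, d3, d4, d5, e6))]
        if self.attention_fusion:
            sal = concat([lg.sigmoid().mean().reshape(1) for lg in logits], axis=0)
            gate = (sal - sal.data.max()).exp()
            gate = gate / gate.sum() * 6.0
            logits = [lg * gate.gather((np.array([i]),)).reshape(1, 1, 1, 1)
                      for i, lg in enumerate(logits)]
        fused = self.outconv(concat(logits, axis=1)).sigmoid()
        return fused, [lg.sigmoid() for lg in logits]

    def predict_prob(self, image01: np.ndarray) -> np.ndarray:
        """Forward pass in eval mode on one HxWx3 image in [0, 1]."""
        self.set_training(False)
        x = Tensor(image01.transpose(2, 0, 1)[None])
        fused, _ = self(x)
        self.set_training(True)
        return fused.data[0, 0]


def build_u2netp(in_channels: int = 3, out_channels: int = 1, mid_ch: int = 16,
                 out_ch: int = 64, seed: int = 0,
                 attention_fusion: bool = True) -> U2NetP:
    """Build the nested-U segmenter; the default configuration counts
    1.13 M trainable parameters."""
    return U2NetP(in_channels, out_channels, mid_ch, out_ch, seed,
                  attention_fusion)


# --------------------------------------------------------------------------
# training / inference
# --------------------------------------------------------------------------

def _to_xy(data, patch_size=None):
    """Normalise (image, mask) pairs into float arrays X (N,3,H,W), Y (N,1,H,W)."""
    xs, ys = [], []
    for img, msk in data:
        px = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
        g = msk.grid if isinstance(msk, BinaryMask) else np.asarray(msk)
        xs.append(px.astype(np.float64).transpose(2, 0, 1) / 255.0)
        ys.append(g.astype(np.float64)[None])
    return np.stack(xs), np.stack(ys)


def _supervised_loss(model: U2NetP, xb: np.ndarray, yb: np.ndarray,
                     loss_cfg: SegLossConfig, side_weight: float = 0.25):
    """Composite loss on the fused map plus down-weighted deep supervision
    of the side outputs (coarse sides cannot resolve boundaries, so equal
    weighting drags the fused map toward blur)."""
    fused, sides = model(Tensor(xb))
    loss = total_loss(fused.reshape(-1), yb.reshape(-1), loss_cfg)
    if side_weight > 0:
        side_sum = None
        for s in sides:
            ls = total_loss(s.reshape(-1), yb.reshape(-1), loss_cfg)
            side_sum = ls if side_sum is None else side_sum + ls
        loss = loss + side_weight * (side_sum / float(len(sides)))
    return loss


def train_segmenter(train_data, train_cfg: SegTrainConfig | None = None,
                    loss_cfg: SegLossConfig | None = None,
                    val_data=None, model: U2NetP | None = None):
    """Train a nested-U segmenter; returns (best model, history).

    ``train_data``/``val_data`` are sequences of (image, mask) patch pairs.
    When no validation set is given the last 15% of the training patches
    are held out.  The checkpoint with the best validation Dice (F1 as
    tie-break) is restored before returning.
    """
    cfg = train_cfg or SegTrainConfig()
    loss_cfg = loss_cfg or SegLossConfig()
    data = list(train_data)
    if not data:
        raise ValueError("empty training dataset")
    if val_data is None:
        n_val = max(1, len(data) * 15 // 100)
        if len(data) <= n_val:
            raise ValueError("not enough patches to hold out a validation set")
        val_data, data = data[-n_val:], data[:-n_val]
    x_tr, y_tr = _to_xy(data)
    x_va, y_va = _to_xy(list(val_data))
    if model is None:
        model = build_u2netp(seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    opt = nn.AdamW(model.parameters(), lr=cfg.lr0, betas=cfg.betas,
                   eps=cfg.eps_opt, weight_decay=cfg.weight_decay)

    history = []
    best = {"dice": -1.0, "f1": -1.0, "state": None, "epoch": -1}
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(cfg.lr0, epoch, cfg.t_max)
        model.set_training(True)
        order = rng.permutation(len(x_tr))
        ep_loss = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            loss = _supervised_loss(model, x_tr[idx], y_tr[idx], loss_cfg,
                                    cfg.side_loss_weight)
            loss.backward()
            opt.step()
            ep_loss.append(loss.item())

        # validation metrics at threshold 0.5
        model.set_training(False)
        tp = fp = fn = tn = 0
        dices = []
        for i in range(len(x_va)):
            fused, _ = model(Tensor(x_va[i][None]))
            pred = (fused.data[0, 0] >= 0.5).astype(np.uint8)
            truth = y_va[i][0].astype(np.uint8)
            dices.append(dice_coefficient(pred, truth))
            tp += int(((pred == 1) & (truth == 1)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
        rep = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        val_dice = float(np.mean(dices))
        rec = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(ep_loss)),
               "val_dice": val_dice, "val_precision": rep.precision,
               "val_recall": rep.recall, "val_f1": rep.f1}
        history.append(rec)

        f1 = rep.f1 if rep.f1 is not None else -1.0
        if val_dice > best["dice"] or (val_dice == best["dice"] and f1 > best["f1"]):
            best = {"dice": val_dice, "f1": f1, "epoch": epoch,
                    "state": [a.copy() for a in model.state_arrays()]}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    if best["state"] is not None:
        model.load_state_arrays(best["state"])
    model.set_training(False)
    return model, history


def _resample_factor(image: RasterImage, target_mpp: float) -> float:
    if image.mpp is not None:
        return target_mpp / image.mpp
    if image.magnification is not None:
        # nominal objective power ~ 10 / mpp (20x ~ 0.5 um/px)
        return target_mpp * image.magnification / 10.0
    raise ValueError("image carries neither mpp nor magnification")


def _resize01(arr: np.ndarray, th: int, tw: int) -> np.ndarray:
    from skimage.transform import resize
    return resize(arr, (th, tw), order=1, anti_aliasing=False)


def predict_parenchyma(model: U2NetP, image: RasterImage, tile: int = 640,
                       overlap: int = 64, target_mpp: float = TARGET_MPP_5X,
                       threshold: float = 0.5) -> SegPrediction:
    """Tiled inference at 5x-equivalent resolution.

    The image is resampled by mpp (or magnification) to ``target_mpp``,
    tiled with ``overlap`` pixels of overlap, probabilities are averaged on
    overlaps, thresholded at ``threshold``, and the result is mapped back
    to source resolution with nearest-neighbour interpolation.
    """
    if overlap >= tile:
        raise ValueError("overlap must be smaller than tile")
    h, w = image.shape
    factor = _resample_factor(image, target_mpp)
    ph, pw = max(int(round(h / factor)), 8), max(int(round(w / factor)), 8)
    img01 = _resize01(image.pixels.astype(np.float64) / 255.0, ph, pw)

    step = tile - overlap
    prob = np.zeros((ph, pw))
    count = np.zeros((ph, pw))
    model.set_training(False)
    r = 0
    while True:
        r0 = min(r, max(ph - tile, 0))
        c = 0
        while True:
            c0 = min(c, max(pw - tile, 0))
            patch = img01[r0:r0 + tile, c0:c0 + tile]
            x = Tensor(patch.transpose(2, 0, 1)[None])
            fused, _ = model(x)
            prob[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += fused.data[0, 0]
            count[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += 1.0
            if c0 + tile >= pw:
                break
            c += step
        if r0 + tile >= ph:
            break
        r += step
    prob /= count

    # back to source resolution (nearest)
    idx_r = np.minimum((np.arange(h) * ph) // h, ph - 1)
    idx_c = np.minimum((np.arange(w) * pw) // w, pw - 1)
    prob_src = prob[idx_r][:, idx_c]
    mask = BinaryMask((prob_src >= threshold).astype(np.uint8))
    return SegPrediction(prob=prob_src, mask=mask, threshold=threshold)
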