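"""Desk-scale evaluation protocols on synthetic scenes.

Each protocol generates its own seeded data, runs one pipeline stage end to
end, and returns the measured quantities.  Problem sizes are chosen so the
whole battery runs on one CPU in minutes: thumbnail-scale scenes for the
deterministic tissue stage, 64 px patches and a narrow nested-U for
segmentation training, and 128 px high-magnification (0.5 um/px) scenes
with sparse cells for detector training.  The narrow-model trainings keep
the full architecture topology and training recipe; only widths, patch
sizes and epoch counts are reduced.
"""

from __future__ import annotations

import numpy as np

from .eval_metrics import dice_coefficient, match_detections
from .parenchyma_unet import (SegTrainConfig, build_u2netp, predict_parenchyma,
                              train_segmenter)
from .synthetic_histology import SceneSpec, generate_scene
from .til_detector import DetTrainConfig, detect_tils, lymphocyte_boxes, \
    train_detector
from .tils_quant import fleiss_kappa, icc_absolute
from .tissue_contour import segment_tissue

__all__ = [
    "tissue_dice_protocol",
    "segmenter_recovery_protocol",
    "detector_recovery_protocol",
    "icc_recovery_protocol",
    "fleiss_null_protocol",
]


def tissue_dice_protocol(n_scenes: int = 50, seed: int = 0) -> dict:
    """Deterministic tissue-contour stage vs generator truth."""
    dices = []
    for i in range(n_scenes):
        scene = generate_scene(SceneSpec(width=128, height=128,
                                         seed=seed * 1000 + i))
        mask, _ = segment_tissue(scene.image)
        dices.append(dice_coefficient(mask, scene.tissue_truth))
    return {"mean_dice": float(np.mean(dices)),
            "min_dice": float(np.min(dices)),
            "n_scenes": n_scenes}


def segmenter_recovery_protocol(seed: int = 0, n_train: int = 12,
                                n_test: int = 4, epochs: int = 60) -> dict:
    """Train a narrow nested-U on synthetic patches; Dice on held-out scenes."""
    train = [generate_scene(SceneSpec(width=64, height=64,
                                      seed=seed * 1000 + s,
                                      lymphocyte_density=100))
             for s in range(n_train)]
    test = [generate_scene(SceneSpec(width=64, height=64,
                                     seed=seed * 1000 + 500 + s,
                                     lymphocyte_density=100))
            for s in range(n_test)]
    cfg = SegTrainConfig(patch_size=64, batch_size=4, max_epochs=epochs,
                         patience=epochs - 1, lr0=3e-3, seed=seed)
    model, history = train_segmenter(
        [(s.image, s.parenchyma_truth) for s in train], cfg,
        model=build_u2netp(mid_ch=4, out_ch=8, seed=seed))
    dices = []
    for s in test:
        pred = predict_parenchyma(model, s.image, tile=64, overlap=16)
        dices.append(dice_coefficient(pred.mask, s.parenchyma_truth))
    return {"holdout_dice_mean": float(np.mean(dices)),
            "holdout_dice_min": float(np.min(dices)),
            "best_val_dice": float(max(h["val_dice"] for h in history)),
            "n_train": n_train, "n_test": n_test, "epochs": len(history)}


def detector_recovery_protocol(seed: int = 0, n_train: int = 22,
                               n_test: int = 8, epochs: int = 200) -> dict:
    """Train the compact detector on sparse scenes; recall/precision at
    IoU 0.5 on held-out scenes."""
    def scene(s):
        return generate_scene(SceneSpec(width=128, height=128, seed=s,
                                        mpp=0.5, lymphocyte_density=2000,
                                        tumor_fraction=0.3))

    train = [scene(seed * 1000 + s) for s in range(n_train)]
    test = [scene(seed * 1000 + 500 + s) for s in range(n_test)]
    cfg = DetTrainConfig(input_size=128, base_channels=8, max_epochs=epochs,
                         seed=seed)
    model, history = train_detector(train, cfg)
    tp = fp = fn = 0
    for s in test:
        dets = detect_tils(model, s.image, None, cfg, tile=128)
        labels, miss = match_detections(dets, lymphocyte_boxes(s), 0.5)
        tp += sum(labels)
        fp += len(labels) - sum(labels)
        fn += miss
    recall = tp / max(tp + fn, 1)
    precision = tp / max(tp + fp, 1)
    return {"recall_iou50": float(recall), "precision_iou50": float(precision),
            "tp": tp, "fp": fp, "fn": fn,
            "n_train": n_train, "n_test": n_test}


def icc_recovery_protocol(seed: int = 0, n_subjects: int = 200,
                          sigma_s: float = 20.0, sigma_e: float = 10.0,
                          replicates: int = 5) -> dict:
    """Two-rater ICC(A,1) vs the simulated truth sigma_s^2/(sigma_s^2+sigma_e^2).

    Averaged over independent n=200 panels so the check reflects the
    estimator rather than one panel's sampling noise."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 6)))
    truth = sigma_s ** 2 / (sigma_s ** 2 + sigma_e ** 2)
    estimates = []
    for _ in range(replicates):
        subj = rng.normal(100.0, sigma_s, n_subjects)
        x = np.column_stack([subj + rng.normal(0, sigma_e, n_subjects)
                             for _ in range(2)])
        estimates.append(icc_absolute(x).estimate)
    est = float(np.mean(estimates))
    return {"estimate": est, "truth": truth, "abs_error": abs(est - truth),
            "per_panel": estimates, "n_subjects": n_subjects}


def fleiss_null_protocol(seed: int = 0, n_subjects: int = 500,
                         k_raters: int = 3, n_categories: int = 3) -> dict:
    """Fleiss' kappa under independent uniform rating (should be near 0)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    labels = rng.integers(0, n_categories, (n_subjects, k_raters))
    res = fleiss_kappa(labels, n_boot=200, seed=seed)
    return {"estimate": res.estimate, "n_subjects": n_subjects}
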