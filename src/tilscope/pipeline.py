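"""End-to-end orchestration: tissue -> parenchyma -> detection -> counts.

Stages run in order on one image; every artifact can be written to an
output directory together with a manifest (input hash, config, seed,
package version).  Mask consistency (stroma = tissue AND NOT parenchyma,
all box centers stromal) is asserted on every run, not just under test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io_annotations import (AnnotationSet, BinaryMask, RasterImage,
                             write_annotation_file, write_mask)
from .parenchyma_unet import U2NetP, predict_parenchyma
from .tils_quant import (GradeThresholds, HPFSpec, count_in_fields, grade,
                         stromal_mask)
from .tissue_contour import ContourConfig, segment_tissue
from .til_detector import Detector, DetTrainConfig, detect_tils

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "validate_config",
    "run_pipeline",
    "save_segmenter",
    "load_segmenter",
    "save_detector",
    "load_detector",
]


def save_segmenter(model: U2NetP, path) -> None:
    arrs = model.state_arrays()
    meta = {"kind": "u2netp", "arch": model.arch}
    np.savez_compressed(path, meta=json.dumps(meta),
                        **{f"a{i}": a for i, a in enumerate(arrs)})


def load_segmenter(path) -> U2NetP:
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    model = U2NetP(**meta["arch"])
    n = len([k for k in z.files if k.startswith("a")])
    model.load_state_arrays([z[f"a{i}"] for i in range(n)])
    model.set_training(False)
    return model


def save_detector(model: Detector, path) -> None:
    arrs = model.state_arrays()
    meta = {"kind": "detector", "cfg": asdict(model.cfg)}
    np.savez_compressed(path, meta=json.dumps(meta),
                        **{f"a{i}": a for i, a in enumerate(arrs)})


def load_detector(path) -> Detector:
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    cfg = meta["cfg"]
    cfg["anchors"] = tuple(tuple(tuple(a) for a in s) for s in cfg["anchors"])
    cfg["loss_weights"] = tuple(cfg["loss_weights"])
    model = Detector(DetTrainConfig(**cfg))
    n = len([k for k in z.files if k.startswith("a")])
    model.load_state_arrays([z[f"a{i}"] for i in range(n)])
    model.set_training(False)
    return model


@dataclass
class PipelineConfig:
    contour: ContourConfig = field(default_factory=ContourConfig)
    det: DetTrainConfig = field(default_factory=DetTrainConfig)
    hpf: HPFSpec = field(default_factory=HPFSpec)
    thresholds: GradeThresholds = field(default_factory=GradeThresholds)
    seg_checkpoint: str | None = None
    det_checkpoint: str | None = None
    seg_tile: int = 640
    seg_overlap: int = 64
    det_tile: int | None = None
    n_fields: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    tissue: BinaryMask
    parenchyma: BinaryMask
    stroma: BinaryMask
    boxes: list
    counts: list[int]
    grades: list[str]
    manifest: dict


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems (empty iff the config is valid)."""
    problems = []
    d = cfg.det
    if not 0.0 < d.conf_threshold < 1.0:
        problems.append(f"det.conf_threshold={d.conf_threshold} outside (0, 1)")
    if not 0.0 < d.nms_iou < 1.0:
        problems.append(f"det.nms_iou={d.nms_iou} outside (0, 1)")
    for scale in d.anchors:
        for aw, ah in scale:
            if aw <= 0 or ah <= 0:
                problems.append(f"non-positive anchor ({aw}, {ah})")
    if cfg.contour.close_iterations < 1:
        problems.append("contour.close_iterations must be >= 1")
    if cfg.contour.median_radius < 1:
        problems.append("contour.median_radius must be >= 1")
    if any(lo > hi for lo, hi in zip(cfg.contour.hsv_low, cfg.contour.hsv_high)):
        problems.append("contour.hsv_low exceeds hsv_high")
    if cfg.hpf.field_area_mm2 <= 0:
        problems.append("hpf.field_area_mm2 must be positive")
    if cfg.hpf.mpp <= 0:
        problems.append("hpf.mpp must be positive")
    if not 0 < cfg.thresholds.low_max <= cfg.thresholds.high_min:
        problems.append("grade thresholds must satisfy 0 < low_max <= high_min")
    if cfg.n_fields < 1:
        problems.append("n_fields must be >= 1")
    if cfg.seg_overlap >= cfg.seg_tile:
        problems.append("seg_overlap must be smaller than seg_tile")
    for name in ("seg_checkpoint", "det_checkpoint"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name} path does not exist: {p}")
    return problems


def _upsample_mask(mask: BinaryMask, shape: tuple[int, int]) -> BinaryMask:
    h, w = shape
    g = mask.grid
    idx_r = np.minimum((np.arange(h) * g.shape[0]) // h, g.shape[0] - 1)
    idx_c = np.minimum((np.arange(w) * g.shape[1]) // w, g.shape[1] - 1)
    return BinaryMask(g[idx_r][:, idx_c])


def _boxes_to_annotation(boxes) -> AnnotationSet:
    polys, points = [], []
    for b in boxes:
        polys.append(("lymphocyte" if b.cls == "lymphocyte" else b.cls,
                      np.array([[b.x0, b.y0], [b.x1, b.y0],
                                [b.x1, b.y1], [b.x0, b.y1]])))
        cx, cy = b.center
        points.append((b.cls, cx, cy))
    # detection boxes reuse the point vocabulary; suppress the polygon-class check
    ann = AnnotationSet.__new__(AnnotationSet)
    ann.polygons = [(c, np.asarray(v, dtype=np.float64)) for c, v in polys]
    ann.points = points
    return ann


def run_pipeline(image: RasterImage, cfg: PipelineConfig,
                 out_dir=None, seg_model: U2NetP | None = None,
                 det_model: Detector | None = None,
                 tissue_factor: float | None = None) -> PipelineResult:
    """Run the three stages and the quantification on one image."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "input_sha256": hashlib.sha256(image.pixels.tobytes()).hexdigest(),
        "seed": cfg.seed,
        "config": {
            "n_fields": cfg.n_fields,
            "hpf_area_mm2": cfg.hpf.field_area_mm2,
            "conf_threshold": cfg.det.conf_threshold,
            "nms_iou": cfg.det.nms_iou,
            "grade_low_max": cfg.thresholds.low_max,
            "grade_high_min": cfg.thresholds.high_min,
        },
        "artifacts": [],
        "stages": [],
    }

    def persist(name, writer):
        if out is not None:
            writer(out / name)
            manifest["artifacts"].append(name)

    def finish(tissue, parenchyma, stroma, boxes, counts, grades_):
        persist("counts.csv", lambda p: Path(p).write_text(
            "subject_id,rater_id,count,grade\n" + "\n".join(
                f"field{i},pipeline,{c},{g}" for i, (c, g)
                in enumerate(zip(counts, grades_))) + "\n"))
        persist("report.json", lambda p: Path(p).write_text(json.dumps(
            {"counts": counts, "grades": grades_,
             "n_boxes": len(boxes)}, indent=1)))
        persist("manifest.json", lambda p: Path(p).write_text(
            json.dumps(manifest, indent=1)))
        return PipelineResult(tissue, parenchyma, stroma, boxes, counts,
                              grades_, manifest)

    # stage 1: tissue contour
    try:
        tissue_thumb, tissue_polys = segment_tissue(image, cfg.contour,
                                                    factor=tissue_factor)
    except Exception as e:
        raise RuntimeError(f"stage 'tissue_contour' failed: {e}") from e
    manifest["stages"].append("tissue_contour")
    tissue = _upsample_mask(tissue_thumb, image.shape)
    persist("tissue.png", lambda p: write_mask(tissue, p))
    persist("tissue.geojson", lambda p: write_annotation_file(tissue_polys, p))

    if not tissue.grid.any():
        empty = BinaryMask(np.zeros(image.shape, dtype=np.uint8))
        persist("parenchyma.png", lambda p: write_mask(empty, p))
        persist("stroma.png", lambda p: write_mask(empty, p))
        persist("boxes.geojson",
                lambda p: write_annotation_file(AnnotationSet(), p))
        counts = [0] * cfg.n_fields
        grades_ = [grade(c, cfg.thresholds) for c in counts]
        return finish(tissue, empty, empty, [], counts, grades_)

    # stage 2: parenchyma segmentation
    if seg_model is None:
        if cfg.seg_checkpoint is None:
            raise RuntimeError("stage 'parenchyma' failed: no model given")
        seg_model = load_segmenter(cfg.seg_checkpoint)
    try:
        pred = predict_parenchyma(seg_model, image, tile=cfg.seg_tile,
                                  overlap=cfg.seg_overlap)
    except Exception as e:
        raise RuntimeError(f"stage 'parenchyma' failed: {e}") from e
    manifest["stages"].append("parenchyma")
    parenchyma = BinaryMask(pred.mask.grid & tissue.grid)
    persist("parenchyma.png", lambda p: write_mask(parenchyma, p))

    stroma = stromal_mask(tissue, parenchyma)
    assert np.array_equal(stroma.grid, tissue.grid & (1 - parenchyma.grid))
    persist("stroma.png", lambda p: write_mask(stroma, p))

    # stage 3: lymphocyte detection
    if det_model is None:
        if cfg.det_checkpoint is None:
            raise RuntimeError("stage 'detection' failed: no model given")
        det_model = load_detector(cfg.det_checkpoint)
    try:
        boxes = detect_tils(det_model, image, stroma, cfg.det,
                            tile=cfg.det_tile)
    except Exception as e:
        raise RuntimeError(f"stage 'detection' failed: {e}") from e
    manifest["stages"].append("detection")
    for b in boxes:
        cx, cy = b.center
        assert stroma.grid[min(int(cy), stroma.grid.shape[0] - 1),
                           min(int(cx), stroma.grid.shape[1] - 1)] == 1
    persist("boxes.geojson",
            lambda p: write_annotation_file(_boxes_to_annotation(boxes), p))

    # stage 4: quantification
    hpf = HPFSpec(field_area_mm2=cfg.hpf.field_area_mm2,
                  mpp=image.mpp if image.mpp else cfg.hpf.mpp)
    try:
        counts = count_in_fields(boxes, stroma, hpf, cfg.n_fields, cfg.seed)
    except Exception as e:
        raise RuntimeError(f"stage 'quantification' failed: {e}") from e
    manifest["stages"].append("quantification")
    grades_ = [grade(c, cfg.thresholds) for c in counts]
    return finish(tissue, parenchyma, stroma, boxes, counts, grades_)
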