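import math

import numpy as np
import pytest

from tilscope import (BinaryMask, DetectionBox, DetTrainConfig, RasterImage,
                      SceneSpec, assign_targets, build_detector, ciou_loss,
                      detect_tils, detection_loss, generate_scene,
                      lymphocyte_boxes, nms, train_detector)
from tilscope.eval_metrics import box_iou
from tilscope.nn import Tensor


def brute_nms(boxes, thr):
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if box_iou(boxes[i].box, boxes[j].box) >= thr:
                ok = False
                break
        if ok:
            kept.append(i)
    return [boxes[i] for i in kept]


def random_boxes(rng, n):
    out = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, 80, 2)
        w, h = rng.uniform(2, 30, 2)
        out.append(DetectionBox(x0, y0, x0 + w, y0 + h,
                                float(rng.uniform(0.01, 0.99))))
    return out


class TestCIoU:
    def test_identical_boxes_zero(self):
        loss, terms = ciou_loss((2, 3, 6, 8), (2, 3, 6, 8))
        assert loss == 0.0
        assert terms.iou == 1.0 and terms.rho2 == 0.0 and terms.v == 0.0

    def test_separated_unit_squares(self):
        loss, terms = ciou_loss((-0.5, -0.5, 0.5, 0.5), (9.5, -0.5, 10.5, 0.5))
        assert terms.iou == 0.0
        assert terms.rho2 == pytest.approx(100.0)
        assert terms.c2 == pytest.approx(11 ** 2 + 1)
        assert terms.v == pytest.approx(0.0)
        assert loss == pytest.approx(1 + 100 / 122, abs=1e-6)

    def test_concentric_different_aspect_term_by_term(self):
        # pred 2x2 and gt 2x4, both centered at origin
        loss, terms = ciou_loss((-1, -1, 1, 1), (-1, -2, 1, 2))
        iou = 4 / 8
        v = (4 / math.pi ** 2) * (math.atan(2 / 4) - math.atan(2 / 2)) ** 2
        alpha = v / ((1 - iou) + v)
        assert terms.rho2 == 0.0 and terms.v == pytest.approx(v)
        assert terms.alpha_ciou == pytest.approx(alpha)
        assert loss == pytest.approx(1 - iou + alpha * v)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ciou_loss((0, 0, 0, 1), (0, 0, 1, 1))

    def test_nonnegative_and_reduces_to_iou_term(self, rng):
        for _ in range(50):
            x0, y0 = rng.uniform(0, 50, 2)
            w, h = rng.uniform(1, 20, 2)
            dx = rng.uniform(-5, 5)
            loss, terms = ciou_loss((x0, y0, x0 + w, y0 + h),
                                    (x0 + dx, y0, x0 + w + dx, y0 + h))
            assert loss >= 0
        # same centers, same aspect: loss is exactly 1 - IoU
        loss, terms = ciou_loss((-2, -2, 2, 2), (-3, -3, 3, 3))
        assert loss == pytest.approx(1 - terms.iou)


class TestNMS:
    def test_high_overlap_keeps_strongest(self):
        a = DetectionBox(0, 0, 10, 10, 0.9)
        b = DetectionBox(0, 0.5, 10, 10.5, 0.8)
        assert box_iou(a.box, b.box) > 0.5
        assert nms([a, b], 0.5) == [a]

    def test_disjoint_all_kept_in_confidence_order(self):
        boxes = [DetectionBox(i * 20, 0, i * 20 + 5, 5, c)
                 for i, c in enumerate((0.3, 0.9, 0.6))]
        kept = nms(boxes, 0.5)
        assert [b.confidence for b in kept] == [0.9, 0.6, 0.3]

    def test_empty_input(self):
        assert nms([], 0.5) == []

    def test_idempotent_and_subset(self, rng):
        boxes = random_boxes(rng, 60)
        kept = nms(boxes, 0.4)
        assert all(b in boxes for b in kept)
        assert nms(kept, 0.4) == kept
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert box_iou(a.box, b.box) < 0.4

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            boxes = random_boxes(rng, int(rng.integers(0, 30)))
            thr = float(rng.uniform(0.2, 0.8))
            assert nms(boxes, thr) == brute_nms(boxes, thr)


class TestDetectorModel:
    def test_grid_shapes_follow_strides(self):
        cfg = DetTrainConfig(input_size=128, base_channels=4, seed=0)
        model = build_detector(cfg)
        model.set_training(False)
        x = Tensor(np.random.default_rng(0).uniform(0, 1, (1, 3, 128, 128)))
        preds = model(x)
        shapes = [(p[0].shape[2], p[0].shape[3]) for p in preds]
        assert shapes == [(16, 16), (8, 8), (4, 4)]

    def test_decoded_confidences_in_unit_interval(self, rng):
        cfg = DetTrainConfig(input_size=64, base_channels=4, seed=0,
                             conf_threshold=0.01)
        model = build_detector(cfg)
        img = RasterImage(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8))
        boxes = detect_tils(model, img, None, cfg, tile=64)
        for b in boxes:
            assert 0.0 < b.confidence < 1.0

    def test_same_seed_identical_initialization(self):
        a = build_detector(DetTrainConfig(base_channels=4, seed=3))
        b = build_detector(DetTrainConfig(base_channels=4, seed=3))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)


class TestAssignment:
    GRIDS = [(16, 16), (8, 8), (4, 4)]

    def test_centered_gt_hits_center_cell(self):
        cfg = DetTrainConfig()
        gt = [(56, 56, 72, 72)]  # 16x16 centered at (64, 64)
        obj, assigns = assign_targets(gt, cfg.anchors, self.GRIDS)
        assert assigns, "gt must be assigned"
        for si, ai, gy, gx, _ in assigns:
            stride = (8, 16, 32)[si]
            assert gy == int(64 // stride) and gx == int(64 // stride)
        # the matching 16px anchor at P3 is among the assignments
        assert any(si == 0 and cfg.anchors[0][ai] == (16.0, 16.0)
                   for si, ai, gy, gx, _ in assigns)

    def test_no_gt_all_targets_zero(self):
        obj, assigns = assign_targets([], DetTrainConfig().anchors, self.GRIDS)
        assert assigns == []
        assert all((t == 0).all() for t in obj)

    def test_border_center_uses_half_open_convention(self):
        cfg = DetTrainConfig()
        gt = [(0, 0, 16, 16)]  # center (8, 8) -> cell 1 at stride 8
        _, assigns = assign_targets(gt, cfg.anchors, self.GRIDS)
        p3 = [a for a in assigns if a[0] == 0]
        assert p3 and all(a[2] == 1 and a[3] == 1 for a in p3)

    def test_every_in_frame_gt_gets_an_anchor(self, rng):
        cfg = DetTrainConfig()
        for _ in range(20):
            x0, y0 = rng.uniform(0, 100, 2)
            w, h = rng.uniform(1, 60, 2)
            _, assigns = assign_targets([(x0, y0, x0 + w, y0 + h)],
                                        cfg.anchors, self.GRIDS,
                                        frame_shape=(128, 128))
            assert len(assigns) >= 1

    def test_out_of_frame_gt_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="outside frame"):
            _, assigns = assign_targets([(200, 200, 220, 220)],
                                        DetTrainConfig().anchors, self.GRIDS,
                                        frame_shape=(128, 128))
        assert assigns == []


class TestDetectionLoss:
    def _preds(self, rng, size=64, a=3):
        model = build_detector(DetTrainConfig(input_size=size,
                                              base_channels=4, seed=0))
        model.set_training(False)
        x = Tensor(rng.uniform(0, 1, (1, 3, size, size)))
        return model(x)

    def test_no_assigned_anchors_box_term_zero(self, rng):
        preds = self._preds(rng)
        grids = [(p[0].shape[2], p[0].shape[3]) for p in preds]
        obj_t, assigns = assign_targets([], DetTrainConfig().anchors, grids)
        total, cls_l, obj_l, box_l = detection_loss(preds, obj_t, assigns)
        assert float(box_l.data) == 0.0 and float(cls_l.data) == 0.0
        assert float(obj_l.data) > 0.0

    def test_single_box_total_is_sum_of_terms(self, rng):
        preds = self._preds(rng)
        grids = [(p[0].shape[2], p[0].shape[3]) for p in preds]
        cfg = DetTrainConfig()
        obj_t, assigns = assign_targets([(24, 24, 40, 40)], cfg.anchors, grids)
        total, cls_l, obj_l, box_l = detection_loss(
            preds, obj_t, assigns, cfg.anchors, weights=(2.0, 3.0, 0.5))
        assert float(total.data) == pytest.approx(
            2 * float(cls_l.data) + 3 * float(obj_l.data)
            + 0.5 * float(box_l.data))
        assert float(box_l.data) > 0.0


@pytest.fixture(scope="module")
def tiny_run():
    scenes = [generate_scene(SceneSpec(width=64, height=64, seed=s,
                                       mpp=0.5, lymphocyte_density=2500,
                                       tumor_fraction=0.3))
              for s in range(6)]
    cfg = DetTrainConfig(input_size=64, base_channels=4, max_epochs=4, seed=0)
    model, hist = train_detector(scenes, cfg)
    return scenes, cfg, model, hist


class TestTraining:

    def test_loss_decreases(self, tiny_run):
        _, _, _, hist = tiny_run
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_same_seed_reproduces_history(self, tiny_run):
        scenes, cfg, _, hist = tiny_run
        _, hist2 = train_detector(scenes, cfg)
        assert [h["train_loss"] for h in hist] == \
            [h["train_loss"] for h in hist2]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_detector([], DetTrainConfig(max_epochs=1))


class TestDetectTils:
    def test_empty_stroma_gives_no_detections(self, rng, detection_scene):
        cfg = DetTrainConfig(input_size=64, base_channels=4, seed=0,
                             conf_threshold=0.01)
        model = build_detector(cfg)
        stroma = BinaryMask(np.zeros(detection_scene.image.shape, np.uint8))
        assert detect_tils(model, detection_scene.image, stroma, cfg,
                           tile=64) == []

    def test_silent_stub_detects_nothing(self, stub_detector, detection_scene):
        cfg = DetTrainConfig(input_size=64, base_channels=4)
        out = detect_tils(stub_detector, detection_scene.image, None, cfg,
                          tile=64)
        assert out == []

    def test_lymphocyte_boxes_use_drawn_radii(self, detection_scene):
        boxes = lymphocyte_boxes(detection_scene)
        assert len(boxes) == len(detection_scene.lymphocyte_truth)
        for (x, y), r, (x0, y0, x1, y1) in zip(
                detection_scene.lymphocyte_truth,
                detection_scene.lymphocyte_radii, boxes):
            assert x1 - x0 == pytest.approx(2 * r)
            assert (x0 + x1) / 2 == pytest.approx(x)
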