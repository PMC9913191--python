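"""The four-head network: shapes, output accounting, decode/encode, loss, NMS."""

import numpy as np
import pytest

from ewenet.anchors import mounting_anchor_set
from ewenet.geometry import BoundingBox, PredictionBox, iou_corners
from ewenet.model import (
    ArchitectureSpec,
    LossWeights,
    assign_targets,
    build_model,
    count_predictions,
    decode,
    loss,
    nms,
)
from ewenet.nn import SGD


def narrow_spec(input_size: int) -> ArchitectureSpec:
    """Full topology with minimal widths: shape contracts do not depend on
    channel counts, and narrow models keep the suite fast."""
    return ArchitectureSpec(
        input_size=input_size, stage_widths=(8, 16, 32, 64, 128)
    )


class TestCountPredictions:
    def test_four_head_416(self):
        assert count_predictions(ArchitectureSpec()) == 43_095

    def test_three_head_pyramid(self):
        assert count_predictions(ArchitectureSpec(), head_scales=(13, 26, 52)) == 10_647

    def test_single_cell_head(self):
        assert count_predictions(ArchitectureSpec(), head_scales=(1,)) == 3


class TestArchitecture:
    @pytest.mark.parametrize("batch", [1, 4])
    @pytest.mark.parametrize("input_size", [320, 416])
    def test_forward_shape_contract(self, batch, input_size):
        spec = narrow_spec(input_size)
        model = build_model(spec, seed=0)
        model.eval()
        x = np.zeros((batch, 3, input_size, input_size), dtype=np.float32)
        out = model(x)
        m = spec.num_classes
        expected_scales = tuple(input_size // s for s in (4, 8, 16, 32))
        assert tuple(out.keys()) == expected_scales
        for s in expected_scales:
            assert out[s].shape == (batch, 3 * (5 + m), s, s)

    def test_grid_sizes_at_320(self):
        assert narrow_spec(320).head_scales == (80, 40, 20, 10)

    def test_more_residual_units_more_parameters(self):
        base = ArchitectureSpec(stage_widths=(8, 16, 32, 64, 128),
                                residual_counts=(1, 2, 8, 8, 4))
        deeper = ArchitectureSpec(stage_widths=(8, 16, 32, 64, 128),
                                  residual_counts=(1, 2, 8, 8, 6))
        n_base = sum(p.data.size for p in build_model(base, 0).parameters())
        n_deeper = sum(p.data.size for p in build_model(deeper, 0).parameters())
        assert n_deeper > n_base

    def test_input_not_divisible_by_32_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(input_size=100)

    def test_full_width_model_matches_published_size_scale(self):
        # ~73M float32 parameters ~ 280 MB: the published order of magnitude
        model = build_model(ArchitectureSpec(), seed=0)
        n = sum(p.data.size for p in model.parameters())
        assert 60e6 < n < 90e6


class TestDecode:
    def test_zero_logits_give_anchor_sized_cell_centre_boxes(self, tiny_spec):
        s = tiny_spec.head_scales[-1]  # coarsest grid
        stride = tiny_spec.input_size / s
        raw = {
            sc: np.zeros((1, 18, sc, sc), dtype=np.float32)
            for sc in tiny_spec.head_scales
        }
        preds = decode(raw, tiny_spec, conf_threshold=0.0)[0]
        anchors = tiny_spec.anchor_set
        # pick out the coarsest head's first cell predictions
        coarse = [
            p for p in preds
            if p.box.cx == pytest.approx(stride / 2) and p.box.cy == pytest.approx(stride / 2)
            and any(p.box.w == aw for aw, _ in anchors.layer_map[s])
        ]
        assert len(coarse) >= 3
        for p in coarse:
            assert p.c == pytest.approx(0.25)  # sigma(0)^2

    def test_threshold_one_empty_threshold_zero_full(self, tiny_spec):
        raw = {
            sc: np.zeros((2, 18, sc, sc), dtype=np.float32)
            for sc in tiny_spec.head_scales
        }
        empty = decode(raw, tiny_spec, conf_threshold=1.0)
        assert all(len(p) == 0 for p in empty)
        full = decode(raw, tiny_spec, conf_threshold=0.0)
        assert all(len(p) == count_predictions(tiny_spec) for p in full)

    def test_shape_mismatch_rejected(self, tiny_spec):
        raw = {sc: np.zeros((1, 17, sc, sc), dtype=np.float32)
               for sc in tiny_spec.head_scales}
        with pytest.raises(ValueError):
            decode(raw, tiny_spec)


class TestAssignTargets:
    def test_anchor_shape_routes_to_its_head(self):
        """A ground truth with exactly a mid-scale anchor's dimensions is
        assigned to that anchor's head, at the cell holding its centre."""
        spec = ArchitectureSpec()  # 416, published anchors
        aset = mounting_anchor_set()
        aw, ah = aset.layer_map[52][0]  # anchor 4 of 12: 40x59
        gt = [[BoundingBox(208, 208, aw, ah)]]
        tgt = assign_targets(gt, spec)
        assert tgt[52]["obj"].sum() == 1.0
        assert tgt[52]["obj"][0, 0, 26, 26] == 1.0
        for other in (104, 26, 13):
            assert tgt[other]["obj"].sum() == 0.0
        # exact-match anchor: log-ratio targets are zero
        assert np.allclose(tgt[52]["t_box"][0, 0, 26, 26, 2:], 0.0)

    def test_two_boxes_two_positive_cells(self, tiny_spec):
        gt = [[BoundingBox(10, 10, 12, 14), BoundingBox(50, 50, 12, 14)]]
        tgt = assign_targets(gt, tiny_spec)
        assert sum(t["obj"].sum() for t in tgt.values()) == 2.0

    def test_empty_gt_all_negative(self, tiny_spec):
        tgt = assign_targets([[]], tiny_spec)
        for t in tgt.values():
            assert t["obj"].sum() == 0.0
            assert t["noobj"].all()

    def test_gt_outside_frame_rejected(self, tiny_spec):
        with pytest.raises(ValueError):
            assign_targets([[BoundingBox(999, 10, 5, 5)]], tiny_spec)


class TestEncodeDecodeInverse:
    def test_decode_recovers_encoded_boxes(self, tiny_spec, rng):
        """Writing a box into its assigned cell as ideal logits and decoding
        recovers the centre within half a cell and sizes within 1%."""
        spec = tiny_spec
        for _ in range(20):
            w = float(rng.uniform(5, 40))
            h = float(rng.uniform(5, 40))
            cx = float(rng.uniform(5, spec.input_size - 5))
            cy = float(rng.uniform(5, spec.input_size - 5))
            gt = BoundingBox(cx, cy, w, h)
            tgt = assign_targets([[gt]], spec)
            raw = {s: np.full((1, 18, s, s), -12.0, dtype=np.float32)
                   for s in spec.head_scales}
            for s in spec.head_scales:
                pos = np.argwhere(tgt[s]["obj"][0] == 1.0)
                for a, gy, gx in pos:
                    tx, ty, tw, th = tgt[s]["t_box"][0, a, gy, gx]
                    # invert the sigmoid, clipping away exact 0/1
                    lx = np.log(np.clip(tx, 1e-6, 1 - 1e-6) / (1 - np.clip(tx, 1e-6, 1 - 1e-6)))
                    ly = np.log(np.clip(ty, 1e-6, 1 - 1e-6) / (1 - np.clip(ty, 1e-6, 1 - 1e-6)))
                    r = raw[s].reshape(1, 3, 6, s, s)
                    r[0, a, 0, gy, gx] = lx
                    r[0, a, 1, gy, gx] = ly
                    r[0, a, 2, gy, gx] = tw
                    r[0, a, 3, gy, gx] = th
                    r[0, a, 4, gy, gx] = 12.0
                    r[0, a, 5, gy, gx] = 12.0
            (preds,) = decode(raw, spec, conf_threshold=0.5)
            assert len(preds) == 1
            p = preds[0]
            scale_of_pos = [s for s in spec.head_scales if tgt[s]["obj"].sum()][0]
            cell = spec.input_size / scale_of_pos
            assert abs(p.box.cx - cx) <= 0.5 * cell
            assert abs(p.box.cy - cy) <= 0.5 * cell
            assert abs(p.box.w - w) / w <= 0.01
            assert abs(p.box.h - h) / h <= 0.01


class TestLoss:
    def _perfect_raw(self, spec, tgt):
        raw = {}
        for s in spec.head_scales:
            r = np.zeros((1, 3, 6, s, s), dtype=np.float32)
            r[:, :, 4] = -30.0  # confident background everywhere
            pos = np.argwhere(tgt[s]["obj"][0] == 1.0)
            for a, gy, gx in pos:
                tx, ty, tw, th = tgt[s]["t_box"][0, a, gy, gx]
                r[0, a, 0, gy, gx] = np.log(tx / (1 - tx)) if 0 < tx < 1 else 30.0
                r[0, a, 1, gy, gx] = np.log(ty / (1 - ty)) if 0 < ty < 1 else 30.0
                r[0, a, 2, gy, gx] = tw
                r[0, a, 3, gy, gx] = th
                r[0, a, 4, gy, gx] = 30.0
                r[0, a, 5, gy, gx] = 30.0
            raw[s] = r.reshape(1, 18, s, s)
        return raw

    def test_perfect_logits_give_negligible_loss(self, tiny_spec):
        gt = [[BoundingBox(30, 40, 12, 18)]]
        tgt = assign_targets(gt, tiny_spec)
        from ewenet.nn import Tensor

        raw = {s: Tensor(v) for s, v in self._perfect_raw(tiny_spec, tgt).items()}
        l, comps = loss(raw, tgt, tiny_spec)
        assert comps["coord"] < 1e-6
        assert float(l.data) < 1e-6

    def test_coord_term_additive_in_positives(self, tiny_spec):
        from ewenet.nn import Tensor

        one = assign_targets([[BoundingBox(16, 16, 12, 18)]], tiny_spec)
        two = assign_targets(
            [[BoundingBox(16, 16, 12, 18), BoundingBox(48, 48, 12, 18)]], tiny_spec
        )
        raw = {s: Tensor(np.zeros((1, 18, s, s), dtype=np.float32))
               for s in tiny_spec.head_scales}
        _, c1 = loss(raw, one, tiny_spec)
        _, c2 = loss(raw, two, tiny_spec)
        assert c2["coord"] == pytest.approx(2 * c1["coord"], rel=0.35)

    def test_loss_decreases_under_optimization_on_fixed_batch(self, tiny_spec, tiny_scenes):
        """Fifty SGD steps on one fixed batch reduce the loss."""
        from ewenet.imaging import apply_letterbox, forward_boxes, letterbox_params
        from ewenet.model import build_model

        images, boxes = tiny_scenes
        params = letterbox_params((128, 128), (64, 64))
        x = np.stack(
            [apply_letterbox(img, params).transpose(2, 0, 1) / 255.0 for img in images[:4]]
        ).astype(np.float32)
        gts = [forward_boxes(b, params) for b in boxes[:4]]
        model = build_model(tiny_spec, seed=0)
        tgt = assign_targets(gts, tiny_spec)
        opt = SGD(list(model.parameters()), lr=1e-3, momentum=0.9)
        losses = []
        for _ in range(50):
            out = model(x)
            l, _ = loss(out, tgt, tiny_spec)
            opt.zero_grad()
            l.backward()
            opt.step()
            losses.append(float(l.data))
        assert losses[-1] < 0.5 * losses[0]


class TestNms:
    def brute_force(self, boxes, thr):
        kept = []
        for p in sorted(boxes, key=lambda b: -b.c):
            if all(
                p.class_id != q.class_id or iou_corners(p.box, q.box) <= thr
                for q in kept
            ):
                kept.append(p)
        return kept

    def test_duplicate_suppressed(self):
        b = BoundingBox(10, 10, 4, 4)
        out = nms([PredictionBox(b, 0.9), PredictionBox(b, 0.8)], 0.45)
        assert len(out) == 1 and out[0].c == 0.9

    def test_disjoint_survive(self):
        preds = [
            PredictionBox(BoundingBox(10, 10, 4, 4), 0.9),
            PredictionBox(BoundingBox(50, 50, 4, 4), 0.8),
        ]
        assert len(nms(preds, 0.45)) == 2

    def test_matches_exhaustive_reference_on_random_sets(self, rng):
        for _ in range(50):
            preds = [
                PredictionBox(
                    BoundingBox(
                        float(rng.uniform(5, 50)),
                        float(rng.uniform(5, 50)),
                        float(rng.uniform(4, 20)),
                        float(rng.uniform(4, 20)),
                    ),
                    float(rng.uniform(0.01, 0.99)),
                    class_id=int(rng.integers(0, 2)),
                )
                for _ in range(10)
            ]
            assert nms(preds, 0.45) == self.brute_force(preds, 0.45)
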