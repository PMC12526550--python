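import math

import numpy as np
import pytest

from cayolo import losses as L
from cayolo.losses import DetectionLoss, FocalParams, LossBreakdown
from cayolo.nn.tensor import Tensor

from oracles import oracle_ciou


class TestBCE:
    def test_perfect_prediction_is_zero(self):
        assert L.bce_loss(1, 1.0 - 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_is_ln2(self):
        assert L.bce_loss(1, 0.5) == pytest.approx(math.log(2), abs=1e-12)

    def test_symmetry_at_half(self):
        assert L.bce_loss(0, 0.5) == pytest.approx(L.bce_loss(1, 0.5))

    def test_rejects_nonbinary_label(self):
        with pytest.raises(ValueError, match="0, 1"):
            L.bce_loss(0.5, 0.5)

    def test_vectorized(self):
        out = L.bce_loss([1, 0], [0.5, 0.5])
        np.testing.assert_allclose(out, math.log(2))


class TestFocal:
    def test_pt_one_is_zero(self):
        for gamma in (0.0, 1.5, 3.0):
            assert L.focal_loss(1, 1.0 - 1e-12, gamma=gamma,
                                alpha_t=0.7) == pytest.approx(0.0, abs=1e-6)

    def test_gamma0_alpha1_reduces_to_bce(self):
        assert L.focal_loss(1, 0.5, gamma=0.0, alpha_t=1.0) == \
            pytest.approx(math.log(2), abs=1e-12)

    def test_derived_high_precision_value(self):
        # alpha=0.25, gamma=2, pt=0.9: 0.25 * 0.01 * (-ln 0.9)
        expected = 0.25 * 0.1 ** 2 * -math.log(0.9)
        assert expected == pytest.approx(2.63401e-4, rel=1e-4)
        assert L.focal_loss(1, 0.9, gamma=2.0, alpha_t=0.25) == \
            pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_gamma(self):
        with pytest.raises(ValueError, match=">= 0"):
            L.focal_loss(1, 0.5, gamma=-1.0)

    def test_equals_bce_on_grid(self):
        # gamma=0, alpha=1 identity over a 10^3-point grid
        ps = np.linspace(1e-4, 1 - 1e-4, 500)
        for y in (0, 1):
            fl = L.focal_loss(np.full_like(ps, y), ps, gamma=0.0, alpha_t=1.0)
            bce = L.bce_loss(np.full_like(ps, y), ps)
            np.testing.assert_allclose(fl, bce, atol=1e-9)

    @pytest.mark.parametrize("gamma", [0.5, 1.5, 3.0])
    def test_strictly_decreasing_in_pt(self, gamma):
        pts = np.linspace(0.01, 0.99, 200)
        vals = L.focal_loss(np.ones_like(pts), pts, gamma=gamma)
        assert np.all(np.diff(vals) < 0)

    def test_higher_gamma_downweights_easy_examples(self):
        for pt in (0.6, 0.8, 0.95):
            lo = L.focal_loss(1, pt, gamma=0.5)
            hi = L.focal_loss(1, pt, gamma=2.5)
            assert hi < lo

    def test_params_validation(self):
        with pytest.raises(ValueError):
            FocalParams(gamma=-0.1)
        with pytest.raises(ValueError):
            FocalParams(alpha=[1.0, 0.0])


class TestAlphaFromFrequency:
    def test_equal_counts_unit_weights(self):
        np.testing.assert_allclose(L.alpha_from_frequency([10, 10]), [1, 1])

    def test_nine_to_one_ratio(self):
        np.testing.assert_allclose(L.alpha_from_frequency([90, 10]),
                                   [0.2, 1.8])

    def test_single_class(self):
        np.testing.assert_allclose(L.alpha_from_frequency([42]), [1.0])

    def test_rarer_class_weighted_higher(self, rng):
        counts = rng.integers(1, 1000, size=5)
        alpha = L.alpha_from_frequency(counts)
        assert np.argmax(alpha) == np.argmin(counts)
        assert alpha.sum() == pytest.approx(5.0)

    def test_zero_count_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="smoothing"):
            L.alpha_from_frequency([5, 0])


class TestCIoU:
    def test_identical_boxes_zero(self):
        assert L.ciou_loss([0, 0, 10, 10], [0, 0, 10, 10]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_range_contract(self, rng):
        for _ in range(200):
            p = np.sort(rng.uniform(0, 100, 2)).tolist()
            q = np.sort(rng.uniform(0, 100, 2)).tolist()
            a = [p[0], q[0], p[1] + 1, q[1] + 1]
            r = np.sort(rng.uniform(0, 100, 2)).tolist()
            s = np.sort(rng.uniform(0, 100, 2)).tolist()
            b = [r[0], s[0], r[1] + 1, s[1] + 1]
            assert 0.0 <= L.ciou_loss(a, b) <= 2.0

    def test_offset_boxes_match_formula_oracle(self):
        p, g = [0, 0, 10, 10], [0, 5, 10, 15]
        # sanity of the hand case: IoU = 50/150
        assert L.ciou([0, 0, 10, 10], [0, 5, 10, 15]) < 1 / 3
        assert L.ciou_loss(p, g) == pytest.approx(1 - oracle_ciou(p, g),
                                                  abs=1e-9)

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(50):
            a = rng.uniform(0, 50, 2)
            b = rng.uniform(1, 30, 2)
            p = [a[0], a[1], a[0] + b[0], a[1] + b[1]]
            c = rng.uniform(0, 50, 2)
            d = rng.uniform(1, 30, 2)
            g = [c[0], c[1], c[0] + d[0], c[1] + d[1]]
            assert L.ciou_loss(p, g) == pytest.approx(1 - oracle_ciou(p, g),
                                                      abs=1e-7)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            L.ciou_loss([0, 0, 0, 10], [0, 0, 5, 5])


class TestDFL:
    def test_one_hot_on_bin_is_zero(self):
        p = np.zeros(8)
        p[3] = 1.0
        assert L.dfl_loss(p, 3.0) == pytest.approx(0.0, abs=1e-5)

    def test_midpoint_uniform_two_bins_ln2(self):
        assert L.dfl_loss([0.5, 0.5], 0.5) == pytest.approx(math.log(2),
                                                            abs=1e-12)

    def test_nonadjacent_bins_only_through_mass(self):
        # moving probability between bins not bracketing the target
        # changes the loss only via the bracketing bins' mass
        base = np.array([0.2, 0.3, 0.3, 0.2])
        perm = np.array([0.2, 0.3, 0.3, 0.2])[[3, 1, 2, 0]]  # swap bins 0,3
        t = 1.5
        assert L.dfl_loss(base, t) == pytest.approx(L.dfl_loss(perm, t))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="outside bin range"):
            L.dfl_loss([0.5, 0.5], 1.5)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            L.dfl_loss([0.5, 0.4], 0.5)


class TestLossBreakdown:
    def test_additivity_identities(self, rng):
        for _ in range(20):
            b, f, c, d = rng.uniform(0, 5, 4)
            lb = LossBreakdown(b, f, c, d)
            assert lb.l_cls_enhanced == b + f
            assert lb.l_bbox == c + d
            assert lb.l_total == (b + f) + (c + d)


class TestDetectionLoss:
    def _toy(self, seed=0, nc=2, a=None, gamma=1.5, **kw):
        rng = np.random.default_rng(seed)
        n, A, rm = 2, 21, 8
        anchors = np.stack([np.tile((np.arange(A) + 0.5) * 8, 1),
                            np.repeat((np.arange(1) + 0.5) * 8, A)], axis=-1)
        anchors = rng.uniform(4, 160, size=(A, 2))
        strides = np.full(A, 8.0)
        cls_logits = Tensor(rng.normal(size=(n, A, nc)), requires_grad=True)
        reg_logits = Tensor(rng.normal(size=(n, A, 4, rm)), requires_grad=True)
        targets = [
            (np.array([0]), np.array([[10.0, 10.0, 80.0, 90.0]])),
            (np.array([1]), np.array([[40.0, 30.0, 120.0, 110.0]])),
        ]
        crit = DetectionLoss(nc, rm, FocalParams(alpha=a if a is not None
                                                 else np.ones(nc),
                                                 gamma=gamma, **kw))
        return crit, (cls_logits, reg_logits), targets, anchors, strides

    def test_components_nonnegative_and_additive(self):
        crit, preds, targets, anchors, strides = self._toy()
        lb = crit(preds, targets, anchors, strides).to_floats()
        for v in (lb.l_bce, lb.l_fl, lb.l_ciou, lb.l_dfl):
            assert v >= 0
        assert lb.l_total == pytest.approx(lb.l_bce + lb.l_fl
                                           + lb.l_ciou + lb.l_dfl)

    def test_gamma0_alpha1_cls_is_twice_bce(self):
        crit, preds, targets, anchors, strides = self._toy(gamma=0.0)
        lb = crit(preds, targets, anchors, strides).to_floats()
        assert lb.l_fl == pytest.approx(lb.l_bce, rel=1e-6)
        assert lb.l_cls_enhanced == pytest.approx(2 * lb.l_bce, rel=1e-6)

    def test_bce_component_matches_scalar_oracle(self):
        crit, preds, targets, anchors, strides = self._toy()
        lb = crit(preds, targets, anchors, strides)
        # recompute BCE with the scalar reference on the same logits/targets
        cls_logits = preds[0].data
        prob = 1 / (1 + np.exp(-cls_logits))
        # rebuild the target map via the criterion's own assignment
        lb_f = lb.to_floats()
        tmap = self._target_map(crit, preds, targets, anchors, strides)
        ref = L.bce_loss(tmap.ravel(), prob.ravel()).sum() / max(tmap.sum(), 1)
        assert lb_f.l_bce == pytest.approx(ref, rel=1e-4)

    def test_focal_component_matches_scalar_oracle(self):
        alpha = np.array([1.6, 0.4])
        crit, preds, targets, anchors, strides = self._toy(a=alpha)
        lb_f = crit(preds, targets, anchors, strides).to_floats()
        prob = 1 / (1 + np.exp(-preds[0].data))
        tmap = self._target_map(crit, preds, targets, anchors, strides)
        at = np.where(tmap > 0, alpha[None, None, :], 1.0)
        ref = L.focal_loss(tmap.ravel(), prob.ravel(), gamma=1.5,
                           alpha_t=at.ravel()).sum() / max(tmap.sum(), 1)
        assert lb_f.l_fl == pytest.approx(ref, rel=1e-4)

    @staticmethod
    def _target_map(crit, preds, targets, anchors, strides):
        cls_logits, reg_logits = preds
        n, A, nc = cls_logits.shape
        rm = crit.reg_max
        prob = np.exp(reg_logits.data - reg_logits.data.max(-1, keepdims=True))
        prob /= prob.sum(-1, keepdims=True)
        dist = (prob * np.arange(rm)).sum(-1)
        dec = np.stack([
            anchors[None, :, 0] - dist[..., 0] * strides,
            anchors[None, :, 1] - dist[..., 1] * strides,
            anchors[None, :, 0] + dist[..., 2] * strides,
            anchors[None, :, 1] + dist[..., 3] * strides], axis=-1)
        cp = 1 / (1 + np.exp(-cls_logits.data))
        tmap = np.zeros((n, A, nc))
        for i, (gc, gb) in enumerate(targets):
            a_idx, g_idx = crit.assign(cp[i], dec[i], anchors, gc,
                                       np.asarray(gb))
            tmap[i, a_idx, gc[g_idx]] = 1.0
        return tmap

    def test_empty_targets_box_terms_zero(self):
        crit, preds, _, anchors, strides = self._toy()
        empty = [(np.array([], dtype=int), np.zeros((0, 4)))] * 2
        lb = crit(preds, empty, anchors, strides).to_floats()
        assert lb.l_ciou == 0.0 and lb.l_dfl == 0.0
        assert lb.l_bce > 0  # negatives still contribute

    def test_bce_only_drops_focal(self):
        crit, preds, targets, anchors, strides = self._toy(bce_only=True)
        lb = crit(preds, targets, anchors, strides).to_floats()
        assert lb.l_fl == 0.0 and lb.l_bce > 0

    def test_focal_only_drops_bce(self):
        crit, preds, targets, anchors, strides = self._toy(focal_only=True)
        lb = crit(preds, targets, anchors, strides).to_floats()
        assert lb.l_bce == 0.0 and lb.l_fl > 0

    def test_gradients_flow(self):
        crit, preds, targets, anchors, strides = self._toy()
        lb = crit(preds, targets, anchors, strides)
        lb.l_total.backward()
        assert preds[0].grad is not None and np.any(preds[0].grad != 0)
        assert preds[1].grad is not None and np.any(preds[1].grad != 0)

    def test_perfect_predictions_small_loss(self):
        # logits strongly favouring the assigned targets -> near-zero cls loss
        crit, preds, targets, anchors, strides = self._toy()
        tmap = self._target_map(crit, preds, targets, anchors, strides)
        preds[0].data[:] = np.where(tmap > 0, 20.0, -20.0)
        lb = crit(preds, targets, anchors, strides).to_floats()
        assert lb.l_bce < 1e-4 and lb.l_fl < 1e-4
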