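import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lpcos.metrics import (
    confusion_counts,
    evaluate,
    roc_curve,
    small_vessel_gt,
    small_vessel_metrics,
    um_to_px,
)


def _as_img(flat, shape=(2, 2)):
    return np.asarray(flat).reshape(shape)


def concordance_auc(scores, labels):
    """Brute-force pairwise-concordance AUC (ties counted 1/2)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        gt = _as_img([1, 1, 0, 0]).astype(bool)
        fov = np.ones((2, 2), bool)
        cc = confusion_counts(gt, gt, fov)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (2, 2, 0, 0)
        assert cc.sensitivity == cc.specificity == cc.accuracy == 1.0

    def test_hand_counted_half_right(self):
        gt = _as_img([1, 1, 0, 0]).astype(bool)
        pred = _as_img([1, 0, 0, 1]).astype(bool)
        cc = confusion_counts(pred, gt, np.ones((2, 2), bool))
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (1, 1, 1, 1)
        assert cc.sensitivity == cc.specificity == cc.accuracy == 0.5

    def test_all_negative_prediction(self):
        rng = np.random.default_rng(0)
        gt = rng.random((16, 16)) > 0.8
        fov = np.ones((16, 16), bool)
        cc = confusion_counts(np.zeros((16, 16), bool), gt, fov)
        v = int(gt.sum())
        assert cc.sensitivity == 0.0 and cc.specificity == 1.0
        assert cc.accuracy == (256 - v) / 256

    def test_counts_restricted_to_fov(self):
        gt = np.zeros((4, 4), bool)
        gt[0, 0] = True
        fov = np.zeros((4, 4), bool)
        fov[2:, 2:] = True  # excludes the vessel pixel
        cc = confusion_counts(np.zeros((4, 4), bool), gt, fov)
        assert cc.n == 4 and cc.tp == cc.fn == 0

    def test_empty_fov_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(
                np.zeros((2, 2), bool), np.zeros((2, 2), bool), np.zeros((2, 2), bool)
            )


class TestROC:
    def test_perfect_and_inverted_ranking(self):
        gt = _as_img([1, 1, 0, 0]).astype(bool)
        fov = np.ones((2, 2), bool)
        assert roc_curve(_as_img([0.9, 0.8, 0.4, 0.3]), gt, fov).auc == 1.0
        assert roc_curve(_as_img([0.3, 0.4, 0.8, 0.9]), gt, fov).auc == 0.0

    def test_trapezoid_equals_pairwise_concordance(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.random(200), 2)  # duplicates force tie handling
        labels = rng.random(200) > 0.6
        auc = roc_curve(scores.reshape(10, 20), labels.reshape(10, 20),
                        np.ones((10, 20), bool)).auc
        assert auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        roc = roc_curve(rng.random((8, 8)), rng.random((8, 8)) > 0.5,
                        np.ones((8, 8), bool))
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_gt_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            roc_curve(np.random.rand(4, 4), np.zeros((4, 4), bool),
                      np.ones((4, 4), bool))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random((6, 6))
        gt = rng.random((6, 6)) > 0.5
        if gt.all() or not gt.any():
            return
        fov = np.ones((6, 6), bool)
        a = roc_curve(scores, gt, fov).auc
        b = roc_curve(1 / (1 + np.exp(-5 * scores)), gt, fov).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestSmallVesselGT:
    def test_thick_bar_survives_opening(self, thick_thin_masks):
        gt = np.zeros((128, 128), bool)
        gt[20:40, 10:118] = True  # 20 px wide
        sv = small_vessel_gt(gt, 9)
        # only end-cap pixels may remain
        assert sv.sum() <= 2 * 9 * 20
        assert not sv[25:35, 30:98].any()

    def test_thin_bar_is_entirely_small(self):
        gt = np.zeros((128, 128), bool)
        gt[90:92, 10:118] = True  # 2 px wide
        sv = small_vessel_gt(gt, 9)
        assert np.array_equal(sv, gt)

    def test_union_decomposes(self, thick_thin_masks):
        gt, _ = thick_thin_masks
        thin = np.zeros_like(gt)
        thin[90:92, 10:118] = True
        sv = small_vessel_gt(gt, 9)
        assert np.array_equal(sv & thin, thin)  # all thin-bar pixels kept
        thick_core = np.zeros_like(gt)
        thick_core[25:35, 30:98] = True
        assert not (sv & thick_core).any()

    def test_single_pixel_kernel_gives_empty_set(self):
        rng = np.random.default_rng(3)
        gt = rng.random((32, 32)) > 0.7
        assert not small_vessel_gt(gt, 1).any()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            small_vessel_gt(np.ones((8, 8), bool), 8)


class TestSmallVesselMetrics:
    def test_superset_prediction_gives_full_sensitivity(self, thick_thin_masks):
        gt, fov = thick_thin_masks
        counts, se, _, _ = small_vessel_metrics(gt.copy(), gt, fov, 9)
        assert se == 1.0 and counts.fn_sv == 0

    def test_opened_prediction_misses_small_vessels(self, thick_thin_masks):
        from skimage.morphology import opening as binary_opening, disk

        gt, fov = thick_thin_masks
        pred = binary_opening(gt, disk(4))  # thick structures only
        counts, se, _, _ = small_vessel_metrics(pred, gt, fov, 9)
        assert se <= 0.05

    def test_perfect_ranking_gives_unit_auc_sv(self, thick_thin_masks):
        gt, fov = thick_thin_masks
        rng = np.random.default_rng(4)
        scores = np.where(gt, 0.5 + 0.5 * rng.random(gt.shape),
                          0.49 * rng.random(gt.shape))
        _, _, roc, auc_sv = small_vessel_metrics(scores, gt, fov, 9)
        assert auc_sv == pytest.approx(1.0, abs=1e-12)

    def test_sv_counts_bounded_by_global_counts(self, thick_thin_masks):
        gt, fov = thick_thin_masks
        rng = np.random.default_rng(5)
        pred = rng.random(gt.shape) > 0.5
        cc = confusion_counts(pred, gt, fov)
        sv, _, _, _ = small_vessel_metrics(pred, gt, fov, 9)
        assert sv.tp_sv <= cc.tp
        assert sv.tp_sv + sv.fn_sv <= cc.tp + cc.fn

    def test_empty_small_gt_rejected(self):
        gt = np.ones((64, 64), bool)  # opening is the identity: nothing is small
        with pytest.raises(ValueError, match="kernel"):
            small_vessel_metrics(gt, gt, np.ones_like(gt), 3)

    def test_roc_sv_x_axis_is_global_fpr(self, thick_thin_masks):
        """Se_sv is plotted against 1 - Sp over all in-FOV negatives."""
        gt, fov = thick_thin_masks
        scores = np.where(gt, 0.9, 0.1)
        scores[0, 0] = 0.95  # one false positive above every vessel score
        _, _, roc, _ = small_vessel_metrics(scores, gt, fov, 9)
        n_neg = (~gt).sum()
        idx = np.argmin(np.abs(roc.thresholds - 0.95))
        assert roc.fpr[idx] == pytest.approx(1 / n_neg)
        assert roc.tpr[idx] == 0.0


class TestUmToPx:
    def test_rounding_to_nearest_odd(self):
        assert um_to_px(65, 8.0) == 9  # 8.125 -> nearest odd
        assert um_to_px(65, 65.0) == 1
        assert um_to_px(65, 10.0) == 7  # 6.5 -> 7
        assert um_to_px(65, 30.0) == 3  # 2.17 -> 3

    def test_unknown_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            um_to_px(65, None)


def test_evaluate_report_schema(thick_thin_masks):
    gt, fov = thick_thin_masks
    rng = np.random.default_rng(6)
    prob = np.clip(np.where(gt, 0.8, 0.2) + 0.05 * rng.standard_normal(gt.shape), 0, 1)
    rep = evaluate(prob, gt, fov, threshold=0.5, kernel_diameter_px=9)
    d = rep.to_dict()
    for key in ("Se", "Sp", "Acc", "AUC", "Se_sv", "AUC_sv"):
        assert key in d and d[key] is not None
    assert d["tp"] + d["tn"] + d["fp"] + d["fn"] == fov.sum()
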