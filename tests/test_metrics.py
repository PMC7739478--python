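"""Segmentation metrics, Hausdorff distance and diagnostic ratios."""

import numpy as np
import pytest

from ptxseg.metrics import (
    ConfusionCounts,
    confusion,
    diagnostic_metrics,
    dice,
    dice_ttest,
    hausdorff,
    hausdorff_masks,
    pixel_accuracy,
)


def _mask(shape, ones):
    m = np.zeros(shape, dtype=np.uint8)
    for rc in ones:
        m[rc] = 1
    return m


class TestPixelAccuracy:
    def test_perfect_prediction(self):
        m = _mask((4, 4), [(1, 1), (1, 2)])
        res = pixel_accuracy([(m, m)])
        assert res["mpa"] == pytest.approx(1.0)
        assert res["pa1"] == pytest.approx(1.0)

    def test_hand_counted_example(self):
        # truth: 4 lesion pixels; prediction recovers 3 of them and 11/12
        # of the background
        truth = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (1, 1)])
        pred = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (3, 3)])
        res = pixel_accuracy([(pred, truth)])
        assert res["pa1"] == pytest.approx(0.75)
        assert res["mpa"] == pytest.approx((0.75 + 11 / 12) / 2)

    def test_empty_truth_empty_prediction_scores_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        res = pixel_accuracy([(z, z)])
        assert res["pa1"] == pytest.approx(1.0)

    def test_empty_truth_nonempty_prediction_scores_zero(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        res = pixel_accuracy([(_mask((4, 4), [(0, 0)]), z)])
        assert res["pa1"] == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_accuracy([(np.zeros((3, 3)), np.zeros((4, 4)))])


class TestDice:
    def test_identical_masks(self):
        m = _mask((4, 4), [(1, 1), (2, 2)])
        assert dice([(m, m)])["dsc1"] == pytest.approx(1.0)

    def test_four_sevenths_example(self):
        pred = _mask((4, 4), [(0, 0), (0, 1), (0, 2)])
        truth = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (1, 1)])
        assert dice([(pred, truth)])["dsc1"] == pytest.approx(4 / 7)

    def test_disjoint_masks(self):
        pred = _mask((4, 4), [(0, 0)])
        truth = _mask((4, 4), [(3, 3)])
        assert dice([(pred, truth)])["dsc1"] == pytest.approx(0.0)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(5)
        a = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        b = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        assert dice([(a, b)])["dsc1"] == pytest.approx(dice([(b, a)])["dsc1"])

    def test_oracle_on_random_masks(self):
        """Direct set-arithmetic evaluation of the overlap formula."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            a = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            b = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            sa = {tuple(p) for p in np.argwhere(a)}
            sb = {tuple(p) for p in np.argwhere(b)}
            if sa or sb:
                expected = 2 * len(sa & sb) / (len(sa) + len(sb))
            else:
                expected = 1.0
            assert dice([(a, b)])["dsc1"] == pytest.approx(expected)


class TestHausdorff:
    def test_identical_sets_zero(self):
        p = np.array([[0, 0], [1, 2]])
        assert hausdorff(p, p) == 0.0

    def test_three_four_five(self):
        assert hausdorff(np.array([[0, 0]]), np.array([[3, 4]])) == pytest.approx(5.0)

    def test_asymmetric_directed_distances(self):
        p = np.array([[0, 0], [10, 0]])
        g = np.array([[0, 0]])
        assert hausdorff(p, g) == pytest.approx(10.0)
        assert hausdorff(g, p) == pytest.approx(10.0)  # symmetrised

    def test_empty_set_returns_nan(self):
        assert np.isnan(hausdorff(np.empty((0, 2)), np.array([[0, 0]])))

    def test_agrees_with_bruteforce_oracle(self):
        """All-pairs max-min evaluation on random small point sets."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            p = rng.integers(0, 15, size=(rng.integers(1, 20), 2))
            g = rng.integers(0, 15, size=(rng.integers(1, 20), 2))
            d = np.sqrt(((p[:, None, :] - g[None, :, :]) ** 2).sum(-1))
            expected = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff(p, g) == pytest.approx(expected)
            assert hausdorff(g, p) == pytest.approx(expected)

    def test_mask_contours_drive_distance(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[2:4, 2:4] = 1
        assert hausdorff_masks(a, a) == 0.0
        assert np.isnan(hausdorff_masks(np.zeros((8, 8), dtype=np.uint8), a))


class TestConfusionAndDiagnostics:
    def test_all_correct_tally(self):
        labels = ["PTX"] * 3 + ["NonPTX"] * 2
        cc = confusion(labels, labels)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (3, 2, 0, 0)

    def test_all_positive_calls(self):
        cc = confusion(["PTX", "NonPTX"], ["PTX", "PTX"])
        assert (cc.tp, cc.fp) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["PTX"], ["PTX", "PTX"])

    def test_perfect_matrix_all_hundred(self):
        m = diagnostic_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        for v in m.values():
            assert v == pytest.approx(100.0)

    def test_uniform_matrix_all_fifty(self):
        m = diagnostic_metrics(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        for v in m.values():
            assert v == pytest.approx(50.0)

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            cc = ConfusionCounts(*[int(v) for v in rng.integers(1, 500, 4)])
            m = diagnostic_metrics(cc)
            hm = 2 / (1 / m["ppv"] + 1 / m["sensitivity"])
            assert m["f1"] == pytest.approx(hm)

    def test_accuracy_is_prevalence_weighted_combination(self):
        cc = ConfusionCounts(tp=30, fp=5, fn=10, tn=55)
        m = diagnostic_metrics(cc)
        pos, neg = cc.tp + cc.fn, cc.tn + cc.fp
        expected = (m["sensitivity"] * pos + m["specificity"] * neg) / (pos + neg)
        assert m["accuracy"] == pytest.approx(expected)

    def test_zero_denominator_yields_nan(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["ppv"])
        assert m["specificity"] == pytest.approx(100.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


def test_dice_ttest_flags_separated_samples():
    rng = np.random.default_rng(1)
    a = rng.normal(0.9, 0.02, 40)
    b = rng.normal(0.5, 0.02, 40)
    t, p = dice_ttest(a, b)
    assert p < 1e-6
    _, p_same = dice_ttest(a, a)
    assert p_same == pytest.approx(1.0)
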