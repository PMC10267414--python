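"""Metrics, rank-sum comparison, and error maps against independent oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

from octseg.evaluation import (ConfusionCounts, compare_methods,
                               compute_metrics, confusion, error_map)


def brute_force_metrics(pred, true, n_classes):
    """Independent per-pixel counting oracle for Dice/IoU/Acc/mPA."""
    dice, iou, pa = [], [], []
    for c in range(n_classes):
        p = pred == c
        t = true == c
        tp = int((p & t).sum())
        fp = int((p & ~t).sum())
        fn = int((~p & t).sum())
        if tp + fp + fn == 0:
            dice.append(np.nan)
            iou.append(np.nan)
            pa.append(np.nan)
            continue
        dice.append(2 * tp / (2 * tp + fp + fn))
        iou.append(tp / (tp + fp + fn))
        pa.append(tp / (tp + fn) if tp + fn else np.nan)
    return (np.array(dice), np.array(iou), float((pred == true).mean()),
            np.nanmean(iou), np.nanmean(pa))


def rank_sum_enumeration(a, b):
    """Exact permutation p-value oracle: Pr(|W - mu| >= |w_obs - mu|)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    mu = n1 * (n + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = sum(1 for idx in combinations(range(n), n1)
               if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9)
    return hits / comb(n, n1)


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self, rng):
        mask = rng.integers(0, 4, size=(8, 8))
        c = confusion(mask, mask, 4)
        assert (c.fp == 0).all() and (c.fn == 0).all()
        assert c.tp.sum() == 64

    def test_four_pixel_enumeration(self):
        true = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        c = confusion(pred, true, 2)
        assert (c.tp[1], c.fp[1], c.fn[1], c.tn[1]) == (2, 1, 0, 1)
        assert (c.tp[0], c.fp[0], c.fn[0], c.tn[0]) == (1, 0, 1, 2)

    def test_swapping_arguments_swaps_fp_fn(self, rng):
        a = rng.integers(0, 5, size=(10, 10))
        b = rng.integers(0, 5, size=(10, 10))
        ab, ba = confusion(a, b, 5), confusion(b, a, 5)
        np.testing.assert_array_equal(ab.fp, ba.fn)
        np.testing.assert_array_equal(ab.fn, ba.fp)
        np.testing.assert_array_equal(ab.tp, ba.tp)

    def test_shape_and_label_validation(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2), int), np.zeros((2, 3), int), 2)
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 7), np.zeros((2, 2), int), 2)


class TestMetrics:
    def test_perfect_prediction_scores_one(self, rng):
        mask = rng.integers(0, 4, size=(10, 10))
        rep = compute_metrics(confusion(mask, mask, 4))
        np.testing.assert_allclose(rep.dice[~np.isnan(rep.dice)], 1.0)
        assert rep.acc == 1.0 and rep.miou == 1.0 and rep.mpa == 1.0

    def test_hand_computed_single_class(self):
        # TP=6, FP=2, FN=2 -> Dice 12/16, IoU 6/10
        c = ConfusionCounts(tp=np.array([90, 6]), tn=np.array([10, 90]),
                            fp=np.array([0, 2]), fn=np.array([0, 2]))
        rep = compute_metrics(c)
        assert rep.dice[1] == pytest.approx(0.75)
        assert rep.iou[1] == pytest.approx(0.6)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 4, size=(20, 20))
            true = rng.integers(0, 4, size=(20, 20))
            rep = compute_metrics(confusion(pred, true, 4))
            dice, iou, acc, miou, mpa = brute_force_metrics(pred, true, 4)
            np.testing.assert_allclose(rep.dice, dice, atol=1e-12)
            np.testing.assert_allclose(rep.iou, iou, atol=1e-12)
            assert rep.acc == pytest.approx(acc, abs=1e-12)
            assert rep.miou == pytest.approx(miou, abs=1e-12)
            assert rep.mpa == pytest.approx(mpa, abs=1e-12)

    def test_dice_iou_identity(self, rng):
        pred = rng.integers(0, 6, size=(15, 15))
        true = rng.integers(0, 6, size=(15, 15))
        rep = compute_metrics(confusion(pred, true, 6))
        np.testing.assert_allclose(rep.dice, 2 * rep.iou / (1 + rep.iou),
                                   atol=1e-12)

    def test_absent_class_excluded_from_means(self):
        pred = np.zeros((4, 4), int)
        true = np.zeros((4, 4), int)
        rep = compute_metrics(confusion(pred, true, 3))
        assert np.isnan(rep.dice[1]) and np.isnan(rep.dice[2])
        assert rep.miou == 1.0

    def test_permutation_equivariance_under_relabelling(self, rng):
        pred = rng.integers(0, 4, size=(12, 12))
        true = rng.integers(0, 4, size=(12, 12))
        perm = np.array([2, 0, 3, 1])
        a = compute_metrics(confusion(pred, true, 4))
        b = compute_metrics(confusion(perm[pred], perm[true], 4))
        assert sorted(a.dice) == pytest.approx(sorted(b.dice))
        assert a.acc == pytest.approx(b.acc)
        assert a.miou == pytest.approx(b.miou)

    def test_micro_accuracy_is_tp_over_total(self, rng):
        pred = rng.integers(0, 3, size=(9, 9))
        true = rng.integers(0, 3, size=(9, 9))
        c = confusion(pred, true, 3)
        assert compute_metrics(c).acc == pytest.approx(c.tp.sum() / 81)

    def test_literal_averaged_accuracy_variant(self):
        # the printed-formula variant: mean_c TP_c / total
        c = ConfusionCounts(tp=np.array([50, 30]), tn=np.array([30, 50]),
                            fp=np.array([10, 10]), fn=np.array([10, 10]))
        rep = compute_metrics(c, literal_eq8=True)
        assert rep.mpa == pytest.approx(0.5 * (50 / 100 + 30 / 100))

    def test_percent_rendering_rounds_half_away(self):
        rep = compute_metrics(ConfusionCounts(
            tp=np.array([1]), tn=np.array([0]), fp=np.array([0]),
            fn=np.array([0])))
        assert rep.percent(0.91249) == 91.2
        assert rep.percent(0.91250) == 91.3
        assert rep.percent(1.0) == 100.0


class TestCompareMethods:
    def test_identical_samples_give_one(self):
        with pytest.warns(UserWarning):
            assert compare_methods([1, 1, 1], [1, 1, 1]) == 1.0

    def test_fully_separated_triplets(self):
        # only 2 of the C(6,3)=20 assignments are as extreme
        assert compare_methods([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_scaling_leaves_p_unchanged(self, rng):
        a = rng.normal(size=6).tolist()
        b = rng.normal(size=5).tolist()
        assert compare_methods(a, b) == pytest.approx(
            compare_methods([2 * v for v in a], [2 * v for v in b]))

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            b = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            assert compare_methods(a, b) == pytest.approx(
                rank_sum_enumeration(a, b))

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 8))
            b = rng.normal(size=rng.integers(3, 8))
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue
            assert compare_methods(a, b) == pytest.approx(ref, abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.3, size=28)
        p = compare_methods(a, b)
        ref = stats.ranksums(a, b).pvalue
        assert p == pytest.approx(ref, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([], [1.0])


class TestErrorMap:
    def test_identical_masks_zero_map(self):
        m = np.arange(9).reshape(3, 3)
        emap, frac = error_map(m, m)
        assert frac == 0.0 and not emap.any()

    def test_complementary_masks_full_map(self):
        a = np.zeros((4, 4), int)
        b = np.ones((4, 4), int)
        emap, frac = error_map(a, b)
        assert frac == 1.0 and emap.all()

    def test_manual_three_by_three(self):
        true = np.array([[0, 1, 2], [0, 1, 2], [0, 1, 2]])
        pred = true.copy()
        pred[0, 0] = 1
        pred[2, 2] = 0
        emap, frac = error_map(pred, true)
        assert frac == pytest.approx(2 / 9)
        assert emap[0, 0] == 1 and emap[2, 2] == 1 and emap.sum() == 2

    def test_fraction_complements_accuracy(self, rng):
        pred = rng.integers(0, 3, size=(10, 10))
        true = rng.integers(0, 3, size=(10, 10))
        _, frac = error_map(pred, true)
        rep = compute_metrics(confusion(pred, true, 3))
        assert frac == pytest.approx(1 - rep.acc)
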