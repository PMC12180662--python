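"""Evaluation metrics against brute-force oracles and hand computations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sliceflow import evalmetrics as em


def brute_force_auroc(scores, labels):
    """Concordant-pair fraction (ties count half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_best_f1(scores, labels):
    best = (None, -1.0)
    for t in sorted(set(scores)):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        f1 = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 0.0
        if f1 > best[1]:
            best = (t, f1)
    return best


class TestBestF1:
    def test_perfect_separation(self):
        thr, f1 = em.best_f1_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert f1 == 1.0 and 0.2 < thr <= 0.8

    def test_all_equal_scores(self):
        labels = np.array([1, 0, 0, 1, 0])
        frac = labels.mean()
        _, f1 = em.best_f1_threshold(np.full(5, 0.4), labels)
        assert np.isclose(f1, 2 * frac / (1 + frac))

    def test_three_point_example(self):
        thr, f1 = em.best_f1_threshold([0.9, 0.8, 0.1], [1, 1, 0])
        assert f1 == 1.0 and thr <= 0.8

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            scores = rng.random(30).round(1)  # force ties
            labels = rng.integers(0, 2, 30)
            if labels.sum() == 0:
                labels[0] = 1
            thr, f1 = em.best_f1_threshold(scores, labels)
            bthr, bf1 = brute_force_best_f1(scores, labels)
            assert np.isclose(f1, bf1)
            assert np.isclose(thr, bthr)  # tie toward smallest threshold

    def test_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            em.best_f1_threshold([0.1, 0.2], [0, 0])


class TestThresholdMetrics:
    def test_perfect_prediction(self):
        spec, acc, prec, f1 = em.threshold_metrics([0.9, 0.1], [1, 0], 0.5)
        assert (spec, acc, prec, f1) == (1.0, 1.0, 1.0, 1.0)

    def test_all_negative_prediction(self):
        spec, acc, prec, f1 = em.threshold_metrics([0.1, 0.2], [1, 0], 0.9)
        assert prec == 0.0 and spec == 1.0 and f1 == 0.0

    def test_confusion_matrix_arithmetic(self):
        # TP=3 FP=1 FN=1 TN=5 via explicit score/label layout
        scores = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        spec, acc, prec, f1 = em.threshold_metrics(scores, labels, 0.5)
        assert np.isclose(prec, 0.75)
        assert np.isclose(spec, 5 / 6)
        assert np.isclose(acc, 0.8)
        assert np.isclose(f1, 0.75)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            em.threshold_metrics([0.5], [2], 0.1)


class TestAurocAuprc:
    def test_perfect_separation(self):
        assert em.auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert em.auprc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_label_independent_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        assert abs(em.auroc(scores, labels) - 0.5) < 0.05

    def test_auroc_equals_pair_counting(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 50))
            scores = rng.random(n).round(1)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            assert np.isclose(em.auroc(scores, labels), brute_force_auroc(scores, labels))

    def test_six_point_hand_example(self):
        scores = np.array([0.9, 0.7, 0.6, 0.4, 0.3, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0])
        assert np.isclose(em.auroc(scores, labels), brute_force_auroc(scores, labels))

    def test_degenerate_labels(self):
        with pytest.raises(ValueError, match="both classes"):
            em.auroc([0.5, 0.6], [1, 1])
        assert em.auprc([0.5, 0.6], [1, 1]) == 1.0
        with pytest.raises(ValueError, match="positive"):
            em.auprc([0.5, 0.6], [0, 0])


def brute_force_pro(scores, mask, cap=0.3):
    """Exhaustive sweep + trapezoid integration on a toy map."""
    from scipy import ndimage

    labeled, n = ndimage.label(mask)
    neg = ~mask.astype(bool)
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pred = scores >= t
        fpr = (pred & neg).sum() / neg.sum()
        overlaps = [
            (pred & (labeled == r)).sum() / (labeled == r).sum() for r in range(1, n + 1)
        ]
        pts.append((fpr, np.mean(overlaps)))
    pts.sort()
    xs, ys = np.array([p[0] for p in pts]), np.array([p[1] for p in pts])
    if xs[-1] < cap:
        xs, ys = np.r_[xs, cap], np.r_[ys, ys[-1]]
    y_cap = np.interp(cap, xs, ys)
    keep = xs <= cap
    return float(np.trapezoid(np.r_[ys[keep], y_cap], np.r_[xs[keep], cap]) / cap)


class TestPro:
    def test_perfect_map(self, rng):
        mask = np.zeros((6, 6), dtype=int)
        mask[1:3, 1:3] = 1
        scores = mask.astype(float)
        assert np.isclose(em.pro_score(scores, mask), 1.0)

    def test_constant_scores_vs_oracle(self):
        mask = np.zeros((6, 6), dtype=int)
        mask[2:4, 2:4] = 1
        scores = np.full((6, 6), 0.5)
        assert np.isclose(em.pro_score(scores, mask), brute_force_pro(scores, mask))

    def test_random_toys_match_oracle(self, rng):
        for _ in range(10):
            mask = (rng.random((6, 6)) > 0.7).astype(int)
            if mask.sum() == 0:
                mask[0, 0] = 1
            scores = rng.random((6, 6)).round(1)
            assert np.isclose(em.pro_score(scores, mask), brute_force_pro(scores, mask))

    def test_two_regions_one_missed(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[0:2, 0:2] = 1
        mask[5:7, 5:7] = 1
        scores = np.zeros((8, 8))
        scores[0:2, 0:2] = 1.0  # one region fully detected, one missed
        fpr, pro = em._pro_curve_points([scores], [mask])
        assert np.allclose(pro[fpr == 0.0], 0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            em.pro_score(np.zeros((4, 4)), np.zeros((4, 4), dtype=int))


class TestMaxDiceEqualsMaxF1:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_identity_on_random_draws(self, seed):
        local = np.random.default_rng(seed)
        n = int(local.integers(5, 200))
        scores = local.random(n).round(2)
        labels = local.integers(0, 2, n)
        if labels.sum() == 0:
            labels[int(local.integers(0, n))] = 1
        _, f1 = em.best_f1_threshold(scores, labels)
        assert em.max_dice(scores, labels) == f1


class TestMonotoneInvariance:
    def test_rank_metrics_invariant_to_monotone_transform(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        labels[:3] = [1, 0, 1]
        transformed = np.exp(3.0 * scores) + 1.0
        assert np.isclose(em.auroc(scores, labels), em.auroc(transformed, labels))
        assert np.isclose(em.auprc(scores, labels), em.auprc(transformed, labels))
        assert np.isclose(em.max_dice(scores, labels), em.max_dice(transformed, labels))
        mask = labels.reshape(10, 20)
        smap = scores.reshape(10, 20)
        assert np.isclose(
            em.pro_score(smap, mask), em.pro_score(np.exp(3.0 * smap) + 1.0, mask)
        )


class TestEvaluatePixelLevel:
    def _toy_pair(self):
        mask = np.zeros((2, 4, 4), dtype=int)
        mask[0, 1:3, 1:3] = 1
        scores = np.where(mask > 0, 0.9, 0.1) + np.linspace(0, 0.05, 32).reshape(2, 4, 4)
        return scores, mask

    def test_duplicated_volume_equals_single(self):
        scores, mask = self._toy_pair()
        single = em.evaluate_pixel_level([scores], [mask])
        double = em.evaluate_pixel_level([scores, scores.copy()], [mask, mask.copy()])
        assert np.isclose(single.auroc, double.auroc)
        assert np.isclose(single.pro, double.pro)

    def test_mean_across_volumes(self, rng):
        # volume A separable, volume B anti-separable in a controlled way
        mask = np.zeros((1, 4, 4), dtype=int)
        mask[0, 0, 0] = 1
        good = np.zeros((1, 4, 4))
        good[0, 0, 0] = 1.0
        coin = np.zeros((1, 4, 4))
        coin[:] = 0.5  # constant: per-volume AUROC 0.5 by tie-handling
        rep = em.evaluate_pixel_level([good, coin], [mask, mask])
        a1 = em.evaluate_pixel_level([good], [mask]).auroc
        a2 = em.evaluate_pixel_level([coin], [mask]).auroc
        assert np.isclose(rep.auroc, (a1 + a2) / 2)

    def test_hand_computed_two_volume_fixture(self):
        scores, mask = self._toy_pair()
        s2 = scores[::-1].copy()
        m2 = mask[::-1].copy()
        rep = em.evaluate_pixel_level([scores, s2], [mask, m2])
        r1 = em.evaluate_pixel_level([scores], [mask])
        r2 = em.evaluate_pixel_level([s2], [m2])
        for field in ("auroc", "auprc", "pro", "max_dice", "precision"):
            assert np.isclose(
                getattr(rep, field), (getattr(r1, field) + getattr(r2, field)) / 2
            )

    def test_empty_mask_volumes_excluded(self):
        scores, mask = self._toy_pair()
        rep = em.evaluate_pixel_level([scores, scores], [mask, np.zeros_like(mask)])
        assert rep.n_excluded == 1
        assert rep.n_volumes == 1

    def test_shape_mismatch_names_volume(self):
        scores, mask = self._toy_pair()
        with pytest.raises(ValueError, match="volume 1"):
            em.evaluate_pixel_level([scores, scores], [mask, mask[:, :3]])

    def test_max_dice_equals_f1_in_report(self):
        scores, mask = self._toy_pair()
        rep = em.evaluate_pixel_level([scores], [mask])
        assert rep.max_dice == rep.per_volume_breakdown[0]["max_dice"]


class TestEvaluateImageLevel:
    def test_separable_slices_auroc_one(self):
        maps, labels = [], []
        for k in range(3):
            m = np.full((4, 3, 3), 0.1)
            m[1] = 0.9  # slice 1 anomalous in every volume
            maps.append(m)
            labels.append([0, 1, 0, 0])
        rep = em.evaluate_image_level(maps, labels)
        assert rep.auroc == 1.0 and rep.max_dice == 1.0

    def test_three_volume_pooled_hand_computation(self):
        maps = [
            np.array([[[0.2]], [[0.8]]]),
            np.array([[[0.5]], [[0.1]]]),
            np.array([[[0.9]], [[0.3]]]),
        ]
        labels = [[0, 1], [1, 0], [1, 0]]
        rep = em.evaluate_image_level(maps, labels)
        # pooled slice scores (dataset-normalized ranks): [.2,.8,.5,.1,.9,.3]
        pooled = np.array([0.2, 0.8, 0.5, 0.1, 0.9, 0.3])
        flat = np.array([0, 1, 1, 0, 1, 0])
        assert np.isclose(rep.auroc, brute_force_auroc(pooled, flat))
        _, bf1 = brute_force_best_f1((pooled - 0.1) / 0.8, flat)
        assert np.isclose(rep.max_dice, bf1)

    def test_label_count_mismatch(self):
        with pytest.raises(ValueError, match="slices"):
            em.evaluate_image_level([np.zeros((3, 2, 2))], [[0, 1]])
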