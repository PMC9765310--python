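"""Dice, vertical CDR, δ, ROC/AUC and the weighted-rank challenge score
checked against brute-force oracles on toy fixtures."""

import numpy as np
import pandas as pd
import pytest

from odcup.metrics import (
    challenge_score,
    cdr_delta,
    dsc,
    evaluate_pair,
    rank_teams,
    roc_auc,
    vertical_cdr,
)


def rect_mask(h, w, r0, r1, c0, c1):
    m = np.zeros((h, w), dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestDsc:
    def test_identity_and_disjoint(self):
        a = rect_mask(10, 10, 2, 8, 2, 8)
        assert dsc(a, a) == 1.0
        assert dsc(rect_mask(10, 10, 0, 3, 0, 3), rect_mask(10, 10, 5, 9, 5, 9)) == 0.0

    def test_hand_counted_three_by_three(self):
        """TP=2, FP=2, FN=2 on a 3x3 grid -> 2*2/(2*2+2+2) = 0.5."""
        pred = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], dtype=bool)
        gt = np.array([[1, 1, 0], [0, 0, 0], [1, 1, 0]], dtype=bool)
        assert dsc(pred, gt) == 0.5

    def test_symmetry_and_probability_binarisation(self):
        rng = np.random.default_rng(0)
        p = rng.random((12, 12))
        g = rng.random((12, 12)) > 0.5
        assert dsc(p, g) == dsc(g, p >= 0.5)

    def test_both_empty_convention(self):
        z = np.zeros((5, 5), dtype=bool)
        assert dsc(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((3, 3)), np.zeros((4, 4)))


class TestVerticalCdr:
    def test_rectangles(self):
        mask = np.stack([rect_mask(120, 50, 10, 110, 5, 45), rect_mask(120, 50, 40, 80, 10, 40)], axis=-1)
        assert vertical_cdr(mask) == pytest.approx(0.4)

    def test_cup_equals_disc(self):
        d = rect_mask(20, 20, 3, 17, 3, 17)
        assert vertical_cdr(np.stack([d, d], axis=-1)) == 1.0

    def test_largest_component_wins(self):
        """Speckle away from the main structure must not widen the extent."""
        disc = rect_mask(40, 40, 10, 30, 10, 30)
        disc[0, 0] = True  # 1-px speckle
        cup = rect_mask(40, 40, 15, 25, 15, 25)
        mask = np.stack([disc, cup], axis=-1)
        assert vertical_cdr(mask) == pytest.approx(10 / 20)

    def test_empty_disc_raises_empty_cup_warns(self, caplog):
        empty = np.zeros((10, 10, 2), dtype=bool)
        with pytest.raises(ValueError):
            vertical_cdr(empty)
        mask = np.stack([rect_mask(10, 10, 2, 8, 2, 8), np.zeros((10, 10), dtype=bool)], axis=-1)
        import logging

        with caplog.at_level(logging.WARNING, logger="odcup.metrics"):
            assert vertical_cdr(mask) == 0.0
        assert any("empty cup" in r.message for r in caplog.records)

    def test_generator_round_trip(self):
        """Requested CDR is recovered from the rasterised ellipses within the
        one-pixel-per-diameter quantisation."""
        from odcup.synthetic import EyeParams, generate_eye

        for cdr in (0.4, 0.6):
            p = EyeParams(disc_axes=(25.0, 20.0), cup_axes=(cdr * 25.0, cdr * 20.0),
                          cup_offset=(0.0, 0.0), vessel_count=0, noise_sd=0.0)
            _, mask = generate_eye(p, seed=0)
            assert vertical_cdr(mask) == pytest.approx(cdr, abs=2 / 50)


class TestCdrDelta:
    def test_examples_and_composition(self):
        gt = np.stack([rect_mask(100, 30, 0, 100, 5, 25), rect_mask(100, 30, 30, 70, 10, 20)], axis=-1)
        assert cdr_delta(gt, gt) == 0.0
        pred = np.stack([gt[..., 0], rect_mask(100, 30, 25, 75, 10, 20)], axis=-1)
        assert cdr_delta(pred, gt) == pytest.approx(abs(vertical_cdr(pred) - vertical_cdr(gt)))
        assert cdr_delta(pred, gt) == pytest.approx(0.1)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_mann_whitney_oracle(self):
        rng = np.random.default_rng(5)
        scores = rng.random(20)
        labels = np.array([0] * 9 + [1] * 11)
        rng.shuffle(labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        # brute force over all positive/negative pairs, ties count half
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestChallengeScore:
    def test_published_entry(self):
        """Cup rank 3, disc rank 1, δ rank 7 -> 0.35*3 + 0.25*1 + 0.4*7 = 4.10."""
        assert challenge_score(3, 1, 7) == pytest.approx(4.10)

    @pytest.mark.parametrize("r,expected", [(1, 1.0), (2, 2.0)])
    def test_equal_ranks(self, r, expected):
        assert challenge_score(r, r, r) == pytest.approx(expected)

    def test_monotone_in_each_rank(self):
        base = challenge_score(2, 2, 2)
        assert challenge_score(3, 2, 2) > base
        assert challenge_score(2, 3, 2) > base
        assert challenge_score(2, 2, 3) > base

    def test_invalid_rank(self):
        with pytest.raises(ValueError):
            challenge_score(0, 1, 1)


class TestRankTeams:
    def test_strict_ordering(self):
        t = pd.DataFrame({
            "team": ["a", "b"],
            "dsc_cup": [0.9, 0.8], "dsc_disc": [0.95, 0.85], "delta": [0.05, 0.10],
        })
        r = rank_teams(t)
        assert list(r["score"]) == [1.0, 2.0]
        assert list(r["team"]) == ["a", "b"]

    def test_tie_gets_average_rank(self):
        t = pd.DataFrame({
            "team": ["a", "b"],
            "dsc_cup": [0.9, 0.9], "dsc_disc": [0.95, 0.85], "delta": [0.05, 0.10],
        })
        r = rank_teams(t)
        assert set(r["rank_cup"]) == {1.5}

    def test_missing_metric_excluded_with_warning(self, caplog):
        import logging

        t = pd.DataFrame({
            "team": ["a", "b", "c"],
            "dsc_cup": [0.9, 0.8, np.nan],
            "dsc_disc": [0.95, 0.85, 0.9],
            "delta": [0.05, 0.1, 0.2],
        })
        with caplog.at_level(logging.WARNING, logger="odcup.metrics"):
            r = rank_teams(t)
        assert len(r) == 2 and "c" not in set(r["team"])

    def test_self_consistent_on_leaderboard_metrics(self):
        """Re-ranking the published leaderboard metric columns yields a score
        column consistent with the weighting formula applied to those ranks."""
        from odcup.benchmarks import REFUGE_LEADERBOARD

        r = rank_teams(REFUGE_LEADERBOARD[["team", "dsc_cup", "dsc_disc", "delta"]])
        recomputed = 0.35 * r["rank_cup"] + 0.25 * r["rank_disc"] + 0.4 * r["rank_delta"]
        np.testing.assert_allclose(r["score"], recomputed)


def test_evaluate_pair_consistency():
    gt = np.stack([rect_mask(60, 60, 10, 50, 10, 50), rect_mask(60, 60, 20, 40, 20, 40)], axis=-1)
    pred = np.stack([rect_mask(60, 60, 12, 50, 10, 50), rect_mask(60, 60, 22, 40, 20, 40)], axis=-1)
    rec = evaluate_pair(pred, gt)
    tp, fp, fn, _ = rec.counts_disc
    assert rec.dsc_disc == pytest.approx(2 * tp / (2 * tp + fp + fn))
    assert rec.delta == pytest.approx(abs(rec.cdr_pred - rec.cdr_gt))
    assert rec.delta >= 0
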