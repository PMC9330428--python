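import numpy as np
import pytest

from renalseg.evaluation import (
    ConfusionCounts,
    classify_stone_size,
    confusion_counts,
    dice_score,
    evaluate_case,
    evaluate_cohort,
    metrics_from_counts,
    per_stone_dice,
    size_stratified_dice,
    stone_inventory,
    success_rate,
)
from renalseg.phantom import generate_phantom


def brute_force_counts(pred, truth, class_id):
    tp = fp = tn = fn = 0
    for idx in np.ndindex(*pred.shape):
        p = pred[idx] == class_id
        t = truth[idx] == class_id
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


class TestConfusionCounts:
    def test_matches_bruteforce_oracle(self, rng):
        pred = rng.integers(0, 3, size=(8, 8, 8))
        truth = rng.integers(0, 3, size=(8, 8, 8))
        for cid in (0, 1, 2):
            c = confusion_counts(pred, truth, cid)
            assert (c.tp, c.fp, c.tn, c.fn) == brute_force_counts(pred, truth, cid)

    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 3, size=(6, 6, 6))
        c = confusion_counts(truth, truth, 1)
        assert c.fp == 0 and c.fn == 0

    def test_complement(self):
        truth = np.array([[[0, 1], [1, 0]]])
        pred = 1 - truth
        c = confusion_counts(pred, truth, 1)
        assert c.tp == 0 and c.tn == 0

    def test_counts_sum_to_total(self, rng):
        pred = rng.integers(0, 3, size=(5, 5, 5))
        truth = rng.integers(0, 3, size=(5, 5, 5))
        c = confusion_counts(pred, truth, 2)
        assert c.total == 125

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)), 1)


class TestMetrics:
    def test_direct_substitution(self):
        m = metrics_from_counts(ConfusionCounts(tp=2, fp=2, tn=0, fn=2))
        assert m["dice"] == pytest.approx(4 / 8)

    def test_identical_masks_all_ones(self, rng):
        truth = rng.integers(0, 3, size=(4, 4, 4))
        for cid in (1, 2):
            m = metrics_from_counts(confusion_counts(truth, truth, cid))
            assert all(v == 1.0 for v in m.values())

    def test_empty_empty_conventions(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=64, fn=0))
        assert m["dice"] == 1.0
        assert m["specificity"] == 1.0
        assert m["sensitivity"] == 1.0

    def test_set_based_dice_equivalence(self, rng):
        # 2TP/(2TP+FP+FN) == 2|A∩B| / (|A|+|B|) exactly, many random pairs
        for _ in range(200):
            a = rng.integers(0, 2, size=(6, 6, 6))
            b = rng.integers(0, 2, size=(6, 6, 6))
            m = metrics_from_counts(confusion_counts(a, b, 1))
            inter = np.count_nonzero((a == 1) & (b == 1))
            sa, sb = np.count_nonzero(a == 1), np.count_nonzero(b == 1)
            expected = 1.0 if sa + sb == 0 else 2 * inter / (sa + sb)
            assert m["dice"] == expected

    def test_dice_symmetric_accuracy_invariant(self, rng):
        a = rng.integers(0, 3, size=(5, 5, 5))
        b = rng.integers(0, 3, size=(5, 5, 5))
        m_ab = metrics_from_counts(confusion_counts(a, b, 1))
        m_ba = metrics_from_counts(confusion_counts(b, a, 1))
        assert m_ab["dice"] == m_ba["dice"]
        assert m_ab["accuracy"] == m_ba["accuracy"]


class TestClassifyStoneSize:
    def test_medium_100(self):
        assert classify_stone_size(100.0) == "medium"

    def test_small_20(self):
        assert classify_stone_size(20.0) == "small"

    def test_boundary_28_is_medium(self):
        assert classify_stone_size(28.0) == "medium"

    def test_boundary_315_is_large(self):
        assert classify_stone_size(315.0) == "large"
        assert classify_stone_size(314.999) == "medium"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_stone_size(-1.0)


class TestStoneInventory:
    def test_matches_generator_truth(self, tiny_spec):
        _, lab, truth = generate_phantom(tiny_spec)
        inv = stone_inventory(lab.voxels, tiny_spec.spacing_mm)
        assert len(inv) == len(truth.stones)
        assert sorted(r.voxel_count for r in inv) == sorted(s.voxel_count for s in truth.stones)
        assert sorted(r.volume_mm3 for r in inv) == sorted(s.volume_mm3 for s in truth.stones)
        assert sorted(r.size_class for r in inv) == sorted(s.size_class for s in truth.stones)

    def test_empty(self):
        assert stone_inventory(np.zeros((4, 4, 4), dtype=np.int16), (1, 1, 1)) == []

    def test_corner_touching_voxels_one_component(self):
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[0, 0, 0] = 2
        lab[1, 1, 1] = 2  # touches only at a corner: 26-connectivity joins them
        inv = stone_inventory(lab, (1.0, 1.0, 1.0))
        assert len(inv) == 1
        assert inv[0].voxel_count == 2

    def test_equivalent_diameter(self):
        lab = np.zeros((8, 8, 8), dtype=np.int16)
        lab[2:6, 2:6, 2:6] = 2
        rec = stone_inventory(lab, (1.0, 1.0, 1.0))[0]
        expected = 2 * (3 * 64 / (4 * np.pi)) ** (1 / 3)
        assert rec.equivalent_diameter_mm == pytest.approx(expected)


class TestSuccessRate:
    def test_all_pass(self):
        assert success_rate([0.9, 0.8], 0.5) == 1.0

    def test_none_pass(self):
        assert success_rate([0.1, 0.2], 0.5) == 0.0

    def test_seven_of_ten(self):
        vals = [0.9] * 7 + [0.1] * 3
        assert success_rate(vals, 0.5) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            success_rate([], 0.5)


class TestSizeStratifiedDice:
    def _case_with_three_strata(self):
        truth = np.zeros((20, 40, 40), dtype=np.int16)
        truth[2, 2, 2] = 2  # 8 mm3 at 2mm voxels: small
        truth[5:8, 5:8, 5:8] = 2  # 27 vox * 8 = 216 mm3: medium
        truth[10:14, 10:17, 10:17] = 2  # 196 vox * 8 = 1568 mm3: large
        return truth, (2.0, 2.0, 2.0)

    def test_perfect_prediction_all_ones(self):
        truth, spacing = self._case_with_three_strata()
        df = size_stratified_dice([(truth.copy(), truth, spacing)])
        assert set(df["size_class"]) == {"small", "medium", "large"}
        assert (df["dice_mean"] == 1.0).all()

    def test_missing_small_stones(self):
        truth, spacing = self._case_with_three_strata()
        pred = truth.copy()
        pred[2, 2, 2] = 0  # drop the small stone
        df = size_stratified_dice([(pred, truth, spacing)]).set_index("size_class")
        assert df.loc["small", "dice_mean"] == 0.0
        assert df.loc["medium", "dice_mean"] == 1.0
        assert df.loc["large", "dice_mean"] == 1.0

    def test_hand_computed_partial_overlap(self):
        truth = np.zeros((10, 10, 10), dtype=np.int16)
        truth[2:6, 2:6, 2:6] = 2  # 64 voxels
        pred = np.zeros_like(truth)
        pred[4:8, 2:6, 2:6] = 2  # 64 voxels, overlap 32
        rows = per_stone_dice(pred, truth, (1.0, 1.0, 1.0))
        assert len(rows) == 1
        assert rows[0]["dice"] == pytest.approx(2 * 32 / (64 + 64))

    def test_empty_strata_absent(self):
        truth = np.zeros((6, 6, 6), dtype=np.int16)
        truth[1:4, 1:4, 1:4] = 2  # 27 mm3 at 1mm: small only
        df = size_stratified_dice([(truth.copy(), truth, (1.0, 1.0, 1.0))])
        assert list(df["size_class"]) == ["small"]

    def test_greedy_matching_prefers_largest_overlap(self):
        truth = np.zeros((10, 20, 20), dtype=np.int16)
        truth[2:5, 2:8, 2:8] = 2
        pred = np.zeros_like(truth)
        pred[2:5, 2:8, 2:6] = 2  # big overlap with the truth stone
        pred[7:9, 14:16, 14:16] = 2  # spurious far-away component
        rows = per_stone_dice(pred, truth, (1.0, 1.0, 1.0))
        assert rows[0]["matched_pred_component"] is not None
        assert rows[0]["dice"] > 0.5


class TestCohortEvaluation:
    def test_evaluate_case_keys(self, rng):
        truth = rng.integers(0, 3, size=(4, 4, 4))
        out = evaluate_case(truth, truth)
        assert set(out) == {"kidney", "stone"}
        assert out["stone"]["dice"] == 1.0

    def test_evaluate_cohort_summary(self, rng):
        truth = rng.integers(0, 3, size=(4, 4, 4))
        per_case, summary = evaluate_cohort([(truth, truth), (truth, truth)])
        assert len(per_case) == 4
        assert (summary["dice_mean"] == 1.0).all()

    def test_dice_score_helper(self):
        a = np.array([[[1, 1, 0, 0]]])
        b = np.array([[[1, 0, 1, 0]]])
        assert dice_score(a, b, 1) == pytest.approx(0.5)
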