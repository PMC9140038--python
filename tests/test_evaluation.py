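"""Dice/IoU scoring and sequence aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervreg.evaluation import dice, evaluate_sequence, improvement, iou


def square_mask(h, w, r0, c0, size):
    m = np.zeros((h, w), dtype=bool)
    m[r0 : r0 + size, c0 : c0 + size] = True
    return m


class TestDiceIoU:
    def test_identical_nonempty_masks(self):
        m = square_mask(8, 8, 2, 2, 3)
        assert dice(m, m) == 1.0
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = square_mask(8, 8, 0, 0, 2)
        b = square_mask(8, 8, 5, 5, 2)
        assert dice(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_hand_counted_example(self):
        # |A| = |B| = 4, |A∩B| = 2
        a = square_mask(4, 4, 0, 0, 2)
        b = np.zeros((4, 4), dtype=bool)
        b[0:2, 1:3] = True
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(2 / 6)

    def test_symmetry(self, rng):
        a = rng.random((10, 10)) > 0.4
        b = rng.random((10, 10)) > 0.6
        assert dice(a, b) == dice(b, a)
        assert iou(a, b) == iou(b, a)

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_dice_iou_algebraic_identity(self, seed):
        r = np.random.default_rng(seed)
        a = r.random((6, 6)) > r.uniform(0.2, 0.8)
        b = r.random((6, 6)) > r.uniform(0.2, 0.8)
        if not (a.any() or b.any()):
            return
        j = iou(a, b)
        assert dice(a, b) == pytest.approx(2 * j / (1 + j))

    def test_both_empty_rejected(self):
        z = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            dice(z, z)

    def test_shape_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            dice(np.ones((3, 3), bool), np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="not binary"):
            dice(np.full((3, 3), 0.5), np.ones((3, 3), bool))


class TestEvaluateSequence:
    def test_identical_masks_score_one(self):
        masks = np.stack([square_mask(8, 8, 2, 2, 4)] * 5)
        rep = evaluate_sequence(masks)
        assert rep.per_frame_dice == [1.0] * 4
        assert rep.mean_dice == 1.0
        assert rep.mean_iou == 1.0

    def test_matches_pixel_count_enumeration(self, rng):
        masks = np.stack([rng.random((7, 7)) > 0.5 for _ in range(3)])
        masks[0, 0, 0] = True  # nonempty reference
        rep = evaluate_sequence(masks)
        for t in (1, 2):
            inter = np.logical_and(masks[t], masks[0]).sum()
            want_d = 2 * inter / (masks[t].sum() + masks[0].sum())
            want_j = inter / (np.logical_or(masks[t], masks[0]).sum())
            assert rep.per_frame_dice[t - 1] == pytest.approx(want_d)
            assert rep.per_frame_iou[t - 1] == pytest.approx(want_j)
        assert rep.mean_dice == pytest.approx(np.mean(rep.per_frame_dice))

    def test_per_frame_dice_bounds_iou(self, rng):
        masks = np.stack([rng.random((9, 9)) > 0.4 for _ in range(6)])
        rep = evaluate_sequence(masks)
        for d, j in zip(rep.per_frame_dice, rep.per_frame_iou):
            assert 0.0 <= j <= d <= 1.0

    def test_empty_reference_rejected(self):
        masks = np.zeros((3, 4, 4), dtype=bool)
        masks[1:, 1, 1] = True
        with pytest.raises(ValueError, match="reference"):
            evaluate_sequence(masks)

    def test_report_serializes_to_json(self, tmp_path):
        masks = np.stack([square_mask(8, 8, 2, 2, 4)] * 3)
        rep = evaluate_sequence(masks, mask_source="test")
        text = rep.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").read_text() == text
        assert '"mask_source": "test"' in text


class TestImprovement:
    def test_no_change_is_zero(self):
        assert improvement(0.7, 0.7) == 0.0

    def test_halving_is_minus_fifty(self):
        assert improvement(0.5, 0.25) == -50.0

    def test_reported_study_means(self):
        assert improvement(0.792, 0.892) == pytest.approx(12.626, abs=1e-3)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            improvement(0.0, 0.5)
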