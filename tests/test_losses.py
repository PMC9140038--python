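"""Loss terms against closed forms and brute-force oracles."""

import numpy as np
import pytest

from cervreg.losses import (
    LossConfig,
    similarity_loss,
    smoothness_loss,
    total_loss,
)
from cervreg.transform import warp, zero_field


def brute_force_lncc(f, m, win, eps):
    """Window-by-window NCC enumerated pixel by pixel (interior windows)."""
    h = win // 2
    H, W = f.shape
    vals = []
    for r in range(h, H - h):
        for c in range(h, W - h):
            pf = f[r - h : r + h + 1, c - h : c + h + 1].ravel()
            pm = m[r - h : r + h + 1, c - h : c + h + 1].ravel()
            cov = np.mean(pf * pm) - pf.mean() * pm.mean()
            vf = np.mean(pf * pf) - pf.mean() ** 2
            vm = np.mean(pm * pm) - pm.mean() ** 2
            vals.append(cov / np.sqrt(vf * vm + eps))
    return -float(np.mean(vals))


class TestSimilarity:
    def test_mse_identity_is_zero(self, rng):
        img = rng.random((6, 6))
        assert similarity_loss(img, img) == 0.0

    def test_mse_constant_closed_form(self):
        assert similarity_loss(np.zeros((5, 5)), np.full((5, 5), 0.5)) == 0.25

    def test_lncc_matches_brute_force_oracle(self, rng):
        f = rng.random((8, 8))
        m = rng.random((8, 8))
        cfg = LossConfig(similarity="lncc", lncc_window=3)
        got = similarity_loss(f, m, cfg)
        want = brute_force_lncc(f, m, 3, cfg.lncc_eps)
        assert got == pytest.approx(want, rel=1e-10)

    def test_lncc_perfect_match_near_minus_one(self, rng):
        img = rng.random((16, 16))
        cfg = LossConfig(similarity="lncc", lncc_window=5)
        assert similarity_loss(img, img, cfg) == pytest.approx(-1.0, abs=5e-3)

    def test_lncc_constant_window_is_stable(self):
        cfg = LossConfig(similarity="lncc", lncc_window=3)
        val = similarity_loss(np.full((8, 8), 0.4), np.full((8, 8), 0.4), cfg)
        assert np.isfinite(val)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            similarity_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestSmoothness:
    def test_constant_field_any_value_is_zero(self):
        assert smoothness_loss(np.full((7, 5, 2), -3.7)) == 0.0

    def test_unit_shear_matches_enumeration(self):
        # u(r,c) = (0, c): explicit finite differences on a 4x4 field
        u = np.zeros((4, 4, 2))
        u[:, :, 1] = np.arange(4)
        diffs = []
        for comp in range(2):
            g = u[:, :, comp]
            diffs.extend((g[1:, :] - g[:-1, :]).ravel())
            diffs.extend((g[:, 1:] - g[:, :-1]).ravel())
        want = float(np.mean(np.square(diffs)))
        assert smoothness_loss(u) == pytest.approx(want)
        assert want == pytest.approx(0.25)

    def test_quadratic_homogeneity(self, rng):
        u = rng.normal(size=(6, 6, 2))
        assert smoothness_loss(3.0 * u) == pytest.approx(9.0 * smoothness_loss(u))

    def test_nonfinite_field_rejected(self):
        u = np.zeros((4, 4, 2))
        u[1, 1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            smoothness_loss(u)


class TestTotalLoss:
    def test_global_minimum_is_zero(self, rng):
        img = rng.random((6, 6))
        pairs = [(img, img)] * 3
        fields = [zero_field(6, 6)] * 3
        assert total_loss(pairs, fields) == 0.0

    def test_zero_weight_reduces_to_similarity_sum(self, rng):
        pairs = [(rng.random((6, 6)), rng.random((6, 6))) for _ in range(3)]
        fields = [rng.normal(scale=0.5, size=(6, 6, 2)) for _ in range(3)]
        cfg = LossConfig(lambda_smooth=0.0)
        want = sum(
            similarity_loss(f, warp(m, u), cfg)
            for (f, m), u in zip(pairs, fields)
        )
        assert total_loss(pairs, fields, cfg) == pytest.approx(want)

    def test_matches_fully_unrolled_scalar_computation(self, rng):
        # hand-built 4x4 three-channel instance, unrolled with plain loops
        pairs = [(rng.random((4, 4)), rng.random((4, 4))) for _ in range(3)]
        fields = [rng.uniform(-1, 1, size=(4, 4, 2)) for _ in range(3)]
        cfg = LossConfig(lambda_smooth=0.7)
        want = 0.0
        for (f, m), u in zip(pairs, fields):
            w = warp(m, u)
            want += np.mean((f - w) ** 2)
            diffs = []
            for comp in range(2):
                g = u[:, :, comp]
                diffs.extend((g[1:, :] - g[:-1, :]).ravel())
                diffs.extend((g[:, 1:] - g[:, :-1]).ravel())
            want += 0.7 * float(np.mean(np.square(diffs)))
        assert total_loss(pairs, fields, cfg) == pytest.approx(want)

    def test_single_channel_aggregation_matches_per_branch(self, rng):
        f, m = rng.random((6, 6)), rng.random((6, 6))
        u = rng.normal(scale=0.3, size=(6, 6, 2))
        cfg = LossConfig(lambda_smooth=0.5)
        want = similarity_loss(f, warp(m, u), cfg) + 0.5 * smoothness_loss(u)
        assert total_loss([(f, m)], [u], cfg) == pytest.approx(want)

    def test_wrong_channel_count_rejected(self, rng):
        pairs = [(rng.random((4, 4)), rng.random((4, 4)))] * 2
        with pytest.raises(ValueError, match="1 or 3"):
            total_loss(pairs, [zero_field(4, 4)] * 2)


def test_config_validation():
    with pytest.raises(ValueError, match="similarity"):
        LossConfig(similarity="ssim").validate()
    with pytest.raises(ValueError, match="lambda_smooth"):
        LossConfig(lambda_smooth=-1.0).validate()
    with pytest.raises(ValueError, match="lncc_window"):
        LossConfig(lncc_window=4).validate()
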