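"""Branch network: architecture contracts, init, determinism, checkpoints."""

import numpy as np
import pytest

from cervreg import nn
from cervreg.losses import LossConfig, similarity_term, smoothness_term
from cervreg.network import (
    DEFAULT_WIDTHS,
    build_branch,
    build_rgb_registrar,
    load_checkpoint,
    predict_field,
    save_checkpoint,
)
from cervreg.nn import Tensor
from cervreg.transform import warp


def test_default_widths_make_four_plus_four_stages_and_2ch_head():
    br = build_branch(32, 32, seed=0)
    assert br.enc_widths == [16, 32, 32, 32]
    assert br.dec_widths == [32, 32, 32, 16]
    assert br.params["head_w"].data.shape[0] == 2


def test_field_resolution_equals_input_resolution(rng):
    for h, w in [(32, 32), (32, 48), (64, 32)]:
        br = build_branch(h, w, seed=1)
        field = predict_field(br, np.stack([rng.random((h, w))] * 2))
        assert field.shape == (h, w, 2)


def test_fresh_branch_predicts_near_identity(rng):
    br = build_branch(32, 32, seed=3)
    pair = np.stack([rng.random((32, 32)), rng.random((32, 32))])
    field = predict_field(br, pair)
    assert np.abs(field).max() < 0.1
    warped = warp(pair[1], field)
    assert np.abs(warped - pair[1]).max() < 1e-3


def test_same_seed_identical_parameters_and_outputs(rng):
    a = build_branch(32, 32, seed=9)
    b = build_branch(32, 32, seed=9)
    for k in a.params:
        assert np.array_equal(a.params[k].data, b.params[k].data)
    pair = np.stack([rng.random((32, 32))] * 2)
    assert np.array_equal(predict_field(a, pair), predict_field(b, pair))


def test_rgb_registrar_has_independent_branch_parameters():
    reg = build_rgb_registrar(32, 32, seed=4)
    assert set(reg.branches) == {"red", "green", "blue"}
    r = reg.branches["red"].params["enc0_w"].data
    g = reg.branches["green"].params["enc0_w"].data
    assert not np.array_equal(r, g)
    shapes = {
        name: [p.data.shape for p in br.parameters()]
        for name, br in reg.branches.items()
    }
    assert shapes["red"] == shapes["green"] == shapes["blue"]


def test_indivisible_dimensions_rejected():
    with pytest.raises(ValueError, match="divisible"):
        build_branch(30, 32)
    with pytest.raises(ValueError, match="widths"):
        build_branch(32, 32, widths=[16, 32, 32])


def test_dimension_mismatch_rejected(rng):
    br = build_branch(32, 32, seed=0)
    with pytest.raises(ValueError, match="input shape"):
        predict_field(br, np.stack([rng.random((16, 16))] * 2))


def test_autodiff_gradient_matches_finite_differences(rng):
    """Total loss gradient vs central differences, 16x16, rel tol 1e-3."""
    br = build_branch(16, 16, seed=2, dtype=np.float64)
    # move the head away from its near-zero init so the warp is probed
    # away from the bilinear kernel's integer-coordinate kinks
    br.params["head_w"].data += rng.normal(0, 0.05, br.params["head_w"].data.shape)
    f = rng.random((16, 16))
    m = rng.random((16, 16))
    cfg = LossConfig()

    def loss():
        u = br.forward(np.stack([f, m]))
        warped = nn.warp(Tensor(m), u)
        return similarity_term(Tensor(f), warped, cfg) + smoothness_term(u)

    for pname in ("enc0_w", "enc2_b", "dec1_w", "head_w"):
        p = br.params[pname]
        for q in br.parameters():
            q.grad = None
        loss().backward()
        g_auto = float(p.grad.ravel()[0])
        eps = 1e-6
        orig = float(p.data.ravel()[0])
        p.data.ravel()[0] = orig + eps
        lp = float(loss().data)
        p.data.ravel()[0] = orig - eps
        lm = float(loss().data)
        p.data.ravel()[0] = orig
        g_fd = (lp - lm) / (2 * eps)
        assert g_auto == pytest.approx(g_fd, rel=1e-3, abs=1e-10)


def test_checkpoint_round_trip(tmp_path, rng):
    reg = build_rgb_registrar(32, 32, seed=6)
    path = tmp_path / "model.npz"
    save_checkpoint(reg, path)
    back = load_checkpoint(path)
    pair = np.stack([rng.random((32, 32))] * 2)
    for name in reg.branches:
        assert np.array_equal(
            predict_field(reg.branches[name], pair),
            predict_field(back.branches[name], pair),
        )
    single = build_branch(32, 32, seed=1)
    save_checkpoint(single, tmp_path / "single.npz")
    back1 = load_checkpoint(tmp_path / "single.npz")
    assert np.array_equal(
        predict_field(single, pair), predict_field(back1, pair)
    )
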