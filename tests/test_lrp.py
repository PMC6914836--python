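"""Relevance-propagation rules: epsilon-rule oracles, the gate/source rule,
conservation, and scaling covariance."""

import numpy as np
import pytest

from deeplight.lrp import (
    LRPAudit,
    decompose,
    decompose_batch,
    lrp_conv_backward,
    lrp_linear,
    lrp_lstm_backward,
    lrp_multiplicative,
    seed_relevance,
)
from deeplight.model import (
    ConvLayerParams,
    LSTMParams,
    conv_layer_forward,
    forward_batch,
    lstm_forward,
    same_pad,
)


# ---------------------------------------------------------------------------
# epsilon rule on dense connections


def test_lrp_linear_splits_proportionally_to_contributions():
    inputs = np.array([1.0, 1.0])
    weights = np.array([[3.0], [1.0]])
    lower = lrp_linear(inputs, weights, np.array([4.0]), epsilon=1e-12)
    np.testing.assert_allclose(lower, [3.0, 1.0], rtol=1e-9)


def test_lrp_linear_zero_input_sends_no_messages(rng):
    weights = rng.normal(size=(4, 3))
    lower = lrp_linear(np.zeros(4), weights, rng.normal(size=3))
    np.testing.assert_array_equal(lower, 0.0)


def test_lrp_linear_conserves_relevance_bias_free(rng):
    inputs = rng.normal(size=(5, 6))
    weights = rng.normal(size=(6, 4))
    upper = rng.normal(size=(5, 4))
    lower = lrp_linear(inputs, weights, upper, epsilon=1e-9)
    np.testing.assert_allclose(lower.sum(axis=1), upper.sum(axis=1), rtol=1e-6)


def test_lrp_linear_matches_exact_contribution_split_on_random_instances(rng):
    """100 random single-layer instances vs the closed-form a_i w_i / sum(z)."""
    for _ in range(100):
        n = int(rng.integers(2, 8))
        a = rng.normal(size=n)
        w = rng.normal(size=(n, 1))
        z = a * w[:, 0]
        zj = z.sum()
        if abs(zj) < 1e-3:  # keep the epsilon->0 limit well-conditioned
            continue
        R = float(rng.normal())
        expected = z / zj * R
        got = lrp_linear(a, w, np.array([R]), epsilon=1e-12)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-12)


def test_stabilizer_sign_convention_at_zero():
    # z_j == 0: denominator must be +epsilon, not 0
    out = lrp_linear(np.array([1.0, -1.0]), np.ones((2, 1)), np.array([2.0]), epsilon=0.5)
    np.testing.assert_allclose(out, [4.0, -4.0])  # z_ij/(0 + 0.5) * 2


# ---------------------------------------------------------------------------
# multiplicative connections


def test_gate_gets_zero_source_gets_all(rng):
    R = rng.normal(size=(3, 4))
    gate_R, source_R = lrp_multiplicative(rng.random((3, 4)), rng.normal(size=(3, 4)), R)
    np.testing.assert_array_equal(gate_R, 0.0)
    np.testing.assert_array_equal(source_R, R)
    np.testing.assert_array_equal(gate_R + source_R, R)  # conservation of the rule


def test_scalar_source_passthrough():
    _, source_R = lrp_multiplicative(np.array(0.4), np.array(1.2), np.array(7.3))
    assert source_R == pytest.approx(7.3)


# ---------------------------------------------------------------------------
# seeding


def test_seed_is_target_logit_only(tiny_model, rng):
    cache = forward_batch(rng.normal(size=(2, 8, 8, 4)), tiny_model)
    seed = seed_relevance(cache, 1)
    np.testing.assert_array_equal(seed[:, [0, 2]], 0.0)
    np.testing.assert_array_equal(seed[:, 1], cache.logits[:, 1])


def test_seed_carries_negative_logits(tiny_model, rng):
    cache = forward_batch(rng.normal(size=(4, 8, 8, 4)), tiny_model)
    for target in range(3):
        seed = seed_relevance(cache, target)
        np.testing.assert_array_equal(seed[:, target], cache.logits[:, target])


def test_invalid_target_rejected(tiny_model, rng):
    cache = forward_batch(rng.normal(size=(1, 8, 8, 4)), tiny_model)
    with pytest.raises(ValueError):
        seed_relevance(cache, 3)


# ---------------------------------------------------------------------------
# LSTM backward


def _scalar_lstm(rng):
    params = LSTMParams(
        W={g: rng.normal(size=(1, 1)) for g in "fico"},
        U={g: rng.normal(size=(1, 1)) for g in "fico"},
        b={g: np.zeros(1) for g in "fico"},
    )
    return params


def test_two_step_scalar_lstm_matches_hand_message_passing(rng):
    """Exhaustive pen-and-paper evaluation of every message on a scalar LSTM."""
    params = _scalar_lstm(rng)
    x1, x2 = float(rng.normal()), float(rng.normal())
    seq = np.array([[[x1]], [[x2]]])
    h_final, cache = lstm_forward(seq, params)
    eps = 1e-3
    R_top = 1.7

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    def stab(z):
        return z + eps * (1.0 if z >= 0 else -1.0)

    W = {g: params.W[g][0, 0] for g in "fico"}
    U = {g: params.U[g][0, 0] for g in "fico"}
    # forward, scalar
    f1, i1, o1 = sig(W["f"] * x1), sig(W["i"] * x1), sig(W["o"] * x1)
    c1bar = np.tanh(W["c"] * x1)
    C1 = i1 * c1bar
    h1 = o1 * np.tanh(C1)
    f2 = sig(W["f"] * x2 + U["f"] * h1)
    i2 = sig(W["i"] * x2 + U["i"] * h1)
    c2bar = np.tanh(W["c"] * x2 + U["c"] * h1)
    C2 = f2 * C1 + i2 * c2bar
    # backward messages, step 2
    RC2 = R_top  # o2 gate zeroed, tanh transparent
    z_f, z_i = f2 * C1, i2 * c2bar
    R_keep = z_f / stab(z_f + z_i) * RC2  # -> C1 (gate f2 zeroed)
    R_cbar2 = z_i / stab(z_f + z_i) * RC2
    zx, zh = x2 * W["c"], h1 * U["c"]
    R_x2 = zx / stab(zx + zh) * R_cbar2
    R_h1 = zh / stab(zx + zh) * R_cbar2
    # backward messages, step 1 (C0 = 0 so the forget branch gets nothing)
    RC1 = R_keep + R_h1
    z_f1, z_i1 = 0.0, i1 * c1bar
    R_cbar1 = z_i1 / stab(z_f1 + z_i1) * RC1
    zx1, zh0 = x1 * W["c"], 0.0
    R_x1 = zx1 / stab(zx1 + zh0) * R_cbar1

    Rx = lrp_lstm_backward(cache, params, np.array([[R_top]]), epsilon=eps)
    assert Rx.shape == (2, 1, 1)
    assert Rx[0, 0, 0] == pytest.approx(R_x1, rel=1e-10)
    assert Rx[1, 0, 0] == pytest.approx(R_x2, rel=1e-10)


def test_forget_gate_zero_routes_all_relevance_through_input_branch(rng):
    params = _scalar_lstm(rng)
    params.b["f"][...] = -50.0  # f ~ 0
    seq = rng.normal(size=(1, 1, 1))
    _, cache = lstm_forward(seq, params)
    Rx = lrp_lstm_backward(cache, params, np.array([[2.0]]), epsilon=1e-9)
    # single step, C0 = 0: everything must land on x_1
    assert Rx[0, 0, 0] == pytest.approx(2.0, rel=1e-4)


def test_lstm_backward_conserves_total_relevance(rng):
    params = LSTMParams(
        W={g: rng.normal(size=(3, 4)) for g in "fico"},
        U={g: rng.normal(size=(4, 4)) for g in "fico"},
        b={g: np.zeros(4) for g in "fico"},
    )
    seq = rng.normal(size=(5, 2, 3))
    _, cache = lstm_forward(seq, params)
    R_top = rng.normal(size=(2, 4))
    Rx = lrp_lstm_backward(cache, params, R_top, epsilon=1e-9)
    np.testing.assert_allclose(
        Rx.sum(axis=(0, 2)), R_top.sum(axis=1), rtol=1e-4
    )


def test_gate_sites_receive_identically_zero_relevance(tiny_model, rng):
    audit = LRPAudit()
    decompose_batch(rng.normal(size=(2, 8, 8, 4)), tiny_model, np.array([0, 1]), audit=audit)
    gate_sites = [k for k in audit.gate_relevance if k[0] in "fio"]
    assert len(gate_sites) >= 3 * 4  # three gate kinds at each of four slice steps
    assert all(audit.gate_relevance[k] == 0.0 for k in gate_sites)


# ---------------------------------------------------------------------------
# convolution backward


def test_identity_kernel_returns_relevance_in_place(rng):
    x = np.abs(rng.normal(size=(1, 4, 4, 1))) + 0.1
    w = np.zeros((3, 3, 1, 1))
    w[1, 1, 0, 0] = 1.0
    layer = ConvLayerParams(w=w, b=np.zeros(1), stride=1, layer_index=1)
    out, cache = conv_layer_forward(x, layer)
    R_out = rng.random((1, 4, 4, 1))
    R_in = lrp_conv_backward([cache], [layer], R_out.reshape(1, -1), epsilon=1e-9)
    np.testing.assert_allclose(R_in, R_out[..., 0], rtol=1e-6)


def test_zero_input_yields_zero_relevance(rng):
    layer = ConvLayerParams(
        w=rng.normal(size=(3, 3, 1, 2)), b=np.zeros(2), stride=1, layer_index=1
    )
    _, cache = conv_layer_forward(np.zeros((1, 5, 5, 1)), layer)
    R_in = lrp_conv_backward([cache], [layer], rng.normal(size=(1, 50)))
    np.testing.assert_array_equal(R_in, 0.0)


@pytest.mark.parametrize("stride", [1, 2])
def test_conv_backward_matches_unrolled_dense_matrix_oracle(rng, stride):
    """The conv epsilon rule equals the dense epsilon rule on the unrolled
    convolution matrix (relevance to zero-padding discarded)."""
    H = W = 6
    Cout = 2
    x = rng.normal(size=(1, H, W, 1))
    layer = ConvLayerParams(
        w=rng.normal(size=(3, 3, 1, Cout)), b=np.zeros(Cout), stride=stride, layer_index=1
    )
    _, cache = conv_layer_forward(x, layer)
    Ho, pt, _ = same_pad(H, 3, stride)
    Wo, pl, _ = same_pad(W, 3, stride)
    R_out = rng.normal(size=(Ho, Wo, Cout))
    eps = 1e-3

    # dense unrolled convolution matrix: rows = output neurons, cols = input voxels
    M = np.zeros((Ho * Wo * Cout, H * W))
    for io in range(Ho):
        for jo in range(Wo):
            for c in range(Cout):
                row = (io * Wo + jo) * Cout + c
                for ki in range(3):
                    for kj in range(3):
                        ii = io * stride + ki - pt
                        jj = jo * stride + kj - pl
                        if 0 <= ii < H and 0 <= jj < W:
                            M[row, ii * W + jj] += layer.w[ki, kj, 0, c]
    a = x[0, :, :, 0].ravel()
    z_ij = a[None, :] * M
    z_j = z_ij.sum(axis=1)
    denom = z_j + eps * np.where(z_j >= 0, 1.0, -1.0)
    expected = (z_ij / denom[:, None] * R_out.ravel()[:, None]).sum(axis=0).reshape(H, W)

    got = lrp_conv_backward([cache], [layer], R_out.reshape(1, -1), epsilon=eps)
    np.testing.assert_allclose(got[0], expected, atol=1e-8)


# ---------------------------------------------------------------------------
# full decomposition


def test_decomposition_conserves_seed_on_bias_free_model(tiny_model, rng):
    vols = rng.normal(size=(3, 8, 8, 4))
    cache = forward_batch(vols, tiny_model)
    R = decompose_batch(vols, tiny_model, np.array([0, 1, 2]), epsilon=1e-9, cache=cache)
    totals = R.reshape(3, -1).sum(axis=1)
    logits = cache.logits[np.arange(3), [0, 1, 2]]
    np.testing.assert_allclose(totals, logits, rtol=1e-3)


def test_per_layer_conservation_on_bias_free_conv_layers(tiny_model, rng):
    audit = LRPAudit()
    decompose_batch(rng.normal(size=(1, 8, 8, 4)), tiny_model, np.array([1]),
                    epsilon=1e-9, audit=audit)
    for name, (incoming, outgoing, magnitude) in audit.layer_conservation.items():
        assert abs(outgoing - incoming) <= 1e-6 * magnitude, name


def test_zero_output_weights_give_zero_map(tiny_model, rng):
    tiny_model.output.W[...] = 0.0
    result = decompose(rng.normal(size=(8, 8, 4)), tiny_model, target_state=0)
    np.testing.assert_array_equal(result.values, 0.0)
    assert result.logit == 0.0


def test_scaling_the_seed_scales_every_voxel_relevance(tiny_model, rng):
    """Propagation is linear in R: scaling all logits by c scales the map by c."""
    vol = rng.normal(size=(1, 8, 8, 4))
    R1 = decompose_batch(vol, tiny_model, np.array([0]), epsilon=1e-9)
    tiny_model.output.W[...] *= 3.0
    tiny_model.output.b[...] *= 3.0
    R3 = decompose_batch(vol, tiny_model, np.array([0]), epsilon=1e-9)
    np.testing.assert_allclose(R3, 3.0 * R1, rtol=1e-5, atol=1e-10)


def test_relevance_map_metadata(tiny_model, rng):
    result = decompose(rng.normal(size=(8, 8, 4)), tiny_model, target_state=2, tr_index=17)
    assert result.values.shape == (8, 8, 4)
    assert np.isfinite(result.values).all()
    assert result.tr_index == 17
    assert result.target_state == 2
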