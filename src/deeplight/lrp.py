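"""Layer-wise relevance propagation through the slice-sequence decoder.

The decoding decision for a target state is decomposed into per-voxel
contributions by propagating relevance backward through the network:

* weighted connections (the output layer, the LSTM gate projections and the
  convolution layers) use the epsilon rule: the message from upper neuron j
  to lower neuron i is ``z_ij / (z_j + eps * sign(z_j)) * R_j`` with
  ``z_ij = a_i * w_ij`` and ``z_j = sum_i z_ij`` (``sign(0) := +1``);
* multiplicative connections (gate * source, i.e. the cell update
  ``C_s = f * C_{s-1} + i * C'`` and the output ``h_s = o * tanh(C_s)``) pass
  all relevance to the source neuron and none to the sigmoid gate;
* ReLU and tanh nonlinearities pass relevance through unchanged;
* biases absorb no relevance, so conservation (sum of input relevances equals
  the seeded output relevance as eps -> 0) is exact only for bias-free
  layers.

Relevance is seeded at the target state's pre-softmax logit; the softmax
itself is not decomposed (it is monotone per logit, so the attribution of
the logit is the attribution of the decision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ConvCache,
    DeepLightModel,
    ForwardCache,
    KERNEL_SIZE,
    forward_batch,
    scatter_patches,
)

DEFAULT_EPSILON = 0.001


@dataclass
class RelevanceMap:
    """Per-voxel relevance for one decoded volume."""

    values: np.ndarray  # (X, Y, Z)
    target_state: int
    tr_index: int | None = None
    correct: bool | None = None
    logit: float | None = None


@dataclass
class LRPAudit:
    """Instrumentation of the backward pass, for conservation/gate checks."""

    gate_relevance: dict[str, float] = field(default_factory=dict)
    #: name -> (signed incoming, signed outgoing, total |incoming| magnitude)
    layer_conservation: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def record_gate(self, site: str, value: np.ndarray) -> None:
        self.gate_relevance[site] = self.gate_relevance.get(site, 0.0) + float(
            np.abs(value).sum()
        )

    def record_layer(
        self, name: str, incoming: float, outgoing: float, magnitude: float
    ) -> None:
        self.layer_conservation[name] = (incoming, outgoing, magnitude)


def _stabilize(z: np.ndarray, epsilon: float) -> np.ndarray:
    sign = np.where(z >= 0, 1.0, -1.0)  # sign(0) := +1
    return z + epsilon * sign


def lrp_linear(
    inputs: np.ndarray,
    weights: np.ndarray,
    relevance: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Epsilon-rule relevance for a dense layer.

    ``inputs``: (..., I); ``weights``: (I, J); ``relevance``: (..., J) on the
    layer outputs. Returns relevance (..., I) on the inputs. Bias terms take
    no share (``z_j`` is the bias-free sum of the messages).
    """
    z_ij = inputs[..., :, None] * weights  # (..., I, J)
    z_j = z_ij.sum(axis=-2)  # (..., J)
    frac = relevance / _stabilize(z_j, epsilon)
    return (z_ij * frac[..., None, :]).sum(axis=-1)


def lrp_multiplicative(
    gate: np.ndarray, source: np.ndarray, relevance: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gate/source rule: the sigmoid gate gets zero, the source gets all."""
    return np.zeros_like(relevance), relevance.copy()


def lrp_additive_split(
    z1: np.ndarray, z2: np.ndarray, relevance: np.ndarray, epsilon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Epsilon-rule split of relevance between the two terms of a sum."""
    total = _stabilize(z1 + z2, epsilon)
    return z1 / total * relevance, z2 / total * relevance


def seed_relevance(cache: ForwardCache, target_state: int) -> np.ndarray:
    """Top-layer relevance: the target logit at its neuron, zero elsewhere.

    A negative target logit yields a negative seed; downstream consumers flag
    such samples because the evidence-for reading of LRP assumes f(a) > 0.
    """
    B, K = cache.logits.shape
    if not 0 <= target_state < K:
        raise ValueError(f"target_state {target_state} outside 0..{K - 1}")
    seed = np.zeros((B, K))
    seed[:, target_state] = cache.logits[:, target_state]
    return seed


def lrp_lstm_backward(
    cache,
    params,
    relevance_h_final: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    audit: LRPAudit | None = None,
) -> np.ndarray:
    """Backward over one LSTM direction: relevance on final h -> on inputs.

    Per step (latest first): ``h_s = o_s * tanh(C_s)`` sends everything to
    ``C_s`` (gate o zeroed, tanh transparent); ``C_s = f*C_{s-1} + i*C'``
    splits by the epsilon rule between its two additive terms, with the gates
    f and i zeroed; candidate relevance maps onto ``[x_s, h_{s-1}]`` by the
    epsilon rule over the candidate layer's weighted sum; the ``h_{s-1}``
    share merges into the next-earlier step. Returns (S, B, D) relevance on
    the slice representations in this direction's processing order.
    """
    S, B, H = cache.h.shape
    D = cache.x.shape[2]
    Rx = np.zeros((S, B, D))
    Rh = relevance_h_final
    RC = np.zeros((B, H))
    for s in range(S - 1, -1, -1):
        # h_s = o_s * tanh(C_s): multiplicative connection
        gate_R, source_R = lrp_multiplicative(cache.o[s], cache.tanhC[s], Rh)
        if audit is not None:
            audit.record_gate(f"o[{s}]", gate_R)
        RC = RC + source_R  # tanh passes relevance unchanged
        # C_s = f*C_{s-1} + i*C': additive split, then gate/source per term
        C_prev = cache.C[s - 1] if s > 0 else np.zeros((B, H))
        z_forget = cache.f[s] * C_prev
        z_input = cache.i[s] * cache.cbar[s]
        R_forget, R_input = lrp_additive_split(z_forget, z_input, RC, epsilon)
        gf, RC_prev = lrp_multiplicative(cache.f[s], C_prev, R_forget)
        gi, R_cbar = lrp_multiplicative(cache.i[s], cache.cbar[s], R_input)
        if audit is not None:
            audit.record_gate(f"f[{s}]", gf)
            audit.record_gate(f"i[{s}]", gi)
        # C' = tanh(Wc x_s + Uc h_{s-1} + bc): epsilon rule over [x, h_prev]
        h_prev = cache.h[s - 1] if s > 0 else np.zeros((B, H))
        stacked = np.concatenate([cache.x[s], h_prev], axis=1)  # (B, D+H)
        W_stacked = np.concatenate([params.W["c"], params.U["c"]], axis=0)
        R_stacked = lrp_linear(stacked, W_stacked, R_cbar, epsilon)
        Rx[s] = R_stacked[:, :D]
        Rh = R_stacked[:, D:]
        RC = RC_prev
    return Rx


def lrp_conv_backward(
    conv_caches: list[ConvCache],
    conv_stack,
    relevance_flat: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    audit: LRPAudit | None = None,
) -> np.ndarray:
    """Backward through the conv stack for a batch of slices.

    ``relevance_flat``: (B, D) on the flattened final activation. The epsilon
    rule runs per output position over its receptive field; relevance landing
    on zero-padding is discarded; ReLU is transparent. Returns (B, H, W)
    relevance on the input slices.
    """
    R = relevance_flat.reshape(conv_caches[-1].out.shape)
    for layer, cache in zip(reversed(conv_stack), reversed(conv_caches)):
        B, Ho, Wo, Cout = R.shape
        kkC = cache.patches.shape[-1]
        wmat = layer.w.reshape(kkC, Cout)
        z_j = cache.patches @ wmat  # bias-free pre-activation (B, Ho, Wo, Cout)
        frac = R / _stabilize(z_j, epsilon)
        # messages z_ij * frac summed over output channels at each position
        dpatches = np.einsum("bhwk,kc,bhwc->bhwk", cache.patches, wmat, frac)
        R_in = scatter_patches(dpatches, cache, KERNEL_SIZE)
        if audit is not None:
            audit.record_layer(
                f"conv{layer.layer_index}",
                float(R.sum()),
                float(R_in.sum()),
                float(np.abs(R).sum()),
            )
        R = R_in
    return R[..., 0]


def decompose_batch(
    volumes: np.ndarray,
    model: DeepLightModel,
    target_states: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    cache: ForwardCache | None = None,
    audit: LRPAudit | None = None,
) -> np.ndarray:
    """Per-voxel relevance maps for a batch of volumes (B, X, Y, Z).

    ``target_states`` holds one class index per volume (typically the true
    state of a correctly decoded sample).
    """
    if volumes.ndim == 3:
        volumes = volumes[None]
    if cache is None:
        cache = forward_batch(volumes, model)
    B, X, Y, Z = volumes.shape
    target_states = np.broadcast_to(np.asarray(target_states), (B,))
    seeds = np.zeros_like(cache.logits)
    seeds[np.arange(B), target_states] = cache.logits[np.arange(B), target_states]
    # output layer: epsilon rule over the concatenated final-step h
    R_concat = lrp_linear(cache.concat, model.output.W, seeds, epsilon)
    H = model.lstm_fwd.hidden_size
    R_fwd = lrp_lstm_backward(cache.lstm_fwd, model.lstm_fwd, R_concat[:, :H], epsilon, audit)
    R_bwd = lrp_lstm_backward(cache.lstm_bwd, model.lstm_bwd, R_concat[:, H:], epsilon, audit)
    R_seq = R_fwd + R_bwd[::-1]  # back to inferior->superior order, (S, B, D)
    S = R_seq.shape[0]
    D = R_seq.shape[2]
    R_flat = R_seq.transpose(1, 0, 2).reshape(B * S, D)
    R_slices = lrp_conv_backward(cache.conv_flat, model.conv_stack, R_flat, epsilon, audit)
    # (B*S, X, Y) -> (B, X, Y, Z)
    return R_slices.reshape(B, S, X, Y).transpose(0, 2, 3, 1)


def decompose(
    volume3d: np.ndarray,
    model: DeepLightModel,
    target_state: int,
    epsilon: float = DEFAULT_EPSILON,
    tr_index: int | None = None,
    audit: LRPAudit | None = None,
) -> RelevanceMap:
    """Decompose one decoding decision into a per-voxel relevance map."""
    cache = forward_batch(volume3d[None], model)
    if not 0 <= target_state < model.n_states:
        raise ValueError("invalid target state")
    values = decompose_batch(
        volume3d[None], model, np.array([target_state]), epsilon, cache=cache, audit=audit
    )[0]
    predicted = int(np.argmax(cache.probabilities[0]))
    return RelevanceMap(
        values=values,
        target_state=target_state,
        tr_index=tr_index,
        correct=predicted == target_state,
        logit=float(cache.logits[0, target_state]),
    )
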