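"""Slice-sequence convolutional-recurrent decoder.

A whole-brain volume is separated into its sequence of axial slices
(inferior -> superior). Each slice passes through an eight-layer
convolutional feature extractor (conv3-16 x4 then conv3-32 x4; 3x3 kernels,
SAME zero-padding; stride 2 on odd-numbered layers, stride 1 on
even-numbered layers; ReLU activations), producing one flattened
representation per slice. A bi-directional LSTM (two independent units, one
iterating bottom-to-top and one top-to-bottom, 40 output neurons each by
default) integrates the slice sequence; the final-step outputs of the two
directions are concatenated and mapped by a fully-connected softmax layer to
one probability per cognitive state.

Everything is implemented in numpy with an explicit forward cache, because
both training (backpropagation) and layer-wise relevance propagation need
access to every intermediate activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

CONV_CHANNELS = (16, 16, 16, 16, 32, 32, 32, 32)
CONV_STRIDES = (2, 1, 2, 1, 2, 1, 2, 1)  # odd-numbered layers (1-based) stride 2
KERNEL_SIZE = 3


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ConvLayerParams:
    w: np.ndarray  # (k, k, in_channels, out_channels)
    b: np.ndarray  # (out_channels,)
    stride: int
    layer_index: int  # 1-based

    @property
    def out_channels(self) -> int:
        return self.w.shape[-1]


@dataclass
class LSTMParams:
    """Gate parameters of one LSTM direction.

    Gates: forget ``f``, input ``i``, candidate ``c`` (tanh layer), output
    ``o``; each has an input projection ``W`` (D x H), a recurrent projection
    ``U`` (H x H) and a bias ``b`` (H,).
    """

    W: dict[str, np.ndarray]
    U: dict[str, np.ndarray]
    b: dict[str, np.ndarray]
    direction: str = "bottom-up"  # or "top-down"

    @property
    def hidden_size(self) -> int:
        return self.W["f"].shape[1]

    @property
    def input_size(self) -> int:
        return self.W["f"].shape[0]


@dataclass
class OutputParams:
    W: np.ndarray  # (2H, K)
    b: np.ndarray  # (K,)

    @property
    def n_states(self) -> int:
        return self.W.shape[1]


@dataclass
class DeepLightModel:
    conv_stack: list[ConvLayerParams]
    lstm_fwd: LSTMParams
    lstm_bwd: LSTMParams
    output: OutputParams
    input_slice_shape: tuple[int, int]

    @property
    def n_states(self) -> int:
        return self.output.n_states

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for layer in self.conv_stack:
            params[f"conv{layer.layer_index}.w"] = layer.w
            params[f"conv{layer.layer_index}.b"] = layer.b
        for name, lstm in (("lstm_fwd", self.lstm_fwd), ("lstm_bwd", self.lstm_bwd)):
            for g in "fico":
                params[f"{name}.W_{g}"] = lstm.W[g]
                params[f"{name}.U_{g}"] = lstm.U[g]
                params[f"{name}.b_{g}"] = lstm.b[g]
        params["output.W"] = self.output.W
        params["output.b"] = self.output.b
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        current = self.parameters()
        for key, value in params.items():
            current[key][...] = value


# ---------------------------------------------------------------------------
# activation primitives


def logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# convolution with SAME zero-padding under stride


def same_pad(n: int, k: int, stride: int) -> tuple[int, int, int]:
    """Output length and (before, after) zero-padding for SAME convolution.

    Output length is ceil(n / stride) — equal to the input for stride 1 —
    which is the only padding convention consistent with a 74 x 92 slice
    reducing to 5 x 6 after four stride-2 layers.
    """
    out = ceil(n / stride)
    pad = max((out - 1) * stride + k - n, 0)
    return out, pad // 2, pad - pad // 2


def conv_output_shape(in_shape: tuple[int, int], stride: int) -> tuple[int, int]:
    return (ceil(in_shape[0] / stride), ceil(in_shape[1] / stride))


@dataclass
class ConvCache:
    """Per-layer forward cache: everything LRP / backprop needs."""

    x: np.ndarray  # layer input (B, H, W, Cin)
    patches: np.ndarray  # (B, Ho, Wo, k*k*Cin) im2col view of padded input
    pre: np.ndarray  # pre-activation (B, Ho, Wo, Cout)
    out: np.ndarray  # post-ReLU (possibly post-dropout) output
    pad: tuple[tuple[int, int], tuple[int, int]]
    padded_shape: tuple[int, int]
    scatter_idx: np.ndarray  # (Ho*Wo*k*k,) flat indices into padded plane
    dropout_mask: np.ndarray | None = None


def _extract_patches(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    # xp: (B, Hp, Wp, Cin) -> (B, Ho, Wo, k*k*Cin), layout (k, k, Cin)
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B, Hp-k+1, Wp-k+1, Cin, k, k)
    win = win[:, ::stride, ::stride]
    B, Ho, Wo = win.shape[:3]
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(B, Ho, Wo, -1), (Ho, Wo)


def _patch_scatter_index(Hp: int, Wp: int, Ho: int, Wo: int, k: int, stride: int) -> np.ndarray:
    ho = np.arange(Ho)[:, None, None, None]
    wo = np.arange(Wo)[None, :, None, None]
    di = np.arange(k)[None, None, :, None]
    dj = np.arange(k)[None, None, None, :]
    return ((ho * stride + di) * Wp + (wo * stride + dj)).ravel()


def conv_layer_forward(
    x: np.ndarray,
    params: ConvLayerParams,
    cache: bool = True,
) -> tuple[np.ndarray, ConvCache | None]:
    """Cross-correlate kernels over the zero-padded input, then ReLU.

    ``x`` is (B, H, W, Cin); output (B, ceil(H/s), ceil(W/s), Cout) >= 0.
    """
    if x.ndim == 2:
        x = x[None, :, :, None]
    elif x.ndim == 3:
        x = x[None]
    k = params.w.shape[0]
    if x.shape[-1] != params.w.shape[2]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[-1]}, kernel expects {params.w.shape[2]}"
        )
    B, H, W, Cin = x.shape
    Ho, pt, pb = same_pad(H, k, params.stride)
    Wo, pl, pr = same_pad(W, k, params.stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    patches, _ = _extract_patches(xp, k, params.stride)
    wmat = params.w.reshape(-1, params.out_channels)
    pre = patches @ wmat + params.b
    out = np.maximum(pre, 0.0)
    if not cache:
        return out, None
    idx = _patch_scatter_index(xp.shape[1], xp.shape[2], Ho, Wo, k, params.stride)
    return out, ConvCache(
        x=x,
        patches=patches,
        pre=pre,
        out=out,
        pad=((pt, pb), (pl, pr)),
        padded_shape=(xp.shape[1], xp.shape[2]),
        scatter_idx=idx,
    )


def scatter_patches(
    dpatches: np.ndarray, cache: ConvCache, k: int
) -> np.ndarray:
    """col2im: accumulate per-patch values back onto the (unpadded) input."""
    B, Ho, Wo, kkC = dpatches.shape
    Cin = kkC // (k * k)
    Hp, Wp = cache.padded_shape
    flat = np.zeros((Hp * Wp, B * Cin))
    vals = (
        dpatches.reshape(B, Ho * Wo, k * k, Cin)
        .transpose(1, 2, 0, 3)
        .reshape(Ho * Wo * k * k, B * Cin)
    )
    np.add.at(flat, cache.scatter_idx, vals)
    dxp = flat.reshape(Hp, Wp, B, Cin).transpose(2, 0, 1, 3)
    (pt, pb), (pl, pr) = cache.pad
    H = Hp - pt - pb
    W = Wp - pl - pr
    return dxp[:, pt : pt + H, pl : pl + W, :]


# ---------------------------------------------------------------------------
# feature extractor


def feature_extract(
    slices: np.ndarray,
    conv_stack: list[ConvLayerParams],
    cache: bool = False,
    dropout_rates: list[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[ConvCache] | None]:
    """Run images through the conv stack; return flattened representations.

    ``slices``: (B, H, W) or (B, H, W, 1). Returns (B, D) with
    D = prod(final spatial shape) * final channels. With inverted dropout
    rates given (training), each layer's output is masked and rescaled.
    """
    x = slices[..., None] if slices.ndim == 3 else slices
    caches: list[ConvCache] = []
    for li, layer in enumerate(conv_stack):
        x, c = conv_layer_forward(x, layer, cache=True)
        if dropout_rates is not None and dropout_rates[li] > 0:
            keep = 1.0 - dropout_rates[li]
            mask = (rng.random(x.shape) < keep) / keep
            x = x * mask
            c.dropout_mask = mask
            c.out = x
        caches.append(c)
    B = x.shape[0]
    flat = x.reshape(B, -1)
    return (flat, caches) if cache else (flat, None)


def feature_dim(input_slice_shape: tuple[int, int], conv_stack: list[ConvLayerParams]) -> int:
    shape = tuple(input_slice_shape)
    for layer in conv_stack:
        shape = conv_output_shape(shape, layer.stride)
    return shape[0] * shape[1] * conv_stack[-1].out_channels


# ---------------------------------------------------------------------------
# LSTM


@dataclass
class LSTMCache:
    """Per-direction cache over the slice sequence (step arrays are (S, B, H))."""

    x: np.ndarray  # inputs in processing order (S, B, D)
    f: np.ndarray
    i: np.ndarray
    o: np.ndarray
    cbar: np.ndarray
    C: np.ndarray  # cell states C_1..C_S
    h: np.ndarray  # outputs h_1..h_S
    tanhC: np.ndarray


def lstm_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
    params: LSTMParams,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """One gated update.

    f, i, o = logistic(W a + U h_prev + b); C' = tanh(Wc a + Uc h_prev + bc);
    C = f * C_prev + i * C'; h = o * tanh(C).
    """
    gates = {
        g: x @ params.W[g] + h_prev @ params.U[g] + params.b[g] for g in "fico"
    }
    f = logistic(gates["f"])
    i = logistic(gates["i"])
    o = logistic(gates["o"])
    cbar = np.tanh(gates["c"])
    C = f * C_prev + i * cbar
    tanhC = np.tanh(C)
    h = o * tanhC
    return h, C, {"f": f, "i": i, "o": o, "cbar": cbar, "tanhC": tanhC}


def lstm_forward(
    seq: np.ndarray, params: LSTMParams
) -> tuple[np.ndarray, LSTMCache]:
    """Run one direction over a sequence (S, B, D); returns final h and cache.

    The caller passes the sequence already in this direction's processing
    order (the top-down unit receives the reversed slice sequence).
    """
    S, B, _ = seq.shape
    H = params.hidden_size
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    store = {k: np.empty((S, B, H)) for k in ("f", "i", "o", "cbar", "C", "h", "tanhC")}
    for s in range(S):
        h, C, aux = lstm_step(seq[s], h, C, params)
        for k in ("f", "i", "o", "cbar", "tanhC"):
            store[k][s] = aux[k]
        store["C"][s] = C
        store["h"][s] = h
    cache = LSTMCache(
        x=seq,
        f=store["f"],
        i=store["i"],
        o=store["o"],
        cbar=store["cbar"],
        C=store["C"],
        h=store["h"],
        tanhC=store["tanhC"],
    )
    return h, cache


# ---------------------------------------------------------------------------
# volume-level forward pass


def slice_volume(volume3d: np.ndarray) -> np.ndarray:
    """Separate an (X, Y, Z) volume into its Z axial slices, inferior->superior.

    Returns (Z, X, Y); ``np.stack(slices, axis=-1)`` restacks exactly.
    """
    if volume3d.ndim != 3:
        raise ValueError("expected a 3D volume")
    return np.moveaxis(volume3d, -1, 0)


@dataclass
class ForwardCache:
    conv: list[list[ConvCache]] | None  # per volume in batch? see forward()
    conv_flat: list[ConvCache]  # conv caches over the (B*S) slice batch
    features: np.ndarray  # (B, S, D) slice representations
    lstm_fwd: LSTMCache
    lstm_bwd: LSTMCache
    concat: np.ndarray  # (B, 2H) final-step outputs [fwd, bwd]
    logits: np.ndarray  # (B, K)
    probabilities: np.ndarray  # (B, K)
    dropout_concat: np.ndarray | None = None


def forward_batch(
    volumes: np.ndarray,
    model: DeepLightModel,
    training: bool = False,
    dropout: "object | None" = None,
    rng: np.random.Generator | None = None,
) -> ForwardCache:
    """Forward pass on a batch of volumes (B, X, Y, Z).

    Inference mode (default) is deterministic; training mode applies
    inverted dropout per the configured schedule.
    """
    if volumes.ndim == 3:
        volumes = volumes[None]
    B, X, Y, Z = volumes.shape
    if (X, Y) != tuple(model.input_slice_shape):
        raise ValueError(
            f"slice shape {(X, Y)} does not match model input {model.input_slice_shape}"
        )
    slices = np.moveaxis(volumes, -1, 1).reshape(B * Z, X, Y)  # (B*Z, X, Y)
    conv_rates = lstm_rate = out_rate = None
    if training and dropout is not None:
        conv_rates = list(dropout.conv_rates)
        lstm_rate = dropout.lstm_rate
        out_rate = dropout.output_rate
    feats, conv_caches = feature_extract(
        slices, model.conv_stack, cache=True, dropout_rates=conv_rates, rng=rng
    )
    D = feats.shape[1]
    seq = feats.reshape(B, Z, D).transpose(1, 0, 2)  # (S, B, D), inferior->superior
    h_fwd, cache_fwd = lstm_forward(seq, model.lstm_fwd)
    h_bwd, cache_bwd = lstm_forward(seq[::-1], model.lstm_bwd)
    concat = np.concatenate([h_fwd, h_bwd], axis=1)
    dropout_concat = None
    if training and lstm_rate:
        keep = 1.0 - lstm_rate
        dropout_concat = (rng.random(concat.shape) < keep) / keep
        concat = concat * dropout_concat
    logits = concat @ model.output.W + model.output.b
    probs = softmax(logits, axis=1)
    return ForwardCache(
        conv=None,
        conv_flat=conv_caches,
        features=seq.transpose(1, 0, 2),
        lstm_fwd=cache_fwd,
        lstm_bwd=cache_bwd,
        concat=concat,
        logits=logits,
        probabilities=probs,
        dropout_concat=dropout_concat,
    )


def forward(volume3d: np.ndarray, model: DeepLightModel) -> tuple[np.ndarray, ForwardCache]:
    """State probabilities for one volume, plus the cached activations."""
    cache = forward_batch(volume3d[None], model)
    return cache.probabilities[0], cache


def decode(volume3d: np.ndarray, model: DeepLightModel) -> int:
    """Predicted state index (argmax probability; ties -> lowest index)."""
    probs, _ = forward(volume3d, model)
    return int(np.argmax(probs))


def decode_batch(volumes: np.ndarray, model: DeepLightModel, batch_size: int = 64) -> np.ndarray:
    preds = []
    for start in range(0, len(volumes), batch_size):
        cache = forward_batch(volumes[start : start + batch_size], model)
        preds.append(np.argmax(cache.probabilities, axis=1))
    return np.concatenate(preds)


# ---------------------------------------------------------------------------
# construction and checkpointing


def glorot_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=shape)


def build_model(
    input_slice_shape: tuple[int, int],
    n_slices: int | None = None,
    n_states: int = 4,
    hidden_size: int = 40,
    conv_channels: tuple[int, ...] = CONV_CHANNELS,
    conv_strides: tuple[int, ...] = CONV_STRIDES,
    seed: int = 0,
    zero_bias: bool = True,
) -> DeepLightModel:
    """Glorot-normal initialized model (biases zero), deterministic per seed."""
    rng = np.random.default_rng(seed)
    k = KERNEL_SIZE
    conv_stack = []
    cin = 1
    for idx, (cout, stride) in enumerate(zip(conv_channels, conv_strides), start=1):
        fan_in = k * k * cin
        fan_out = k * k * cout
        conv_stack.append(
            ConvLayerParams(
                w=glorot_normal(rng, (k, k, cin, cout), fan_in, fan_out),
                b=np.zeros(cout),
                stride=stride,
                layer_index=idx,
            )
        )
        cin = cout
    D = feature_dim(input_slice_shape, conv_stack)
    lstms = {}
    for direction in ("bottom-up", "top-down"):
        W = {g: glorot_normal(rng, (D, hidden_size), D, hidden_size) for g in "fico"}
        U = {
            g: glorot_normal(rng, (hidden_size, hidden_size), hidden_size, hidden_size)
            for g in "fico"
        }
        b = {g: np.zeros(hidden_size) for g in "fico"}
        lstms[direction] = LSTMParams(W=W, U=U, b=b, direction=direction)
    out_W = glorot_normal(rng, (2 * hidden_size, n_states), 2 * hidden_size, n_states)
    output = OutputParams(W=out_W, b=np.zeros(n_states))
    return DeepLightModel(
        conv_stack=conv_stack,
        lstm_fwd=lstms["bottom-up"],
        lstm_bwd=lstms["top-down"],
        output=output,
        input_slice_shape=tuple(input_slice_shape),
    )


def save_checkpoint(path, model: DeepLightModel) -> None:
    """Single-archive checkpoint: parameter tensors + architecture descriptor."""
    import json

    arch = {
        "input_slice_shape": list(model.input_slice_shape),
        "n_states": model.n_states,
        "hidden_size": model.lstm_fwd.hidden_size,
        "conv_channels": [l.out_channels for l in model.conv_stack],
        "conv_strides": [l.stride for l in model.conv_stack],
    }
    np.savez(
        path,
        __arch__=np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8),
        **model.parameters(),
    )


def load_checkpoint(path) -> DeepLightModel:
    import json

    with np.load(path) as data:
        arch = json.loads(bytes(data["__arch__"]).decode())
        params = {k: data[k] for k in data.files if k != "__arch__"}
    model = build_model(
        input_slice_shape=tuple(arch["input_slice_shape"]),
        n_states=arch["n_states"],
        hidden_size=arch["hidden_size"],
        conv_channels=tuple(arch["conv_channels"]),
        conv_strides=tuple(arch["conv_strides"]),
    )
    model.set_parameters(params)
    return model
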