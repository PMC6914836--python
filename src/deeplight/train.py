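"""Training by backpropagation.

Categorical cross-entropy over the softmax outputs, minimized with ADAM
(default learning rate 1e-4, batch size 32, up to 60 epochs), global
gradient-norm clipping at threshold 5, inverted dropout on all layers
(drop probability 30% on conv layers 1-2, 40% on conv layers 3-4, 50%
everywhere else), and early stopping on validation cross-entropy with
best-weight restore. All randomness (shuffling, dropout masks) flows from
the config seed, so fixed-seed runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ConvCache,
    DeepLightModel,
    ForwardCache,
    KERNEL_SIZE,
    build_model,
    forward_batch,
    scatter_patches,
)

logger = logging.getLogger(__name__)


@dataclass
class DropoutSchedule:
    """Per-layer drop probabilities (conv layers 1-8, LSTM outputs, output input)."""

    conv_rates: tuple[float, ...] = (0.3, 0.3, 0.4, 0.4, 0.5, 0.5, 0.5, 0.5)
    lstm_rate: float = 0.5
    output_rate: float = 0.5  # folded into lstm_rate site (concat vector)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 60
    clip_norm: float = 5.0
    dropout: DropoutSchedule | None = field(default_factory=DropoutSchedule)
    patience: int = 5  # early stopping on validation loss
    validation_fraction: float = 0.2
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate:
            raise ValueError("learning_rate must be positive")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gradients


def clip_gradients(
    gradients: dict[str, np.ndarray], threshold: float
) -> dict[str, np.ndarray]:
    """Global L2-norm clipping: scale all gradients so the norm is <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    total = np.sqrt(sum(float(np.sum(g * g)) for g in gradients.values()))
    if total <= threshold or total == 0.0:
        return gradients
    scale = threshold / total
    return {k: g * scale for k, g in gradients.items()}


def global_norm(gradients: dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float(np.sum(g * g)) for g in gradients.values())))


def _lstm_backward(
    cache, params, d_h_final: np.ndarray, name: str, grads: dict[str, np.ndarray]
) -> np.ndarray:
    """BPTT through one direction; returns gradient on the input sequence (S,B,D)."""
    S, B, H = cache.h.shape
    D = cache.x.shape[2]
    dx = np.zeros((S, B, D))
    dh_next = d_h_final.copy()
    dC_next = np.zeros((B, H))
    for s in range(S - 1, -1, -1):
        h_prev = cache.h[s - 1] if s > 0 else np.zeros((B, H))
        C_prev = cache.C[s - 1] if s > 0 else np.zeros((B, H))
        f, i, o, cbar, tanhC = (
            cache.f[s],
            cache.i[s],
            cache.o[s],
            cache.cbar[s],
            cache.tanhC[s],
        )
        dh = dh_next
        do = dh * tanhC
        dC = dC_next + dh * o * (1.0 - tanhC**2)
        df = dC * C_prev
        di = dC * cbar
        dcbar = dC * i
        dC_next = dC * f
        dpre = {
            "f": df * f * (1.0 - f),
            "i": di * i * (1.0 - i),
            "o": do * o * (1.0 - o),
            "c": dcbar * (1.0 - cbar**2),
        }
        dh_next = np.zeros((B, H))
        x_s = cache.x[s]
        for g, dg in dpre.items():
            grads[f"{name}.W_{g}"] += x_s.T @ dg
            grads[f"{name}.U_{g}"] += h_prev.T @ dg
            grads[f"{name}.b_{g}"] += dg.sum(axis=0)
            dx[s] += dg @ params.W[g].T
            dh_next += dg @ params.U[g].T
    return dx


def _conv_backward(
    dflat: np.ndarray,
    conv_caches: list[ConvCache],
    model: DeepLightModel,
    grads: dict[str, np.ndarray],
) -> None:
    """Backward through the conv stack for the (B*S) slice batch."""
    x = conv_caches[-1].out
    dout = dflat.reshape(x.shape)
    for layer, cache in zip(reversed(model.conv_stack), reversed(conv_caches)):
        if cache.dropout_mask is not None:
            dout = dout * cache.dropout_mask
        dpre = dout * (cache.pre > 0)
        B, Ho, Wo, Cout = dpre.shape
        kkC = cache.patches.shape[-1]
        dpre_flat = dpre.reshape(-1, Cout)
        grads[f"conv{layer.layer_index}.w"] += (
            cache.patches.reshape(-1, kkC).T @ dpre_flat
        ).reshape(layer.w.shape)
        grads[f"conv{layer.layer_index}.b"] += dpre_flat.sum(axis=0)
        wmat = layer.w.reshape(kkC, Cout)
        dpatches = dpre @ wmat.T  # (B, Ho, Wo, kkC)
        dout = scatter_patches(dpatches, cache, KERNEL_SIZE)


def loss_and_gradients(
    volumes: np.ndarray,
    labels: np.ndarray,
    model: DeepLightModel,
    training: bool = False,
    dropout: DropoutSchedule | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray], ForwardCache]:
    """Mean cross-entropy and gradients for a batch of labeled volumes."""
    cache = forward_batch(volumes, model, training=training, dropout=dropout, rng=rng)
    B = len(labels)
    probs = cache.probabilities
    loss = float(-np.mean(np.log(np.clip(probs[np.arange(B), labels], 1e-300, None))))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")

    grads = {k: np.zeros_like(v) for k, v in model.parameters().items()}
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    grads["output.W"] += cache.concat.T @ dlogits
    grads["output.b"] += dlogits.sum(axis=0)
    dconcat = dlogits @ model.output.W.T
    if cache.dropout_concat is not None:
        dconcat = dconcat * cache.dropout_concat
    H = model.lstm_fwd.hidden_size
    dx_fwd = _lstm_backward(cache.lstm_fwd, model.lstm_fwd, dconcat[:, :H], "lstm_fwd", grads)
    dx_bwd = _lstm_backward(cache.lstm_bwd, model.lstm_bwd, dconcat[:, H:], "lstm_bwd", grads)
    dseq = dx_fwd + dx_bwd[::-1]  # top-down unit saw the reversed sequence
    S, Bv, D = dseq.shape
    dflat = dseq.transpose(1, 0, 2).reshape(Bv * S, D)
    _conv_backward(dflat, cache.conv_flat, model, grads)
    return loss, grads, cache


# ---------------------------------------------------------------------------
# optimizer and loop


class Adam:
    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.config = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.config
        self.t += 1
        b1t = 1.0 - c.adam_beta1**self.t
        b2t = 1.0 - c.adam_beta2**self.t
        for k, g in grads.items():
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_epsilon)


def init_weights(
    input_slice_shape: tuple[int, int],
    n_states: int = 4,
    hidden_size: int = 40,
    seed: int = 0,
    **kwargs,
) -> DeepLightModel:
    """Glorot-normal initialized model (weights var 2/(fan_in+fan_out), biases 0)."""
    return build_model(
        input_slice_shape=input_slice_shape,
        n_states=n_states,
        hidden_size=hidden_size,
        seed=seed,
        **kwargs,
    )


def evaluate_loss(volumes, labels, model, batch_size=64) -> tuple[float, float]:
    losses = []
    correct = 0
    for start in range(0, len(labels), batch_size):
        sl = slice(start, start + batch_size)
        cache = forward_batch(volumes[sl], model)
        p = cache.probabilities
        idx = np.arange(len(labels[sl]))
        losses.append(-np.log(np.clip(p[idx, labels[sl]], 1e-300, None)))
        correct += int(np.sum(np.argmax(p, axis=1) == labels[sl]))
    all_losses = np.concatenate(losses)
    return float(all_losses.mean()), correct / len(labels)


def train(
    volumes: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    model: DeepLightModel,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[DeepLightModel, TrainHistory]:
    """Fit the model on labeled task volumes (rest TRs excluded upstream).

    When no validation split is given, a stratified fraction is carved from
    the training data. Stops early when validation loss has not improved for
    ``config.patience`` epochs and restores the best weights.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    rng = np.random.default_rng(config.seed)
    if validation is None and config.validation_fraction > 0:
        val_idx = []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            n_val = max(1, int(round(config.validation_fraction * len(idx))))
            val_idx.extend(idx[:n_val])
        val_idx = np.sort(np.array(val_idx))
        train_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
        validation = (volumes[val_idx], labels[val_idx])
        volumes, labels = volumes[train_idx], labels[train_idx]

    history = TrainHistory()
    params = model.parameters()
    optimizer = Adam(params, config)
    best_val = np.inf
    best_params = None
    stall = 0
    n = len(labels)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads, _ = loss_and_gradients(
                volumes[batch],
                labels[batch],
                model,
                training=config.dropout is not None,
                dropout=config.dropout,
                rng=rng,
            )
            grads = clip_gradients(grads, config.clip_norm)
            optimizer.step(params, grads)
            epoch_losses.append(loss)
        train_loss, train_acc = evaluate_loss(volumes, labels, model)
        history.train_loss.append(train_loss)
        history.train_accuracy.append(train_acc)
        if validation is not None:
            val_loss, val_acc = evaluate_loss(validation[0], validation[1], model)
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
            logger.info(
                "epoch %d: train_loss=%.4f val_loss=%.4f val_acc=%.3f",
                epoch,
                train_loss,
                val_loss,
                val_acc,
            )
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    logger.info("early stopping at epoch %d", epoch)
                    break
        else:
            logger.info("epoch %d: train_loss=%.4f", epoch, train_loss)
    if best_params is not None:
        model.set_parameters(best_params)
    return model, history


def task_samples(
    volume_data: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop rest TRs: returns (volumes, labels) for labeled task samples only."""
    keep = labels >= 0
    return volume_data[keep], labels[keep]
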