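"""Decoding metrics and voxelwise map-similarity (F1) scoring.

The F1 map score compares a thresholded source brain map against a target
ROI mask voxel by voxel: a kept source voxel inside the target is a true
positive, outside a false positive, and a missed target voxel a false
negative. Precision = TP/(TP+FP), recall = TP/(TP+FN), and F1 is their
harmonic mean — by construction invariant to the number of true-negative
voxels, hence robust to ROI size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def confusion_matrix(true_labels, predicted_labels, n_states: int) -> np.ndarray:
    """K x K counts; entry (i, j) = samples of true state i predicted as j."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must align")
    if np.any((t < 0) | (t >= n_states)) or np.any((p < 0) | (p >= n_states)):
        raise ValueError(f"labels outside 0..{n_states - 1}")
    counts = np.zeros((n_states, n_states), dtype=int)
    np.add.at(counts, (t, p), 1)
    return counts


def accuracy(true_labels, predicted_labels) -> float:
    t = np.asarray(true_labels)
    return float(np.mean(t == np.asarray(predicted_labels)))


def accuracy_time_course(
    correct: np.ndarray,
    block_onsets: list[tuple[float, int]],
    tr: float,
    block_length: float,
) -> np.ndarray:
    """Mean correctness per within-block TR offset, pooled over blocks.

    Offset 0 is the first TR at or after each block's onset; offsets are
    indexed in TR steps.
    """
    correct = np.asarray(correct, dtype=float)
    n_offsets = int(np.ceil(block_length / tr))
    sums = np.zeros(n_offsets)
    counts = np.zeros(n_offsets)
    n = len(correct)
    for onset, _ in block_onsets:
        first = int(np.ceil(onset / tr - 1e-9))
        for o in range(n_offsets):
            idx = first + o
            if idx >= n or (idx * tr) >= onset + block_length - 1e-9:
                break
            sums[o] += correct[idx]
            counts[o] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def hrf_window_mask(
    labels: np.ndarray,
    block_onsets: list[tuple[float, int]],
    tr: float,
    window: tuple[float, float] = (5.0, 15.0),
) -> np.ndarray:
    """Boolean mask of TRs acquired ``window`` seconds after their block onset.

    These are the hemodynamically valid samples of a block design: the BOLD
    response to a block is near zero for the first seconds after onset, so
    decoding accuracy is reported both over all task TRs and over this window.
    """
    labels = np.asarray(labels)
    times = np.arange(len(labels)) * tr
    mask = np.zeros(len(labels), dtype=bool)
    for onset, state in block_onsets:
        lo, hi = onset + window[0], onset + window[1]
        mask |= (times >= lo - 1e-9) & (times <= hi + 1e-9) & (labels == state)
    return mask


@dataclass
class F1Result:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def map_f1(
    source: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray | None = None,
) -> F1Result:
    """Voxelwise F1 between a thresholded source map and a target ROI mask.

    ``source`` is a thresholded map (voxel associated iff value != 0 after
    thresholding) or a boolean mask; ``target`` is a boolean mask. Voxels
    outside ``mask`` are excluded from every count.
    """
    src = np.asarray(source)
    src_assoc = src if src.dtype == bool else src > 0
    tgt = np.asarray(target).astype(bool)
    if src_assoc.shape != tgt.shape:
        raise ValueError("source and target shapes differ")
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        src_assoc = src_assoc & m
        tgt = tgt & m
    tp = int(np.sum(src_assoc & tgt))
    fp = int(np.sum(src_assoc & ~tgt))
    fn = int(np.sum(~src_assoc & tgt))
    if tp + fp == 0 and tp + fn == 0:
        return F1Result(0, 0, 0, 0.0, 0.0, 0.0, degenerate=True)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return F1Result(tp, fp, fn, precision, recall, f1)
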