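"""Aggregation of per-TR relevance maps into subject- and group-level maps.

Only TRs that were decoded correctly and acquired 5-15 s after their block's
onset (where the hemodynamic response is strongest) are decomposed. Each
selected relevance map is smoothed with a 3 mm FWHM Gaussian and averaged
within cognitive state, giving one map per subject x state; group maps are
the voxelwise mean of the subject maps. Maps are thresholded at the 90th
percentile of their (by default positive) in-mask values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import FWHM_TO_SIGMA, BrainMask

LEVELS = ("tr", "block", "subject", "group")


@dataclass
class BrainMap:
    values: np.ndarray  # (X, Y, Z)
    level: str  # tr | block | subject | group
    state: int
    mask: BrainMask | None = None
    threshold: float | None = None
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")

    def in_mask_values(self) -> np.ndarray:
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask.mask]


def select_decomposable(
    predictions: np.ndarray,
    labels: np.ndarray,
    block_onsets: list[tuple[float, int]],
    tr: float,
    window: tuple[float, float] = (5.0, 15.0),
) -> np.ndarray:
    """Indices of TRs to decompose: correctly classified, in the HRF window.

    A TR acquired at ``index * tr`` qualifies if its block's onset satisfies
    ``onset + window[0] <= time <= onset + window[1]`` (endpoints inclusive)
    and prediction equals label.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must align")
    times = np.arange(len(labels)) * tr
    in_window = np.zeros(len(labels), dtype=bool)
    for onset, state in block_onsets:
        lo, hi = onset + window[0], onset + window[1]
        in_window |= (times >= lo - 1e-9) & (times <= hi + 1e-9) & (labels == state)
    keep = in_window & (predictions == labels) & (labels >= 0)
    return np.flatnonzero(keep)


def smooth_map(values: np.ndarray, fwhm: float, voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    if fwhm == 0:
        return values.copy()
    sigmas = [fwhm * FWHM_TO_SIGMA / vs for vs in voxel_size]
    return ndimage.gaussian_filter(values, sigma=sigmas)


def subject_map(
    relevance_maps: list[np.ndarray],
    state: int,
    fwhm: float = 3.0,
    voxel_size=(2.0, 2.0, 2.0),
    mask: BrainMask | None = None,
) -> BrainMap:
    """Smooth each selected TR map, then voxelwise mean: one map per subject x state."""
    if not relevance_maps:
        raise ValueError(f"no relevance maps to aggregate for state {state} (0 given)")
    smoothed = [smooth_map(np.asarray(m, dtype=float), fwhm, voxel_size) for m in relevance_maps]
    return BrainMap(
        values=np.mean(smoothed, axis=0),
        level="subject",
        state=state,
        mask=mask,
        n_samples=len(relevance_maps),
    )


def group_map(subject_maps: list[BrainMap]) -> BrainMap:
    """Voxelwise mean of subject-level maps of one state."""
    if not subject_maps:
        raise ValueError("no subject maps to aggregate")
    states = {m.state for m in subject_maps}
    if len(states) > 1:
        raise ValueError(f"subject maps mix states {sorted(states)}")
    return BrainMap(
        values=np.mean([m.values for m in subject_maps], axis=0),
        level="group",
        state=subject_maps[0].state,
        mask=subject_maps[0].mask,
        n_samples=sum(m.n_samples for m in subject_maps),
    )


def threshold_percentile(
    brain_map: BrainMap, q: float = 90.0, positive_only: bool = True
) -> BrainMap:
    """Keep voxels at or above the q-th percentile of in-mask values.

    With ``positive_only`` (the default used for map comparisons), the map is
    first restricted to its positive values — the evidence-for reading of
    relevance — and the percentile is taken over that positive support.
    Percentiles use linear interpolation.
    """
    if not 0 < q < 100:
        raise ValueError("q must lie in (0, 100)")
    values = brain_map.values
    if positive_only:
        values = np.where(values > 0, values, 0.0)
    mask = brain_map.mask.mask if brain_map.mask is not None else np.ones(values.shape, bool)
    pool = values[mask]
    if positive_only:
        pool = pool[pool > 0]
    if pool.size == 0:
        raise ValueError("no in-mask voxels to threshold")
    threshold = float(np.percentile(pool, q))
    kept = np.where((values >= threshold) & mask, values, 0.0)
    return BrainMap(
        values=kept,
        level=brain_map.level,
        state=brain_map.state,
        mask=brain_map.mask,
        threshold=threshold,
        n_samples=brain_map.n_samples,
    )
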