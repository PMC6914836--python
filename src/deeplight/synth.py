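"""Synthetic block-design fMRI generator with known ground truth.

Emulates the structure of a four-state visual block paradigm: each cognitive
state is presented in timed blocks separated by rest, and activates a
state-specific, spatially disjoint spherical ROI. The voxel model is

    signal = baseline + linear drift + slow sine drift + Gaussian noise
           + effect_amplitude * (state boxcar (*) double-gamma HRF)   [ROI voxels]

so that detrending, highpass filtering, decoding and relevance-map recovery
are each independently testable against the planted ground truth. The
generator intentionally omits MR physics (motion, spatial noise correlation,
multi-run effects); see docs/methods.md for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import convolve_boxcar
from .io import DEFAULT_STATES, REST, Volume4D, write_events, write_mask_nifti, write_nifti


@dataclass
class SyntheticConfig:
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    tr: float = 1.0  # seconds
    n_states: int = 4
    block_length: float = 20.0  # seconds
    blocks_per_state: int = 2
    rest_length: float = 10.0  # seconds of rest before/between blocks
    roi_specs: list[tuple[tuple[int, int, int], float]] = field(default_factory=list)
    effect_amplitude: float = 5.0  # signal units at HRF plateau
    noise_sd: float = 1.0
    baseline: float = 100.0
    drift_slope: float = 0.01  # signal units per volume
    drift_sine_amplitude: float = 1.0
    drift_sine_period: float = 120.0  # seconds
    hrf_peak_delay: float = 6.0  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.roi_specs:
            self.roi_specs = default_roi_specs(self.grid_shape, self.n_states)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.roi_specs) != self.n_states:
            raise ValueError("need one ROI spec per state")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic run: the acceptance surface."""

    roi_masks: np.ndarray  # (n_states, X, Y, Z) boolean
    labels: np.ndarray  # per-TR state index, REST outside blocks
    block_onsets: list[tuple[float, int]]  # (onset seconds, state index)
    state_names: tuple[str, ...]

    def events(self, block_length: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [onset for onset, _ in self.block_onsets],
                "duration": block_length,
                "trial_type": [self.state_names[s] for _, s in self.block_onsets],
            }
        )


def default_roi_specs(
    grid_shape: tuple[int, int, int], n_states: int
) -> list[tuple[tuple[int, int, int], float]]:
    """Disjoint spherical ROIs in the four x-y quadrants of the grid.

    With the default 16x16x12 grid and radius 3 each sphere holds ~123 voxels,
    ~4% of the grid, so chance-level overlap of a top-decile map with any one
    ROI stays well below 5%.
    """
    if n_states > 4:
        raise ValueError("default ROI layout supports at most 4 states; pass roi_specs")
    nx, ny, nz = grid_shape
    lo_x, lo_y = int(round(0.28 * nx)), int(round(0.28 * ny))
    hi_x, hi_y = nx - 1 - lo_x, ny - 1 - lo_y
    # largest radius (capped at 3) keeping the quadrant spheres disjoint
    radius = min(3.0, (hi_x - lo_x) / 2 - 0.01, (hi_y - lo_y) / 2 - 0.01)
    if radius <= 0:
        raise ValueError(f"grid {grid_shape} too small for the default ROI layout")
    zc = nz // 2
    centers = [(lo_x, lo_y), (hi_x, lo_y), (lo_x, hi_y), (hi_x, hi_y)]
    return [((cx, cy, zc), radius) for cx, cy in centers[:n_states]]


def sphere_mask(grid_shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    cx, cy, cz = center
    x, y, z = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def _roi_masks(config: SyntheticConfig) -> np.ndarray:
    masks = np.zeros((config.n_states,) + tuple(config.grid_shape), dtype=bool)
    for k, (center, radius) in enumerate(config.roi_specs):
        for c, n in zip(center, config.grid_shape):
            if not (0 <= c < n):
                raise ValueError(f"ROI center {center} outside grid {config.grid_shape}")
        masks[k] = sphere_mask(tuple(config.grid_shape), center, radius)
        if not masks[k].any():
            raise ValueError(f"ROI spec {k} selects no voxels")
    overlap = masks.sum(axis=0) > 1
    if overlap.any():
        raise ValueError("ROI masks of distinct states overlap")
    return masks


def block_schedule(config: SyntheticConfig, rng: np.random.Generator) -> list[tuple[float, int]]:
    """Interleaved block order: shuffled state order per sweep, rest gaps."""
    order = []
    for _ in range(config.blocks_per_state):
        sweep = rng.permutation(config.n_states)
        order.extend(int(s) for s in sweep)
    onsets = []
    t = config.rest_length
    for state in order:
        onsets.append((t, state))
        t += config.block_length + config.rest_length
    return onsets


def run_length_volumes(config: SyntheticConfig) -> int:
    total = config.rest_length + config.n_states * config.blocks_per_state * (
        config.block_length + config.rest_length
    )
    return int(round(total / config.tr))


def generate_run(config: SyntheticConfig) -> tuple[Volume4D, GroundTruth]:
    """Generate one synthetic run; identical seeds give bit-identical output."""
    rng = np.random.default_rng(config.seed)
    masks = _roi_masks(config)
    n_vol = run_length_volumes(config)
    onsets = block_schedule(config, rng)
    run_end = n_vol * config.tr
    for onset, _ in onsets:
        if onset + config.block_length > run_end + 1e-9:
            raise ValueError("block schedule exceeds run length")

    times = np.arange(n_vol) * config.tr
    labels = np.full(n_vol, REST, dtype=int)
    for onset, state in onsets:
        labels[(times >= onset - 1e-9) & (times < onset + config.block_length - 1e-9)] = state

    shape = tuple(config.grid_shape)
    data = np.full((n_vol,) + shape, config.baseline, dtype=float)
    drift = config.drift_slope * np.arange(n_vol)
    if config.drift_sine_amplitude != 0 and config.drift_sine_period > 0:
        drift = drift + config.drift_sine_amplitude * np.sin(
            2 * np.pi * times / config.drift_sine_period
        )
    data += drift[:, None, None, None]

    # state-specific BOLD responses in the planted ROIs
    for state in range(config.n_states):
        boxcar = (labels == state).astype(float)
        response = config.effect_amplitude * convolve_boxcar(
            boxcar, config.tr, peak_delay=config.hrf_peak_delay
        )
        data[:, masks[state]] += response[:, None]

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    volume = Volume4D(data=data, tr=config.tr)
    truth = GroundTruth(
        roi_masks=masks,
        labels=labels,
        block_onsets=onsets,
        state_names=DEFAULT_STATES[: config.n_states],
    )
    return volume, truth


def generate_dataset(
    config: SyntheticConfig, n_subjects: int, base_seed: int
) -> list[tuple[Volume4D, GroundTruth]]:
    """One run per synthetic subject, seeds ``base_seed + index``.

    ROI masks are shared across subjects (they derive from the config);
    noise realizations and block orders differ per subject.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dataset = []
    for i in range(n_subjects):
        cfg = SyntheticConfig(**{**config.__dict__, "seed": base_seed + i})
        dataset.append(generate_run(cfg))
    return dataset


def write_run(out_dir, name: str, volume: Volume4D, truth: GroundTruth, config: SyntheticConfig):
    """Write a run as NIfTI + BIDS events TSV + ground-truth mask NIfTIs."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(out / f"{name}_bold.nii.gz", volume)
    write_events(out / f"{name}_events.tsv", truth.events(config.block_length))
    for k, state in enumerate(truth.state_names):
        write_mask_nifti(out / f"{name}_roi-{state}_mask.nii.gz", truth.roi_masks[k])
    return out
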