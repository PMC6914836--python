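"""NIfTI and events-table I/O.

A run is a 4D volume (stored here time-first, ``T x X x Y x Z``) plus its
repetition time, and a BIDS-style events table (``onset``, ``duration``,
``trial_type``) that assigns a cognitive-state label to every TR. TRs that
fall outside every event block are labeled rest and excluded from decoding,
mirroring the removal of fixation blocks from the analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

#: label value used for TRs outside any experiment block
REST = -1

#: canonical state names of the four-category visual N-back paradigm
DEFAULT_STATES = ("body", "face", "place", "tool")


@dataclass
class Volume4D:
    """A single fMRI run: ``T`` volumes of ``X x Y x Z`` voxel intensities."""

    data: np.ndarray  # (T, X, Y, Z)
    tr: float  # seconds
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (T,X,Y,Z) data, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def write_nifti(path, volume: Volume4D) -> None:
    """Write a run as 4D NIfTI-1 (spatial-first on disk, TR in the header)."""
    arr = np.moveaxis(volume.data, 0, -1)  # (X, Y, Z, T)
    img = nib.Nifti1Image(arr, volume.affine)
    zooms = tuple(volume.voxel_size) + (volume.tr,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_nifti(path) -> Volume4D:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., None]
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(
        data=np.moveaxis(arr, -1, 0),
        tr=tr,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(img.affine),
    )


def write_mask_nifti(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def write_map_nifti(path, values: np.ndarray, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=float), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return events


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def _check_overlap(events: pd.DataFrame) -> None:
    ordered = events.sort_values("onset")
    ends = (ordered["onset"] + ordered["duration"]).to_numpy()
    onsets = ordered["onset"].to_numpy()
    if np.any(onsets[1:] < ends[:-1] - 1e-9):
        raise ValueError("overlapping events in events table")


def labels_from_events(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    state_names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Per-TR state labels from block events.

    A TR acquired at time ``index * tr`` is assigned to the block whose
    half-open interval ``[onset, onset + duration)`` contains it; TRs outside
    every block are labeled :data:`REST`. Unknown ``trial_type`` values are
    indexed by first appearance when ``state_names`` is not given.
    """
    _check_overlap(events)
    if state_names is None:
        seen = list(dict.fromkeys(events["trial_type"]))
        if set(seen) <= set(DEFAULT_STATES):
            state_names = DEFAULT_STATES
        else:
            state_names = tuple(seen)
    name_to_idx = {name: i for i, name in enumerate(state_names)}
    labels = np.full(n_volumes, REST, dtype=int)
    times = np.arange(n_volumes) * tr
    run_end = n_volumes * tr
    for _, row in events.iterrows():
        if row["onset"] + row["duration"] > run_end + 1e-9:
            warnings.warn(
                "event extends past the end of the run; truncating to run length",
                stacklevel=2,
            )
        inside = (times >= row["onset"] - 1e-9) & (times < row["onset"] + row["duration"] - 1e-9)
        labels[inside] = name_to_idx[row["trial_type"]]
    return labels


def read_run(
    nifti_path,
    events_path,
    state_names: tuple[str, ...] | None = None,
) -> tuple[Volume4D, np.ndarray]:
    """Load a run and its per-TR labels (rest = :data:`REST`)."""
    volume = read_nifti(nifti_path)
    events = read_events(events_path)
    labels = labels_from_events(events, volume.n_volumes, volume.tr, state_names)
    return volume, labels
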