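"""Preprocessing chain for decoding analyses.

The fixed order is: spatial smoothing (3 mm FWHM Gaussian), per-voxel linear
detrending + standardization (zero mean, unit variance), zero-phase
Butterworth highpass (cutoff 128 s), then cropping to a box-shaped brain
mask. The mask marks voxels whose raw intensity exceeds 5% of the per-volume
maximum and is the filled per-axis bounding box of all such voxels across
the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage, signal

from .io import Volume4D

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BrainMask:
    """Box-shaped brain mask: the filled per-axis bounding box."""

    mask: np.ndarray  # boolean (X, Y, Z)
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # inclusive

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def crop(self, data: np.ndarray) -> np.ndarray:
        """Crop the spatial axes (last three) to the bounding box."""
        (x0, x1), (y0, y1), (z0, z1) = self.bounding_box
        return data[..., x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1]

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "BrainMask":
        return cls(
            mask=np.ones(shape, dtype=bool),
            bounding_box=tuple((0, n - 1) for n in shape),
        )


def compute_brain_mask(volumes: Iterable[Volume4D], fraction: float = 0.05) -> BrainMask:
    """Bounding-box brain mask from the 5%-of-maximum voxel rule.

    Within each raw volume, voxels with absolute intensity above ``fraction``
    of that volume's maximum count as brain; the mask is the filled box from
    the first to the last such voxel along each axis, over all volumes of the
    dataset.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].spatial_shape
    passed = np.zeros(shape, dtype=bool)
    for vol in volumes:
        if vol.spatial_shape != shape:
            raise ValueError("inconsistent spatial dimensions across volumes")
        absdata = np.abs(vol.data)
        vmax = absdata.reshape(vol.n_volumes, -1).max(axis=1)
        passed |= (absdata > fraction * vmax[:, None, None, None]).any(axis=0)
    if not passed.any():
        raise ValueError("degenerate brain mask: no voxel exceeds the threshold")
    box = []
    for axis in range(3):
        proj = passed.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        box.append((int(idx[0]), int(idx[-1])))
    mask = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    mask[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = True
    return BrainMask(mask=mask, bounding_box=tuple(box))


def smooth_gaussian(volume: Volume4D, fwhm: float = 3.0) -> Volume4D:
    """Isotropic Gaussian smoothing of each 3D frame (FWHM in mm)."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return Volume4D(volume.data.copy(), volume.tr, volume.voxel_size, volume.affine)
    sigmas = [fwhm * FWHM_TO_SIGMA / vs for vs in volume.voxel_size]
    out = ndimage.gaussian_filter(volume.data, sigma=[0.0] + sigmas)
    return Volume4D(out, volume.tr, volume.voxel_size, volume.affine)


def detrend_standardize(volume: Volume4D, mask: BrainMask | None = None) -> Volume4D:
    """Remove each in-mask voxel's linear trend; center and scale to unit sd.

    Voxels whose detrended series has zero variance are set to zero (logged),
    never NaN. Out-of-mask voxels are zeroed.
    """
    T = volume.n_volumes
    if T < 3:
        raise ValueError("need at least 3 volumes to detrend")
    if mask is None:
        mask = BrainMask.full(volume.spatial_shape)
    Y = volume.data.reshape(T, -1)
    m = mask.mask.ravel()
    t = np.arange(T, dtype=float)
    t_c = t - t.mean()
    slope = (t_c @ Y[:, m]) / (t_c @ t_c)
    resid = Y[:, m] - np.outer(t, slope)
    resid = resid - resid.mean(axis=0)
    sd = resid.std(axis=0)
    degenerate = sd <= 1e-12
    if degenerate.any():
        logger.info("detrend_standardize: %d zero-variance voxel(s) set to 0", degenerate.sum())
    sd_safe = np.where(degenerate, 1.0, sd)
    out = np.zeros_like(Y)
    out[:, m] = np.where(degenerate, 0.0, resid / sd_safe)
    return Volume4D(out.reshape(volume.data.shape), volume.tr, volume.voxel_size, volume.affine)


def butterworth_sos(cutoff_period: float, tr: float, order: int = 5):
    fs = 1.0 / tr
    fc = 1.0 / cutoff_period
    if fc >= fs / 2:
        raise ValueError("highpass cutoff frequency at or above Nyquist")
    return signal.butter(order, fc, btype="highpass", fs=fs, output="sos")


def highpass_butterworth(
    volume: Volume4D, cutoff_period: float = 128.0, order: int = 5
) -> Volume4D:
    """Zero-phase (forward-backward) Butterworth highpass per voxel.

    Forward-backward application squares the magnitude response and cancels
    the phase, so the effective amplitude gain at frequency ``f`` is
    ``|H(f)|**2`` of the order-``order`` Butterworth filter.
    """
    if cutoff_period <= 2 * volume.tr:
        raise ValueError("cutoff_period must exceed 2*TR (Nyquist)")
    sos = butterworth_sos(cutoff_period, volume.tr, order)
    out = signal.sosfiltfilt(sos, volume.data, axis=0)
    return Volume4D(out, volume.tr, volume.voxel_size, volume.affine)


def highpass_gain(frequency: float, cutoff_period: float, tr: float, order: int = 5) -> float:
    """Analytic amplitude gain of the zero-phase highpass at ``frequency`` Hz."""
    sos = butterworth_sos(cutoff_period, tr, order)
    _, h = signal.sosfreqz(sos, worN=[2 * np.pi * frequency * tr])
    return float(np.abs(h[0]) ** 2)


def preprocess_run(
    volume: Volume4D,
    mask: BrainMask | None = None,
    fwhm: float = 3.0,
    cutoff_period: float = 128.0,
) -> Volume4D:
    """The full chain: smooth -> detrend/standardize -> highpass.

    The mask (computed from the raw data when not given) zeroes out-of-mask
    voxels during detrending; cropping to the box is left to the caller so
    relevance maps can be reported in the original grid.
    """
    if mask is None:
        mask = compute_brain_mask([volume])
    out = smooth_gaussian(volume, fwhm)
    out = detrend_standardize(out, mask)
    out = highpass_butterworth(out, cutoff_period)
    return out
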