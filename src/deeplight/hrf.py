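"""Canonical hemodynamic response function.

The BOLD signal measured by fMRI is a delayed, smoothed transform of the
underlying neural activity. Both the synthetic-data generator and the GLM
design matrix model this with the canonical double-gamma HRF: a positive
gamma lobe peaking ~6 s after stimulus onset followed by a smaller negative
undershoot lobe around ~16 s.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    The response is normalized so its peak equals 1.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak_delay) - ratio * _gamma.pdf(t, undershoot_delay)
    h[t < 0] = 0.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def hrf_kernel(tr: float, duration: float = 32.0, peak_delay: float = 6.0) -> np.ndarray:
    """HRF sampled on the TR grid, for discrete convolution with a boxcar."""
    t = np.arange(0.0, duration + 1e-9, tr)
    return double_gamma_hrf(t, peak_delay=peak_delay)


def convolve_boxcar(boxcar: np.ndarray, tr: float, peak_delay: float = 6.0) -> np.ndarray:
    """Convolve a per-TR boxcar with the canonical HRF, truncated to length.

    The kernel is scaled to unit sum so a sustained block plateaus at the
    boxcar height: an amplitude-``a`` block produces a steady-state response
    of ``a``, which keeps effect sizes interpretable as plateau signal change.
    """
    kernel = hrf_kernel(tr, peak_delay=peak_delay)
    kernel = kernel / kernel.sum()
    return np.convolve(boxcar, kernel)[: len(boxcar)]
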