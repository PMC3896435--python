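"""Canonical two-gamma hemodynamic response function and block-design convolution.

The BOLD response to a task block is modelled as the block's boxcar convolved
with a double-gamma impulse response: a positive gamma peaking ~5 s after
stimulus onset and a delayed negative gamma (the post-stimulus undershoot)
peaking ~15 s, with a peak-to-undershoot amplitude ratio of 6.  The kernel is
normalised to unit area so that the plateau of a long boxcar equals the
configured amplitude, which keeps percent-signal-change bookkeeping simple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (seconds).

    ``peak_s`` / ``undershoot_s`` are the modes of the two gamma densities;
    ``ratio`` is the peak/undershoot amplitude ratio; ``length_s`` the kernel
    support.
    """

    peak_s: float = 5.0
    undershoot_s: float = 15.0
    ratio: float = 6.0
    length_s: float = 32.0


def hrf_kernel(tr_s: float = 1.0, params: HrfParams = HrfParams()) -> np.ndarray:
    """Sample the double-gamma HRF at ``tr_s`` spacing, unit-area normalised.

    With unit rate, a gamma density of shape ``a`` peaks at ``a - 1``; shapes
    are therefore ``peak_s + 1`` and ``undershoot_s + 1``.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0, params.length_s + tr_s / 2, tr_s)
    pos = stats.gamma.pdf(t, params.peak_s + 1.0)
    neg = stats.gamma.pdf(t, params.undershoot_s + 1.0)
    h = pos - neg / params.ratio
    area = h.sum() * tr_s
    return h / area


def boxcar(onsets_s: np.ndarray, durations_s: np.ndarray, n_volumes: int, tr_s: float) -> np.ndarray:
    """Indicator time course of task occupancy on the volume grid (half-open)."""
    x = np.zeros(n_volumes)
    for onset, dur in zip(np.atleast_1d(onsets_s), np.atleast_1d(durations_s)):
        i0 = int(round(onset / tr_s))
        i1 = int(round((onset + dur) / tr_s))
        x[max(i0, 0):min(i1, n_volumes)] = 1.0
    return x


def convolve_boxcar(onsets_s, durations_s, n_volumes: int, tr_s: float = 1.0,
                    params: HrfParams = HrfParams()) -> np.ndarray:
    """Boxcar ⊗ HRF predictor; plateau of a long block equals 1."""
    x = boxcar(np.asarray(onsets_s, float), np.asarray(durations_s, float), n_volumes, tr_s)
    h = hrf_kernel(tr_s, params)
    return np.convolve(x, h)[:n_volumes] * tr_s
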