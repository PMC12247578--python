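"""Hemodynamic response model and temporal basis functions.

Both the generator and the first-level GLM use the same canonical
double-gamma HRF and the same discrete-cosine drift basis, so that a
noiseless planted percent-signal-change round-trips through the analysis
exactly.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma


def double_gamma_hrf(
    dt: float = 0.1,
    duration_s: float = 32.0,
    peak_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    undershoot_ratio: float = 6.0,
    normalize: str = "peak",
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``.

    The response is a gamma density peaking ~5-6 s post-stimulus minus a
    later gamma undershoot (shape 16) scaled by 1/``undershoot_ratio``.
    ``normalize="peak"`` scales the maximum to 1 (display convention);
    ``normalize="area"`` scales the time integral to 1 so that a sustained
    boxcar convolved with the response plateaus at the boxcar amplitude.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration_s, dt)
    h = _gamma.pdf(t, peak_shape) - _gamma.pdf(t, undershoot_shape) / undershoot_ratio
    if normalize == "peak":
        return h / h.max()
    if normalize == "area":
        return h / (h.sum() * dt)
    raise ValueError("normalize must be 'peak' or 'area'")


def condition_regressor(
    onsets_s: np.ndarray,
    durations_s: np.ndarray | float,
    n_volumes: int,
    tr_s: float,
    t0_s: float = 0.0,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume acquisition times.

    A unit boxcar spans each ``[onset, onset + duration)`` window on a fine
    ``dt`` grid and is convolved (continuous-time convolution, i.e. the
    discrete convolution scaled by ``dt``) with the area-normalized
    canonical HRF, so a sustained block plateaus at the boxcar amplitude.
    The result is sampled at ``t0_s + i * tr_s`` for each retained volume
    ``i``; ``t0_s`` shifts the sampling grid when leading volumes have been
    discarded.
    """
    onsets = np.atleast_1d(np.asarray(onsets_s, float))
    durations = np.broadcast_to(np.asarray(durations_s, float), onsets.shape)
    t_end = t0_s + n_volumes * tr_s + 1.0
    fine = np.zeros(int(np.ceil(t_end / dt)) + 1)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        if i0 < len(fine):
            fine[i0 : min(i1, len(fine))] = 1.0
    h = double_gamma_hrf(dt, normalize="area")
    conv = np.convolve(fine, h)[: len(fine)] * dt
    sample_idx = np.round((t0_s + np.arange(n_volumes) * tr_s) / dt).astype(int)
    return conv[sample_idx]


def dct_drift_basis(n_volumes: int, tr_s: float, highpass_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine low-frequency drift basis (SPM convention).

    Returns the ``n_volumes x k`` matrix of cosines whose frequencies
    ``j / (2 * n * TR)`` do not exceed the ``1 / highpass_s`` cutoff; the
    constant term is excluded (the GLM carries an explicit intercept).
    """
    if highpass_s <= 0:
        raise ValueError("highpass_s must be positive")
    n = int(n_volumes)
    k = int(np.floor(2.0 * n * tr_s / highpass_s))
    t = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * (2 * t + 1) * j / (2.0 * n))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))
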