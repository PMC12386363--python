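"""Shared low-level signal primitives: exponential moving averages and robust noise scale."""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

__all__ = ["ema", "ema_alpha", "robust_noise_sd"]

# Normal-consistency constant for the median absolute deviation.
_MAD_TO_SD = 1.4826022185056018


def ema_alpha(tau_s: float, frame_rate_hz: float) -> float:
    """Smoothing factor of a first-order EMA with time constant ``tau_s``.

    alpha = 1 - exp(-1 / (tau_s * frame_rate_hz)); alpha -> 1 as tau -> 0
    (no smoothing) and alpha -> 0 as tau -> inf (frozen baseline).
    """
    if tau_s <= 0:
        raise ValueError(f"tau_s must be > 0, got {tau_s}")
    if frame_rate_hz <= 0:
        raise ValueError(f"frame_rate_hz must be > 0, got {frame_rate_hz}")
    return 1.0 - float(np.exp(-1.0 / (tau_s * frame_rate_hz)))


def ema(x: np.ndarray, tau_s: float, frame_rate_hz: float) -> np.ndarray:
    """Causal exponential moving average along the last axis.

    Implements y[t] = alpha * x[t] + (1 - alpha) * y[t-1] with y[0] = x[0],
    i.e. the filter is initialized at the first sample and uses no look-ahead.
    Closed form for a unit step from zero at t=0: y[t] = 1 - (1-alpha)**(t+1).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("cannot smooth an empty trace")
    alpha = ema_alpha(tau_s, frame_rate_hz)
    # y[0] = x[0] requires initial condition zi = (1 - alpha) * x[0]
    zi = (1.0 - alpha) * x[..., :1]
    y, _ = lfilter([alpha], [1.0, alpha - 1.0], x, axis=-1, zi=zi)
    return y


def robust_noise_sd(x: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Robust per-trace noise standard deviation from temporal first differences.

    For i.i.d. Gaussian noise the first difference has sd sqrt(2)*sigma, so
    sigma = MAD(diff(x)) * 1.4826 / sqrt(2). The median absolute deviation
    ignores the sparse large differences produced by calcium transients, making
    the estimate insensitive to event content and to any additive baseline.
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x, axis=axis)
    med = np.median(d, axis=axis, keepdims=True)
    mad = np.median(np.abs(d - med), axis=axis)
    return mad * _MAD_TO_SD / np.sqrt(2.0)
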