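"""Signal conditioning for the deep-learning pipeline and the discrete derivative.

The neural models consume windows that are resampled to a common rate,
min-max normalised per window and smoothed with a one-second moving average —
in that order. Hand-crafted features and the Boolean rules, by contrast, work
on the raw traces; nothing here is applied to them.

The discrete derivative x'_i = x_i - x_{i-1} (with x'_1 fixed to 0) is shared
by the rule module and the slope masks: its sum telescopes to x_l - x_1, which
is what makes the "start vs end" and "positive drift" rules identical.
"""

from __future__ import annotations

import numpy as np

from .synth import EDAWindow

__all__ = [
    "resample_window",
    "resample_values",
    "minmax_normalize",
    "moving_average",
    "discrete_derivative",
    "dl_pipeline",
]


def resample_values(values: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Linear-interpolation resampling onto round(l * target_fs / fs) points.

    Endpoints are preserved: the new grid spans the same time interval
    [0, (l-1)/fs] as the original samples.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot resample an empty window")
    l = values.size
    n_out = int(round(l * target_fs / fs))
    if n_out == l and target_fs == fs:
        return values.copy()
    t_old = np.arange(l) / fs
    t_new = np.linspace(0.0, t_old[-1], n_out)
    return np.interp(t_new, t_old, values)


def resample_window(window: EDAWindow, target_fs: float) -> EDAWindow:
    v = resample_values(window.values, window.fs, target_fs)
    return EDAWindow(values=np.maximum(v, np.min(window.values) * 1e-9 + 1e-12),
                     fs=target_fs, label=window.label,
                     subject_id=window.subject_id, rep=window.rep)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant input maps to all zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalise an empty array")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def moving_average(values: np.ndarray, fs: float, span_s: float = 1.0) -> np.ndarray:
    """Centered moving average over round(fs * span_s) samples.

    Output length equals input length; at the edges the mean is taken over
    the samples that actually fall inside the window (truncated mean).
    """
    if span_s <= 0:
        raise ValueError("span_s must be positive")
    values = np.asarray(values, dtype=float)
    n = values.size
    k = max(1, int(round(fs * span_s)))
    if k == 1 or n == 0:
        return values.copy()
    half_left = (k - 1) // 2
    half_right = k - 1 - half_left
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_left, 0)
    hi = np.minimum(idx + half_right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def discrete_derivative(values: np.ndarray) -> np.ndarray:
    """First differences with the leading element fixed to 0.

    x'_1 = 0 and x'_i = x_i - x_{i-1} for i >= 2, so sum(x') = x_l - x_1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one sample")
    out = np.empty_like(values)
    out[0] = 0.0
    if values.size > 1:
        out[1:] = np.diff(values)
    return out


def dl_pipeline(values: np.ndarray, fs: float, target_fs: float = 256.0,
                span_s: float = 1.0) -> np.ndarray:
    """Resample -> min-max normalise -> one-second moving average."""
    v = resample_values(values, fs, target_fs)
    v = minmax_normalize(v)
    return moving_average(v, target_fs, span_s)
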