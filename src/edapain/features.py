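"""Hand-crafted EDA feature battery.

Each stimulus-locked window is summarised by a fixed registry of scalar
features computed on the *raw* trace: plain statistics (extrema and their
indices, first/second-difference statistics, interquartile range, RMS, the
first-minus-last difference), tonic/phasic summaries after an additive
decomposition, SCR event statistics (count, amplitudes, rise and recovery
times), a resampled derivative of the phasic component (dPhEDA), and a
band-limited sympathetic-tone envelope (TVSymp) plus a late-window variant
(MTVSymp).

The tonic estimator is a moving minimum followed by a centered moving
average; the binding contract is exact additivity (tonic + phasic == input),
and the estimator itself is pluggable. SCR statistics over an empty event
list are imputed as 0 so the feature matrix stays dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d
from scipy.signal import butter, filtfilt, hilbert

from .preprocess import discrete_derivative, minmax_normalize, moving_average
from .synth import WindowSet

__all__ = [
    "FEATURE_REGISTRY",
    "SCREvent",
    "decompose_tonic_phasic",
    "detect_scrs",
    "statistical_features",
    "dpheda",
    "tvsymp",
    "extract_features",
    "feature_matrix_to_csv",
    "feature_matrix_from_csv",
]

N_DPHEDA = 20
N_TVSYMP = 5

_BASE_FEATURES = [
    "min", "max", "iqr", "rms", "mav",
    "mavfd", "mavfd_std", "mavsd", "mavsd_std",
    "var_moment1", "var_moment2",
    "local_max", "local_min", "argmax", "argmin", "diff_start_end",
    "mean_phasic", "sd_phasic", "mean_tonic", "sd_tonic", "range_tonic",
    "n_scrs", "sum_amplitudes", "first_amplitude", "phasic_max",
    "mean_amp", "sd_amp", "mean_rise", "sd_rise",
    "mean_half_rec", "sd_half_rec", "mean_rec", "sd_rec",
    "norm_mean", "norm_sd", "norm_var",
]

#: Canonical, ordered feature-name registry; column order of every matrix.
FEATURE_REGISTRY: tuple[str, ...] = tuple(
    _BASE_FEATURES
    + [f"dPhEDA_{i}" for i in range(1, N_DPHEDA + 1)]
    + [f"TVSymp_{i}" for i in range(1, N_TVSYMP + 1)]
    + [f"MTVSymp_{i}" for i in range(1, N_TVSYMP + 1)]
)


@dataclass(frozen=True)
class SCREvent:
    """One detected skin conductance response (indices are 1-based)."""

    onset_idx: int
    peak_idx: int
    amplitude: float  # µS
    rise_time: float  # s
    half_recovery: float | None  # s, None if the signal never falls that far
    recovery: float | None  # s, at 37% of the amplitude above onset


def decompose_tonic_phasic(values: np.ndarray, fs: float,
                           tonic_span_s: float = 4.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Split a trace into tonic (SCL) and phasic (SCR) parts, additively.

    tonic = moving minimum over ``tonic_span_s`` seconds, smoothed by a
    centered moving average over the same span; phasic = values - tonic.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two samples")
    k = max(1, int(round(fs * tonic_span_s)))
    tonic = minimum_filter1d(values, size=k, mode="nearest")
    tonic = moving_average(tonic, fs, tonic_span_s)
    phasic = values - tonic
    return tonic, phasic


def _strict_local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """0-based indices of strict local maxima and minima (interior points)."""
    if x.size < 3:
        empty = np.array([], dtype=int)
        return empty, empty
    mid = x[1:-1]
    maxima = np.flatnonzero((mid > x[:-2]) & (mid > x[2:])) + 1
    minima = np.flatnonzero((mid < x[:-2]) & (mid < x[2:])) + 1
    return maxima, minima


def detect_scrs(phasic: np.ndarray, fs: float,
                amp_threshold: float = 0.01) -> list[SCREvent]:
    """Detect SCR events as strict local maxima of the phasic component.

    Onset is the nearest preceding strict local minimum (or the first
    sample); events whose onset-to-peak amplitude falls below
    ``amp_threshold`` µS are dropped. Half-recovery (recovery) is the time
    from the peak until the signal first falls below onset + amplitude/2
    (onset + 0.37 * amplitude), None when that never happens in the window.
    """
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    phasic = np.asarray(phasic, dtype=float)
    peaks, troughs = _strict_local_extrema(phasic)
    events: list[SCREvent] = []
    for p in peaks:
        prior = troughs[troughs < p]
        onset = int(prior[-1]) if prior.size else 0
        amp = phasic[p] - phasic[onset]
        if amp < amp_threshold:
            continue
        tail = phasic[p + 1:]
        half = _first_crossing_time(tail, phasic[onset] + amp / 2.0, fs)
        rec = _first_crossing_time(tail, phasic[onset] + amp * 0.37, fs)
        events.append(SCREvent(
            onset_idx=onset + 1, peak_idx=int(p) + 1, amplitude=float(amp),
            rise_time=(p - onset) / fs, half_recovery=half, recovery=rec,
        ))
    events.sort(key=lambda e: e.onset_idx)
    return events


def _first_crossing_time(tail: np.ndarray, level: float, fs: float) -> float | None:
    below = np.flatnonzero(tail < level)
    if below.size == 0:
        return None
    return float((below[0] + 1) / fs)


def statistical_features(values: np.ndarray, fs: float) -> dict[str, float]:
    """Plain statistical summaries of one raw trace (1-based arg indices)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    d1 = np.diff(x)
    d2 = np.diff(x, n=2) if x.size > 2 else np.array([0.0])
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    zd1 = np.diff(z)
    zd2 = np.diff(z, n=2) if z.size > 2 else np.array([0.0])
    maxima, minima = _strict_local_extrema(x)
    norm = minmax_normalize(x)
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "iqr": float(q75 - q25),
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "mav": float(np.mean(np.abs(x))),
        "mavfd": float(np.mean(np.abs(d1))),
        "mavfd_std": float(np.mean(np.abs(zd1))),
        "mavsd": float(np.mean(np.abs(d2))),
        "mavsd_std": float(np.mean(np.abs(zd2))),
        "var_moment1": float(np.var(d1)),
        "var_moment2": float(np.var(d2)),
        "local_max": float(np.mean(x[maxima])) if maxima.size else float(x.max()),
        "local_min": float(np.mean(x[minima])) if minima.size else float(x.min()),
        "argmax": float(np.argmax(x) + 1),
        "argmin": float(np.argmin(x) + 1),
        "diff_start_end": float(x[-1] - x[0]),
        "norm_mean": float(norm.mean()),
        "norm_sd": float(norm.std()),
        "norm_var": float(norm.var()),
    }


def dpheda(values: np.ndarray, fs: float, n_out: int = N_DPHEDA,
           tonic_span_s: float = 4.0) -> np.ndarray:
    """Derivative of the phasic component, resampled to ``n_out`` points."""
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.size < n_out:
        raise ValueError("window shorter than n_out")
    _, phasic = decompose_tonic_phasic(values, fs, tonic_span_s)
    deriv = discrete_derivative(phasic) * fs  # µS/s
    src = np.linspace(0.0, 1.0, deriv.size)
    dst = np.linspace(0.0, 1.0, n_out)
    return np.interp(dst, src, deriv)


def tvsymp(values: np.ndarray, fs: float, variant: str = "standard",
           n_out: int = N_TVSYMP) -> np.ndarray:
    """Band-limited sympathetic-tone index, resampled to ``n_out`` points.

    The input is z-scored, band-passed to 0.08-0.24 Hz and summarised by its
    analytic envelope. The "modified" variant evaluates the same index on the
    final half of the window only, emphasising the post-stimulus response.
    """
    values = np.asarray(values, dtype=float)
    if values.size / fs < 4.0:
        raise ValueError("window must be at least 4 s long")
    if variant not in ("standard", "modified"):
        raise ValueError(f"unknown variant {variant!r}")
    x = values[values.size // 2:] if variant == "modified" else values
    sd = x.std()
    if sd == 0:
        return np.zeros(n_out)
    z = (x - x.mean()) / sd
    nyq = fs / 2.0
    lo, hi = 0.08 / nyq, 0.24 / nyq
    hi = min(hi, 0.99)
    b, a = butter(2, [lo, hi], btype="band")
    band = filtfilt(b, a, z, padlen=min(3 * max(len(a), len(b)), z.size - 1))
    env = np.abs(hilbert(band))
    src = np.linspace(0.0, 1.0, env.size)
    dst = np.linspace(0.0, 1.0, n_out)
    return np.interp(dst, src, env)


def _scr_summary(events: list[SCREvent], phasic: np.ndarray) -> dict[str, float]:
    """SCR event statistics; empty lists impute 0 (dense-matrix rule)."""
    out = {
        "mean_phasic": float(phasic.mean()),
        "sd_phasic": float(phasic.std()),
        "phasic_max": float(phasic.max()),
        "n_scrs": float(len(events)),
    }
    amps = np.array([e.amplitude for e in events])
    rises = np.array([e.rise_time for e in events])
    halves = np.array([e.half_recovery for e in events if e.half_recovery is not None])
    recs = np.array([e.recovery for e in events if e.recovery is not None])

    def mean_sd(a: np.ndarray) -> tuple[float, float]:
        if a.size == 0:
            return 0.0, 0.0
        return float(a.mean()), float(a.std())

    out["sum_amplitudes"] = float(amps.sum()) if amps.size else 0.0
    out["first_amplitude"] = float(amps[0]) if amps.size else 0.0
    out["mean_amp"], out["sd_amp"] = mean_sd(amps)
    out["mean_rise"], out["sd_rise"] = mean_sd(rises)
    out["mean_half_rec"], out["sd_half_rec"] = mean_sd(halves)
    out["mean_rec"], out["sd_rec"] = mean_sd(recs)
    return out


@dataclass(frozen=True)
class FeatureConfig:
    tonic_span_s: float = 4.0
    amp_threshold: float = 0.01  # µS
    n_dpheda: int = N_DPHEDA
    n_tvsymp: int = N_TVSYMP


def window_features(values: np.ndarray, fs: float,
                    cfg: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """Full registry of features for one raw trace."""
    tonic, phasic = decompose_tonic_phasic(values, fs, cfg.tonic_span_s)
    events = detect_scrs(phasic, fs, cfg.amp_threshold)
    feats = statistical_features(values, fs)
    feats.update({
        "mean_tonic": float(tonic.mean()),
        "sd_tonic": float(tonic.std()),
        "range_tonic": float(tonic.max() - tonic.min()),
    })
    feats.update(_scr_summary(events, phasic))
    dph = dpheda(values, fs, cfg.n_dpheda, cfg.tonic_span_s)
    feats.update({f"dPhEDA_{i + 1}": float(v) for i, v in enumerate(dph)})
    tv = tvsymp(values, fs, "standard", cfg.n_tvsymp)
    feats.update({f"TVSymp_{i + 1}": float(v) for i, v in enumerate(tv)})
    mtv = tvsymp(values, fs, "modified", cfg.n_tvsymp)
    feats.update({f"MTVSymp_{i + 1}": float(v) for i, v in enumerate(mtv)})
    return feats


def extract_features(windowset: WindowSet,
                     cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """One row per window with the full feature registry.

    The returned frame carries ``subject_id`` and ``label`` columns alongside
    the features; rows follow the window order of the set.
    """
    if len(windowset) == 0:
        raise ValueError("empty window set")
    lengths = {len(w) for w in windowset.windows}
    if len(lengths) != 1:
        raise ValueError("inconsistent window lengths")
    rows = []
    for w in windowset.windows:
        feats = window_features(w.values, w.fs, cfg)
        row = {"subject_id": w.subject_id, "label": w.label}
        row.update({name: feats[name] for name in FEATURE_REGISTRY})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_REGISTRY])


def feature_matrix_to_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def feature_matrix_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV lacks columns: {missing}")
    return df
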