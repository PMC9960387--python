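"""Synthetic electrodermal activity (EDA) generator.

Produces stimulus-locked conductance windows with the statistical structure a
pain-recognition analysis assumes: a slowly varying tonic level (skin
conductance level, SCL) with linear drift, event-related skin conductance
responses (SCRs) whose amplitude grows with stimulus intensity, spontaneous
SCRs at a label-independent rate, white measurement noise, and a fraction of
non-responder subjects showing no evoked activity.

SCR morphology is a difference-of-exponentials (Bateman) pulse, the standard
shape in sudomotor-activity models. Evoked SCR peaks are placed 3-6 s after
stimulus onset when the window is long enough, otherwise within the middle of
the window. Sustained noxious stimulation also recruits the tonic level:
alongside the phasic pulse, an evoked window adds a saturating SCL ramp
(``tonic_gain`` times the phasic amplitude) that does not recover within the
window, so strong pain windows keep rising the way stimulus-locked recordings
do; set ``tonic_gain = 0`` for pure-pulse responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusProtocol",
    "SubjectProfile",
    "EDAWindow",
    "WindowSet",
    "SimParams",
    "BVDB_PROTOCOL",
    "PMDB_PROTOCOL",
    "desk_protocol",
    "scr_kernel",
    "scr_peak_time",
    "generate_window",
    "generate_dataset",
]

CONDUCTANCE_FLOOR = 0.01  # µS; skin conductance is strictly positive


@dataclass(frozen=True)
class StimulusProtocol:
    """Acquisition geometry of one study: who, what, how often, how sampled."""

    name: str
    n_subjects: int
    labels: tuple[str, ...]
    reps_per_label: int
    fs: float
    window_s: float

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.fs <= 0 or self.window_s <= 0:
            raise ValueError("fs and window_s must be positive")
        if not self.labels:
            raise ValueError("labels must be non-empty")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_samples(self) -> int:
        """Samples per window, round(fs * window_s)."""
        return int(round(self.fs * self.window_s))

    @property
    def n_windows(self) -> int:
        return self.n_subjects * len(self.labels) * self.reps_per_label


#: BioVid heat pain database part A geometry: 87 subjects, T0..T4, 20 reps,
#: 5.5 s windows at 512 Hz -> 8700 windows of 2816 samples.
BVDB_PROTOCOL = StimulusProtocol(
    name="bvdb",
    n_subjects=87,
    labels=("T0", "T1", "T2", "T3", "T4"),
    reps_per_label=20,
    fs=512.0,
    window_s=5.5,
)

#: PainMonit database geometry: 52 subjects, baseline + non-painful + P1..P4,
#: 8 reps, 10 s windows at 250 Hz -> 2496 windows of 2500 samples.
PMDB_PROTOCOL = StimulusProtocol(
    name="pmdb",
    n_subjects=52,
    labels=("B", "NP", "P1", "P2", "P3", "P4"),
    reps_per_label=8,
    fs=250.0,
    window_s=10.0,
)


def desk_protocol(
    n_subjects: int = 50,
    reps_per_label: int = 4,
    fs: float = 32.0,
    window_s: float = 10.0,
) -> StimulusProtocol:
    """Two-class desk-scale protocol (no pain vs high pain) for experiments
    that must run on a single CPU in minutes rather than hours."""
    return StimulusProtocol(
        name="desk",
        n_subjects=n_subjects,
        labels=("no_pain", "high_pain"),
        reps_per_label=reps_per_label,
        fs=fs,
        window_s=window_s,
    )


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters, drawn once per subject."""

    subject_id: str
    baseline_scl: float  # µS
    drift_rate: float  # µS/s, typically slightly negative at rest
    noise_sd: float  # µS
    responder: bool
    amplitude_scale: float  # multiplier on evoked SCR amplitude

    def __post_init__(self) -> None:
        if self.baseline_scl <= 0:
            raise ValueError("baseline_scl must be positive")
        if self.noise_sd < 0 or self.amplitude_scale < 0:
            raise ValueError("noise_sd and amplitude_scale must be >= 0")
        if not self.responder and self.amplitude_scale != 0:
            raise ValueError("non-responder requires amplitude_scale == 0")


@dataclass(frozen=True)
class EDAWindow:
    """One stimulus-locked conductance trace with its label and provenance."""

    values: np.ndarray  # µS, strictly positive
    fs: float
    label: str
    subject_id: str
    rep: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(v <= 0):
            raise ValueError("conductance values must be strictly positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class WindowSet:
    """A homogeneous collection of windows under one protocol."""

    windows: list[EDAWindow]
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        n = self.protocol.n_samples
        for w in self.windows:
            if len(w) != n or w.fs != self.protocol.fs:
                raise ValueError(
                    f"window ({w.subject_id}, {w.label}, rep {w.rep}) does not "
                    f"match protocol geometry ({n} samples @ {self.protocol.fs} Hz)"
                )
            if w.label not in self.protocol.labels:
                raise ValueError(f"unknown label {w.label!r}")

    def __len__(self) -> int:
        return len(self.windows)

    def values_matrix(self) -> np.ndarray:
        """(n_windows, n_samples) stack of the traces."""
        return np.stack([w.values for w in self.windows]) if self.windows else \
            np.empty((0, self.protocol.n_samples))

    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows])

    def subject_ids(self) -> np.ndarray:
        return np.array([w.subject_id for w in self.windows])

    def subset(self, labels: Sequence[str]) -> "WindowSet":
        keep = set(labels)
        return WindowSet([w for w in self.windows if w.label in keep], self.protocol)


@dataclass(frozen=True)
class SimParams:
    """Population-level simulation parameters.

    amplitude_means maps each label to the mean evoked SCR amplitude (µS);
    labels absent from the mapping get an amplitude interpolated monotonically
    by label order. Spontaneous SCRs occur at the same Poisson rate in every
    label, mirroring the fact that SCRs are not specific to pain.
    """

    amplitude_means: dict[str, float] | None = None
    amplitude_cv: float = 0.25  # sd of evoked amplitude = cv * mean
    scale_sigma: float = 0.7  # log-sd of the per-subject amplitude scale
    p_spont: float = 0.2  # expected spontaneous SCRs per window
    spont_amp_range: tuple[float, float] = (0.05, 0.3)  # µS
    nonresponder_prob: float = 0.1
    baseline_range: tuple[float, float] = (2.0, 12.0)  # µS
    drift_mean: float = -0.005  # µS/s
    drift_sd: float = 0.003
    noise_sd: float = 0.01  # µS
    tau_rise: float = 0.75  # s
    tau_decay: float = 4.0  # s
    tonic_gain: float = 2.5  # evoked SCL ramp amplitude, x phasic amplitude
    tonic_tau: float = 6.0  # s, rise constant of the evoked SCL ramp
    wander_sd: float = 0.05  # µS, sd of the slow SCL wander amplitude
    wander_freq: tuple[float, float] = (0.02, 0.05)  # Hz, wander arc band

    def label_amplitude(self, label: str, labels: tuple[str, ...]) -> float:
        if self.amplitude_means is not None and label in self.amplitude_means:
            return float(self.amplitude_means[label])
        # monotone default ramp: first label 0 (no pain) up to 0.5 µS
        defaults_5 = [0.0, 0.05, 0.1, 0.25, 0.5]
        k = labels.index(label)
        if len(labels) == 1:
            return 0.0
        if len(labels) <= 5:
            # take the first and last of the canonical ramp, spread in between
            pts = np.linspace(0, 4, len(labels))
            return float(np.interp(pts[k], np.arange(5), defaults_5))
        return float(0.5 * k / (len(labels) - 1))


def scr_kernel(t: np.ndarray | float, tau_rise: float = 0.75,
               tau_decay: float = 4.0) -> np.ndarray:
    """Unit-peak Bateman pulse h(t) = (e^(-t/tau_decay) - e^(-t/tau_rise)) / peak.

    Zero for t < 0; peak value exactly 1 at
    t* = tau_rise*tau_decay/(tau_decay - tau_rise) * ln(tau_decay/tau_rise).
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("requires 0 < tau_rise < tau_decay")
    t = np.asarray(t, dtype=float)
    t_peak = scr_peak_time(tau_rise, tau_decay)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = np.where(
        t >= 0,
        (np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise)) / peak,
        0.0,
    )
    return out


def scr_peak_time(tau_rise: float = 0.75, tau_decay: float = 4.0) -> float:
    """Closed-form argmax of the Bateman pulse."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("requires 0 < tau_rise < tau_decay")
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def _evoked_peak_window(window_s: float, tau_rise: float, tau_decay: float
                        ) -> tuple[float, float]:
    """Admissible evoked-peak latency range.

    Peaks land 3-6 s post-stimulus when the window permits; shorter windows
    fall back to [0.3, 0.6] * window_s. The lower edge is clamped so the SCR
    onset stays inside the window.
    """
    t_peak = scr_peak_time(tau_rise, tau_decay)
    if window_s >= 6.0 + 0.25:
        lo, hi = 3.0, 6.0
    else:
        lo, hi = 0.3 * window_s, 0.6 * window_s
    lo = max(lo, t_peak + 0.05)
    hi = max(hi, lo)
    return lo, hi


def generate_window(profile: SubjectProfile, label: str,
                    protocol: StimulusProtocol, rng: np.random.Generator,
                    params: SimParams | None = None) -> EDAWindow:
    """Simulate one stimulus-locked window for one subject.

    values = baseline + drift*t + noise + evoked SCR + spontaneous SCRs,
    clipped to a strictly positive conductance floor.
    """
    params = params or SimParams()
    if label not in protocol.labels:
        raise ValueError(f"unknown label {label!r}; protocol has {protocol.labels}")
    n = protocol.n_samples
    t = np.arange(n) / protocol.fs
    x = profile.baseline_scl + profile.drift_rate * t
    if profile.noise_sd > 0:
        x = x + rng.normal(0.0, profile.noise_sd, size=n)

    amp_mean = params.label_amplitude(label, protocol.labels)
    if amp_mean > 0 and profile.amplitude_scale > 0:
        amp = max(0.0, rng.normal(amp_mean, params.amplitude_cv * amp_mean))
        amp *= profile.amplitude_scale
        if amp > 0:
            lo, hi = _evoked_peak_window(protocol.window_s, params.tau_rise,
                                         params.tau_decay)
            peak_t = rng.uniform(lo, min(hi, protocol.window_s))
            onset_t = peak_t - scr_peak_time(params.tau_rise, params.tau_decay)
            dt = t - onset_t
            x = x + amp * scr_kernel(dt, params.tau_rise, params.tau_decay)
            if params.tonic_gain > 0:
                ramp = np.where(dt >= 0, 1.0 - np.exp(-np.maximum(dt, 0)
                                                      / params.tonic_tau), 0.0)
                x = x + amp * params.tonic_gain * ramp

    # slow tonic wander: a partial arc of a 20-50 s oscillation, anchored at 0
    # at window start, emulating resting SCL meandering in every label
    if params.wander_sd > 0:
        arc_amp = abs(rng.normal(0.0, params.wander_sd))
        arc_f = rng.uniform(*params.wander_freq)
        arc_phase = rng.uniform(0.0, 2 * np.pi)
        x = x + arc_amp * (np.sin(2 * np.pi * arc_f * t + arc_phase)
                           - np.sin(arc_phase))

    # spontaneous SCRs: same rate for every label, scaled like evoked activity
    n_spont = rng.poisson(params.p_spont)
    for _ in range(n_spont):
        amp = rng.uniform(*params.spont_amp_range) * profile.amplitude_scale
        onset_t = rng.uniform(0.0, protocol.window_s)
        if amp > 0:
            x = x + amp * scr_kernel(t - onset_t, params.tau_rise, params.tau_decay)

    np.maximum(x, CONDUCTANCE_FLOOR, out=x)
    return EDAWindow(values=x, fs=protocol.fs, label=label,
                     subject_id=profile.subject_id, rep=0)


def _draw_profile(subject_id: str, rng: np.random.Generator,
                  params: SimParams) -> SubjectProfile:
    baseline = rng.uniform(*params.baseline_range)
    drift = rng.normal(params.drift_mean, params.drift_sd)
    responder = bool(rng.random() >= params.nonresponder_prob)
    amp_scale = float(np.exp(rng.normal(0.0, params.scale_sigma))) \
        if responder else 0.0
    return SubjectProfile(
        subject_id=subject_id,
        baseline_scl=baseline,
        drift_rate=drift,
        noise_sd=params.noise_sd,
        responder=responder,
        amplitude_scale=amp_scale,
    )


def generate_dataset(protocol: StimulusProtocol,
                     params: SimParams | None = None,
                     seed: int = 0) -> WindowSet:
    """Simulate one window per (subject, label, repetition).

    Deterministic for a fixed seed; subject profiles are drawn once per
    subject from the population distributions in ``params``.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    n_sub = protocol.n_subjects
    width = max(2, len(str(max(n_sub - 1, 0))))
    windows: list[EDAWindow] = []
    for s in range(n_sub):
        profile = _draw_profile(f"S{s:0{width}d}", rng, params)
        for label in protocol.labels:
            for rep in range(protocol.reps_per_label):
                w = generate_window(profile, label, protocol, rng, params)
                windows.append(EDAWindow(values=w.values, fs=w.fs, label=w.label,
                                         subject_id=w.subject_id, rep=rep))
    return WindowSet(windows=windows, protocol=protocol)


def sim_params_dict(params: SimParams) -> dict:
    """JSON-serialisable view of the simulation parameters."""
    d = asdict(params)
    d["spont_amp_range"] = list(d["spont_amp_range"])
    d["baseline_range"] = list(d["baseline_range"])
    return d
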