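"""Synthetic cohorts with the generative structure the analysis assumes.

The signal model mirrors the study's observed dissociation: the fundamental
ssVEP amplitude (7.5 Hz) carries an aversive-context offset, while the second
harmonic (15 Hz) carries a CS+-peaked generalization gradient over the cue
orientations.  Epochs add an occipitally peaked topography and 1/f background
noise; pupil traces add blink gaps; ratings add subject intercepts and
truncation to the 0-100 expectancy scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .epochs import EPOCH_WINDOW_MS, SFREQ, EpochArray, epoch_times_ms
from .schedule import CS_PLUS, ORIENTATIONS, TrialSchedule
from .sensors import SensorNet

# substream tags so each generator draws from an independent stream of the
# same master seed
_STREAM_EEG = 11
_STREAM_PUPIL = 12
_STREAM_RATINGS = 13
_STREAM_SUBJECT = 14

PUPIL_SFREQ = 60.0
PUPIL_WINDOW_MS = (-500.0, 4000.0)


@dataclass(frozen=True)
class GenParams:
    """Generative parameters of the synthetic cohort.

    Amplitudes are in microvolts at the topography peak.  The harmonic
    gradient and the pupil/rating gradients share a Gaussian tuning over
    orientation distance from the CS+ (``a2_gradient_width_deg``).
    """

    n_subjects: int = 52
    f0_hz: float = 7.5
    # fundamental: context offset, no cue tuning
    a1_base: float = 1.0
    a1_context_offset: float = 0.3
    # second harmonic: CS+-peaked generalization gradient
    a2_base: float = 0.8
    a2_gradient_peak: float = 0.5
    a2_gradient_width_deg: float = 15.0
    phase1_rad: float = 0.0
    phase2_rad: float = 0.0
    # 1/f^a background noise, microvolts RMS per sensor; raw single-trial
    # EEG dwarfs the ~1 uV ssVEP, which only emerges in narrowband averages
    noise_exponent: float = 1.0
    noise_scale: float = 15.0
    # multiplicative between-subject amplitude variability (log-normal sd)
    subject_sd: float = 0.2
    # occipital topography concentration (von-Mises-like kernel)
    topo_kappa: float = 8.0
    # US-expectancy rating model, 0-100 scale
    rating_base: float = 10.0
    rating_gradient: float = 60.0
    rating_context_offset: float = 5.0
    rating_noise_sd: float = 10.0
    rating_subject_sd: float = 8.0
    # pupil model, mm
    pupil_baseline_mm: float = 3.5
    pupil_gain_mm: float = 0.15
    pupil_context_offset_mm: float = 0.05
    pupil_subject_sd_mm: float = 0.08
    pupil_trial_sd_mm: float = 0.35
    pupil_noise_sd_mm: float = 0.05
    blink_rate_hz: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("a1_base", "a1_context_offset", "a2_base",
                     "a2_gradient_peak", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if not 0 <= self.blink_rate_hz < 1:
            raise ValueError("blink_rate_hz must be in [0, 1)")

    def with_(self, **kw) -> "GenParams":
        return replace(self, **kw)


def gradient(orientation_deg, width_deg) -> np.ndarray:
    """Gaussian tuning in orientation distance from the CS+ (peak 1 at CS+)."""
    d = np.abs(np.asarray(orientation_deg, dtype=float) - CS_PLUS)
    return np.exp(-(d**2) / (2.0 * width_deg**2))


def _subject_gain(params: GenParams, subject_id: int) -> float:
    rng = np.random.default_rng([params.seed, int(subject_id), _STREAM_SUBJECT])
    return float(np.exp(params.subject_sd * rng.standard_normal()))


def occipital_topography(net: SensorNet, kappa: float) -> np.ndarray:
    """Spatial weights peaked at the occipital pool centre (max weight 1)."""
    pool = net.pool_indices()
    centre = net.positions[pool].mean(axis=0)
    centre /= np.linalg.norm(centre)
    cosang = np.clip(net.positions @ centre, -1.0, 1.0)
    return np.exp(kappa * (cosang - 1.0))


def _one_over_f_noise(rng, shape, n_samples, sfreq, exponent, scale):
    """Batched 1/f^a noise with exact unit-variance normalization."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    gain = np.empty_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = 0.0  # no DC power
    # variance of irfft(rfft(white)*gain) for unit white noise
    g2 = gain**2
    if n_samples % 2 == 0:
        var = (g2[0] + 2.0 * g2[1:-1].sum() + g2[-1]) / n_samples
    else:
        var = (g2[0] + 2.0 * g2[1:].sum()) / n_samples
    out = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    return out * (scale / np.sqrt(var))


def trial_amplitudes(schedule: TrialSchedule, params: GenParams):
    """Per-trial (a1, a2) amplitudes implied by the signal model."""
    ori = schedule.records["orientation_deg"].to_numpy()
    aversive = (schedule.records["context"] == "aversive").to_numpy()
    a1 = params.a1_base + params.a1_context_offset * aversive
    a2 = params.a2_base + params.a2_gradient_peak * gradient(
        ori, params.a2_gradient_width_deg
    )
    return a1, a2


def generate_eeg_epochs(
    schedule: TrialSchedule,
    params: GenParams,
    net: SensorNet,
    subject_id: int,
) -> EpochArray:
    """Synthesize epoched EEG for one subject.

    Per trial the cue-locked signal is ``a1 cos(2 pi f0 t + phi1) +
    a2 cos(4 pi f0 t + phi2)`` during cue-on time, spatially weighted by the
    occipital topography, plus 1/f background noise.  Deterministic for a
    fixed ``(params.seed, subject_id)``.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng([params.seed, int(subject_id), _STREAM_EEG])
    times = epoch_times_ms(SFREQ, EPOCH_WINDOW_MS)
    t = times / 1000.0
    on = t >= 0.0
    n_trials = len(schedule)
    n_sensors = net.n_sensors
    n_samples = len(t)

    gain = _subject_gain(params, subject_id)
    a1, a2 = trial_amplitudes(schedule, params)
    w = 2.0 * np.pi * params.f0_hz
    carrier1 = np.where(on, np.cos(w * t + params.phase1_rad), 0.0)
    carrier2 = np.where(on, np.cos(2.0 * w * t + params.phase2_rad), 0.0)
    # trials x samples
    sig = gain * (np.outer(a1, carrier1) + np.outer(a2, carrier2))
    topo = occipital_topography(net, params.topo_kappa)
    data = topo[None, :, None] * sig[:, None, :]
    if params.noise_scale > 0:
        data = data + _one_over_f_noise(
            rng, (n_trials, n_sensors), n_samples, SFREQ,
            params.noise_exponent, params.noise_scale,
        )

    labels = schedule.records[["orientation_deg", "context", "phase"]].copy()
    labels["half"] = "none"
    return EpochArray(data, SFREQ, times, labels, net.sensor_ids)


# -- artifact injection --------------------------------------------------

@dataclass(frozen=True)
class ArtifactEvent:
    """A ground-truth artifact planted at one (trial, sensor)."""

    trial: int
    sensor: int
    kind: str  # {"spike", "drift", "flatline"}
    magnitude: float = 500.0


def inject_artifacts(
    epochs: EpochArray, events, seed: int = 0
) -> tuple[EpochArray, list]:
    """Return a copy of ``epochs`` with artifacts added at listed locations.

    Spikes add ``magnitude`` at a seeded random sample, drifts add a linear
    ramp from 0 to ``magnitude``, flatlines replace the channel with its
    first sample value.  The event list is returned unchanged as ground
    truth for screening tests.
    """
    out = epochs.copy()
    rng = np.random.default_rng(seed)
    n_trials, n_sensors, n_samples = out.data.shape
    for ev in events:
        if not (0 <= ev.trial < n_trials and 0 <= ev.sensor < n_sensors):
            raise IndexError(
                f"artifact event out of range: trial={ev.trial}, "
                f"sensor={ev.sensor}"
            )
        ch = out.data[ev.trial, ev.sensor]
        if ev.kind == "spike":
            ch[rng.integers(n_samples)] += ev.magnitude
        elif ev.kind == "drift":
            ch += np.linspace(0.0, ev.magnitude, n_samples)
        elif ev.kind == "flatline":
            ch[:] = ch[0]
        else:
            raise ValueError(f"unknown artifact kind {ev.kind!r}")
    return out, list(events)


# -- pupil ---------------------------------------------------------------

@dataclass
class PupilTraceSet:
    """Per-trial pupil diameter traces at 60 Hz with a missing-sample mask."""

    traces: np.ndarray  # trials x samples, mm (NaN where missing)
    missing_mask: np.ndarray  # trials x samples bool
    times_ms: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.traces.shape != self.missing_mask.shape:
            raise ValueError("traces and missing_mask shapes differ")
        step = 1000.0 / PUPIL_SFREQ
        if not np.allclose(np.diff(self.times_ms), step, atol=1e-9):
            raise ValueError("pupil times must be uniform at 1000/60 ms")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    def copy(self) -> "PupilTraceSet":
        return PupilTraceSet(
            self.traces.copy(), self.missing_mask.copy(),
            np.asarray(self.times_ms).copy(), self.labels.copy(),
        )


def pupil_times_ms() -> np.ndarray:
    step = 1000.0 / PUPIL_SFREQ
    n0 = int(np.round(PUPIL_WINDOW_MS[0] / step))
    n1 = int(np.round(PUPIL_WINDOW_MS[1] / step))
    return np.arange(n0, n1 + 1) * step


def pupil_response_shape(t_s: np.ndarray) -> np.ndarray:
    """Normalized event-related dilation: smooth rise over 1 s, then hold."""
    t = np.asarray(t_s, dtype=float)
    r = np.where(t <= 0.0, 0.0, 0.5 * (1.0 - np.cos(np.pi * np.minimum(t, 1.0))))
    return r


def generate_pupil(
    schedule: TrialSchedule, params: GenParams, subject_id: int
) -> PupilTraceSet:
    """Synthesize per-trial pupil traces with blink gaps for one subject.

    Dilation amplitude is ``pupil_gain_mm * gradient(orientation) +
    pupil_context_offset_mm`` in aversive blocks; blinks arrive as a Poisson
    process at ``blink_rate_hz`` and mask 100-300 ms of samples.
    """
    rng = np.random.default_rng([params.seed, int(subject_id), _STREAM_PUPIL])
    times = pupil_times_ms()
    t = times / 1000.0
    shape = pupil_response_shape(t)
    ori = schedule.records["orientation_deg"].to_numpy()
    aversive = (schedule.records["context"] == "aversive").to_numpy()
    subject_shift = params.pupil_subject_sd_mm * rng.standard_normal()
    amp = (
        params.pupil_gain_mm * gradient(ori, params.a2_gradient_width_deg)
        + params.pupil_context_offset_mm * aversive
        + subject_shift
        # trial-to-trial arousal fluctuations dominate pupil variability
        + params.pupil_trial_sd_mm * rng.standard_normal(len(ori))
    )
    traces = params.pupil_baseline_mm + np.outer(amp, shape)
    if params.pupil_noise_sd_mm > 0:
        traces = traces + params.pupil_noise_sd_mm * rng.standard_normal(
            traces.shape
        )
    mask = np.zeros(traces.shape, dtype=bool)
    if params.blink_rate_hz > 0:
        span_s = (times[-1] - times[0]) / 1000.0
        for i in range(traces.shape[0]):
            n_blinks = rng.poisson(params.blink_rate_hz * span_s)
            for _ in range(n_blinks):
                start = rng.uniform(0.0, span_s)
                dur = rng.uniform(0.1, 0.3)
                sel = (t - t[0] >= start) & (t - t[0] < start + dur)
                mask[i, sel] = True
        traces = np.where(mask, np.nan, traces)
    labels = schedule.records[["orientation_deg", "context", "phase"]].copy()
    return PupilTraceSet(traces, mask, times, labels)


# -- ratings -------------------------------------------------------------

def generate_ratings(
    params: GenParams,
    n_subjects: int | None = None,
    seed: int | None = None,
    contexts=("aversive", "neutral"),
) -> pd.DataFrame:
    """US-expectancy rating table (subject x orientation x context, 0-100).

    value = base + gradient * tuning(orientation) + context offset +
    subject intercept + noise, clipped to the rating scale.  Pass
    ``contexts=("none",)`` for the post-acquisition ratings.
    """
    n_subjects = params.n_subjects if n_subjects is None else n_subjects
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(
        [params.seed if seed is None else seed, _STREAM_RATINGS]
    )
    rows = []
    tuning = gradient(ORIENTATIONS, params.a2_gradient_width_deg)
    for s in range(n_subjects):
        intercept = params.rating_subject_sd * rng.standard_normal()
        for ctx in contexts:
            offset = params.rating_context_offset if ctx == "aversive" else 0.0
            for ori, g in zip(ORIENTATIONS, tuning):
                val = (
                    params.rating_base
                    + params.rating_gradient * g
                    + offset
                    + intercept
                    + params.rating_noise_sd * rng.standard_normal()
                )
                rows.append((s, int(ori), ctx, float(np.clip(val, 0.0, 100.0))))
    return pd.DataFrame(
        rows, columns=["subject", "orientation_deg", "context", "rating"]
    )
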