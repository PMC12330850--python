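"""Pupil preprocessing: blink interpolation, 2 Hz low-pass, baseline, window mean.

The pipeline operates on per-trial diameter traces at 60 Hz spanning -500 to
+4000 ms around cue onset: linear interpolation of missing samples, a
zero-phase 2 Hz low-pass, subtraction of the -500..0 ms baseline mean, and
the mean change within 500-4000 ms as the scalar response.  Binocular
averaging happens upstream of this module (the synthetic generator emits a
single averaged trace); ``average_eyes`` is the documented pass-through hook.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .synth import PUPIL_SFREQ, PupilTraceSet

BASELINE_MS = (-500.0, 0.0)
RESPONSE_WINDOW_MS = (500.0, 4000.0)


def average_eyes(left: PupilTraceSet, right: PupilTraceSet) -> PupilTraceSet:
    """Average binocular traces; a sample is missing iff missing in both."""
    out = left.copy()
    both = np.stack([left.traces, right.traces])
    with np.errstate(invalid="ignore"):
        out.traces = np.nanmean(both, axis=0)
    out.missing_mask = left.missing_mask & right.missing_mask
    out.traces[out.missing_mask] = np.nan
    return out


def interpolate_missing(traces: PupilTraceSet) -> tuple[PupilTraceSet, list]:
    """Linearly interpolate blink/tracking gaps between flanking samples.

    Leading and trailing gaps are filled by nearest-valid extension.
    Trials without any valid sample cannot be reconstructed; they are
    dropped and their indices returned.
    """
    out = traces.copy()
    t = np.asarray(out.times_ms, dtype=float)
    excluded = []
    for i in range(out.n_trials):
        valid = ~out.missing_mask[i]
        if valid.sum() == 0:
            excluded.append(i)
            continue
        if valid.all():
            continue
        out.traces[i] = np.interp(t, t[valid], out.traces[i, valid])
    out.missing_mask[:] = False
    if excluded:
        keep = np.setdiff1d(np.arange(out.n_trials), excluded)
        out = PupilTraceSet(
            out.traces[keep], out.missing_mask[keep], out.times_ms,
            out.labels.iloc[keep],
        )
    return out, excluded


def lowpass_2hz(
    traces: PupilTraceSet, cutoff_hz: float = 2.0, order: int = 2
) -> PupilTraceSet:
    """Zero-phase Butterworth low-pass of each trace."""
    if np.isnan(traces.traces).any():
        raise ValueError("interpolate missing samples before filtering")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=PUPIL_SFREQ,
                        output="sos")
    out = traces.copy()
    out.traces = signal.sosfiltfilt(sos, out.traces, axis=-1)
    return out


def baseline_correct(
    traces: PupilTraceSet, baseline_ms=BASELINE_MS
) -> PupilTraceSet:
    """Subtract the per-trial baseline-window mean from every sample."""
    t = np.asarray(traces.times_ms, dtype=float)
    sel = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not sel.any():
        raise ValueError("baseline window outside the trace")
    out = traces.copy()
    base = out.traces[:, sel]
    if np.isnan(base).all(axis=1).any():
        raise ValueError("baseline fully missing in at least one trial")
    out.traces = out.traces - np.nanmean(base, axis=1, keepdims=True)
    return out


def mean_response(
    traces: PupilTraceSet, window_ms=RESPONSE_WINDOW_MS
) -> np.ndarray:
    """Per-trial mean diameter change within the response window (mm)."""
    t = np.asarray(traces.times_ms, dtype=float)
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    if not sel.any():
        raise ValueError("response window outside the trace")
    return traces.traces[:, sel].mean(axis=1)


def preprocess_pupil(
    traces: PupilTraceSet,
    max_missing_fraction: float | None = None,
) -> tuple[PupilTraceSet, np.ndarray]:
    """Full pupil pipeline; returns preprocessed traces and scalar responses.

    ``max_missing_fraction`` optionally drops trials with more than that
    fraction of missing samples before interpolation (off by default).
    """
    if max_missing_fraction is not None:
        frac = traces.missing_mask.mean(axis=1)
        keep = np.flatnonzero(frac <= max_missing_fraction)
        traces = PupilTraceSet(
            traces.traces[keep], traces.missing_mask[keep], traces.times_ms,
            traces.labels.iloc[keep],
        )
    filled, _ = interpolate_missing(traces)
    smoothed = lowpass_2hz(filled)
    corrected = baseline_correct(smoothed)
    return corrected, mean_response(corrected)


def condition_means(
    traces: PupilTraceSet, responses: np.ndarray, subject: int
) -> pd.DataFrame:
    """Aggregate per-trial responses to subject x condition means."""
    df = traces.labels.copy()
    df["response_mm"] = responses
    out = (
        df.groupby(["orientation_deg", "context"])["response_mm"]
        .mean()
        .reset_index()
    )
    out.insert(0, "subject", subject)
    return out
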