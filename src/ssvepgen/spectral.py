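"""CSD transform, FFT power spectra and harmonic SNR extraction.

Power spectra are computed on the 600-3900 ms post-onset window of the
condition-average waveforms.  Because 3300 ms is not an integer number of
7.5 Hz cycles at 500 Hz, the window is truncated to the largest whole number
of driving-frequency cycles (3200 ms, bin width 0.3125 Hz), which places the
fundamental (bin 24) and second harmonic (bin 48) exactly on FFT bins as the
neighbour-bin SNR formula requires.

SNR at a target bin is its power divided by the mean power of six adjacent
bins, skipping the two immediate neighbours (offsets +/-2, +/-3, +/-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ConditionAverage
from .sensors import SensorNet
from .splines import DEFAULT_LAMBDA, DEFAULT_M, DEFAULT_TERMS, csd_matrix

F_FUNDAMENTAL = 7.5
F_HARMONIC = 15.0
ANALYSIS_WINDOW_MS = (600.0, 3900.0)


def csd_transform(
    avg: ConditionAverage,
    net: SensorNet,
    lam: float = DEFAULT_LAMBDA,
    m: int = DEFAULT_M,
    n_terms: int = DEFAULT_TERMS,
) -> ConditionAverage:
    """Current-source-density transform of condition averages.

    Linear in the input; requires a reasonably dense montage of valid
    unit-sphere positions.
    """
    if net.n_sensors < 32:
        raise ValueError("CSD needs at least 32 sensors")
    if tuple(net.sensor_ids) != tuple(avg.sensor_ids):
        raise ValueError("sensor net does not match the condition average")
    T = csd_matrix(net.positions, lam=lam, m=m, n_terms=n_terms)
    return avg.map(lambda v: T @ v, units="CSD")


@dataclass
class PowerSpectrum:
    """Per-sensor power spectrum (squared amplitude units per bin)."""

    power: np.ndarray  # sensors x bins
    freqs_hz: np.ndarray
    bin_width_hz: float
    window_ms: tuple

    def bin_index(self, target_hz: float, tol: float = 1e-6) -> int:
        k = target_hz / self.bin_width_hz
        if abs(k - round(k)) > tol:
            raise ValueError(
                f"{target_hz} Hz is not on a bin (width {self.bin_width_hz} Hz)"
            )
        k = int(round(k))
        if not 0 <= k < len(self.freqs_hz):
            raise ValueError(f"{target_hz} Hz outside the spectrum")
        return k


def power_spectrum(
    data: np.ndarray,
    times_ms: np.ndarray,
    sfreq: float,
    window_ms=ANALYSIS_WINDOW_MS,
    align_cycles_to_hz: float = F_FUNDAMENTAL,
) -> PowerSpectrum:
    """Squared-amplitude FFT spectrum on a cycle-aligned analysis window.

    The window is truncated to the largest integer number of
    ``align_cycles_to_hz`` cycles and the mean is removed before the FFT.
    Normalization: a unit-amplitude sinusoid at a bin frequency yields
    power 1.0 in its bin.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    times_ms = np.asarray(times_ms, dtype=float)
    sel = np.flatnonzero((times_ms >= window_ms[0]) & (times_ms < window_ms[1]))
    if sel.size == 0:
        raise ValueError("analysis window outside the epoch")
    avail_s = sel.size / sfreq
    n_cycles = int(np.floor(avail_s * align_cycles_to_hz + 1e-9))
    if n_cycles < 1:
        raise ValueError("analysis window shorter than one cycle")
    n_samples = int(round(n_cycles / align_cycles_to_hz * sfreq))
    sel = sel[:n_samples]
    seg = data[:, sel]
    seg = seg - seg.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(seg, axis=-1)
    amp = np.abs(spec) * 2.0 / n_samples
    amp[:, 0] /= 2.0
    if n_samples % 2 == 0:
        amp[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    return PowerSpectrum(
        power=amp**2,
        freqs_hz=freqs,
        bin_width_hz=float(freqs[1]),
        window_ms=(times_ms[sel[0]], times_ms[sel[-1]] + 1000.0 / sfreq),
    )


def compute_power_spectrum(
    avg: ConditionAverage,
    window_ms=ANALYSIS_WINDOW_MS,
    align_cycles_to_hz: float = F_FUNDAMENTAL,
) -> dict:
    """Power spectrum per condition of a ConditionAverage."""
    return {
        cond: power_spectrum(
            v, avg.times_ms, avg.sfreq, window_ms, align_cycles_to_hz
        )
        for cond, v in avg.data.items()
    }


def snr_at(
    spectrum: PowerSpectrum,
    target_hz: float,
    n_noise_bins_per_side: int = 3,
    skip_immediate: int = 1,
) -> np.ndarray:
    """Per-sensor SNR: target-bin power over the mean of neighbour bins.

    Neighbours are the ``n_noise_bins_per_side`` bins on each side after
    skipping ``skip_immediate`` immediate neighbours (default offsets
    +/-2, +/-3, +/-4).
    """
    k = spectrum.bin_index(target_hz)
    offsets = np.arange(skip_immediate + 1,
                        skip_immediate + 1 + n_noise_bins_per_side)
    idx = np.concatenate([k - offsets[::-1], k + offsets])
    if idx.min() < 0 or idx.max() >= spectrum.power.shape[1]:
        raise ValueError(
            f"noise bins out of range for target {target_hz} Hz"
        )
    noise = spectrum.power[:, idx].mean(axis=1)
    return spectrum.power[:, k] / noise


def pool_sensors(snr_per_sensor: np.ndarray, net: SensorNet) -> float:
    """Arithmetic mean SNR over the occipital analysis pool."""
    snr_per_sensor = np.asarray(snr_per_sensor, dtype=float)
    missing = [s for s in net.occipital_pool if s not in net.sensor_ids]
    if missing:
        raise ValueError(f"pool sensors missing from net: {missing}")
    if not net.occipital_pool:
        raise ValueError("sensor net defines no occipital pool")
    return float(snr_per_sensor[net.pool_indices()].mean())


def extract_snr_table(
    avg_csd: ConditionAverage,
    net: SensorNet,
    subject: int,
    frequencies=(F_FUNDAMENTAL, F_HARMONIC),
    window_ms=ANALYSIS_WINDOW_MS,
    align_cycles_to_hz: float = F_FUNDAMENTAL,
) -> pd.DataFrame:
    """Tidy SNR rows (per sensor and pooled) for one subject's averages.

    Returns columns: subject, orientation_deg, context, frequency_hz,
    sensor, snr, pooled.  Pooled rows carry sensor="pool".
    """
    spectra = compute_power_spectrum(avg_csd, window_ms, align_cycles_to_hz)
    rows = []
    for cond, spec in spectra.items():
        ori, ctx = cond
        for f in frequencies:
            snr = snr_at(spec, f)
            for sid, val in zip(net.sensor_ids, snr):
                rows.append((subject, ori, ctx, f, sid, float(val), False))
            rows.append((subject, ori, ctx, f, "pool",
                         pool_sensors(snr, net), True))
    return pd.DataFrame(
        rows,
        columns=["subject", "orientation_deg", "context", "frequency_hz",
                 "sensor", "snr", "pooled"],
    )
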