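"""EEG preprocessing: filtering, artifact screening, interpolation, averaging.

Artifact handling follows the statistical-screening approach for dense-array
recordings (SCADS): per (trial, sensor) the absolute maximum, standard
deviation and maximum successive difference are computed, robust-z scored
against their distributions both over trials (within sensor) and over
sensors (within trial), and cells exceeding the threshold in either
comparison are flagged.  Flagged sensors are replaced by spherical-spline
interpolation; trials with more than ``max_bad_sensors`` flagged sensors are
rejected outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import EpochArray
from .sensors import SensorNet
from .splines import DEFAULT_M, DEFAULT_TERMS, interpolation_matrix

DEFAULT_Z = 3.0
DEFAULT_MAX_BAD = 20
_MAD_SCALE = 1.4826  # MAD -> sd for a normal distribution


def lowpass_filter(
    epochs: EpochArray, cutoff_hz: float = 40.0, order: int = 4
) -> EpochArray:
    """Zero-phase Butterworth low-pass, applied per trial and sensor.

    The forward-backward pass doubles the effective order, so the default
    4th-order design attenuates by more than 40 dB at twice the cutoff.
    """
    if cutoff_hz >= epochs.sfreq / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz at or above Nyquist ({epochs.sfreq / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=epochs.sfreq,
                        output="sos")
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


@dataclass
class ArtifactReport:
    """Screening outcome: per-cell flags, interpolation marks, rejections."""

    sensor_flags: np.ndarray  # trials x sensors bool
    interpolated: np.ndarray  # trials x sensors bool
    rejected_trials: np.ndarray  # trial indices
    stats: np.ndarray  # trials x sensors x 3 (absmax, sd, maxdiff)
    z_threshold: float
    max_bad_sensors: int

    @property
    def fraction_rejected(self) -> float:
        return len(self.rejected_trials) / self.sensor_flags.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "z_threshold": self.z_threshold,
            "max_bad_sensors": self.max_bad_sensors,
            "n_trials": int(self.sensor_flags.shape[0]),
            "rejected_trials": [int(t) for t in self.rejected_trials],
            "fraction_rejected": self.fraction_rejected,
            "flagged": [
                [int(t), int(s)] for t, s in np.argwhere(self.sensor_flags)
            ],
            "interpolated": [
                [int(t), int(s)] for t, s in np.argwhere(self.interpolated)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def screening_stats(epochs: EpochArray) -> np.ndarray:
    """Per (trial, sensor): absolute max, standard deviation, max |diff|."""
    d = epochs.data
    absmax = np.abs(d).max(axis=-1)
    sd = d.std(axis=-1)
    maxdiff = np.abs(np.diff(d, axis=-1)).max(axis=-1)
    return np.stack([absmax, sd, maxdiff], axis=-1)


def _robust_z(x: np.ndarray, axis: int) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    mad = np.median(np.abs(x - med), axis=axis, keepdims=True) * _MAD_SCALE
    dev = x - med
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev / mad
    # degenerate spread: identical values score 0, deviants infinity
    z = np.where(mad > 0, z, np.where(dev == 0, 0.0, np.inf))
    return z


def scads_screen(
    epochs: EpochArray,
    net: SensorNet | None = None,
    z_threshold: float = DEFAULT_Z,
    max_bad_sensors: int = DEFAULT_MAX_BAD,
) -> ArtifactReport:
    """Statistical artifact screening over trials and sensors.

    Each statistic is robust-z scored (median/MAD) against its distribution
    over trials within each sensor and over sensors within each trial; a
    cell is flagged if any |z| exceeds ``z_threshold`` in either direction
    of comparison.  Trials with more than ``max_bad_sensors`` flagged
    sensors are rejected; remaining flags are marked for interpolation.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials to screen against")
    stats = screening_stats(epochs)
    z_over_trials = _robust_z(stats, axis=0)
    z_over_sensors = _robust_z(stats, axis=1)
    flags = (np.abs(z_over_trials) > z_threshold).any(axis=-1) | (
        np.abs(z_over_sensors) > z_threshold
    ).any(axis=-1)
    n_bad = flags.sum(axis=1)
    rejected = np.flatnonzero(n_bad > max_bad_sensors)
    interp = flags.copy()
    interp[rejected] = False
    return ArtifactReport(
        sensor_flags=flags,
        interpolated=interp,
        rejected_trials=rejected,
        stats=stats,
        z_threshold=z_threshold,
        max_bad_sensors=max_bad_sensors,
    )


def interpolate_sensors(
    epochs: EpochArray,
    report: ArtifactReport,
    net: SensorNet,
    m: int = DEFAULT_M,
    n_terms: int = DEFAULT_TERMS,
) -> EpochArray:
    """Replace flagged sensors by spherical-spline interpolated values.

    Only sensors marked for interpolation (flags on non-rejected trials) are
    touched; all other channels pass through bit-unchanged.  Rejected trials
    are left as-is for the caller to drop.
    """
    out = epochs.copy()
    for t in range(out.n_trials):
        bad = np.flatnonzero(report.interpolated[t])
        if bad.size == 0:
            continue
        good = np.setdiff1d(np.arange(out.n_sensors), bad)
        if good.size == 0:
            raise ValueError(f"all sensors flagged in trial {t}")
        T = interpolation_matrix(
            net.positions[good], net.positions[bad], m=m, n_terms=n_terms
        )
        out.data[t, bad] = T @ out.data[t, good]
    return out


@dataclass
class ConditionAverage:
    """Per-condition mean waveforms (sensors x samples) with trial counts."""

    data: dict  # condition tuple -> ndarray (sensors, samples)
    n_trials: dict  # condition tuple -> int
    times_ms: np.ndarray
    sfreq: float
    sensor_ids: tuple
    units: str = "uV"
    empty_cells: tuple = field(default=())

    @property
    def conditions(self) -> list:
        return list(self.data)

    def map(self, fn, units: str | None = None) -> "ConditionAverage":
        return ConditionAverage(
            {c: fn(v) for c, v in self.data.items()},
            dict(self.n_trials),
            self.times_ms,
            self.sfreq,
            self.sensor_ids,
            units or self.units,
            self.empty_cells,
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["sfreq"] = self.sfreq
            fh.attrs["units"] = self.units
            fh.create_dataset("times_ms", data=self.times_ms)
            fh.create_dataset(
                "sensor_ids", data=np.array(self.sensor_ids, dtype="S16")
            )
            grp = fh.create_group("conditions")
            for cond, wave in self.data.items():
                name = "|".join(str(c) for c in cond)
                ds = grp.create_dataset(name, data=wave)
                ds.attrs["n_trials"] = self.n_trials[cond]

    @classmethod
    def from_hdf5(cls, path) -> "ConditionAverage":
        import h5py

        with h5py.File(path, "r") as fh:
            times = fh["times_ms"][()]
            ids = tuple(s.decode() for s in fh["sensor_ids"][()])
            data, counts = {}, {}
            for name, ds in fh["conditions"].items():
                cond = tuple(
                    int(p) if p.lstrip("+-").isdigit() else p
                    for p in name.split("|")
                )
                data[cond] = ds[()]
                counts[cond] = int(ds.attrs["n_trials"])
            return cls(data, counts, times, float(fh.attrs["sfreq"]), ids,
                       units=str(fh.attrs["units"]))


def average_conditions(
    epochs: EpochArray,
    grouping=("orientation_deg", "context"),
    expected_cells=None,
) -> ConditionAverage:
    """Arithmetic-mean waveform per condition cell.

    Rejected trials must already be excluded.  Cells listed in
    ``expected_cells`` but absent from the data are recorded in
    ``empty_cells`` (feeding the participant-exclusion rule) and omitted.
    """
    grouping = list(grouping)
    data, counts = {}, {}
    for key, grp in epochs.labels.groupby(grouping, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        idx = grp.index.to_numpy()
        data[key] = epochs.data[idx].mean(axis=0)
        counts[key] = len(idx)
    empty = ()
    if expected_cells is not None:
        empty = tuple(c for c in expected_cells if tuple(c) not in data)
    return ConditionAverage(
        data, counts, epochs.times_ms, epochs.sfreq, epochs.sensor_ids,
        units="uV", empty_cells=empty,
    )


def split_halves_and_screen(
    epochs: EpochArray, rejected_trials=()
) -> tuple[EpochArray, bool]:
    """Label acquisition trials by half and apply the empty-cell rule.

    Halves are assigned by presentation order over all trials (first
    ceil(n/2) trials form half "1").  After dropping rejected trials the
    participant is excluded iff any orientation x half cell is empty.
    """
    out = epochs.copy()
    n = out.n_trials
    first = int(np.ceil(n / 2))
    out.labels["half"] = np.where(np.arange(n) < first, "1", "2")
    retained = out.drop_trials(np.asarray(rejected_trials, dtype=int))
    cells = retained.labels.groupby(["orientation_deg", "half"]).size()
    orientations = sorted(epochs.labels["orientation_deg"].unique())
    excluded = any(
        (ori, half) not in cells.index
        for ori in orientations
        for half in ("1", "2")
    )
    return out, excluded
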