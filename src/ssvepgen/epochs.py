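"""Epoched multichannel EEG container and epoch extraction.

Epochs span -600 ms pre-stimulus to +3900 ms post-stimulus at 500 Hz.  The
last 100 ms of the 4 s cue are excluded by construction of the window, so the
co-terminating aversive stimulation never contaminates the analysed signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

EPOCH_WINDOW_MS = (-600.0, 3900.0)
SFREQ = 500.0

LABEL_COLUMNS = ["orientation_deg", "context", "phase", "half"]


@dataclass
class EpochArray:
    """Trials x sensors x samples EEG epochs with per-trial labels.

    ``times_ms`` is relative to cue onset and strictly uniform at
    ``1000 / sfreq`` ms.  ``labels`` carries one row per trial with columns
    orientation_deg, context, phase and half ("1", "2" or "none").
    """

    data: np.ndarray
    sfreq: float
    times_ms: np.ndarray
    labels: pd.DataFrame
    sensor_ids: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x samples")
        n_trials, n_sensors, n_samples = self.data.shape
        if self.times_ms.shape != (n_samples,):
            raise ValueError("times_ms length must match sample count")
        step = 1000.0 / self.sfreq
        if not np.allclose(np.diff(self.times_ms), step, atol=1e-9):
            raise ValueError("times_ms must be uniform at 1000/sfreq")
        if len(self.labels) != n_trials:
            raise ValueError("labels must have one row per trial")
        if len(self.sensor_ids) != n_sensors:
            raise ValueError("sensor_ids must match sensor count")
        self.sensor_ids = tuple(self.sensor_ids)
        if "half" not in self.labels.columns:
            self.labels = self.labels.assign(half="none")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochArray":
        return EpochArray(
            self.data.copy(), self.sfreq, self.times_ms.copy(),
            self.labels.copy(), self.sensor_ids,
        )

    def select_trials(self, index) -> "EpochArray":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return EpochArray(
            self.data[index], self.sfreq, self.times_ms,
            self.labels.iloc[index].reset_index(drop=True), self.sensor_ids,
        )

    def drop_trials(self, trial_indices) -> "EpochArray":
        keep = np.setdiff1d(np.arange(self.n_trials), np.asarray(trial_indices))
        return self.select_trials(keep)

    def time_mask(self, window_ms) -> np.ndarray:
        lo, hi = window_ms
        return (self.times_ms >= lo) & (self.times_ms < hi)

    # -- I/O -------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.create_dataset("times_ms", data=self.times_ms)
            fh.attrs["sfreq"] = self.sfreq
            fh.create_dataset(
                "sensor_ids",
                data=np.array(self.sensor_ids, dtype="S16"),
            )
            grp = fh.create_group("labels")
            grp.create_dataset(
                "orientation_deg",
                data=self.labels["orientation_deg"].to_numpy(int),
            )
            for col in ("context", "phase", "half"):
                grp.create_dataset(
                    col, data=self.labels[col].astype(str).to_numpy(dtype="S16")
                )

    @classmethod
    def from_hdf5(cls, path) -> "EpochArray":
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            times = fh["times_ms"][()]
            sfreq = float(fh.attrs["sfreq"])
            ids = tuple(s.decode() for s in fh["sensor_ids"][()])
            lab = {
                "orientation_deg": fh["labels/orientation_deg"][()],
            }
            for col in ("context", "phase", "half"):
                lab[col] = [s.decode() for s in fh[f"labels/{col}"][()]]
        return cls(data, sfreq, times, pd.DataFrame(lab), ids)


def epoch_times_ms(sfreq: float = SFREQ, window_ms=EPOCH_WINDOW_MS) -> np.ndarray:
    """Sample times for one epoch; t=0 is the first at-or-after-onset sample."""
    step = 1000.0 / sfreq
    n0 = int(np.ceil(window_ms[0] / step - 1e-9))
    n1 = int(np.ceil(window_ms[1] / step - 1e-9))
    return np.arange(n0, n1) * step


def load_brainvision(vhdr_path):
    """Load a BrainVision recording as (data_uV, sfreq, channel_names).

    Thin adapter over MNE for feeding real continuous recordings into
    :func:`extract_epochs`; MNE returns volts, this converts to microvolts.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), tuple(raw.ch_names)


def extract_epochs(
    continuous: np.ndarray,
    sfreq: float,
    onsets_s,
    window_ms=EPOCH_WINDOW_MS,
    labels: pd.DataFrame | None = None,
    sensor_ids=None,
) -> EpochArray:
    """Cut fixed windows around event onsets from a continuous recording.

    Parameters
    ----------
    continuous : ndarray, shape (n_sensors, n_samples)
    onsets_s : sequence of float
        Event onsets in seconds from recording start.  The sample at t=0 of
        each epoch is the first sample at or after the onset.

    Raises
    ------
    ValueError
        If any event's window does not fit inside the recording; the error
        names the offending event.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous must be sensors x samples")
    n_sensors, n_total = continuous.shape
    times = epoch_times_ms(sfreq, window_ms)
    step = 1000.0 / sfreq
    rel = np.round(times / step).astype(int)
    epochs = []
    for k, onset in enumerate(onsets_s):
        i0 = int(np.ceil(onset * sfreq - 1e-9))
        lo, hi = i0 + rel[0], i0 + rel[-1] + 1
        if lo < 0 or hi > n_total:
            raise ValueError(
                f"event {k} at {onset:.3f} s: window [{lo}, {hi}) exceeds "
                f"recording of {n_total} samples"
            )
        epochs.append(continuous[:, lo:hi])
    data = np.stack(epochs) if epochs else np.empty((0, n_sensors, len(times)))
    if labels is None:
        labels = pd.DataFrame(
            {
                "orientation_deg": np.zeros(len(epochs), dtype=int),
                "context": "none",
                "phase": "none",
                "half": "none",
            }
        )
    if sensor_ids is None:
        sensor_ids = tuple(f"S{i + 1}" for i in range(n_sensors))
    return EpochArray(data, sfreq, times, labels, sensor_ids)
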