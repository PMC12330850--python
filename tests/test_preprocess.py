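"""Epoch extraction, filtering, SCADS screening, interpolation, averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from ssvepgen import (
    ArtifactEvent,
    EpochArray,
    GenParams,
    average_conditions,
    extract_epochs,
    generate_eeg_epochs,
    inject_artifacts,
    interpolate_sensors,
    lowpass_filter,
    scads_screen,
    split_halves_and_screen,
)
from ssvepgen.epochs import epoch_times_ms
from ssvepgen.preprocess import screening_stats


def _sine_epochs(freq_hz, n_trials=1, n_sensors=2, sfreq=500.0, amp=1.0):
    times = epoch_times_ms(sfreq)
    t = times / 1000.0
    data = np.broadcast_to(
        amp * np.sin(2 * np.pi * freq_hz * t), (n_trials, n_sensors, len(t))
    ).copy()
    labels = pd.DataFrame(
        {"orientation_deg": 45, "context": "none", "phase": "none",
         "half": "none"}, index=range(n_trials),
    )
    return EpochArray(data, sfreq, times, labels,
                      tuple(f"S{i+1}" for i in range(n_sensors)))


# -- extraction ----------------------------------------------------------

def test_extract_epochs_shape_and_slice_oracle():
    sfreq = 500.0
    cont = np.arange(2 * 10000, dtype=float).reshape(2, 10000)
    onsets = [2.0, 5.0, 10.0]
    out = extract_epochs(cont, sfreq, onsets)
    assert out.data.shape == (3, 2, 2250)
    for k, onset in enumerate(onsets):
        i0 = int(np.ceil(onset * sfreq))
        np.testing.assert_array_equal(
            out.data[k], cont[:, i0 - 300 : i0 + 1950]
        )
    assert out.times_ms[300] == 0.0


def test_extract_epochs_truncated_window_error():
    cont = np.zeros((1, 5000))  # 10 s at 500 Hz
    with pytest.raises(ValueError, match="event 0"):
        extract_epochs(cont, 500.0, [9.0])  # post-window exceeds recording
    with pytest.raises(ValueError, match="event 1"):
        extract_epochs(cont, 500.0, [2.0, 0.5])  # pre-window before start


# -- filtering -----------------------------------------------------------

def test_lowpass_passband_stopband_and_dc():
    pass_e = lowpass_filter(_sine_epochs(7.5), 40.0)
    mid = slice(300, 1950)
    ratio = pass_e.data[0, 0, mid].std() / _sine_epochs(7.5).data[0, 0, mid].std()
    assert ratio == pytest.approx(1.0, abs=0.01)

    stop_e = lowpass_filter(_sine_epochs(100.0), 40.0)
    atten = stop_e.data[0, 0, mid].std() / _sine_epochs(100.0).data[0, 0, mid].std()
    # analytic zero-phase Butterworth magnitude at 100 Hz
    sos = signal.butter(4, 40.0, btype="low", fs=500.0, output="sos")
    _, h = signal.sosfreqz(sos, worN=[100.0], fs=500.0)
    assert atten == pytest.approx(np.abs(h[0]) ** 2, rel=0.05)
    assert atten < 10 ** (-40 / 20)

    dc = _sine_epochs(7.5)
    dc.data[:] = 3.14
    out = lowpass_filter(dc, 40.0)
    np.testing.assert_allclose(out.data, 3.14, rtol=1e-9)


def test_lowpass_linearity():
    a = _sine_epochs(5.0)
    b = _sine_epochs(30.0)
    combo = a.copy()
    combo.data = 2.0 * a.data + 0.5 * b.data
    lhs = lowpass_filter(combo, 40.0).data
    rhs = 2.0 * lowpass_filter(a, 40.0).data + 0.5 * lowpass_filter(b, 40.0).data
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_lowpass_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError):
        lowpass_filter(_sine_epochs(7.5), 250.0)


# -- SCADS ---------------------------------------------------------------

def test_screening_stats_definitions():
    e = _sine_epochs(7.5)
    s = screening_stats(e)
    x = e.data[0, 0]
    assert s[0, 0, 0] == np.abs(x).max()
    assert s[0, 0, 1] == x.std()
    assert s[0, 0, 2] == np.abs(np.diff(x)).max()


def _flat_epochs(net, schedule):
    """Zero-signal background: every screening statistic is exactly flat."""
    params = GenParams(seed=1, noise_scale=0.0, subject_sd=0.0,
                       a1_base=0.0, a1_context_offset=0.0,
                       a2_base=0.0, a2_gradient_peak=0.0)
    return generate_eeg_epochs(schedule, params, net, 0)


def test_single_spike_flagged_exactly(small_net, context_schedule):
    """On a deterministic background only the spiked cell exceeds threshold."""
    epochs = _flat_epochs(small_net, context_schedule)
    spiked, _ = inject_artifacts(
        epochs, [ArtifactEvent(3, 7, "spike", 500.0)], seed=2
    )
    report = scads_screen(spiked, small_net)
    assert np.argwhere(report.sensor_flags).tolist() == [[3, 7]]
    assert report.rejected_trials.size == 0
    assert np.array_equal(report.interpolated, report.sensor_flags)


def test_trial_rejected_when_too_many_sensors_bad(small_net, context_schedule):
    epochs = _flat_epochs(small_net, context_schedule)
    events = [ArtifactEvent(5, s, "spike", 500.0) for s in range(25)]
    spiked, _ = inject_artifacts(epochs, events, seed=3)
    report = scads_screen(spiked, small_net, max_bad_sensors=20)
    assert report.rejected_trials.tolist() == [5]
    assert not report.interpolated[5].any()


def test_clean_gaussian_data_not_rejected():
    rng = np.random.default_rng(0)
    n_trials, n_sensors = 200, 32
    times = epoch_times_ms(500.0)
    data = rng.standard_normal((n_trials, n_sensors, len(times)))
    labels = pd.DataFrame({"orientation_deg": 45, "context": "none",
                           "phase": "none", "half": "none"},
                          index=range(n_trials))
    epochs = EpochArray(data, 500.0, times, labels,
                        tuple(f"S{i+1}" for i in range(n_sensors)))
    report = scads_screen(epochs)
    assert report.rejected_trials.size == 0
    # false-positive flag rate stays in the tail-probability regime
    assert report.sensor_flags.mean() < 0.10


def test_artifacts_increase_flags(small_net, context_schedule):
    params = GenParams(seed=2, noise_scale=5.0)
    clean = generate_eeg_epochs(context_schedule, params, small_net, 0)
    events = [ArtifactEvent(t, t % small_net.n_sensors, "drift", 400.0)
              for t in range(0, 20, 2)]
    dirty, _ = inject_artifacts(clean, events, seed=4)
    assert (scads_screen(dirty, small_net).sensor_flags.sum()
            > scads_screen(clean, small_net).sensor_flags.sum())


def test_screen_needs_two_trials(small_net):
    e = _sine_epochs(7.5, n_trials=1)
    with pytest.raises(ValueError):
        scads_screen(e)


# -- interpolation -------------------------------------------------------

def _epochs_from_field(values, net, n_trials=1):
    times = epoch_times_ms(500.0)
    data = np.tile(values[None, :, None], (n_trials, 1, len(times)))
    labels = pd.DataFrame({"orientation_deg": 45, "context": "none",
                           "phase": "none", "half": "none"},
                          index=range(n_trials))
    return EpochArray(data, 500.0, times, labels, net.sensor_ids)


def _report_with_interp(net, n_trials, cells):
    from ssvepgen.preprocess import ArtifactReport

    flags = np.zeros((n_trials, net.n_sensors), dtype=bool)
    for t, s in cells:
        flags[t, s] = True
    return ArtifactReport(
        sensor_flags=flags.copy(), interpolated=flags,
        rejected_trials=np.array([], dtype=int),
        stats=np.zeros((n_trials, net.n_sensors, 3)),
        z_threshold=3.0, max_bad_sensors=20,
    )


def test_interpolation_constant_field_and_identity(small_net):
    epochs = _epochs_from_field(np.full(small_net.n_sensors, 2.5), small_net)
    report = _report_with_interp(small_net, 1, [(0, 4)])
    out = interpolate_sensors(epochs, report, small_net)
    assert out.data[0, 4, 0] == pytest.approx(2.5, abs=1e-6)
    # untouched channels are bit-identical
    untouched = np.delete(np.arange(small_net.n_sensors), 4)
    assert np.array_equal(out.data[0, untouched], epochs.data[0, untouched])
    same = interpolate_sensors(
        epochs, _report_with_interp(small_net, 1, []), small_net
    )
    assert np.array_equal(same.data, epochs.data)


def test_interpolation_leave_one_out_spherical_harmonic(small_net):
    """A degree-2 harmonic field is recovered within 5% at held-out sites."""
    z = small_net.positions[:, 2]
    field = 0.5 * (3 * z**2 - 1)
    epochs = _epochs_from_field(field, small_net)
    for bad in (0, 11, 29):
        report = _report_with_interp(small_net, 1, [(0, bad)])
        out = interpolate_sensors(epochs, report, small_net)
        assert out.data[0, bad, 0] == pytest.approx(
            field[bad], abs=0.05 * np.abs(field).max()
        )


def test_interpolation_preserves_zero_mean_field(small_net):
    z = small_net.positions[:, 2]
    field = 0.5 * (3 * z**2 - 1)
    field = field - field.mean()
    epochs = _epochs_from_field(field, small_net)
    report = _report_with_interp(small_net, 1, [(0, 3), (0, 17)])
    out = interpolate_sensors(epochs, report, small_net)
    assert out.data[0, :, 0].mean() == pytest.approx(field.mean(), abs=0.01)


# -- averaging and half split -------------------------------------------

def test_average_conditions_matches_loop_oracle(small_net, context_schedule):
    params = GenParams(seed=3, noise_scale=2.0)
    epochs = generate_eeg_epochs(context_schedule, params, small_net, 0)
    avg = average_conditions(epochs)
    for cond, mean in avg.data.items():
        idx = [
            i for i in range(epochs.n_trials)
            if (epochs.labels.loc[i, "orientation_deg"],
                epochs.labels.loc[i, "context"]) == cond
        ]
        oracle = sum(epochs.data[i] for i in idx) / len(idx)
        np.testing.assert_allclose(mean, oracle, atol=1e-12)
        assert avg.n_trials[cond] == len(idx)


def test_average_symmetry_and_identity():
    e = _sine_epochs(7.5, n_trials=2)
    e.data[1] = -e.data[0]
    avg = average_conditions(e)
    np.testing.assert_allclose(avg.data[(45, "none")], 0.0, atol=1e-12)
    e.data[1] = e.data[0]
    avg = average_conditions(e)
    np.testing.assert_array_equal(avg.data[(45, "none")], e.data[0])


def test_empty_cell_recorded():
    e = _sine_epochs(7.5, n_trials=4)
    e.labels["orientation_deg"] = [45, 45, 15, 15]
    avg = average_conditions(
        e, expected_cells=[(45, "none"), (15, "none"), (25, "none")]
    )
    assert avg.empty_cells == ((25, "none"),)


def test_split_halves_assignment_and_exclusion():
    from ssvepgen.schedule import generate_schedule

    sched = generate_schedule("acquisition", seed=11)  # 18 per orientation
    times = epoch_times_ms(500.0)
    labels = sched.records[["orientation_deg", "context"]].copy()
    labels["phase"] = "acquisition"
    labels["half"] = "none"
    epochs = EpochArray(
        np.zeros((len(sched), 2, len(times))), 500.0, times, labels,
        ("S1", "S2"),
    )
    out, excluded = split_halves_and_screen(epochs)
    n = epochs.n_trials
    first = int(np.ceil(n / 2))
    assert (out.labels["half"][:first] == "1").all()
    assert (out.labels["half"][first:] == "2").all()
    assert excluded is False
    # rejecting every second-half CS+ trial empties a Cue x Half cell
    cs_second = [
        i for i in range(first, n)
        if epochs.labels.loc[i, "orientation_deg"] == 45
    ]
    _, excluded = split_halves_and_screen(epochs, rejected_trials=cs_second)
    assert excluded is True


def test_condition_average_hdf5_round_trip(small_net, context_schedule, tmp_path):
    params = GenParams(seed=5, noise_scale=2.0)
    epochs = generate_eeg_epochs(context_schedule, params, small_net, 0)
    avg = average_conditions(epochs)
    path = tmp_path / "avg.h5"
    avg.to_hdf5(path)
    from ssvepgen.preprocess import ConditionAverage

    back = ConditionAverage.from_hdf5(path)
    assert set(back.data) == set(avg.data)
    for cond in avg.data:
        np.testing.assert_array_equal(back.data[cond], avg.data[cond])
        assert back.n_trials[cond] == avg.n_trials[cond]
    assert back.units == avg.units and back.sfreq == avg.sfreq


def test_split_halves_odd_count_gives_extra_to_first():
    e = _sine_epochs(7.5, n_trials=5)
    out, _ = split_halves_and_screen(e)
    assert (out.labels["half"] == "1").sum() == 3
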