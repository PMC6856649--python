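"""Synthetic task battery: kinematics, markers, EMG-like signals."""

import numpy as np
import pytest

import scapsim as ss
from scapsim.emg import emg_envelope
from scapsim.synthetic import (
    TaskSpec,
    generate_synthetic_emg,
    generate_task_kinematics,
    minimum_jerk,
    task_activation_profiles,
    trial_battery_specs,
)


def test_battery_is_eighteen_trials():
    specs = trial_battery_specs()
    assert len(specs) == 18
    assert sum(1 for s in specs if s.hand_mass == 2.0) == 9
    assert {s.task for s in specs} == {"shrug", "flexion", "abduction"}


def test_minimum_jerk_boundary_conditions():
    s = np.linspace(0, 1, 1001)
    x = minimum_jerk(s)
    v = np.gradient(x, s)
    assert x[0] == 0.0 and x[-1] == 1.0
    assert abs(v[0]) < 1e-3 and abs(v[-1]) < 1e-3


def test_shrug_leaves_humeral_coordinates_at_default():
    times, q = generate_task_kinematics(TaskSpec(task="shrug", duration=2.0))
    assert np.all(q[:, 4:] == 0.0)
    assert np.all(q[:, [0, 2, 3]] == 0.0)
    assert q[:, 1].max() > 0.0


def test_flexion_peak_amplitude_exact():
    spec = TaskSpec(task="flexion", duration=2.0, peak=np.deg2rad(110.0))
    _, q = generate_task_kinematics(spec)
    assert abs(q[:, 4].max() - np.deg2rad(110.0)) < 1e-9


def test_scapulohumeral_rhythm_coupling():
    """Upward rotation tracks the humeral elevation coordinate at 1:2."""
    _, q = generate_task_kinematics(TaskSpec(task="abduction", duration=2.0))
    assert np.allclose(q[:, 2], 0.5 * q[:, 5], atol=1e-12)


def test_trajectory_velocity_zero_at_endpoints():
    times, q = generate_task_kinematics(TaskSpec(task="flexion", duration=2.0))
    v = np.gradient(q[:, 4], times)
    assert abs(v[0]) < 1e-2 and abs(v[-1]) < 1e-2


def test_noise_free_markers_equal_forward_kinematics(model):
    spec = TaskSpec(task="flexion", duration=0.5)
    times, q = generate_task_kinematics(spec)
    mk = ss.generate_marker_data(model, times, q, noise_sd=0.0)
    _, expected = ss.marker_positions(model, q)
    assert np.array_equal(mk.positions, expected)


def test_marker_noise_statistics(model):
    """3 mm isotropic noise: empirical per-axis SD within 10% over > 1000
    samples."""
    spec = TaskSpec(task="shrug", duration=4.0)
    times, q = generate_task_kinematics(spec)
    clean = ss.generate_marker_data(model, times, q, noise_sd=0.0)
    noisy = ss.generate_marker_data(model, times, q, noise_sd=0.003, seed=9)
    resid = (noisy.positions - clean.positions).ravel()
    assert resid.size > 1000
    assert abs(resid.std() - 0.003) < 0.0003


def test_marker_generation_deterministic(model, tmp_path):
    """A fixed seed reproduces the trial bit-for-bit, including the file."""
    spec = TaskSpec(task="abduction", duration=0.5, trial=2)
    times, q = generate_task_kinematics(spec)
    a = ss.generate_marker_data(model, times, q, 0.003, seed=spec.seed_sequence)
    b = ss.generate_marker_data(model, times, q, 0.003,
                                seed=TaskSpec(task="abduction", duration=0.5,
                                              trial=2).seed_sequence)
    assert np.array_equal(a.positions, b.positions)
    from scapsim.io import write_trc

    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    d1.mkdir(), d2.mkdir()
    write_trc(a, d1 / "trial.trc")
    write_trc(b, d2 / "trial.trc")
    assert (d1 / "trial.trc").read_bytes() == (d2 / "trial.trc").read_bytes()


def test_synthetic_emg_zero_activation_is_silent():
    act = np.zeros(4000)
    raw = generate_synthetic_emg(act, fs=1000.0, snr=10.0, seed=1)
    env = emg_envelope(raw, 1000.0)
    assert np.max(env[500:-500]) < 1e-9


def test_synthetic_emg_amplitude_tracks_activation():
    """Envelopes recovered from constant activations 0.5 and 1.0 have a
    ratio of 0.5 within 0.1."""
    n = 6000
    env_by_level = {}
    for level in (0.5, 1.0):
        raw = generate_synthetic_emg(np.full(n, level), fs=1000.0,
                                     snr=50.0, seed=4)
        env = emg_envelope(raw, 1000.0)
        env_by_level[level] = np.mean(env[1000:-1000])
    ratio = env_by_level[0.5] / env_by_level[1.0]
    assert abs(ratio - 0.5) < 0.1


def test_emg_round_trip_correlation():
    """At SNR >= 10 the envelope of the synthetic raw signal correlates
    above 0.95 with the generating activation profile."""
    spec = TaskSpec(task="abduction", duration=4.0, emg_snr=10.0)
    t = np.arange(4001) / 1000.0
    names, act = task_activation_profiles(spec, t)
    j = names.index("Deltoideus.Middle")
    raw = generate_synthetic_emg(act[:, j], fs=1000.0, snr=10.0, seed=2)
    env = emg_envelope(raw, 1000.0)
    core = slice(300, -300)
    r = np.corrcoef(env[core], act[core, j])[0, 1]
    assert r > 0.95


def test_synthetic_emg_reproducible():
    act = np.clip(np.sin(np.linspace(0, np.pi, 2000)), 0, 1)
    a = generate_synthetic_emg(act, 1000.0, seed=7)
    b = generate_synthetic_emg(act, 1000.0, seed=7)
    assert np.array_equal(a, b)


def test_activation_out_of_range_rejected():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        generate_synthetic_emg(np.array([0.2, 1.4]), 1000.0)


def test_invalid_task_spec_rejected():
    with pytest.raises(ValueError, match="unknown task"):
        TaskSpec(task="jump")
    with pytest.raises(ValueError, match="duration"):
        TaskSpec(task="shrug", duration=0.0)
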