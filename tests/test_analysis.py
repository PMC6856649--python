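"""Muscle power/work accounting and activation-vs-EMG comparison."""

import numpy as np
import pytest

import scapsim as ss
from scapsim.analysis import (
    activation_mae,
    elevation_phase,
    external_work,
    muscle_group,
    muscle_power,
    positive_work,
)
from scapsim.dynamics import gravity_force, potential_energy


# ---------------------------------------------------------------------------
# power and work primitives
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f,v,expected", [
    (100.0, -0.1, 10.0),   # shortening: positive power
    (100.0, 0.1, -10.0),   # lengthening: negative power
    (0.0, 0.5, 0.0),
])
def test_power_sign_convention(f, v, expected):
    assert muscle_power(f, v) == pytest.approx(expected)


def test_power_requires_aligned_series():
    with pytest.raises(ValueError, match="shapes"):
        muscle_power(np.zeros(5), np.zeros(4))


def test_positive_work_constant_power():
    t = np.linspace(0, 2, 201)
    assert positive_work(t, np.full_like(t, 10.0)) == pytest.approx(20.0)


def test_positive_work_sine_half_wave_closed_form():
    """For P = A sin(wt) over whole periods the positive work equals the
    analytic half-wave integral n * 2A/w."""
    A, w, n_periods = 5.0, 2 * np.pi, 3
    t = np.linspace(0, n_periods, 3001)
    p = A * np.sin(w * t)
    expected = n_periods * 2 * A / w
    assert positive_work(t, p) == pytest.approx(expected, rel=1e-5)


def test_all_negative_power_gives_zero_work():
    t = np.linspace(0, 1, 101)
    assert positive_work(t, -np.abs(np.sin(8 * t)) - 0.1) == 0.0


def test_empty_interval_warns_and_returns_zero():
    t = np.linspace(0, 1, 11)
    with pytest.warns(UserWarning, match="empty"):
        assert positive_work(t, np.ones_like(t), (5.0, 6.0)) == 0.0


def test_work_refinement_invariance():
    """Positive work changes only at O(dt^2) under grid refinement."""
    A, w = 3.0, 2 * np.pi
    coarse = np.linspace(0, 2, 201)
    fine = np.linspace(0, 2, 2001)
    wc = positive_work(coarse, A * np.sin(w * coarse))
    wf = positive_work(fine, A * np.sin(w * fine))
    assert abs(wc - wf) < 1e-3


# ---------------------------------------------------------------------------
# external work
# ---------------------------------------------------------------------------

def test_hand_mass_external_work_is_mgh(model):
    """Adding 2 kg in the hand raises the external work of an arm lift by
    exactly m g dh of the hand point."""
    loaded = model.with_hand_mass(2.0)
    q_low = model.default_pose()
    q_high = q_low.copy()
    q_high[5] = np.pi / 2  # arm horizontal
    frames_l = ss.forward_kinematics(model, q_low)
    frames_h = ss.forward_kinematics(model, q_high)
    from scapsim.kinematics import body_point_world

    h0 = body_point_world(frames_l, "forearm", model.hand_point)[1]
    h1 = body_point_world(frames_h, "forearm", model.hand_point)[1]
    times = np.array([0.0, 1.0])
    qs = np.stack([q_low, q_high])
    w_plain = external_work(model, times, qs, (0.0, 1.0))
    w_loaded = external_work(loaded, times, qs, (0.0, 1.0))
    assert w_loaded - w_plain == pytest.approx(2.0 * 9.81 * (h1 - h0), rel=1e-9)


def test_no_elevation_no_external_work(model):
    q = model.default_pose()
    times = np.array([0.0, 1.0])
    assert external_work(model, times, np.stack([q, q]), (0.0, 1.0)) == 0.0


def test_external_work_path_independent(model):
    """Potential-energy change depends only on the interval endpoints."""
    q0 = model.default_pose()
    q1 = q0.copy()
    q1[4] = 1.0
    detour = q0.copy()
    detour[1] = 0.3
    times = np.linspace(0, 1, 5)
    direct = np.stack([q0, q0, q0, q1, q1])
    wiggly = np.stack([q0, detour, q0, detour, q1])
    w1 = external_work(model, times, direct, (0.0, 1.0))
    w2 = external_work(model, times, wiggly, (0.0, 1.0))
    assert w1 == pytest.approx(w2, rel=1e-12)


def test_potential_change_equals_gravity_work_integral(model):
    """dPE matches the integral of -(gravity generalized force) . qdot
    along a fixture motion within 1%."""
    spec = ss.TaskSpec(task="flexion", duration=1.0)
    times, q = ss.generate_task_kinematics(spec)
    half = len(times) // 2 + 1
    times, q = times[:half], q[:half]  # monotone raise
    qd = np.gradient(q, times, axis=0)
    integrand = np.array([-gravity_force(model, qi) @ qdi
                          for qi, qdi in zip(q, qd)])
    w_int = np.trapezoid(integrand, times)
    d_pe = potential_energy(model, q[-1]) - potential_energy(model, q[0])
    assert w_int == pytest.approx(d_pe, rel=0.01)


# ---------------------------------------------------------------------------
# phase detection and summaries
# ---------------------------------------------------------------------------

def test_elevation_phase_onset_and_peak():
    t = np.linspace(0, 2, 201)
    x = np.sin(np.pi * t / 2) ** 2  # rises to peak at t = 1
    t0, t1 = elevation_phase(t, x)
    assert t1 == pytest.approx(1.0, abs=0.02)
    assert 0.0 < t0 < 0.4


def test_work_summary_idle_muscles_are_zero(shrug_sim):
    tuned, res, _ = shrug_sim
    idle = copy_result_with_zero_forces(res)
    ws = ss.work_summary(idle, tuned, task="shrug")
    assert ws.total == 0.0
    assert all(v == 0.0 for v in ws.per_muscle.values())


def copy_result_with_zero_forces(res):
    import dataclasses

    return dataclasses.replace(res, forces=np.zeros_like(res.forces))


def test_work_summary_conserves_total(shrug_sim):
    tuned, res, _ = shrug_sim
    ws = ss.work_summary(res, tuned, task="shrug")
    assert ws.total == pytest.approx(sum(ws.per_muscle.values()), rel=1e-12)
    assert ws.total == pytest.approx(sum(ws.groups.values()), rel=1e-12)
    # the <3% contributors are flagged, not dropped
    for name in ws.excluded:
        assert ws.per_muscle[name] < 0.03 * ws.total + 1e-12


def test_muscle_group_assignment():
    assert muscle_group("Trapezius.ScapulaSuperior") == "thoracoscapular"
    assert muscle_group("SerratusAnterior.Middle") == "thoracoscapular"
    assert muscle_group("PectoralisMinor") == "thoracoscapular"
    assert muscle_group("Deltoideus.Middle") == "glenohumeral"
    assert muscle_group("Subscapularis.Inferior") == "glenohumeral"
    assert muscle_group("Biceps.Long") == "glenohumeral"
    with pytest.raises(KeyError):
        muscle_group("NotAMuscle")


# ---------------------------------------------------------------------------
# activation vs EMG
# ---------------------------------------------------------------------------

def test_mae_identical_series_is_zero():
    t = np.linspace(0, 1, 50)
    a = np.sin(t)
    assert activation_mae(t, a, t, a) == 0.0


def test_mae_constant_offset():
    t = np.linspace(0, 1, 50)
    a = 0.3 * np.ones_like(t)
    assert activation_mae(t, a, t, a + 0.05) == pytest.approx(0.05)


def test_mae_non_overlapping_series_rejected():
    with pytest.raises(ValueError, match="overlap"):
        activation_mae(np.linspace(0, 1, 10), np.zeros(10),
                       np.linspace(5, 6, 10), np.zeros(10))


def test_serratus_bundle_averaging_rule(shrug_sim):
    """The model quantity compared to the serratus electrode is the mean of
    the three bundle activations: bundles at (0.1, 0.2, 0.3) against an
    envelope of 0.2 give MAE 0."""
    _, res, _ = shrug_sim
    import dataclasses

    acts = res.activations.copy()
    for b, val in zip(("Superior", "Middle", "Inferior"), (0.1, 0.2, 0.3)):
        acts[:, res.muscle_index(f"SerratusAnterior.{b}")] = val
    mod = dataclasses.replace(res, activations=acts)
    avg = ss.serratus_bundle_average(mod)
    assert np.allclose(avg, 0.2)
    env = 0.2 * np.ones_like(res.time)
    assert activation_mae(res.time, avg, res.time, env) == pytest.approx(0.0)
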