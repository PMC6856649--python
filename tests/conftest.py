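import numpy as np
import pytest

import scapsim as ss


@pytest.fixture(scope="session")
def model():
    """The built-in shoulder model (no hand mass)."""
    return ss.builtin_thoracoscapular_model()


def run_task(task, hand_mass, duration=2.0, base_seed=42):
    """Tracking simulation of one synthetic task on a retuned model copy."""
    m = ss.builtin_thoracoscapular_model(hand_mass=hand_mass)
    spec = ss.TaskSpec(task=task, duration=duration, hand_mass=hand_mass,
                       base_seed=base_seed)
    times, q = ss.generate_task_kinematics(spec)
    tuned, _ = ss.tune_muscle_lengths(m, q[::10])
    result = ss.run_tracking(tuned, times, q)
    return tuned, result, spec


@pytest.fixture(scope="session")
def task_sims():
    """Tracking simulations of all six study conditions (2 s versions)."""
    sims = {}
    for task in ("shrug", "flexion", "abduction"):
        for hand_mass in (0.0, 2.0):
            sims[(task, hand_mass)] = run_task(task, hand_mass)
    return sims


@pytest.fixture(scope="session")
def shrug_sim(task_sims):
    return task_sims[("shrug", 0.0)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
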