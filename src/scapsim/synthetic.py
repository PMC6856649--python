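"""Synthetic study-condition generator.

Emulates the experimental battery the model is meant to consume: three
shoulder tasks (shrug, forward flexion, abduction), each without and with a
2 kg hand-held mass, three trials each — 18 trials.  Joint-angle
trajectories are minimum-jerk raise-and-return profiles; for arm tasks the
scapular upward rotation is coupled at ~1:2 to humeral elevation, emulating
scapulohumeral rhythm as a target for the controller rather than a model
constraint, and the shrug moves only scapular coordinates.  Marker data are
forward-kinematics positions at 120 Hz plus isotropic Gaussian noise;
EMG-like signals are band-limited (20-450 Hz) noise carriers amplitude-
modulated by activation profiles, so the envelope pipeline can recover the
modulation.

Everything is seeded: one seed per (task, load, trial), derived from a base
seed, makes the whole battery bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .kinematics import marker_positions
from .io import MarkerTrajectories, Motion
from .types import ShoulderModel

__all__ = [
    "TaskSpec",
    "TASKS",
    "minimum_jerk",
    "generate_task_kinematics",
    "generate_marker_data",
    "generate_synthetic_emg",
    "generate_trial",
    "trial_battery_specs",
    "EMG_CHANNELS",
]

TASKS = ("shrug", "flexion", "abduction")

#: default peak amplitudes, rad.  The shrug amplitude is a surface
#: latitude: 15 deg on the 0.21 m thorax semi-axis raises the scapula
#: ~5.5 cm, a physiological shrug excursion.
_DEFAULT_PEAKS = {
    "shrug": np.deg2rad(15.0),  # scapular elevation (latitude)
    "flexion": np.deg2rad(110.0),  # humeral elevation coordinate
    "abduction": np.deg2rad(110.0),
}

#: surface-EMG channels recorded in the study protocol
EMG_CHANNELS = [
    "Trapezius.ScapulaSuperior", "Trapezius.ScapulaMiddle",
    "Trapezius.ScapulaInferior", "SerratusAnterior",
    "Deltoideus.Anterior", "Deltoideus.Middle", "Deltoideus.Posterior",
    "Infraspinatus", "TeresMajor", "PectoralisMajor.Clavicle",
    "LatissimusDorsi",
]

# nominal channel gains per task for the EMG-like stimulus
_EMG_GAINS = {
    "shrug": {"Trapezius.ScapulaSuperior": 0.5, "Trapezius.ScapulaMiddle": 0.15,
              "SerratusAnterior": 0.1, "Deltoideus.Middle": 0.05},
    "flexion": {"Deltoideus.Anterior": 0.5, "Trapezius.ScapulaSuperior": 0.3,
                "SerratusAnterior": 0.4, "PectoralisMajor.Clavicle": 0.3,
                "Deltoideus.Middle": 0.2},
    "abduction": {"Deltoideus.Middle": 0.6, "Trapezius.ScapulaSuperior": 0.4,
                  "SerratusAnterior": 0.4, "Deltoideus.Anterior": 0.2,
                  "Infraspinatus": 0.2},
}


@dataclass
class TaskSpec:
    """One synthetic trial of the study battery."""

    task: str = "abduction"
    hand_mass: float = 0.0  # kg, 0 or 2 in the study
    duration: float = 4.0  # s
    peak: float | None = None  # rad; task default if None
    trial: int = 1
    marker_noise_sd: float = 0.003  # m
    emg_snr: float = 10.0
    emg_rate: float = 1000.0  # Hz (kinematics are 120 Hz)
    rate: float = 120.0
    base_seed: int = 42

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.trial < 1:
            raise ValueError("trial index starts at 1")

    @property
    def peak_amplitude(self) -> float:
        return _DEFAULT_PEAKS[self.task] if self.peak is None else self.peak

    @property
    def seed_sequence(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            [self.base_seed, TASKS.index(self.task),
             int(round(self.hand_mass * 10)), self.trial]
        )

    @property
    def label(self) -> str:
        return f"{self.task}{'+' if self.hand_mass > 0 else ''}_t{self.trial}"


def minimum_jerk(s):
    """Minimum-jerk position profile on [0, 1] (zero velocity/acceleration
    at both ends)."""
    s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _raise_and_return(t, duration):
    """Raise over the first half, return over the second, both minimum-jerk."""
    t = np.asarray(t, dtype=float)
    half = duration / 2.0
    up = minimum_jerk(t / half)
    down = minimum_jerk((duration - t) / half)
    return np.where(t < half, up, down)


def generate_task_kinematics(spec: TaskSpec, n_coords: int = 7):
    """Joint-angle trajectories for one trial.

    Returns ``(times, q)`` with q of shape (N, n_coords) in the fixed
    coordinate order (4 scapulothoracic then 3 humeral).
    """
    n = int(round(spec.duration * spec.rate)) + 1
    times = np.arange(n) / spec.rate
    profile = _raise_and_return(times, spec.duration) * spec.peak_amplitude
    q = np.zeros((n, n_coords))
    if spec.task == "shrug":
        q[:, 1] = profile  # scapular elevation only
    else:
        col = 4 if spec.task == "flexion" else 5
        q[:, col] = profile
        q[:, 2] = 0.5 * profile  # scapulohumeral rhythm target, ~1:2
    return times, q


def generate_marker_data(
    model: ShoulderModel,
    times,
    q_traj,
    noise_sd: float = 0.003,
    seed=None,
) -> MarkerTrajectories:
    """Forward-kinematics marker trajectories plus isotropic Gaussian noise."""
    times = np.asarray(times, dtype=float)
    names, pos = marker_positions(model, np.asarray(q_traj, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
    rate = 1.0 / np.mean(np.diff(times))
    return MarkerTrajectories(times=times, names=names, positions=np.asarray(pos),
                              rate=float(round(rate, 6)))


def generate_synthetic_emg(activation_traj, fs: float, snr: float = 10.0,
                           seed=None):
    """EMG-like raw signals: band-limited (20-450 Hz) noise carriers
    amplitude-modulated by the activation profiles.

    ``activation_traj`` is (N,) or (N, n_channels), sampled at ``fs``.
    Returns an array of the same shape.  The carrier is normalized to unit
    RMS so the envelope chain recovers the modulation amplitude up to the
    rectified-noise mean; an additive floor at 1/snr of the peak
    activation sets the signal-to-noise ratio.
    """
    act = np.atleast_2d(np.asarray(activation_traj, dtype=float).T).T
    if act.min() < 0 or act.max() > 1:
        raise ValueError("activations must lie in [0, 1]")
    n, ch = act.shape
    rng = np.random.default_rng(seed)
    high = min(450.0, 0.45 * fs)
    b, a = butter(4, [20.0, high], btype="band", fs=fs)
    raw = np.empty_like(act)
    for j in range(ch):
        carrier = filtfilt(b, a, rng.standard_normal(n))
        carrier /= np.std(carrier)
        floor = filtfilt(b, a, rng.standard_normal(n))
        floor /= np.std(floor)
        amax = act[:, j].max()
        raw[:, j] = act[:, j] * carrier + (amax / snr) * floor
    return raw if np.ndim(activation_traj) > 1 else raw[:, 0]


def task_activation_profiles(spec: TaskSpec, times):
    """Nominal per-channel activation profiles used as the EMG stimulus."""
    shape = _raise_and_return(np.asarray(times), spec.duration)
    gains = _EMG_GAINS[spec.task]
    load_boost = 1.0 + 0.3 * (spec.hand_mass > 0)
    act = np.zeros((len(times), len(EMG_CHANNELS)))
    for j, chn in enumerate(EMG_CHANNELS):
        g = gains.get(chn, 0.02) * load_boost
        act[:, j] = np.clip(g * shape, 0.0, 1.0)
    return EMG_CHANNELS, act


@dataclass
class TrialData:
    """One synthetic trial: markers, coordinates, and raw EMG."""

    spec: TaskSpec
    motion: Motion
    markers: MarkerTrajectories
    emg_times: np.ndarray
    emg_names: list[str] = field(default_factory=list)
    emg_raw: np.ndarray | None = None


def generate_trial(model: ShoulderModel, spec: TaskSpec) -> TrialData:
    """Generate one complete synthetic trial (kinematics, markers, EMG)."""
    seeds = spec.seed_sequence.spawn(2)
    times, q = generate_task_kinematics(spec, model.n_coords)
    markers = generate_marker_data(
        model, times, q, noise_sd=spec.marker_noise_sd, seed=seeds[0]
    )
    n_emg = int(round(spec.duration * spec.emg_rate)) + 1
    t_emg = np.arange(n_emg) / spec.emg_rate
    names, act = task_activation_profiles(spec, t_emg)
    raw = generate_synthetic_emg(act, spec.emg_rate, spec.emg_snr, seed=seeds[1])
    motion = Motion(times=times, names=[
        "scap_abduction", "scap_elevation", "scap_upward_rot", "scap_winging",
        "shoulder_flexion", "shoulder_abduction", "shoulder_rotation",
    ][: model.n_coords], values=q, name=spec.label)
    return TrialData(spec=spec, motion=motion, markers=markers,
                     emg_times=t_emg, emg_names=names, emg_raw=raw)


def trial_battery_specs(
    base_seed: int = 42,
    duration: float = 4.0,
    trials: int = 3,
) -> list[TaskSpec]:
    """The 18-trial study battery (3 tasks x 2 loads x ``trials``)."""
    specs = []
    for task in TASKS:
        for hand_mass in (0.0, 2.0):
            for trial in range(1, trials + 1):
                specs.append(TaskSpec(
                    task=task, hand_mass=hand_mass, duration=duration,
                    trial=trial, base_seed=base_seed,
                ))
    return specs
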