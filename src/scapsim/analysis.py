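"""Muscle work accounting and activation-vs-EMG comparison.

Muscle power is the product of MTU force and shortening velocity
(concentric contraction = positive power); positive work is the time
integral of the positive part of power over the elevation phase of a task.
External work is the change in system gravitational potential energy
(arm segments plus any hand-held mass) between the phase endpoints.  Since
lengthening muscles absorb energy and segments accelerate relative to the
center of mass, total positive muscle work is expected to exceed the
external work in elevation tasks.

Work is grouped into thoracoscapular muscles (trapezius, serratus anterior,
rhomboids, levator scapulae, pectoralis minor — thorax/spine to scapula)
and glenohumeral muscles (deltoids, rotator cuff, teres major, and the
remaining actuators crossing the glenohumeral joint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import potential_energy
from .tracking import SimulationResult
from .types import ShoulderModel

__all__ = [
    "MUSCLE_GROUPS",
    "muscle_group",
    "muscle_power",
    "positive_work",
    "external_work",
    "elevation_phase",
    "WorkSummary",
    "work_summary",
    "activation_mae",
    "serratus_bundle_average",
]

#: group membership; prefixes matched against muscle names
MUSCLE_GROUPS = {
    "thoracoscapular": (
        "Trapezius", "SerratusAnterior", "Rhomboideus", "LevatorScapulae",
        "PectoralisMinor",
    ),
    "glenohumeral": (
        "Deltoideus", "Supraspinatus", "Infraspinatus", "TeresMinor",
        "Subscapularis", "TeresMajor", "LatissimusDorsi", "PectoralisMajor",
        "Coracobrachialis", "Biceps", "TricepsLong",
    ),
}

#: primary coordinate whose excursion defines the elevation phase per task
PRIMARY_COORD = {
    "shrug": "scap_elevation",
    "flexion": "shoulder_flexion",
    "abduction": "shoulder_abduction",
}


def muscle_group(name: str) -> str:
    for group, prefixes in MUSCLE_GROUPS.items():
        if name.split(".")[0] in prefixes:
            return group
    raise KeyError(f"muscle {name!r} not in any group")


def muscle_power(f_mtu, v_mtu):
    """Muscle power P = F * (-v), W; v positive when lengthening, so
    shortening (concentric) contractions yield positive power."""
    f = np.asarray(f_mtu, dtype=float)
    v = np.asarray(v_mtu, dtype=float)
    if f.shape != v.shape:
        raise ValueError(
            f"force and velocity series have different shapes {f.shape} vs {v.shape}"
        )
    return f * (-v)


def positive_work(times, power, interval=None):
    """Trapezoidal integral of max(P, 0) over ``interval`` (J)."""
    times = np.asarray(times, dtype=float)
    power = np.asarray(power, dtype=float)
    if interval is None:
        sel = slice(None)
    else:
        t0, t1 = interval
        mask = (times >= t0) & (times <= t1)
        if not np.any(mask):
            import warnings

            warnings.warn("empty integration interval; returning 0 J", stacklevel=2)
            return 0.0
        sel = mask
    return float(np.trapezoid(np.clip(power[sel], 0.0, None), times[sel]))


def external_work(model: ShoulderModel, times, q_series, interval) -> float:
    """External work = change in model potential energy over ``interval``.

    Depends only on the interval endpoints (path independence of the
    potential); includes the hand-held mass carried by the model.
    """
    times = np.asarray(times, dtype=float)
    q_series = np.asarray(q_series, dtype=float)
    t0, t1 = interval
    i0 = int(np.argmin(np.abs(times - t0)))
    i1 = int(np.argmin(np.abs(times - t1)))
    return potential_energy(model, q_series[i1]) - potential_energy(
        model, q_series[i0]
    )


def elevation_phase(times, coord_series, onset_fraction: float = 0.05):
    """(t_onset, t_peak) of an elevation movement.

    Onset is the first time the primary coordinate exceeds
    ``onset_fraction`` of its total excursion; the phase ends at peak
    elevation.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(coord_series, dtype=float)
    x0 = x[0]
    peak_i = int(np.argmax(x - x0))
    excursion = x[peak_i] - x0
    if excursion <= 0:
        return float(times[0]), float(times[peak_i])
    above = np.nonzero(x - x0 >= onset_fraction * excursion)[0]
    onset_i = int(above[0]) if above.size else 0
    return float(times[onset_i]), float(times[peak_i])


@dataclass
class WorkSummary:
    """Per-muscle positive work over the elevation phase of one task."""

    interval: tuple[float, float]
    per_muscle: dict[str, float]
    total: float
    external: float
    groups: dict[str, float]
    #: muscles below the reporting threshold (< 3% of total work)
    excluded: list[str] = field(default_factory=list)


def work_summary(
    result: SimulationResult,
    model: ShoulderModel,
    task: str | None = None,
    interval: tuple[float, float] | None = None,
    exclusion_fraction: float = 0.03,
) -> WorkSummary:
    """Positive muscle work per muscle over the elevation phase, grouped.

    ``task`` selects the primary coordinate for automatic phase detection;
    pass ``interval`` to override.  Muscles doing less than 3% of the total
    positive work are flagged as excluded from the headline ranking (they
    remain in ``per_muscle``; the sum is over all muscles).
    """
    if interval is None:
        if task is None:
            raise ValueError("need either a task name or an explicit interval")
        ci = result.coord_names.index(PRIMARY_COORD[task])
        interval = elevation_phase(result.time, result.q[:, ci])
    power = muscle_power(result.forces, result.v_mtu)
    per = {
        name: positive_work(result.time, power[:, j], interval)
        for j, name in enumerate(result.muscle_names)
    }
    total = float(sum(per.values()))
    groups = {g: 0.0 for g in MUSCLE_GROUPS}
    for name, w in per.items():
        groups[muscle_group(name)] += w
    ext = external_work(model, result.time, result.q, interval)
    excluded = [n for n, w in per.items() if w < exclusion_fraction * total]
    return WorkSummary(
        interval=interval, per_muscle=per, total=total, external=ext,
        groups=groups, excluded=excluded,
    )


def serratus_bundle_average(result: SimulationResult) -> np.ndarray:
    """Mean activation of the three serratus anterior bundles (the model
    quantity compared against the single serratus surface electrode)."""
    idx = [result.muscle_index(f"SerratusAnterior.{b}")
           for b in ("Superior", "Middle", "Inferior")]
    return result.activations[:, idx].mean(axis=1)


def activation_mae(
    t_model,
    a_model,
    t_emg,
    emg_env,
    interval=None,
) -> float:
    """Mean absolute error between a simulated activation and a normalized
    EMG envelope over a task interval (unitless).

    The envelope is resampled onto the model time grid restricted to the
    interval; non-overlapping series raise a ``ValueError``.
    """
    t_model = np.asarray(t_model, dtype=float)
    a_model = np.asarray(a_model, dtype=float)
    t_emg = np.asarray(t_emg, dtype=float)
    emg_env = np.asarray(emg_env, dtype=float)
    lo = max(t_model[0], t_emg[0])
    hi = min(t_model[-1], t_emg[-1])
    if interval is not None:
        lo, hi = max(lo, interval[0]), min(hi, interval[1])
    if hi <= lo:
        raise ValueError("activation and EMG series do not overlap the interval")
    mask = (t_model >= lo) & (t_model <= hi)
    env_i = np.interp(t_model[mask], t_emg, emg_env)
    return float(np.mean(np.abs(a_model[mask] - env_i)))
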