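"""Muscle-driven tracking of coordinate trajectories.

A per-step static-optimization variant of computed muscle control: at each
control step (default 10 ms) a PD law converts tracking error into desired
accelerations, and a bound-constrained quadratic program distributes the
required generalized forces over muscle activations (cost sum a_i^2) plus
heavily penalized reserve actuators, one per coordinate, that guarantee
feasibility.  Commanded activations pass through first-order activation
dynamics between control steps; the skeleton is integrated semi-implicitly
at a fixed 1 ms substep with gravity re-evaluated every substep and the
mass matrix / velocity bias held over the control interval (the tasks are
slow, so the kinetic terms change little within 10 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import lsq_linear

from .dynamics import (
    gravity_force,
    kinetic_energy,
    mass_matrix,
    coriolis_bias,
    potential_energy,
)
from .geometry import geometry_state
from .mechanics import DEFAULT_CURVES, activation_dynamics, force_components
from .types import ShoulderModel

__all__ = [
    "TrackingError",
    "SimulationResult",
    "desired_accelerations",
    "resolve_redundancy",
    "run_tracking",
]


class TrackingError(RuntimeError):
    """The tracking simulation failed (infeasible or integration error)."""


@dataclass
class SimulationResult:
    """Trajectories logged on the control grid of a tracking simulation."""

    time: np.ndarray  # (K,)
    coord_names: list[str]
    muscle_names: list[str]
    q: np.ndarray  # (K, n)
    qd: np.ndarray  # (K, n)
    q_des: np.ndarray  # (K, n)
    activations: np.ndarray  # (K, m)
    forces: np.ndarray  # (K, m) MTU forces, N
    l_mtu: np.ndarray  # (K, m)
    v_mtu: np.ndarray  # (K, m), positive = lengthening
    reserves: np.ndarray  # (K, n) reserve generalized forces
    muscle_torque: np.ndarray  # (K, n) muscle-generated generalized forces
    #: exact accumulated work integrals from the integrator substeps
    work: dict = field(default_factory=dict)

    @property
    def tracking_error(self) -> np.ndarray:
        return self.q - self.q_des

    def muscle_index(self, name: str) -> int:
        return self.muscle_names.index(name)


def desired_accelerations(
    q_des, qd_des, qdd_des, q, qd, kp: float = 100.0, kv: float = 20.0
):
    """PD tracking law: q''* = q''_des + kv (q'_des - q') + kp (q_des - q).

    The defaults are critically damped (kv = 2 sqrt(kp))."""
    return (
        np.asarray(qdd_des)
        + kv * (np.asarray(qd_des) - np.asarray(qd))
        + kp * (np.asarray(q_des) - np.asarray(q))
    )


def _resolve(A, tau_needed, w_r, r_scale, bounds=(0.0, 1.0)):
    """Bound-constrained least squares for activations; reserves close the
    residual exactly.

    Minimizes sum a^2 + w_r sum (r/r_scale)^2 subject to A a + r = tau and
    lo <= a <= hi (reserves eliminated in closed form)."""
    n, m = A.shape
    s = np.sqrt(w_r) / r_scale
    C = np.vstack([s * A, np.eye(m)])
    d = np.concatenate([s * tau_needed, np.zeros(m)])
    sol = lsq_linear(C, d, bounds=bounds, method="bvls", tol=1e-12)
    if sol.status < 0:
        raise TrackingError(f"redundancy resolution failed: {sol.message}")
    a = np.clip(sol.x, *bounds)
    reserves = tau_needed - A @ a
    return a, reserves


def resolve_redundancy(
    model: ShoulderModel,
    state,
    qdd_star,
    w_r: float = 1000.0,
    r_scale: float = 1.0,
    curves=DEFAULT_CURVES,
    cache: dict | None = None,
):
    """Distribute the torque demand of ``qdd_star`` over muscle activations.

    ``state`` is ``(q, qd)``.  Returns ``(activations, reserves)`` where the
    reserve generalized forces exactly close the equation of motion at the
    current kinematics.
    """
    q, qd = (np.asarray(x, dtype=float) for x in state)
    lengths, R = geometry_state(model, q, cache=cache)
    v = -R @ qd
    names = list(model.muscles)
    fa = np.empty(len(names))
    fp = np.empty(len(names))
    for j, nm in enumerate(names):
        fa[j], fp[j] = force_components(model.muscles[nm].params, lengths[j], v[j], curves)
    M = mass_matrix(model, q)
    c = coriolis_bias(model, q, qd)
    G = gravity_force(model, q)
    tau_needed = M @ np.asarray(qdd_star, dtype=float) + c - G - R.T @ fp
    A = R.T @ np.diag(fa)
    return _resolve(A, tau_needed, w_r, r_scale)


def run_tracking(
    model: ShoulderModel,
    times,
    q_des_traj,
    dt: float = 1e-3,
    control_dt: float = 1e-2,
    kp: float = 100.0,
    kv: float = 20.0,
    w_r: float = 1000.0,
    r_scale: float = 1.0,
    tau_act: float = 0.010,
    tau_deact: float = 0.040,
    curves=DEFAULT_CURVES,
) -> SimulationResult:
    """Run a muscle-driven simulation tracking ``q_des_traj``.

    Parameters
    ----------
    times : (N,) time grid of the desired trajectory, s.
    q_des_traj : (N, n) desired coordinate values, rad.
    dt, control_dt : integration substep and control step, s.

    Returns
    -------
    SimulationResult with states, activations, forces and reserves on the
    control grid, plus exact work integrals in ``result.work``.
    """
    times = np.asarray(times, dtype=float)
    q_des_traj = np.asarray(q_des_traj, dtype=float)
    spline = CubicSpline(times, q_des_traj, axis=0)
    dspline = spline.derivative()
    ddspline = dspline.derivative()

    n = model.n_coords
    names = list(model.muscles)
    m = len(names)
    params = [model.muscles[nm].params for nm in names]

    q = spline(times[0]).copy()
    qd = dspline(times[0]).copy()
    a = np.zeros(m)
    cache: dict = {}

    n_ctrl = int(round((times[-1] - times[0]) / control_dt))
    n_sub = max(int(round(control_dt / dt)), 1)
    dts = control_dt / n_sub

    K = n_ctrl + 1
    out = {
        "time": np.empty(K), "q": np.empty((K, n)), "qd": np.empty((K, n)),
        "q_des": np.empty((K, n)), "activations": np.empty((K, m)),
        "forces": np.empty((K, m)), "l_mtu": np.empty((K, m)),
        "v_mtu": np.empty((K, m)), "reserves": np.empty((K, n)),
        "muscle_torque": np.empty((K, n)),
    }
    W_mus = 0.0
    W_res = 0.0
    E0 = kinetic_energy(model, q, qd) + potential_energy(model, q)

    for k in range(K):
        t = times[0] + k * control_dt
        lengths, R = geometry_state(model, q, cache=cache)
        v = -R @ qd
        fa = np.empty(m)
        fp = np.empty(m)
        for j in range(m):
            fa[j], fp[j] = force_components(params[j], lengths[j], v[j], curves)

        M = mass_matrix(model, q)
        c = coriolis_bias(model, q, qd)
        qdd_star = desired_accelerations(
            spline(t), dspline(t), ddspline(t), q, qd, kp=kp, kv=kv
        )
        G = gravity_force(model, q)
        tau_needed = M @ qdd_star + c - G - R.T @ fp
        A = R.T @ np.diag(fa)
        # activation-dynamics inversion: optimize over the activation
        # reachable within one control step, then back out the excitation
        beta_up = np.exp(-control_dt / tau_act)
        beta_dn = np.exp(-control_dt / tau_deact)
        a_hi = 1.0 - (1.0 - a) * beta_up
        a_lo = a * beta_dn
        a_new, reserves = _resolve(A, tau_needed, w_r, r_scale, (a_lo, a_hi))
        u = np.where(
            a_new >= a,
            (a_new - a * beta_up) / (1.0 - beta_up),
            (a_new - a * beta_dn) / (1.0 - beta_dn),
        )
        a = activation_dynamics(a, np.clip(u, 0.0, 1.0), control_dt,
                                tau_act, tau_deact)
        F = np.clip(a * fa + fp, 0.0, None)
        tau_m = R.T @ F

        out["time"][k] = t
        out["q"][k], out["qd"][k] = q, qd
        out["q_des"][k] = spline(t)
        out["activations"][k] = a
        out["forces"][k] = F
        out["l_mtu"][k] = lengths
        out["v_mtu"][k] = v
        out["reserves"][k] = reserves
        out["muscle_torque"][k] = tau_m

        if k == n_ctrl:
            break
        # integrate the control interval with held M, c, muscle forces
        Mi = np.linalg.inv(M)
        for _ in range(n_sub):
            Gs = gravity_force(model, q)
            qdd = Mi @ (tau_m + reserves + Gs - c)
            if not np.all(np.isfinite(qdd)):
                raise TrackingError(
                    f"integration failure at t={t:.3f}s: state {q}, {qd}"
                )
            qd = qd + dts * qdd
            q = q + dts * qd
            W_mus += float(tau_m @ qd) * dts
            W_res += float(reserves @ qd) * dts

    E1 = kinetic_energy(model, q, qd) + potential_energy(model, q)
    result = SimulationResult(
        time=out["time"], coord_names=model.coordinate_names,
        muscle_names=names, q=out["q"], qd=out["qd"], q_des=out["q_des"],
        activations=out["activations"], forces=out["forces"],
        l_mtu=out["l_mtu"], v_mtu=out["v_mtu"], reserves=out["reserves"],
        muscle_torque=out["muscle_torque"],
        work={
            "muscle": W_mus,
            "reserve": W_res,
            "energy_change": E1 - E0,
        },
    )
    return result
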