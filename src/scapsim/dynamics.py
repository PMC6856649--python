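"""Generalized rigid-body dynamics of the shoulder model.

The model has seven generalized coordinates (four scapulothoracic, three
glenohumeral); the mobile bodies are the scapula, humerus and lumped
forearm+hand, plus an optional hand-held point mass.  Body Jacobians are
obtained by central differences of the (vectorized) forward kinematics,
the joint-space mass matrix M(q) by assembling J^T m J contributions, the
gravity force as the exact negative gradient of the potential energy, and
the velocity-dependent bias via the Christoffel symbols of a finite-
differenced M — which preserves the skew-symmetry property underlying the
work-energy balance of the simulations.
"""

from __future__ import annotations

import numpy as np

from .kinematics import forward_kinematics
from .types import ShoulderModel

__all__ = [
    "mobile_bodies",
    "mass_matrix",
    "gravity_force",
    "coriolis_bias",
    "mass_matrix_and_bias",
    "potential_energy",
    "kinetic_energy",
]

_FD_STEP = 1e-6


def mobile_bodies(model: ShoulderModel):
    """(name, mass, com, inertia) for bodies that move with q."""
    out = []
    for name in ("scapula", "humerus", "forearm"):
        b = model.bodies[name]
        out.append((name, b.mass, b.com, b.inertia))
    return out


def _fk_batch(model, Q):
    return forward_kinematics(model, Q)


def _com_positions(model, frames):
    """Stack world COM positions of mobile bodies plus the hand point.

    Returns (n_points, ...) with masses aligned.
    """
    pts, masses = [], []
    for name, mass, com, _ in mobile_bodies(model):
        R, p = frames[name]
        pts.append(p + np.einsum("...ij,j->...i", R, com))
        masses.append(mass)
    if model.hand_mass > 0.0:
        R, p = frames["forearm"]
        pts.append(p + np.einsum("...ij,j->...i", R, model.hand_point))
        masses.append(model.hand_mass)
    return pts, np.asarray(masses)


def potential_energy(model: ShoulderModel, q) -> float:
    """Gravitational potential energy (J), zero level at the ground origin."""
    frames = forward_kinematics(model, np.asarray(q, dtype=float))
    pts, masses = _com_positions(model, frames)
    g = model.gravity
    return float(-sum(m * np.dot(g, p) for m, p in zip(masses, pts)))


def gravity_force(model: ShoulderModel, q, h: float = _FD_STEP) -> np.ndarray:
    """Generalized gravity force G(q) = -dPE/dq (central differences)."""
    q = np.asarray(q, dtype=float)
    n = q.size
    Q = np.repeat(q[None], 2 * n, axis=0)
    idx = np.arange(n)
    Q[2 * idx, idx] += h
    Q[2 * idx + 1, idx] -= h
    frames = _fk_batch(model, Q)
    pts, masses = _com_positions(model, frames)
    g = model.gravity
    pe = -sum(m * (p @ g) for m, p in zip(masses, pts))
    return -(pe[2 * idx] - pe[2 * idx + 1]) / (2.0 * h)


def _mass_matrix_from_frames(model, frames0, frames_p, frames_m, h):
    """Assemble M from nominal frames and the +/- perturbed frame batches.

    ``frames_p``/``frames_m`` hold, per body, arrays with a leading axis of
    size n (one entry per perturbed coordinate).
    """
    n = model.n_coords
    M = np.zeros((n, n))
    bodies = mobile_bodies(model)
    for name, mass, com, inertia in bodies:
        R0, _ = frames0[name]
        Rp, pp = frames_p[name]
        Rm, pm = frames_m[name]
        cp = pp + np.einsum("kij,j->ki", Rp, com)
        cm = pm + np.einsum("kij,j->ki", Rm, com)
        Jv = (cp - cm).T / (2.0 * h)  # (3, n)
        dR = (Rp - Rm) / (2.0 * h)  # (n, 3, 3)
        W = np.einsum("kij,lj->kil", dR, R0)  # dR R0^T, (n,3,3)
        Jw = np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=0)  # (3, n)
        I_w = R0 @ inertia @ R0.T
        M += mass * (Jv.T @ Jv) + Jw.T @ I_w @ Jw
    if model.hand_mass > 0.0:
        Rp, pp = frames_p["forearm"]
        Rm, pm = frames_m["forearm"]
        cp = pp + np.einsum("kij,j->ki", Rp, model.hand_point)
        cm = pm + np.einsum("kij,j->ki", Rm, model.hand_point)
        Jv = (cp - cm).T / (2.0 * h)
        M += model.hand_mass * (Jv.T @ Jv)
    return M


def _split_frames(frames, sel):
    return {k: (R[sel], p[sel]) for k, (R, p) in frames.items()}


def mass_matrix(model: ShoulderModel, q, h: float = _FD_STEP) -> np.ndarray:
    """Joint-space mass matrix M(q), (n, n), symmetric positive definite."""
    q = np.asarray(q, dtype=float)
    n = q.size
    Q = np.vstack([q[None], np.repeat(q[None], 2 * n, axis=0)])
    idx = np.arange(n)
    Q[1 + 2 * idx, idx] += h
    Q[2 + 2 * idx, idx] -= h
    frames = _fk_batch(model, Q)
    f0 = _split_frames(frames, 0)
    fp = _split_frames(frames, 1 + 2 * idx)
    fm = _split_frames(frames, 2 + 2 * idx)
    return _mass_matrix_from_frames(model, f0, fp, fm, h)


def coriolis_bias(model: ShoulderModel, q, qd, h: float = 1e-5) -> np.ndarray:
    """Velocity-product bias c(q, qd) from Christoffel symbols of M.

    c_i = sum_jk (dM_ij/dq_k - 0.5 dM_jk/dq_i) qd_j qd_k, with dM/dq by
    central differences.  Using the Christoffel form preserves the
    skew-symmetry of (dM/dt - 2C), i.e. the velocity bias does no work.
    """
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    n = q.size
    dM = np.empty((n, n, n))  # dM[k] = dM/dq_k
    for k in range(n):
        qp, qm = q.copy(), q.copy()
        qp[k] += h
        qm[k] -= h
        dM[k] = (mass_matrix(model, qp) - mass_matrix(model, qm)) / (2.0 * h)
    c = np.einsum("kij,j,k->i", dM, qd, qd) - 0.5 * np.einsum(
        "ijk,j,k->i", dM, qd, qd
    )
    return c


def mass_matrix_and_bias(model: ShoulderModel, q, qd, h: float = 1e-5):
    """(M, c) evaluated together (shares no work, provided for symmetry)."""
    return mass_matrix(model, q), coriolis_bias(model, q, qd, h=h)


def kinetic_energy(model: ShoulderModel, q, qd) -> float:
    qd = np.asarray(qd, dtype=float)
    return float(0.5 * qd @ mass_matrix(model, q) @ qd)
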