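"""Scapulothoracic joint kinematics and whole-model forward kinematics.

The scapula glides on a thorax-fixed ellipsoid.  Two surface angles
(abduction = longitude about the vertical axis, elevation = latitude) locate
the contact point through the trigonometric parameterization of the
ellipsoid; upward rotation spins the scapula about the outward surface
normal, and winging rotates it about the vertical surface tangent (the
medial-border axis).  The contact point therefore satisfies the implicit
ellipsoid equation identically, for every pose.

All routines broadcast over a leading batch axis: ``q`` may be ``(nq,)`` or
``(N, nq)``.
"""

from __future__ import annotations

import numpy as np

from .types import ScapulothoracicJoint, ShoulderModel

__all__ = [
    "CoordinateRangeError",
    "scapula_transform",
    "scapula_transform_jacobian",
    "rot_x",
    "rot_y",
    "rot_z",
    "humerus_rotation",
    "forward_kinematics",
    "marker_positions",
    "body_point_world",
]


class CoordinateRangeError(ValueError):
    """A coordinate value lies outside its allowed range."""


# ---------------------------------------------------------------------------
# elementary rotations (batched)
# ---------------------------------------------------------------------------

def _rot(theta, i, j):
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = R[..., 1, 1] = R[..., 2, 2] = 1.0
    R[..., i, i] = c
    R[..., j, j] = c
    R[..., i, j] = -s
    R[..., j, i] = s
    return R


def rot_x(theta):
    return _rot(theta, 1, 2)


def rot_y(theta):
    return _rot(theta, 2, 0)


def rot_z(theta):
    return _rot(theta, 0, 1)


def _normalize(v):
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# scapulothoracic joint
# ---------------------------------------------------------------------------

def scapula_transform(
    joint: ScapulothoracicJoint,
    q_st,
    ranges=None,
):
    """Pose of the scapula frame in the thorax frame.

    Parameters
    ----------
    joint : ScapulothoracicJoint
    q_st : array_like, shape (..., 4)
        (abduction, elevation, upward_rotation, winging), rad.
    ranges : sequence of (lo, hi), optional
        When given, each coordinate is checked against its range and a
        :class:`CoordinateRangeError` naming the coordinate is raised on
        violation.

    Returns
    -------
    R : ndarray (..., 3, 3), p : ndarray (..., 3)
        Rotation and origin (the ellipsoid contact point) of the scapula
        frame expressed in the thorax frame.
    """
    q_st = np.asarray(q_st, dtype=float)
    if ranges is not None:
        q2 = np.atleast_2d(q_st)
        for k, (lo, hi) in enumerate(ranges):
            if np.any(q2[:, k] < lo - 1e-12) or np.any(q2[:, k] > hi + 1e-12):
                raise CoordinateRangeError(
                    f"coordinate {joint.coordinate_names[k]!r} outside range"
                    f" [{lo}, {hi}]"
                )
    a = joint.ref_abduction + q_st[..., 0]
    e = joint.ref_elevation + q_st[..., 1]
    up = q_st[..., 2]
    wing = q_st[..., 3]
    rx, ry, rz = joint.radii

    ca, sa = np.cos(a), np.sin(a)
    ce, se = np.cos(e), np.sin(e)

    # contact point and surface basis in the (possibly tilted) ellipsoid frame
    p_e = np.stack([-rx * ce * ca, ry * se, rz * ce * sa], axis=-1)
    dpda = np.stack([rx * ce * sa, np.zeros_like(sa), rz * ce * ca], axis=-1)
    n = np.stack([-ca * ce / rx, se / ry, sa * ce / rz], axis=-1)
    n = _normalize(n)
    t1 = dpda - np.sum(dpda * n, axis=-1, keepdims=True) * n
    t1 = _normalize(t1)
    t2 = np.cross(n, t1)
    B = np.stack([t1, t2, n], axis=-1)  # columns: lateral tangent, up tangent, normal

    R_tilt = rot_z(joint.tilt)
    # winging first: its axis stays the (near-vertical) medial-border
    # tangent at every upward-rotation angle
    R_local = rot_y(wing) @ rot_z(up)
    R = R_tilt @ B @ R_local
    p = joint.center + np.einsum("ij,...j->...i", R_tilt, p_e)
    return R, p


_JAC_FUNC = None


def _build_jacobian_func():
    """Closed-form Jacobian of the 12 transform components w.r.t. q_st,
    generated symbolically once and cached."""
    import sympy as sp

    qa, qe, qu, qw = sp.symbols("qa qe qu qw")
    rx, ry, rz, tilt, a0, e0 = sp.symbols("rx ry rz tilt a0 e0")
    cx, cy, cz = sp.symbols("cx cy cz")
    a, e = a0 + qa, e0 + qe

    ca, sa, ce, se = sp.cos(a), sp.sin(a), sp.cos(e), sp.sin(e)
    p_e = sp.Matrix([-rx * ce * ca, ry * se, rz * ce * sa])
    dpda = sp.Matrix([rx * ce * sa, 0, rz * ce * ca])
    n = sp.Matrix([-ca * ce / rx, se / ry, sa * ce / rz])
    n = n / sp.sqrt(n.dot(n))
    t1 = dpda - dpda.dot(n) * n
    t1 = t1 / sp.sqrt(t1.dot(t1))
    t2 = n.cross(t1)  # sympy cross of column vectors
    B = sp.Matrix.hstack(t1, t2, n)

    def Rz(t):
        return sp.Matrix(
            [[sp.cos(t), -sp.sin(t), 0], [sp.sin(t), sp.cos(t), 0], [0, 0, 1]]
        )

    def Ry(t):
        return sp.Matrix(
            [[sp.cos(t), 0, sp.sin(t)], [0, 1, 0], [-sp.sin(t), 0, sp.cos(t)]]
        )

    R_tilt = Rz(tilt)
    R = R_tilt * B * Ry(qw) * Rz(qu)
    p = sp.Matrix([cx, cy, cz]) + R_tilt * p_e

    comps = sp.Matrix.vstack(R.reshape(9, 1), p)
    jac = comps.jacobian([qa, qe, qu, qw])
    return sp.lambdify(
        (qa, qe, qu, qw, rx, ry, rz, tilt, a0, e0, cx, cy, cz), jac, "numpy"
    )


def scapula_transform_jacobian(joint: ScapulothoracicJoint, q_st) -> np.ndarray:
    """Analytic Jacobian of the scapula transform.

    Returns the (12, 4) derivative of the stacked transform components
    (the 9 rotation entries in row-major order followed by the 3 origin
    components) with respect to the four joint coordinates.
    """
    global _JAC_FUNC
    if _JAC_FUNC is None:
        _JAC_FUNC = _build_jacobian_func()
    q_st = np.asarray(q_st, dtype=float)
    rx, ry, rz = joint.radii
    cx, cy, cz = joint.center
    return np.asarray(
        _JAC_FUNC(
            q_st[0], q_st[1], q_st[2], q_st[3],
            rx, ry, rz, joint.tilt,
            joint.ref_abduction, joint.ref_elevation,
            cx, cy, cz,
        ),
        dtype=float,
    )


# ---------------------------------------------------------------------------
# whole-model forward kinematics
# ---------------------------------------------------------------------------

def humerus_rotation(q_hum):
    """Humerus orientation relative to its thorax-aligned reference.

    ``q_hum = (flexion, abduction, axial)``; R = Rz(flex) Ry(axial) Rx(-abd).
    Axial rotation sits in the middle of the sequence because it stays small
    in the study tasks, so the parameterization is non-singular both at the
    arm-hanging reference and through 90 deg of flexion or abduction.
    """
    q_hum = np.asarray(q_hum, dtype=float)
    return rot_z(q_hum[..., 0]) @ rot_y(q_hum[..., 2]) @ rot_x(-q_hum[..., 1])


def forward_kinematics(model: ShoulderModel, q):
    """Frames of all bodies in the ground (= thorax) frame.

    Parameters
    ----------
    q : array_like, shape (..., n_coords)

    Returns
    -------
    dict name -> (R, p) with R ``(..., 3, 3)`` and p ``(..., 3)``.
    """
    q = np.asarray(q, dtype=float)
    batch = q.shape[:-1]
    eye = np.broadcast_to(np.eye(3), batch + (3, 3))
    zero = np.broadcast_to(np.zeros(3), batch + (3,))
    frames = {"thorax": (eye, zero)}

    Rc, pc = model.fixed_transforms["clavicle"]
    frames["clavicle"] = (
        np.broadcast_to(Rc, batch + (3, 3)),
        np.broadcast_to(pc, batch + (3,)),
    )

    Rs, ps = scapula_transform(model.st_joint, q[..., :4])
    frames["scapula"] = (Rs, ps)

    # ball-joint rotations are defined about thorax-aligned reference axes
    # (the scapula's default orientation is factored out), so flexion /
    # abduction / axial rotation keep their anatomical meaning
    C, gh = model.fixed_transforms["humerus_offset"]
    Rh = Rs @ C @ humerus_rotation(q[..., 4:7])
    ph = ps + np.einsum("...ij,j->...i", Rs, gh)
    frames["humerus"] = (Rh, ph)

    Rfe, pfe = model.fixed_transforms["forearm"]
    Rf = Rh @ Rfe
    pf = ph + np.einsum("...ij,j->...i", Rh, pfe)
    frames["forearm"] = (Rf, pf)
    return frames


def body_point_world(frames, body: str, location) -> np.ndarray:
    """World position of a point fixed in ``body``'s frame (batched)."""
    R, p = frames[body]
    return p + np.einsum("...ij,j->...i", R, np.asarray(location, dtype=float))


def marker_positions(model: ShoulderModel, q, names=None):
    """World positions of model markers.

    Returns
    -------
    names : list of str, pos : ndarray (..., n_markers, 3)
    """
    if names is None:
        names = list(model.markers)
    frames = forward_kinematics(model, q)
    pos = np.stack(
        [body_point_world(frames, model.markers[n].body, model.markers[n].location)
         for n in names],
        axis=-2,
    )
    return names, pos
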