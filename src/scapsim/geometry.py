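"""Muscle path lengths, wrap-surface routing, and tendon-excursion moment arms.

Sphere and cylinder wrapping are solved in closed form; ellipsoid wrapping is
solved numerically as the shortest polyline whose interior vertices lie on
the surface (initialized from the sphere solution of the axis-scaled space,
optionally Richardson-extrapolated in the vertex count to cancel the
chord-versus-arc discretization error).  A segment that only grazes a
surface is tie-broken to the straight segment so path length is continuous
in the coordinates.

The moment arm of a muscle about a rotational coordinate is the tendon
excursion r = -dL/dq, evaluated by central differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .kinematics import forward_kinematics
from .types import ShoulderModel, WrapSurface

__all__ = [
    "PathSolution",
    "UndefinedPathError",
    "wrap_over_surface",
    "solve_path",
    "path_length",
    "moment_arm",
    "moment_arm_matrix",
    "mtu_lengths",
    "check_fiber_operating_range",
    "tune_muscle_lengths",
    "TuningError",
]


class UndefinedPathError(RuntimeError):
    """The wrapping path is undefined (an endpoint lies inside the surface)."""


class TuningError(RuntimeError):
    """Fiber/tendon tuning failed to converge."""


@dataclass
class PathSolution:
    """A resolved muscle path in world space."""

    points: np.ndarray  # (k, 3) ordered path points, origin -> insertion
    length: float
    wrap_active: list[bool] = field(default_factory=list)
    #: warm-start data for numeric wraps (per wrapped segment)
    _warm: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# closed-form sphere / cylinder wrapping
# ---------------------------------------------------------------------------

def _sphere_wrap_local(p1, p2, r, n_arc):
    """Shortest path around a sphere of radius ``r`` at the origin.

    Returns (points (k,3), length, wrapped).  Straight segments (including
    the grazing-tangency limit) return the two endpoints unchanged.
    """
    d1, d2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if d1 < r or d2 < r:
        raise UndefinedPathError("path endpoint inside wrap sphere")
    # closest approach of the segment to the center
    d = p2 - p1
    t = -np.dot(p1, d) / np.dot(d, d)
    t = min(max(t, 0.0), 1.0)
    if np.linalg.norm(p1 + t * d) >= r:
        return np.stack([p1, p2]), float(np.linalg.norm(d)), False

    u = p1 / d1
    w = p2 - np.dot(p2, u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-14:  # collinear through center: undefined direction
        raise UndefinedPathError("wrap path through sphere center")
    w = w / wn
    phi = math.atan2(np.dot(p2, w), np.dot(p2, u))
    a1 = math.acos(min(r / d1, 1.0))
    a2 = math.acos(min(r / d2, 1.0))
    arc = phi - a1 - a2
    if arc <= 0:  # tangency tie-break: straight
        return np.stack([p1, p2]), float(np.linalg.norm(d)), False
    length = math.sqrt(d1 * d1 - r * r) + math.sqrt(d2 * d2 - r * r) + r * arc
    ang = np.linspace(a1, phi - a2, max(n_arc, 2))
    arc_pts = r * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * w)
    pts = np.vstack([p1[None], arc_pts, p2[None]])
    return pts, float(length), True


def _cylinder_wrap_local(p1, p2, r, n_arc):
    """Shortest path around an infinite cylinder (axis = local Z)."""
    a2d, b2d = p1[:2], p2[:2]
    da, db = np.linalg.norm(a2d), np.linalg.norm(b2d)
    if da < r or db < r:
        raise UndefinedPathError("path endpoint inside wrap cylinder")
    d = b2d - a2d
    t = -np.dot(a2d, d) / max(np.dot(d, d), 1e-300)
    t = min(max(t, 0.0), 1.0)
    if np.linalg.norm(a2d + t * d) >= r:
        return np.stack([p1, p2]), float(np.linalg.norm(p2 - p1)), False

    u = a2d / da
    w = b2d - np.dot(b2d, u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-14:
        raise UndefinedPathError("wrap path through cylinder axis")
    w = w / wn
    phi = math.atan2(np.dot(b2d, w), np.dot(b2d, u))
    a1 = math.acos(min(r / da, 1.0))
    a2 = math.acos(min(r / db, 1.0))
    arc = phi - a1 - a2
    if arc <= 0:
        return np.stack([p1, p2]), float(np.linalg.norm(p2 - p1)), False
    s_planar = (
        math.sqrt(da * da - r * r) + math.sqrt(db * db - r * r) + r * arc
    )
    dz = p2[2] - p1[2]
    length = math.hypot(s_planar, dz)
    # path points: planar tangent-arc path, z linear in planar arc length
    ang = np.linspace(a1, phi - a2, max(n_arc, 2))
    arc2d = r * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * w)
    s_entry = math.sqrt(da * da - r * r)
    s_at = s_entry + r * (ang - a1)
    z_at = p1[2] + dz * s_at / s_planar
    pts = np.vstack(
        [p1[None], np.hstack([arc2d, z_at[:, None]]), p2[None]]
    )
    return pts, float(length), True


def _taut_string_relax(chain, axes, tol=1e-10, max_sweeps=20000, omega=1.8):
    """Relax interior vertices of ``chain`` to the taut-string equilibrium
    around the ellipsoid ``diag(axes)`` (red-black Gauss-Seidel with
    over-relaxation).

    Each vertex moves toward the midpoint of its neighbors; vertices that
    would penetrate the surface are projected back onto it.  Vertices off
    the contact region line up on the straight tangent segments, so partial
    surface contact is handled naturally and no vertex pile-up can occur.
    """
    x = chain.copy()
    inv = 1.0 / axes
    k = x.shape[0]

    def update(idx, w):
        m = 0.5 * (x[idx - 1] + x[idx + 1])
        m = x[idx] + w * (m - x[idx])
        s = m * inv
        r = np.linalg.norm(s, axis=1)
        inside = r < 1.0
        if np.any(inside):
            m[inside] = (s[inside] / r[inside, None]) * axes
        moved = np.max(np.linalg.norm(m - x[idx], axis=1))
        x[idx] = m
        return moved

    odd = np.arange(1, k - 1, 2)
    even = np.arange(2, k - 1, 2)
    for sweep in range(max_sweeps):
        # plain Gauss-Seidel for the first sweeps keeps the projection stable
        w = 1.0 if sweep < 10 else omega
        moved = update(odd, w)
        if even.size:
            moved = max(moved, update(even, w))
        if moved < tol:
            break
    return x


def _chain_length(chain):
    return float(np.sum(np.linalg.norm(np.diff(chain, axis=0), axis=1)))


def _refine_chain(chain):
    """Insert chord midpoints (doubling the segment count)."""
    fine = np.empty((2 * (chain.shape[0] - 1) + 1, 3))
    fine[::2] = chain
    fine[1::2] = 0.5 * (chain[:-1] + chain[1:])
    return fine


def _ellipsoid_wrap_local(p1, p2, axes, n_arc, richardson, warm=None, tol=1e-10):
    """Numeric shortest path around an ellipsoid centered at the origin.

    The path is a polyline relaxed to the taut-string equilibrium (straight
    where clear of the surface, tension balance on it), initialized from
    the closed-form sphere solution of the axis-scaled space.  With
    ``richardson`` the vertex count is doubled and the O(1/k^2) chord
    discretization error extrapolated away.  Returns
    ``(points, length, wrapped, warm_data)``.
    """
    axes = np.asarray(axes, dtype=float)
    s1, s2 = p1 / axes, p2 / axes
    if np.linalg.norm(s1) < 1.0 or np.linalg.norm(s2) < 1.0:
        raise UndefinedPathError("path endpoint inside wrap ellipsoid")
    d = s2 - s1
    t = -np.dot(s1, d) / np.dot(d, d)
    t = min(max(t, 0.0), 1.0)
    straight = (np.stack([p1, p2]), float(np.linalg.norm(p2 - p1)), False, None)
    if np.linalg.norm(s1 + t * d) >= 1.0:
        return straight

    k = max(n_arc, 4)
    if warm is not None and warm.shape == (k + 2, 3):
        chain = warm.copy()
        chain[0], chain[-1] = p1, p2
    else:
        sp_pts, _, wrapped = _sphere_wrap_local(s1, s2, 1.0, k)
        if not wrapped:  # grazing tie-break
            return straight
        chain = np.vstack([p1[None], sp_pts[1:-1] * axes, p2[None]])
    chain = _taut_string_relax(chain, axes, tol=tol)
    L1 = _chain_length(chain)
    # no vertex ended up on the surface: the taut string is straight
    if np.all(np.linalg.norm(chain[1:-1] / axes, axis=1) > 1.0 + 1e-9):
        return straight
    if richardson:
        fine = _taut_string_relax(_refine_chain(chain), axes, tol=tol)
        L2 = _chain_length(fine)
        length = (4.0 * L2 - L1) / 3.0
        out = fine
    else:
        length, out = L1, chain
    return out, float(length), True, chain


def wrap_over_surface(
    p1,
    p2,
    surface: WrapSurface,
    surface_rotation=None,
    surface_translation=None,
    n_arc: int = 24,
    richardson: bool = True,
    warm=None,
    tol: float = 1e-10,
) -> PathSolution:
    """Shortest smooth path from ``p1`` to ``p2`` that does not penetrate
    ``surface``.

    ``surface_rotation``/``surface_translation`` place the surface frame in
    the frame of ``p1``/``p2`` (default: the surface's stored body pose,
    i.e. points given in the surface's body frame).  Reduces to the straight
    segment when the segment clears (or only grazes) the surface.  The
    defaults resolve an ellipsoid wrap to well under 1e-6 m; model-level
    path evaluation (:func:`solve_path`) uses a faster, coarser setting.
    """
    R = surface.rotation if surface_rotation is None else np.asarray(surface_rotation)
    c = (
        surface.translation
        if surface_translation is None
        else np.asarray(surface_translation)
    )
    q1 = R.T @ (np.asarray(p1, dtype=float) - c)
    q2 = R.T @ (np.asarray(p2, dtype=float) - c)
    warm_out = None
    try:
        if surface.kind == "sphere":
            pts, length, wrapped = _sphere_wrap_local(
                q1, q2, surface.dimensions[0], n_arc
            )
        elif surface.kind == "cylinder":
            pts, length, wrapped = _cylinder_wrap_local(
                q1, q2, surface.dimensions[0], n_arc
            )
        elif surface.kind == "ellipsoid":
            pts, length, wrapped, warm_out = _ellipsoid_wrap_local(
                q1, q2, surface.dimensions, n_arc, richardson, warm, tol=tol
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown wrap kind {surface.kind!r}")
    except UndefinedPathError as err:
        raise UndefinedPathError(f"{err} (surface {surface.name!r})") from None
    sol = PathSolution(
        points=pts @ R.T + c, length=length, wrap_active=[wrapped]
    )
    sol._warm["angles"] = warm_out
    return sol


# ---------------------------------------------------------------------------
# model-level path evaluation
# ---------------------------------------------------------------------------

def solve_path(
    model: ShoulderModel,
    q,
    muscle: str,
    frames=None,
    cache: dict | None = None,
    n_arc: int = 12,
    richardson: bool = False,
    wrap_tol: float = 1e-9,
) -> PathSolution:
    """Resolve a muscle's world-space path at pose ``q``.

    Uses a faster wrap setting than :func:`wrap_over_surface` (coarser
    chain, no Richardson step, ~1e-4 m length bias on a deep ellipsoid
    wrap) appropriate for repeated evaluation inside sweeps and tracking;
    pass a persistent ``cache`` dict to warm-start consecutive solves.
    """
    mus = model.muscles[muscle]
    if frames is None:
        frames = forward_kinematics(model, np.asarray(q, dtype=float))
    world = []
    for pt in mus.path.points:
        R, p = frames[pt.body]
        world.append(p + R @ pt.location)
    pts_out = [world[0]]
    total = 0.0
    status = []
    for i, wname in enumerate(mus.path.wraps):
        a, b = world[i], world[i + 1]
        if wname is None:
            total += float(np.linalg.norm(b - a))
            pts_out.append(b)
            status.append(False)
            continue
        surf = model.wrap_surfaces[wname]
        Rw, pw = frames[surf.body]
        Rs = Rw @ surf.rotation
        cs = pw + Rw @ surf.translation
        warm = None
        key = (muscle, i)
        if cache is not None:
            warm = cache.get(key)
        try:
            sol = wrap_over_surface(
                a, b, surf, Rs, cs, n_arc=n_arc, richardson=richardson,
                warm=warm, tol=wrap_tol,
            )
        except UndefinedPathError as err:
            raise UndefinedPathError(f"muscle {muscle!r}: {err}") from None
        if cache is not None and sol._warm.get("angles") is not None:
            cache[key] = sol._warm["angles"]
        total += sol.length
        pts_out.extend(list(sol.points[1:]))
        status.append(bool(sol.wrap_active[0]))
    return PathSolution(points=np.asarray(pts_out), length=total, wrap_active=status)


def path_length(
    model: ShoulderModel, q, muscle: str, cache: dict | None = None
) -> float:
    """Musculotendon path length (m) at pose ``q``."""
    return solve_path(model, q, muscle, cache=cache).length


def mtu_lengths(model: ShoulderModel, q, cache: dict | None = None) -> np.ndarray:
    """Path lengths of all muscles at pose ``q`` (model muscle order)."""
    frames = forward_kinematics(model, np.asarray(q, dtype=float))
    return np.array(
        [solve_path(model, q, m, frames=frames, cache=cache).length
         for m in model.muscles]
    )


# the joint articulated by each coordinate splits the tree in two; a muscle
# length varies with the coordinate only if its bodies span that split
_JOINT_SPLIT = {
    i: ({"thorax", "clavicle"}, {"scapula", "humerus", "forearm"})
    for i in range(4)
}
_JOINT_SPLIT.update({
    i: ({"thorax", "clavicle", "scapula"}, {"humerus", "forearm"})
    for i in range(4, 7)
})


def muscle_depends_on(model: ShoulderModel, muscle: str, coord_idx: int) -> bool:
    """Whether a muscle's length can vary with a coordinate (tree locality)."""
    mus = model.muscles[muscle]
    bodies = {pt.body for pt in mus.path.points}
    for w in mus.path.wraps:
        if w is not None:
            bodies.add(model.wrap_surfaces[w].body)
    proximal, distal = _JOINT_SPLIT[coord_idx]
    return bool(bodies & proximal) and bool(bodies & distal)


def moment_arm(
    model: ShoulderModel,
    q,
    muscle: str,
    coord: str | int,
    step: float = 1e-5,
    cache: dict | None = None,
) -> float:
    """Tendon-excursion moment arm r = -dL/dq (m) by central difference.

    Positive r means the muscle generates a positive generalized force on
    the coordinate.  ``step`` is the finite-difference step in rad.
    """
    idx = coord if isinstance(coord, int) else model.coordinate_index(coord)
    q = np.asarray(q, dtype=float)
    if not muscle_depends_on(model, muscle, idx):
        return 0.0
    qp, qm = q.copy(), q.copy()
    qp[idx] += step
    qm[idx] -= step
    lp = path_length(model, qp, muscle, cache=cache)
    lm = path_length(model, qm, muscle, cache=cache)
    return -(lp - lm) / (2.0 * step)


def moment_arm_matrix(
    model: ShoulderModel, q, step: float = 1e-5, cache: dict | None = None
) -> np.ndarray:
    """(n_muscles, n_coords) tendon-excursion moment arms at pose ``q``."""
    names = list(model.muscles)
    out = np.zeros((len(names), model.n_coords))
    for j, m in enumerate(names):
        for i in range(model.n_coords):
            if muscle_depends_on(model, m, i):
                out[j, i] = moment_arm(model, q, m, i, step=step, cache=cache)
    return out


def geometry_state(
    model: ShoulderModel,
    q,
    step: float = 1e-5,
    cache: dict | None = None,
):
    """MTU lengths and the full tendon-excursion moment-arm matrix at ``q``.

    Shares one batched forward-kinematics evaluation across the nominal
    pose and all +/- coordinate perturbations, so it is the evaluation
    path used inside tracking simulations.

    Returns
    -------
    lengths : ndarray (n_muscles,), moment_arms : ndarray (n_muscles, n_coords)
    """
    q = np.asarray(q, dtype=float)
    n = model.n_coords
    Q = np.vstack([q[None], np.repeat(q[None], 2 * n, axis=0)])
    idx = np.arange(n)
    Q[1 + 2 * idx, idx] += step
    Q[2 + 2 * idx, idx] -= step
    frames = forward_kinematics(model, Q)
    names = list(model.muscles)
    lengths = np.zeros(len(names))
    arms = np.zeros((len(names), n))
    for j, mname in enumerate(names):
        mus = model.muscles[mname]
        world = []
        for pt in mus.path.points:
            R, p = frames[pt.body]
            world.append(p + R @ pt.location)  # (2n+1, 3)
        deps = [i for i in range(n) if muscle_depends_on(model, mname, i)]
        rows = [0] + [1 + 2 * i for i in deps] + [2 + 2 * i for i in deps]
        L = np.zeros(2 * n + 1)
        for i, wname in enumerate(mus.path.wraps):
            a, b = world[i], world[i + 1]
            if wname is None:
                L[rows] += np.linalg.norm(b[rows] - a[rows], axis=1)
                continue
            surf = model.wrap_surfaces[wname]
            Rw, pw = frames[surf.body]
            for r_i in rows:
                Rs = Rw[r_i] @ surf.rotation
                cs = pw[r_i] + Rw[r_i] @ surf.translation
                warm = cache.get((mname, i)) if cache is not None else None
                sol = wrap_over_surface(
                    a[r_i], b[r_i], surf, Rs, cs,
                    n_arc=12, richardson=False, warm=warm, tol=1e-9,
                )
                if cache is not None and sol._warm.get("angles") is not None:
                    cache[(mname, i)] = sol._warm["angles"]
                L[r_i] += sol.length
        lengths[j] = L[0]
        for i in deps:
            arms[j, i] = -(L[1 + 2 * i] - L[2 + 2 * i]) / (2.0 * step)
    return lengths, arms


# ---------------------------------------------------------------------------
# fiber operating range and the incremental fiber/tendon tuning rule
# ---------------------------------------------------------------------------

def check_fiber_operating_range(
    model: ShoulderModel,
    q_trajectory,
    low: float = 0.5,
    high: float = 1.5,
    cache: dict | None = None,
) -> dict:
    """Min/max normalized (rigid-tendon) fiber length per muscle over a
    trajectory, flagging excursions outside ``[low, high]``.

    Returns ``{name: {"min": r, "max": r, "flag_low": bool, "flag_high": bool}}``.
    """
    q_trajectory = np.atleast_2d(np.asarray(q_trajectory, dtype=float))
    names = list(model.muscles)
    lengths = np.stack([mtu_lengths(model, q, cache=cache) for q in q_trajectory])
    report = {}
    for j, name in enumerate(names):
        p = model.muscles[name].params
        lf = (lengths[:, j] - p.l_ts) / math.cos(p.pennation_rad)
        ratio = np.maximum(lf, 0.0) / p.l_opt
        rmin, rmax = float(ratio.min()), float(ratio.max())
        report[name] = {
            "min": rmin,
            "max": rmax,
            "flag_low": rmin < low,
            "flag_high": rmax > high,
        }
    return report


def tune_muscle_lengths(
    model: ShoulderModel,
    q_trajectory,
    low: float = 0.5,
    high: float = 1.5,
    increment: float = 0.02,
    max_iter: int = 100,
):
    """Iteratively retune flagged muscles: grow optimal fiber length by 2%
    and shorten tendon slack length by the same absolute amount, until each
    muscle operates inside ``[low, high]`` or its tendon slack reaches zero
    (then clamp and stop adjusting that muscle).

    Returns ``(tuned_model, change_log)`` where the log records every step.
    """
    import copy

    tuned = copy.deepcopy(model)
    log = []
    clamped: set[str] = set()
    for it in range(max_iter):
        report = check_fiber_operating_range(tuned, q_trajectory, low, high)
        flagged = [
            n for n, r in report.items()
            if (r["flag_low"] or r["flag_high"]) and n not in clamped
        ]
        if not flagged:
            remaining = [
                n for n, r in report.items() if r["flag_low"] or r["flag_high"]
            ]
            return tuned, log + (
                [{"iteration": it, "unresolved_clamped": remaining}]
                if remaining else []
            )
        for name in flagged:
            p = tuned.muscles[name].params
            delta = increment * p.l_opt
            new_lts = p.l_ts - delta
            if new_lts < 0.0:
                new_lts = 0.0
                clamped.add(name)
            log.append({
                "iteration": it,
                "muscle": name,
                "l_opt": p.l_opt * (1.0 + increment),
                "l_ts": new_lts,
                "clamped": name in clamped,
            })
            p.l_opt *= 1.0 + increment
            p.l_ts = new_lts
    report = check_fiber_operating_range(tuned, q_trajectory, low, high)
    still = [n for n, r in report.items() if r["flag_low"] or r["flag_high"]]
    if still:
        raise TuningError(
            f"fiber/tendon tuning did not converge in {max_iter} iterations"
            f" for: {', '.join(still)}"
        )
    return tuned, log
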