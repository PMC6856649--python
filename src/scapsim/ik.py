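"""Marker-based inverse kinematics and thorax-ellipsoid calibration.

Each frame solves the weighted least-squares problem

    min_q  sum_i w_i || m_i^exp - m_i^model(q) ||^2

with a trust-region reflective solver bounded by the coordinate ranges and
warm-started from the previous frame for temporal coherence.  Frames with
fewer than three visible markers are flagged and filled by interpolation.

The thorax-ellipsoid calibration reproduces the model-personalization step
of scaling: the ellipsoid tilt and radii of the scapulothoracic joint are
optimized (Nelder-Mead over an inner warm-started IK on subsampled
calibration frames) to minimize the total marker-tracking error.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from .io import MarkerTrajectories
from .kinematics import marker_positions
from .types import ShoulderModel

__all__ = ["IKResult", "solve_inverse_kinematics", "fit_thorax_ellipsoid"]


@dataclass
class IKResult:
    """Inverse-kinematics solution for one trial."""

    times: np.ndarray  # (N,)
    coord_names: list[str]
    q: np.ndarray  # (N, n)
    marker_rmse: np.ndarray  # (N,) per-frame RMSE over visible markers, m
    flagged: np.ndarray  # (N,) bool: < 3 visible markers (interpolated)
    info: dict = field(default_factory=dict)

    @property
    def rmse(self) -> float:
        """Trial RMSE (m) over all frames and visible markers."""
        return float(self.info["total_rmse"])


def _frame_solver(model, weights, names):
    sw = np.sqrt(np.asarray(weights, dtype=float))
    lb = np.array([c.range[0] for c in model.coordinates])
    ub = np.array([c.range[1] for c in model.coordinates])

    def solve(target, visible, q0):
        idx = np.nonzero(visible)[0]

        def residuals(q):
            _, pos = marker_positions(model, q, names=names)
            return ((pos[idx] - target[idx]) * sw[idx, None]).ravel()

        sol = least_squares(
            residuals, np.clip(q0, lb, ub), bounds=(lb, ub),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-10,
        )
        _, pos = marker_positions(model, sol.x, names=names)
        err = pos[idx] - target[idx]
        sq = np.sum(err**2, axis=1)
        return sol.x, sq

    return solve


def solve_inverse_kinematics(
    model: ShoulderModel,
    markers: MarkerTrajectories,
    weights: dict[str, float] | None = None,
) -> IKResult:
    """Solve IK for every frame of a marker trial.

    ``weights`` overrides the model marker weights by name.  Returns the
    coordinate trajectory, per-frame marker RMSE, and flags for frames with
    fewer than three visible markers (their coordinates are interpolated
    from neighboring solved frames).
    """
    names = [n for n in markers.names if n in model.markers]
    if len(names) < 3:
        raise ValueError("need at least three model markers present in the data")
    name_idx = [markers.names.index(n) for n in names]
    w = np.array([
        weights.get(n, model.markers[n].weight) if weights else
        model.markers[n].weight
        for n in names
    ])
    solve = _frame_solver(model, w, names)

    N = markers.times.size
    n = model.n_coords
    q_out = np.zeros((N, n))
    rmse = np.zeros(N)
    flagged = np.zeros(N, dtype=bool)
    sq_all = []
    q_prev = model.default_pose()
    for i in range(N):
        target = markers.positions[i, name_idx]
        visible = ~np.isnan(target).any(axis=1)
        if visible.sum() < 3:
            flagged[i] = True
            q_out[i] = q_prev
            rmse[i] = np.nan
            continue
        q_out[i], sq = solve(target, visible, q_prev)
        rmse[i] = float(np.sqrt(np.mean(sq)))
        sq_all.append(sq)
        q_prev = q_out[i]
    if flagged.any() and not flagged.all():
        good = np.nonzero(~flagged)[0]
        for j in range(n):
            q_out[flagged, j] = np.interp(
                markers.times[flagged], markers.times[good], q_out[good, j]
            )
    total = float(np.sqrt(np.mean(np.concatenate(sq_all)))) if sq_all else np.nan
    return IKResult(
        times=markers.times, coord_names=model.coordinate_names, q=q_out,
        marker_rmse=rmse, flagged=flagged,
        info={"total_rmse": total, "n_flagged": int(flagged.sum())},
    )


def fit_thorax_ellipsoid(
    model: ShoulderModel,
    markers: MarkerTrajectories,
    n_frames: int = 12,
    fit_tilt: bool = True,
    maxiter: int = 150,
):
    """Calibrate the scapulothoracic ellipsoid (tilt and radii) to a
    calibration trial by minimizing the total IK marker error.

    Returns ``(fitted_model, info)``; ``info['objective']`` holds the
    (before, after) summed weighted squared marker error on the subsampled
    frames.  The post-fit objective never exceeds the pre-fit one.
    """
    if len([n for n in markers.names if n in model.markers]) < 3:
        raise ValueError("degenerate marker set: need >= 3 model markers")
    sel = np.unique(
        np.linspace(0, markers.times.size - 1, n_frames).round().astype(int)
    )
    sub = MarkerTrajectories(
        times=markers.times[sel], names=markers.names,
        positions=markers.positions[sel], rate=markers.rate,
    )
    st0 = model.st_joint
    x0 = np.array([st0.tilt, *st0.radii]) if fit_tilt else np.array(st0.radii)

    def build(x):
        mdl = copy.deepcopy(model)
        if fit_tilt:
            mdl.st_joint.tilt = float(x[0])
            mdl.st_joint.radii = tuple(np.abs(x[1:4]))
        else:
            mdl.st_joint.radii = tuple(np.abs(x[:3]))
        return mdl

    def objective(x):
        mdl = build(x)
        res = solve_inverse_kinematics(mdl, sub)
        r = res.marker_rmse[~res.flagged]
        return float(np.sum(r**2))

    f0 = objective(x0)
    out = minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-12},
    )
    x_best, f_best = (out.x, out.fun) if out.fun <= f0 else (x0, f0)
    fitted = build(x_best)
    return fitted, {
        "objective": (f0, float(f_best)),
        "tilt": fitted.st_joint.tilt,
        "radii": fitted.st_joint.radii,
        "n_frames": int(sel.size),
    }
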