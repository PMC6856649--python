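"""Rigid-tendon Hill-type musculotendon mechanics and activation dynamics.

The tendon is treated as inextensible, so fiber kinematics follow directly
from the musculotendon (MTU) length: l_fiber = (l_mtu - l_ts)/cos(pennation)
with constant pennation.  Several bundles in the parameter table carry zero
or near-zero tendon slack length, which makes tendon compliance negligible
and the rigid-tendon construction appropriate.

Force generation is the classic product form

    F = [a f_L(l~) f_V(v~) + f_P(l~)] F_max cos(pennation)

with l~ = l_fiber / l_opt and v~ = v_fiber / (10 l_opt / s).  Curve shapes
(Gaussian active force-length, exponential passive engagement above optimal
length, Hill hyperbola with an eccentric plateau of 1.4) are held in
:class:`MuscleCurves` and are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import MuscleParameters

__all__ = [
    "MuscleCurves",
    "DEFAULT_CURVES",
    "fiber_kinematics",
    "tendon_force",
    "force_components",
    "activation_dynamics",
]


@dataclass(frozen=True)
class MuscleCurves:
    """Normalized Hill-model curve constants."""

    #: Gaussian width of the active force-length curve.
    fl_width: float = 0.45
    #: passive exponential shape factor and the fiber strain at which the
    #: passive force reaches F_max (compliant parallel-elastic element).
    passive_shape: float = 4.0
    passive_strain: float = 0.7
    #: curvature of the concentric (shortening) hyperbola.
    fv_curvature: float = 0.25
    #: eccentric force plateau (multiple of isometric).
    fv_ecc_plateau: float = 1.4
    #: maximum shortening velocity, optimal fiber lengths per second.
    v_max_factor: float = 10.0

    def active_fl(self, l_norm):
        return np.exp(-((np.asarray(l_norm) - 1.0) ** 2) / self.fl_width)

    def passive_fl(self, l_norm):
        l_norm = np.asarray(l_norm)
        k = self.passive_shape
        scale = math.exp(k * self.passive_strain) - 1.0
        return np.where(
            l_norm > 1.0, (np.exp(k * np.minimum(l_norm - 1.0, 1.0)) - 1.0) / scale, 0.0
        )

    def fv(self, v_norm):
        """Force-velocity multiplier; v_norm < 0 is shortening."""
        v = np.asarray(v_norm, dtype=float)
        g = self.fv_curvature
        conc = np.clip((1.0 + v) / (1.0 - v / g), 0.0, None)
        # eccentric branch, C1-matched to the concentric slope at v = 0
        slope0 = 1.0 + 1.0 / g
        plateau = self.fv_ecc_plateau
        k = slope0 / (plateau - 1.0)
        ecc = plateau - (plateau - 1.0) * np.exp(-k * np.maximum(v, 0.0))
        return np.where(v < 0.0, conc, ecc)


DEFAULT_CURVES = MuscleCurves()


def fiber_kinematics(params: MuscleParameters, l_mtu, v_mtu):
    """Rigid-tendon fiber length and velocity from MTU kinematics.

    Returns ``(l_fiber, v_fiber, slack)``; when the MTU is shorter than the
    tendon slack length the fiber is slack (zero length/velocity reported,
    slack flag set, force is zero).
    """
    l_mtu = np.asarray(l_mtu, dtype=float)
    v_mtu = np.asarray(v_mtu, dtype=float)
    cosp = math.cos(params.pennation_rad)
    slack = l_mtu <= params.l_ts
    l_fiber = np.where(slack, 0.0, (l_mtu - params.l_ts) / cosp)
    v_fiber = np.where(slack, 0.0, v_mtu / cosp)
    if l_fiber.ndim == 0:
        return float(l_fiber), float(v_fiber), bool(slack)
    return l_fiber, v_fiber, slack


def force_components(
    params: MuscleParameters, l_mtu, v_mtu, curves: MuscleCurves = DEFAULT_CURVES
):
    """Affine decomposition of tendon force in activation: F = a*Fa + Fp.

    ``Fa`` is the fully-activated active-force capacity at the current
    kinematics and ``Fp`` the passive contribution; both along the tendon.
    """
    l_fiber, v_fiber, slack = fiber_kinematics(params, l_mtu, v_mtu)
    cosp = math.cos(params.pennation_rad)
    l_norm = np.asarray(l_fiber) / params.l_opt
    v_norm = np.asarray(v_fiber) / (curves.v_max_factor * params.l_opt)
    fa = curves.active_fl(l_norm) * curves.fv(v_norm) * params.f_max * cosp
    fp = curves.passive_fl(l_norm) * params.f_max * cosp
    fa = np.where(slack, 0.0, fa)
    fp = np.where(slack, 0.0, fp)
    if np.ndim(fa) == 0:
        return float(fa), float(fp)
    return fa, fp


def tendon_force(
    params: MuscleParameters,
    l_mtu,
    v_mtu,
    a,
    curves: MuscleCurves = DEFAULT_CURVES,
):
    """Tendon (MTU) force, N; non-negative, zero when slack."""
    fa, fp = force_components(params, l_mtu, v_mtu, curves)
    f = np.clip(np.asarray(a) * fa + fp, 0.0, None)
    return float(f) if np.ndim(f) == 0 else f


def activation_dynamics(a, u, dt, tau_act: float = 0.010, tau_deact: float = 0.040):
    """First-order activation lag toward excitation ``u`` over one step.

    Uses the exact exponential update for piecewise-constant excitation:
    a(t+dt) = u + (a - u) exp(-dt/tau), tau = tau_act when u > a else
    tau_deact.  Output clamped to [0, 1].
    """
    a = np.asarray(a, dtype=float)
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    tau = np.where(u > a, tau_act, tau_deact)
    out = u + (a - u) * np.exp(-dt / tau)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
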