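"""Core domain types for the scapulothoracic shoulder model.

All quantities are SI internally (m, kg, s, N, J, rad); degrees appear only
at I/O boundaries.  The model is a kinematic tree of rigid bodies connected
by joints; the scapula rides on a thorax-fixed ellipsoid through a dedicated
four-coordinate joint (abduction, elevation, upward rotation, winging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MuscleParameters",
    "BodySegment",
    "Coordinate",
    "WrapSurface",
    "PathPoint",
    "MusclePath",
    "Marker",
    "ScapulothoracicJoint",
    "Muscle",
    "ShoulderModel",
    "ModelValidationError",
    "GRAVITY",
]

#: Default gravitational acceleration magnitude, m/s^2 (acts along -Y).
GRAVITY = 9.81


class ModelValidationError(ValueError):
    """Raised when a model component violates a structural invariant."""


@dataclass
class MuscleParameters:
    """Architecture of one musculotendon actuator.

    Parameters
    ----------
    name : str
        Actuator identifier, e.g. ``"Deltoideus.Middle"``.
    group : str
        Anatomical grouping label (e.g. ``"Scapula superior"``); empty for
        single-bundle muscles.
    f_max : float
        Maximum isometric force of the fibers, N.
    l_opt : float
        Optimal fiber length, m.
    l_ts : float
        Tendon slack length, m (zero is permitted: some serratus bundles
        are modeled with no in-series tendon).
    pennation : float
        Pennation angle at optimal fiber length, degrees.
    source_bundles : str
        Free-text provenance of the aggregated bundles.
    """

    name: str
    group: str = ""
    f_max: float = 0.0
    l_opt: float = 0.0
    l_ts: float = 0.0
    pennation: float = 0.0
    source_bundles: str = ""

    def validate(self) -> None:
        if not self.f_max > 0:
            raise ModelValidationError(
                f"muscle {self.name!r}: f_max must be > 0, got {self.f_max}"
            )
        if not self.l_opt > 0:
            raise ModelValidationError(
                f"muscle {self.name!r}: l_opt must be > 0, got {self.l_opt}"
            )
        if self.l_ts < 0:
            raise ModelValidationError(
                f"muscle {self.name!r}: l_ts must be >= 0, got {self.l_ts}"
            )
        if not 0 <= self.pennation < 90:
            raise ModelValidationError(
                f"muscle {self.name!r}: pennation must be in [0, 90) deg,"
                f" got {self.pennation}"
            )

    @property
    def pennation_rad(self) -> float:
        return math.radians(self.pennation)


@dataclass
class BodySegment:
    """A rigid body segment of the kinematic tree."""

    name: str
    mass: float = 0.0
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    parent_joint: str | None = None

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.inertia.shape == (3,):
            self.inertia = np.diag(self.inertia)
        self.com = np.asarray(self.com, dtype=float)

    def validate(self) -> None:
        if self.mass < 0:
            raise ModelValidationError(f"body {self.name!r}: mass must be >= 0")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ModelValidationError(f"body {self.name!r}: inertia not symmetric")
        if np.linalg.eigvalsh(self.inertia).min() < -1e-12:
            raise ModelValidationError(
                f"body {self.name!r}: inertia not positive-semidefinite"
            )


@dataclass
class Coordinate:
    """A generalized coordinate (angle in rad, or length in m)."""

    name: str
    value: float = 0.0
    range: tuple[float, float] = (-math.pi, math.pi)
    default: float = 0.0

    def validate(self) -> None:
        lo, hi = self.range
        if not lo <= self.default <= hi:
            raise ModelValidationError(
                f"coordinate {self.name!r}: default {self.default} outside"
                f" range [{lo}, {hi}]"
            )

    def clip(self, q: float) -> float:
        return min(max(q, self.range[0]), self.range[1])


@dataclass
class WrapSurface:
    """A smooth obstacle that a muscle path may route around.

    ``kind`` is one of ``"sphere"``, ``"cylinder"``, ``"ellipsoid"``.
    ``dimensions`` holds the radius (sphere), (radius, half_length)
    (cylinder, axis along local Z), or the three semi-axes (ellipsoid).
    ``rotation``/``translation`` place the surface frame in the parent body.
    """

    name: str
    kind: str
    body: str
    dimensions: tuple[float, ...] = ()
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)

    def validate(self) -> None:
        if self.kind not in ("sphere", "cylinder", "ellipsoid"):
            raise ModelValidationError(
                f"wrap {self.name!r}: unknown kind {self.kind!r}"
            )
        if any(d <= 0 for d in self.dimensions):
            raise ModelValidationError(f"wrap {self.name!r}: radii must be > 0")


@dataclass
class PathPoint:
    """One attachment point of a muscle path, fixed in a body frame."""

    body: str
    location: np.ndarray

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)


@dataclass
class MusclePath:
    """Ordered attachments (origin first, insertion last) with optional
    wrap-surface names assigned to the segment after each point."""

    points: list[PathPoint]
    #: wraps[i] routes the segment points[i] -> points[i+1]; None = straight.
    wraps: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.wraps:
            self.wraps = [None] * (len(self.points) - 1)

    def validate(self) -> None:
        if len(self.points) < 2:
            raise ModelValidationError("muscle path needs >= 2 attachment points")
        if len(self.wraps) != len(self.points) - 1:
            raise ModelValidationError("wraps list must have n_points - 1 entries")


@dataclass
class Muscle:
    """A musculotendon actuator: architecture plus geometric path."""

    params: MuscleParameters
    path: MusclePath

    @property
    def name(self) -> str:
        return self.params.name


@dataclass
class Marker:
    """A motion-capture marker fixed to a body (ISB landmark codes)."""

    name: str
    body: str
    location: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)

    def validate(self) -> None:
        if self.weight < 0:
            raise ModelValidationError(f"marker {self.name!r}: weight < 0")


@dataclass
class ScapulothoracicJoint:
    """Four-coordinate scapula-on-ellipsoid joint.

    The contact point is located on a thorax-fixed ellipsoid by two surface
    angles (abduction: longitude about the vertical axis measured from the
    posterior midline; elevation: latitude).  Upward rotation spins the
    scapula about the outward surface normal and winging lifts the medial
    border about the vertical surface tangent.  ``ref_abduction`` and
    ``ref_elevation`` place the zero pose posterolaterally on the thorax so
    that all four coordinates are zero in the reference configuration.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radii: tuple[float, float, float] = (0.09, 0.21, 0.145)
    tilt: float = 0.0  # rotation of ellipsoid frame about thorax Z, rad
    ref_abduction: float = 0.6
    ref_elevation: float = 0.35
    coordinate_names: tuple[str, str, str, str] = (
        "scap_abduction",
        "scap_elevation",
        "scap_upward_rot",
        "scap_winging",
    )

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    def validate(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ModelValidationError("scapulothoracic joint radii must be > 0")


@dataclass
class ShoulderModel:
    """The complete shoulder model.

    The kinematic tree is fixed: thorax (welded to ground) -> clavicle
    (welded) -> absent, thorax -> scapula (scapulothoracic joint) -> humerus
    (ball joint) -> forearm (welded, lumped forearm+hand).  Coordinates are
    the four scapulothoracic angles followed by three humeral angles.
    """

    name: str = "thoracoscapular_shoulder"
    bodies: dict[str, BodySegment] = field(default_factory=dict)
    joints: dict[str, dict] = field(default_factory=dict)
    coordinates: list[Coordinate] = field(default_factory=list)
    muscles: dict[str, Muscle] = field(default_factory=dict)
    wrap_surfaces: dict[str, WrapSurface] = field(default_factory=dict)
    markers: dict[str, Marker] = field(default_factory=dict)
    st_joint: ScapulothoracicJoint = field(default_factory=ScapulothoracicJoint)
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -GRAVITY, 0.0]))
    #: fixed transforms: body name -> (R, p) of the body frame in its parent.
    fixed_transforms: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    #: point mass held in the hand: (mass kg, location in forearm frame).
    hand_mass: float = 0.0
    hand_point: np.ndarray = field(default_factory=lambda: np.array([0.03, -0.23, 0.0]))

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float)
        self.hand_point = np.asarray(self.hand_point, dtype=float)

    # -- convenience -----------------------------------------------------
    @property
    def coordinate_names(self) -> list[str]:
        return [c.name for c in self.coordinates]

    @property
    def n_coords(self) -> int:
        return len(self.coordinates)

    def default_pose(self) -> np.ndarray:
        return np.array([c.default for c in self.coordinates])

    def coordinate(self, name: str) -> Coordinate:
        for c in self.coordinates:
            if c.name == name:
                return c
        raise KeyError(name)

    def coordinate_index(self, name: str) -> int:
        for i, c in enumerate(self.coordinates):
            if c.name == name:
                return i
        raise KeyError(name)

    def with_hand_mass(self, mass: float) -> "ShoulderModel":
        """Return a shallow copy carrying a hand-held point mass (kg)."""
        return replace(self, hand_mass=float(mass))

    def validate(self) -> None:
        for m in self.muscles.values():
            m.params.validate()
            m.path.validate()
            for pt in m.path.points:
                if pt.body not in self.bodies:
                    raise ModelValidationError(
                        f"muscle {m.name!r} references unknown body {pt.body!r}"
                    )
            for w in m.path.wraps:
                if w is not None and w not in self.wrap_surfaces:
                    raise ModelValidationError(
                        f"muscle {m.name!r} references unknown wrap {w!r}"
                    )
        for b in self.bodies.values():
            b.validate()
        for c in self.coordinates:
            c.validate()
        for w in self.wrap_surfaces.values():
            w.validate()
        for mk in self.markers.values():
            mk.validate()
            if mk.body not in self.bodies:
                raise ModelValidationError(
                    f"marker {mk.name!r} references unknown body {mk.body!r}"
                )
        self.st_joint.validate()
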