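"""Built-in thoracoscapular shoulder model fixture.

The 33 musculotendon actuators carry the published architecture parameters
(maximum isometric force, optimal fiber length, tendon slack length,
pennation).  Attachment coordinates and wrap geometry are NOT published;
the geometry here is authored to be qualitatively correct (each muscle's
line of action produces the anatomically expected moment signs at the
reference pose, e.g. superior trapezius elevates and upward-rotates the
scapula) and is a documented fixture, not anatomical ground truth.  Users
needing anatomical fidelity should import the deposited model file.

Segment masses default to standard anthropometric fractions of the 52 kg,
1.62 m reference subject.  After authoring, each muscle's origin is slid
along its default-pose line of action so the default MTU length equals
l_ts + l_opt*cos(pennation): normalized fiber length is 1.0 at the
reference pose, which keeps the published architecture usable with the
approximate geometry while preserving default-pose moment arms.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import solve_path
from .kinematics import rot_z
from .types import (
    BodySegment,
    Coordinate,
    Marker,
    Muscle,
    MuscleParameters,
    MusclePath,
    PathPoint,
    ScapulothoracicJoint,
    ShoulderModel,
    WrapSurface,
)

__all__ = ["TABLE1_PARAMETERS", "builtin_thoracoscapular_model"]

#: (name, group, f_max N, l_opt m, l_ts m, pennation deg, source bundles)
TABLE1_PARAMETERS = [
    ("Trapezius.ScapulaSuperior", "Scapula superior", 1043.0, 0.1127, 0.027, 0, "1-6"),
    ("Trapezius.ScapulaMiddle", "Scapula middle", 470.4, 0.0832, 0.032, 0, "7-9"),
    ("Trapezius.ScapulaInferior", "Scapula inferior", 414.4, 0.1264, 0.035, 0, "10-12"),
    ("Trapezius.Clavicle", "Clavicle", 201.6, 0.1116, 0.027, 0, "C1-C2"),
    ("SerratusAnterior.Superior", "Superior", 387.8, 0.0945, 0.000, 0, "9-12"),
    ("SerratusAnterior.Middle", "Middle", 508.0, 0.1538, 0.012, 0, "5-8"),
    ("SerratusAnterior.Inferior", "Inferior", 430.0, 0.1587, 0.000, 0, "1-4"),
    ("Rhomboideus.Superior", "Superior", 200.2, 0.0986, 0.015, 0, "1-2"),
    ("Rhomboideus.Inferior", "Inferior", 407.4, 0.1152, 0.028, 0, "3-4"),
    ("LevatorScapulae", "", 280.0, 0.1578, 0.019, 0, "All"),
    ("Coracobrachialis", "", 648.2, 0.0683, 0.104, 0, "All"),
    ("Deltoideus.Anterior", "Anterior", 707.7, 0.0940, 0.088, 5, "C1-C4"),
    ("Deltoideus.Middle", "Middle", 2597.8, 0.0748, 0.064, 5, "4-11"),
    ("Deltoideus.Posterior", "Posterior", 1324.4, 0.0949, 0.076, 5, "1-3"),
    ("LatissimusDorsi.Superior", "Superior", 201.6, 0.2109, 0.081, 0, "1-2"),
    ("LatissimusDorsi.Middle", "Middle", 315.0, 0.2656, 0.095, 0, "3-4"),
    ("LatissimusDorsi.Inferior", "Inferior", 270.2, 0.3062, 0.062, 0, "5-6"),
    ("PectoralisMajor.Clavicle", "Clavicle", 408.8, 0.1087, 0.014, 0, "C1-C2"),
    ("PectoralisMajor.ThoraxMiddle", "Thorax middle", 683.2, 0.1500, 0.026, 0, "4-6"),
    ("PectoralisMajor.ThoraxInferior", "Thorax inferior", 571.2, 0.1830, 0.043, 0, "1-3"),
    ("TeresMajor", "", 851.2, 0.1410, 0.006, 0, "All"),
    ("Infraspinatus.Superior", "Superior", 967.4, 0.0698, 0.050, 0, "4-6"),
    ("Infraspinatus.Inferior", "Inferior", 1037.4, 0.0677, 0.084, 0, "1-3"),
    ("PectoralisMinor", "", 429.8, 0.1183, 0.032, 0, "All"),
    ("TeresMinor", "", 695.8, 0.0550, 0.051, 0, "All"),
    ("Subscapularis.Superior", "Superior", 540.4, 0.0676, 0.059, 5, "1-3"),
    ("Subscapularis.Middle", "Middle", 609.0, 0.0744, 0.055, 5, "4-5,10"),
    ("Subscapularis.Inferior", "Inferior", 854.0, 0.0721, 0.059, 0, "6-9, 11"),
    ("Supraspinatus.Anterior", "Anterior", 543.2, 0.0554, 0.031, 0, "3-4"),
    ("Supraspinatus.Posterior", "Posterior", 326.2, 0.0591, 0.025, 0, "1-2"),
    ("TricepsLong", "", 1580.6, 0.0969, 0.241, 10, "All"),
    ("Biceps.Long", "Long", 485.8, 0.1412, 0.257, 0, "All"),
    ("Biceps.Brevis", "Brevis", 693.0, 0.1264, 0.212, 0, "All"),
]

# authored attachment geometry: muscle -> list of (body, xyz), wrap names
# (None = straight segment).  Thorax frame: X anterior, Y up, Z right;
# origin at the thorax-ellipsoid center.
_PATHS = {
    "Trapezius.ScapulaSuperior": ([("thorax", (-0.060, 0.240, 0.000)),
                                   ("scapula", (0.070, 0.045, 0.045))], [None]),
    "Trapezius.ScapulaMiddle": ([("thorax", (-0.090, 0.100, 0.000)),
                                 ("scapula", (0.030, 0.025, 0.015))], [None]),
    "Trapezius.ScapulaInferior": ([("thorax", (-0.095, -0.020, 0.000)),
                                   ("scapula", (0.000, 0.020, 0.012))], [None]),
    "Trapezius.Clavicle": ([("thorax", (-0.060, 0.230, 0.010)),
                            ("clavicle", (-0.005, 0.005, 0.100))], [None]),
    "SerratusAnterior.Superior": ([("thorax", (0.040, 0.100, 0.115)),
                                   ("scapula", (-0.030, 0.020, 0.008))],
                                  ["thorax_wrap"]),
    "SerratusAnterior.Middle": ([("thorax", (0.055, 0.000, 0.125)),
                                 ("scapula", (-0.032, -0.040, 0.008))],
                                ["thorax_wrap"]),
    "SerratusAnterior.Inferior": ([("thorax", (0.050, -0.100, 0.120)),
                                   ("scapula", (-0.020, -0.110, 0.008))],
                                  ["thorax_wrap"]),
    "Rhomboideus.Superior": ([("thorax", (-0.090, 0.130, 0.000)),
                              ("scapula", (-0.012, 0.000, 0.006))], [None]),
    "Rhomboideus.Inferior": ([("thorax", (-0.095, 0.040, 0.000)),
                              ("scapula", (-0.008, -0.080, 0.006))], [None]),
    "LevatorScapulae": ([("thorax", (-0.050, 0.260, 0.030)),
                         ("scapula", (-0.012, 0.035, 0.006))], [None]),
    "Coracobrachialis": ([("scapula", (0.085, 0.015, 0.050)),
                          ("humerus", (0.005, -0.150, -0.005))], [None]),
    "Deltoideus.Anterior": ([("clavicle", (0.000, 0.005, 0.145)),
                             ("humerus", (0.012, -0.130, 0.005))],
                            ["humeral_head"]),
    "Deltoideus.Middle": ([("scapula", (0.105, 0.050, 0.075)),
                           ("humerus", (0.005, -0.100, 0.020))],
                          ["humeral_head"]),
    "Deltoideus.Posterior": ([("scapula", (0.050, 0.040, 0.045)),
                              ("humerus", (-0.008, -0.120, 0.010))],
                             ["humeral_head"]),
    "LatissimusDorsi.Superior": ([("thorax", (-0.090, -0.040, 0.000)),
                                  ("humerus", (0.006, -0.040, -0.008))], [None]),
    "LatissimusDorsi.Middle": ([("thorax", (-0.090, -0.100, 0.000)),
                                ("humerus", (0.007, -0.045, -0.008))], [None]),
    "LatissimusDorsi.Inferior": ([("thorax", (-0.085, -0.160, 0.000)),
                                  ("humerus", (0.008, -0.050, -0.008))], [None]),
    "PectoralisMajor.Clavicle": ([("clavicle", (0.005, 0.000, 0.030)),
                                  ("humerus", (0.008, -0.050, 0.002))], [None]),
    "PectoralisMajor.ThoraxMiddle": ([("thorax", (0.088, 0.040, 0.010)),
                                      ("humerus", (0.008, -0.055, 0.000))], [None]),
    "PectoralisMajor.ThoraxInferior": ([("thorax", (0.085, -0.050, 0.010)),
                                        ("humerus", (0.008, -0.060, -0.002))], [None]),
    "TeresMajor": ([("scapula", (0.010, -0.105, 0.010)),
                    ("humerus", (0.004, -0.050, -0.010))], [None]),
    "Infraspinatus.Superior": ([("scapula", (0.020, -0.020, 0.006)),
                                ("humerus", (-0.005, -0.015, 0.022))],
                               ["humeral_head"]),
    "Infraspinatus.Inferior": ([("scapula", (0.015, -0.060, 0.006)),
                                ("humerus", (-0.008, -0.020, 0.020))],
                               ["humeral_head"]),
    "PectoralisMinor": ([("thorax", (0.075, -0.010, 0.075)),
                         ("scapula", (0.080, 0.010, 0.050))], [None]),
    "TeresMinor": ([("scapula", (0.040, -0.070, 0.010)),
                    ("humerus", (-0.006, -0.025, 0.018))], ["humeral_head"]),
    "Subscapularis.Superior": ([("scapula", (0.020, 0.000, -0.010)),
                                ("humerus", (0.022, -0.014, 0.004))],
                               ["humeral_head"]),
    "Subscapularis.Middle": ([("scapula", (0.020, -0.030, -0.008)),
                              ("humerus", (0.018, -0.018, 0.000))],
                             ["humeral_head"]),
    "Subscapularis.Inferior": ([("scapula", (0.015, -0.055, -0.008)),
                                ("humerus", (0.018, -0.022, -0.002))],
                               ["humeral_head"]),
    "Supraspinatus.Anterior": ([("scapula", (0.010, 0.030, 0.000)),
                                ("humerus", (0.004, 0.020, 0.020))],
                               ["humeral_head"]),
    "Supraspinatus.Posterior": ([("scapula", (-0.005, 0.030, 0.000)),
                                 ("humerus", (-0.002, 0.020, 0.020))],
                                ["humeral_head"]),
    "TricepsLong": ([("scapula", (0.095, -0.015, 0.040)),
                     ("forearm", (-0.025, 0.005, 0.000))], [None]),
    "Biceps.Long": ([("scapula", (0.100, 0.010, 0.040)),
                     ("forearm", (0.020, -0.040, 0.000))], [None]),
    "Biceps.Brevis": ([("scapula", (0.085, 0.015, 0.050)),
                       ("forearm", (0.020, -0.042, 0.002))], [None]),
}

_MARKERS = [
    # ISB landmark codes
    ("C7", "thorax", (-0.085, 0.170, 0.000)),
    ("T8", "thorax", (-0.095, -0.050, 0.000)),
    ("IJ", "thorax", (0.088, 0.130, 0.010)),
    ("PX", "thorax", (0.095, -0.040, 0.010)),
    ("AC", "clavicle", (-0.005, 0.012, 0.140)),
    ("TS", "scapula", (-0.015, 0.020, 0.012)),
    ("AI", "scapula", (0.005, -0.115, 0.012)),
    ("AA", "scapula", (0.095, 0.035, 0.065)),
    ("EL", "humerus", (0.000, -0.280, 0.030)),
    ("EM", "humerus", (0.000, -0.280, -0.030)),
    ("RS", "forearm", (0.020, -0.240, 0.020)),
    ("US", "forearm", (0.020, -0.240, -0.020)),
]

#: reference subject used for default anthropometry.
SUBJECT_MASS_KG = 52.0
SUBJECT_HEIGHT_M = 1.62


def _bodies() -> dict[str, BodySegment]:
    return {
        "thorax": BodySegment("thorax", mass=0.0, parent_joint="ground_weld"),
        "clavicle": BodySegment(
            "clavicle", mass=0.2, inertia=np.diag([1e-4, 1e-4, 1e-4]),
            com=np.array([0.0, 0.0, 0.06]), parent_joint="sternoclavicular_weld",
        ),
        "scapula": BodySegment(
            "scapula", mass=0.70, inertia=np.diag([0.003, 0.003, 0.003]),
            com=np.array([0.05, -0.03, 0.02]), parent_joint="scapulothoracic",
        ),
        "humerus": BodySegment(
            # 2.8% body mass (upper arm), slender-rod inertia about the COM
            "humerus", mass=0.028 * SUBJECT_MASS_KG,
            inertia=np.diag([0.0102, 0.0013, 0.0102]),
            com=np.array([0.0, -0.13, 0.0]), parent_joint="glenohumeral",
        ),
        "forearm": BodySegment(
            # forearm + hand lumped, 2.2% body mass
            "forearm", mass=0.022 * SUBJECT_MASS_KG,
            inertia=np.diag([0.006, 0.0008, 0.006]),
            com=np.array([0.015, -0.11, 0.0]), parent_joint="elbow_weld",
        ),
    }


def _coordinates() -> list[Coordinate]:
    r = [
        ("scap_abduction", (-0.6, 0.9)),
        ("scap_elevation", (-0.5, 0.7)),
        ("scap_upward_rot", (-0.5, 1.3)),
        ("scap_winging", (-0.4, 0.6)),
        ("shoulder_flexion", (-1.0, 2.2)),
        ("shoulder_abduction", (-0.6, 2.2)),
        ("shoulder_rotation", (-1.6, 1.6)),
    ]
    return [Coordinate(name=n, range=rng, default=0.0, value=0.0) for n, rng in r]


def builtin_thoracoscapular_model(
    hand_mass: float = 0.0,
    wrap_tilt: float = -0.08,
    calibrate_lengths: bool = True,
) -> ShoulderModel:
    """Construct the built-in shoulder model fixture.

    Parameters
    ----------
    hand_mass : float
        Hand-held point mass, kg (0 or 2 in the study tasks), welded to the
        distal forearm.
    wrap_tilt : float
        Sagittal tilt (rad, about the thorax Z axis) of the thoracic muscle
        wrapping ellipsoid; negative tips its top toward the sternum, which
        keeps the serratus anterior path well-defined across the scapular
        range of motion.
    calibrate_lengths : bool
        Slide each muscle origin along its default-pose line of action so
        the default MTU length matches l_ts + l_opt*cos(pennation).
    """
    model = ShoulderModel()
    model.bodies = _bodies()
    model.coordinates = _coordinates()
    model.st_joint = ScapulothoracicJoint()
    from .kinematics import scapula_transform

    R_scap0, _ = scapula_transform(model.st_joint, np.zeros(4))
    model.fixed_transforms = {
        "clavicle": (np.eye(3), np.array([0.025, 0.155, 0.010])),
        # rotation part: factor out the default scapula orientation so the
        # humeral Euler angles are about thorax-aligned axes at reference
        "humerus_offset": (R_scap0.T, np.array([0.105, 0.000, 0.050])),
        "forearm": (rot_z(0.35), np.array([0.0, -0.29, 0.0])),
    }
    model.joints = {
        "sternoclavicular_weld": {"parent": "thorax", "child": "clavicle"},
        "scapulothoracic": {"parent": "thorax", "child": "scapula"},
        "glenohumeral": {"parent": "scapula", "child": "humerus"},
        "elbow_weld": {"parent": "humerus", "child": "forearm"},
    }
    model.wrap_surfaces = {
        "thorax_wrap": WrapSurface(
            name="thorax_wrap", kind="ellipsoid", body="thorax",
            dimensions=(0.088, 0.205, 0.138),
            translation=np.zeros(3), rotation=rot_z(wrap_tilt),
        ),
        "humeral_head": WrapSurface(
            name="humeral_head", kind="sphere", body="humerus",
            dimensions=(0.024,), translation=np.zeros(3), rotation=np.eye(3),
        ),
    }
    model.markers = {
        name: Marker(name=name, body=body, location=np.array(loc), weight=1.0)
        for name, body, loc in _MARKERS
    }
    for name, group, f_max, l_opt, l_ts, penn, bundles in TABLE1_PARAMETERS:
        pts, wraps = _PATHS[name]
        model.muscles[name] = Muscle(
            params=MuscleParameters(
                name=name, group=group, f_max=f_max, l_opt=l_opt,
                l_ts=l_ts, pennation=penn, source_bundles=bundles,
            ),
            path=MusclePath(
                points=[PathPoint(body=b, location=np.array(loc)) for b, loc in pts],
                wraps=list(wraps),
            ),
        )
    model.hand_mass = float(hand_mass)
    if calibrate_lengths:
        _calibrate_default_lengths(model)
    model.validate()
    return model


def _calibrate_default_lengths(model: ShoulderModel, n_iter: int = 4) -> None:
    """Slide each origin along the first path segment so the default-pose
    MTU length equals l_ts + l_opt*cos(pennation).

    Sliding along the (possibly tangent) line of action preserves the line
    of force at the reference pose, hence default-pose moment arms.  The
    slide is limited so the origin keeps 5 mm clearance from the next path
    vertex.
    """
    from .kinematics import forward_kinematics

    q0 = model.default_pose()
    frames = forward_kinematics(model, q0)
    for name, mus in model.muscles.items():
        p = mus.params
        target = p.l_ts + p.l_opt * math.cos(p.pennation_rad)
        for _ in range(n_iter):
            sol = solve_path(model, q0, name, frames=frames)
            delta = target - sol.length
            if abs(delta) < 1e-9:
                break
            p0, p1 = sol.points[0], sol.points[1]
            seg = p0 - p1
            seg_len = np.linalg.norm(seg)
            u = seg / seg_len
            # keep the origin clear of the next vertex
            slide = max(delta, -(seg_len - 0.005))
            new_world = p0 + slide * u
            # and clear of any wrap surface on the muscle's path
            for wname in mus.path.wraps:
                if wname is None:
                    continue
                surf = model.wrap_surfaces[wname]
                Rw, pw = frames[surf.body]
                cs = pw + Rw @ surf.translation
                Rs = Rw @ surf.rotation
                local = Rs.T @ (new_world - cs)
                if surf.kind == "sphere":
                    margin = surf.dimensions[0] + 0.004
                    d = np.linalg.norm(local)
                    if d < margin:
                        local *= margin / d
                        new_world = Rs @ local + cs
                elif surf.kind == "ellipsoid":
                    axes = np.asarray(surf.dimensions)
                    s = np.linalg.norm(local / axes)
                    if s < 1.03:
                        local *= 1.03 / s
                        new_world = Rs @ local + cs
            origin = mus.path.points[0]
            Rb, pb = frames[origin.body]
            origin.location = Rb.T @ (new_world - pb)
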