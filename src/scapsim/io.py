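"""Readers and writers for the motion-capture and model file formats.

Supports the tab-delimited TRC marker format (millimeters converted to
meters on read when the header declares mm), the MOT/STO coordinate and
results format (``inDegrees=yes`` columns converted to radians on read),
and a documented XML subset of the .osim 4.0 model format.  Unknown XML
elements are reported with a warning and skipped, so files carrying extra
elements still load.
"""

from __future__ import annotations

import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

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

__all__ = [
    "FileFormatError",
    "MarkerTrajectories",
    "Motion",
    "read_trc",
    "write_trc",
    "read_mot",
    "read_sto",
    "write_sto",
    "write_mot",
    "read_model",
    "write_model",
]


class FileFormatError(ValueError):
    """A motion/marker/model file violates its format contract."""


@dataclass
class MarkerTrajectories:
    """Time-stamped marker positions in meters (NaN = missing sample)."""

    times: np.ndarray  # (n,)
    names: list[str]
    positions: np.ndarray  # (n, m, 3), meters
    rate: float = 120.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise FileFormatError("marker time stamps must be strictly increasing")
        if self.positions.shape[:2] != (self.times.size, len(self.names)):
            raise FileFormatError("marker array shape does not match names/times")


@dataclass
class Motion:
    """A time series of named columns (coordinates, forces, activations).

    Angles are radians internally; degree conversion happens only when a
    file declares ``inDegrees=yes``.
    """

    times: np.ndarray
    names: list[str]
    values: np.ndarray  # (n, k)
    name: str = "motion"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise FileFormatError("time column must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def read_trc(path) -> MarkerTrajectories:
    """Read a TRC marker file; positions are returned in meters."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 6:
        raise FileFormatError(f"{path}: truncated TRC header")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header.get("Units", "mm").strip()
    except (KeyError, ValueError) as err:
        raise FileFormatError(f"{path}: bad TRC header ({err})") from None
    name_row = lines[3].split("\t")
    names = [n for n in name_row[2:] if n.strip()]
    if len(names) != n_markers:
        raise FileFormatError(
            f"{path}: header declares {n_markers} markers, found {len(names)}"
        )
    scale = 1e-3 if units.lower() == "mm" else 1.0
    times, rows = [], []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2 + 3 * n_markers:
            raise FileFormatError(
                f"{path}: row has {len(parts)} columns, expected {2 + 3 * n_markers}"
            )
        times.append(float(parts[1]))
        rows.append(
            [float(p) * scale if p.strip() else np.nan for p in parts[2:]]
        )
    if not rows:
        raise FileFormatError(f"{path}: TRC file contains no data rows")
    pos = np.asarray(rows).reshape(len(rows), n_markers, 3)
    return MarkerTrajectories(
        times=np.asarray(times), names=names, positions=pos, rate=rate
    )


def write_trc(markers: MarkerTrajectories, path, units: str = "mm") -> None:
    scale = 1e3 if units == "mm" else 1.0
    n, m = markers.times.size, len(markers.names)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{pathlib.Path(path).name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{markers.rate:.2f}\t{markers.rate:.2f}\t{n}\t{m}\t{units}\t"
            f"{markers.rate:.2f}\t1\t{n}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(markers.names) + "\t\t\n")
        fh.write(
            "\t\t"
            + "\t".join(
                f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(m)
            )
            + "\n"
        )
        for i in range(n):
            row = [str(i + 1), repr(float(markers.times[i]))]
            for j in range(m):
                for c in range(3):
                    v = markers.positions[i, j, c]
                    row.append("" if np.isnan(v) else repr(float(v * scale)))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# MOT / STO
# ---------------------------------------------------------------------------

def read_sto(path) -> Motion:
    """Read a tab-delimited MOT/STO file (nRows/nColumns header)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = {}
    name = "motion"
    i = 0
    for i, ln in enumerate(lines):
        if ln.strip() == "endheader":
            break
        if "=" in ln:
            k, v = ln.split("=", 1)
            meta[k.strip()] = v.strip()
        elif ln.strip() and i == 0:
            name = ln.strip()
    else:
        raise FileFormatError(f"{path}: missing endheader")
    cols = lines[i + 1].split("\t")
    if cols[0].strip().lower() != "time":
        raise FileFormatError(f"{path}: first column must be time")
    names = [c.strip() for c in cols[1:] if c.strip()]
    data = []
    for ln in lines[i + 2:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != len(names) + 1:
            raise FileFormatError(
                f"{path}: row has {len(parts)} columns, expected {len(names) + 1}"
            )
        data.append([float(p) for p in parts])
    if not data:
        raise FileFormatError(f"{path}: no data rows")
    arr = np.asarray(data)
    values = arr[:, 1:]
    if meta.get("inDegrees", "no").lower() == "yes":
        values = np.deg2rad(values)
    return Motion(times=arr[:, 0], names=names, values=values, name=name)


read_mot = read_sto


def write_sto(motion: Motion, path, in_degrees: bool = False) -> None:
    values = np.rad2deg(motion.values) if in_degrees else motion.values
    n, k = values.shape
    with open(path, "w") as fh:
        fh.write(f"{motion.name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={n}\n")
        fh.write(f"nColumns={k + 1}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(motion.names) + "\n")
        for i in range(n):
            fh.write(
                repr(float(motion.times[i]))
                + "\t"
                + "\t".join(repr(float(v)) for v in values[i])
                + "\n"
            )


def write_mot(motion: Motion, path) -> None:
    """Write a coordinate motion file with angles in degrees."""
    write_sto(motion, path, in_degrees=True)


# ---------------------------------------------------------------------------
# model XML (documented .osim 4.0 subset)
# ---------------------------------------------------------------------------

_KNOWN = {
    "OpenSimDocument", "Model", "gravity", "hand_mass", "hand_point",
    "BodySet", "JointSet", "ForceSet", "MarkerSet", "objects",
    "Body", "mass", "mass_center", "inertia", "WrapObjectSet",
    "WrapSphere", "WrapCylinder", "WrapEllipsoid", "radius", "length",
    "dimensions", "translation", "xyz_body_rotation",
    "WeldJoint", "BallJoint", "ScapulothoracicJoint",
    "parent_body", "child_body", "orientation",
    "thoracic_ellipsoid_radii_x_y_z", "ellipsoid_tilt",
    "reference_abduction", "reference_elevation",
    "CoordinateSet", "Coordinate", "default_value", "range",
    "Thelen2003Muscle", "max_isometric_force", "optimal_fiber_length",
    "tendon_slack_length", "pennation_angle_at_optimal", "group",
    "source_bundles", "GeometryPath", "PathPointSet", "PathPoint",
    "body", "location", "PathWrapSet", "PathWrap", "wrap_object",
    "segment_index", "Marker", "weight",
}


def _vec(text) -> np.ndarray:
    return np.array([float(x) for x in text.split()])


def _fmt(arr) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr).ravel())


def write_model(model: ShoulderModel, path) -> None:
    """Serialize a model to the documented XML subset (.osim element names)."""
    root = etree.Element("OpenSimDocument", Version="40000")
    mdl = etree.SubElement(root, "Model", name=model.name)
    etree.SubElement(mdl, "gravity").text = _fmt(model.gravity)
    etree.SubElement(mdl, "hand_mass").text = repr(float(model.hand_mass))
    etree.SubElement(mdl, "hand_point").text = _fmt(model.hand_point)

    bodyset = etree.SubElement(etree.SubElement(mdl, "BodySet"), "objects")
    for b in model.bodies.values():
        eb = etree.SubElement(bodyset, "Body", name=b.name)
        etree.SubElement(eb, "mass").text = repr(float(b.mass))
        etree.SubElement(eb, "mass_center").text = _fmt(b.com)
        ine = b.inertia
        etree.SubElement(eb, "inertia").text = _fmt(
            [ine[0, 0], ine[1, 1], ine[2, 2], ine[0, 1], ine[0, 2], ine[1, 2]]
        )
        wraps = [w for w in model.wrap_surfaces.values() if w.body == b.name]
        if wraps:
            ws = etree.SubElement(etree.SubElement(eb, "WrapObjectSet"), "objects")
            for w in wraps:
                tag = {"sphere": "WrapSphere", "cylinder": "WrapCylinder",
                       "ellipsoid": "WrapEllipsoid"}[w.kind]
                ew = etree.SubElement(ws, tag, name=w.name)
                if w.kind == "sphere":
                    etree.SubElement(ew, "radius").text = repr(float(w.dimensions[0]))
                elif w.kind == "cylinder":
                    etree.SubElement(ew, "radius").text = repr(float(w.dimensions[0]))
                    etree.SubElement(ew, "length").text = repr(float(w.dimensions[1]))
                else:
                    etree.SubElement(ew, "dimensions").text = _fmt(w.dimensions)
                etree.SubElement(ew, "translation").text = _fmt(w.translation)
                etree.SubElement(ew, "xyz_body_rotation").text = _fmt(
                    _rotation_to_xyz(w.rotation)
                )

    jointset = etree.SubElement(etree.SubElement(mdl, "JointSet"), "objects")
    for jname, j in model.joints.items():
        if jname == "scapulothoracic":
            ej = etree.SubElement(jointset, "ScapulothoracicJoint", name=jname)
            etree.SubElement(ej, "parent_body").text = j["parent"]
            etree.SubElement(ej, "child_body").text = j["child"]
            st = model.st_joint
            etree.SubElement(ej, "thoracic_ellipsoid_radii_x_y_z").text = _fmt(st.radii)
            etree.SubElement(ej, "translation").text = _fmt(st.center)
            etree.SubElement(ej, "ellipsoid_tilt").text = repr(float(st.tilt))
            etree.SubElement(ej, "reference_abduction").text = repr(
                float(st.ref_abduction))
            etree.SubElement(ej, "reference_elevation").text = repr(
                float(st.ref_elevation))
            _write_coords(ej, model, st.coordinate_names)
        elif jname == "glenohumeral":
            ej = etree.SubElement(jointset, "BallJoint", name=jname)
            etree.SubElement(ej, "parent_body").text = j["parent"]
            etree.SubElement(ej, "child_body").text = j["child"]
            C, t = model.fixed_transforms["humerus_offset"]
            etree.SubElement(ej, "translation").text = _fmt(t)
            etree.SubElement(ej, "orientation").text = _fmt(_rotation_to_xyz(C))
            hum_coords = [c.name for c in model.coordinates[4:7]]
            _write_coords(ej, model, hum_coords)
        else:
            ej = etree.SubElement(jointset, "WeldJoint", name=jname)
            etree.SubElement(ej, "parent_body").text = j["parent"]
            etree.SubElement(ej, "child_body").text = j["child"]
            key = j["child"] if j["child"] in model.fixed_transforms else None
            if key:
                R, t = model.fixed_transforms[key]
                etree.SubElement(ej, "translation").text = _fmt(t)
                etree.SubElement(ej, "orientation").text = _fmt(_rotation_to_xyz(R))

    forceset = etree.SubElement(etree.SubElement(mdl, "ForceSet"), "objects")
    for mus in model.muscles.values():
        em = etree.SubElement(forceset, "Thelen2003Muscle", name=mus.name)
        p = mus.params
        etree.SubElement(em, "group").text = p.group
        etree.SubElement(em, "source_bundles").text = p.source_bundles
        etree.SubElement(em, "max_isometric_force").text = repr(float(p.f_max))
        etree.SubElement(em, "optimal_fiber_length").text = repr(float(p.l_opt))
        etree.SubElement(em, "tendon_slack_length").text = repr(float(p.l_ts))
        etree.SubElement(em, "pennation_angle_at_optimal").text = repr(
            float(p.pennation))
        gp = etree.SubElement(em, "GeometryPath")
        pps = etree.SubElement(etree.SubElement(gp, "PathPointSet"), "objects")
        for i, pt in enumerate(mus.path.points):
            ep = etree.SubElement(pps, "PathPoint", name=f"{mus.name}_P{i + 1}")
            etree.SubElement(ep, "body").text = pt.body
            etree.SubElement(ep, "location").text = _fmt(pt.location)
        if any(w is not None for w in mus.path.wraps):
            pws = etree.SubElement(etree.SubElement(gp, "PathWrapSet"), "objects")
            for i, w in enumerate(mus.path.wraps):
                if w is None:
                    continue
                ew = etree.SubElement(pws, "PathWrap", name=f"{mus.name}_W{i}")
                etree.SubElement(ew, "wrap_object").text = w
                etree.SubElement(ew, "segment_index").text = str(i)

    markerset = etree.SubElement(etree.SubElement(mdl, "MarkerSet"), "objects")
    for mk in model.markers.values():
        emk = etree.SubElement(markerset, "Marker", name=mk.name)
        etree.SubElement(emk, "body").text = mk.body
        etree.SubElement(emk, "location").text = _fmt(mk.location)
        etree.SubElement(emk, "weight").text = repr(float(mk.weight))

    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _write_coords(parent, model: ShoulderModel, names) -> None:
    cs = etree.SubElement(etree.SubElement(parent, "CoordinateSet"), "objects")
    for cname in names:
        c = model.coordinate(cname)
        ec = etree.SubElement(cs, "Coordinate", name=c.name)
        etree.SubElement(ec, "default_value").text = repr(float(c.default))
        etree.SubElement(ec, "range").text = _fmt(c.range)


def _rotation_to_xyz(R) -> np.ndarray:
    """Body-fixed X-Y-Z Euler angles of a rotation matrix."""
    R = np.asarray(R)
    sy = -R[2, 0]
    sy = min(max(sy, -1.0), 1.0)
    y = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-12:
        x = np.arctan2(R[2, 1], R[2, 2])
        z = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal: fold into x
        x = np.arctan2(-R[1, 2], R[1, 1])
        z = 0.0
    return np.array([x, y, z])


def _xyz_to_rotation(angles) -> np.ndarray:
    from .kinematics import rot_x, rot_y, rot_z

    x, y, z = angles
    return rot_z(z) @ rot_y(y) @ rot_x(x)


def read_model(path) -> ShoulderModel:
    """Load a model from the documented XML subset.

    Unknown elements are reported (``UserWarning``) and skipped; structural
    problems (negative forces, missing bodies) raise a validation error
    naming the offending component.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as err:
        raise FileFormatError(
            f"{path}: malformed XML at line {err.lineno}: {err.msg}"
        ) from None
    root = tree.getroot()
    unknown = sorted(
        {el.tag for el in root.iter() if isinstance(el.tag, str)} - _KNOWN
    )
    if unknown:
        warnings.warn(
            f"{path}: skipping unsupported element(s): {', '.join(unknown)}",
            UserWarning,
            stacklevel=2,
        )
    mdl_el = root.find("Model")
    model = ShoulderModel(name=mdl_el.get("name", "model"))

    def text(el, tag, default=None):
        child = el.find(tag)
        return child.text if child is not None and child.text else default

    if text(mdl_el, "gravity"):
        model.gravity = _vec(text(mdl_el, "gravity"))
    model.hand_mass = float(text(mdl_el, "hand_mass", "0.0"))
    if text(mdl_el, "hand_point"):
        model.hand_point = _vec(text(mdl_el, "hand_point"))

    for eb in mdl_el.findall("BodySet/objects/Body"):
        ivals = _vec(text(eb, "inertia", "0 0 0 0 0 0"))
        inertia = np.array([
            [ivals[0], ivals[3], ivals[4]],
            [ivals[3], ivals[1], ivals[5]],
            [ivals[4], ivals[5], ivals[2]],
        ])
        b = BodySegment(
            name=eb.get("name"),
            mass=float(text(eb, "mass", "0")),
            inertia=inertia,
            com=_vec(text(eb, "mass_center", "0 0 0")),
        )
        model.bodies[b.name] = b
        for ew in eb.findall("WrapObjectSet/objects/*"):
            kind = {"WrapSphere": "sphere", "WrapCylinder": "cylinder",
                    "WrapEllipsoid": "ellipsoid"}.get(ew.tag)
            if kind is None:
                continue
            if kind == "sphere":
                dims = (float(text(ew, "radius")),)
            elif kind == "cylinder":
                dims = (float(text(ew, "radius")), float(text(ew, "length")))
            else:
                dims = tuple(_vec(text(ew, "dimensions")))
            model.wrap_surfaces[ew.get("name")] = WrapSurface(
                name=ew.get("name"), kind=kind, body=b.name, dimensions=dims,
                translation=_vec(text(ew, "translation", "0 0 0")),
                rotation=_xyz_to_rotation(
                    _vec(text(ew, "xyz_body_rotation", "0 0 0"))),
            )

    coords: list[Coordinate] = [None] * 7  # fixed coordinate layout
    order = ["scap_abduction", "scap_elevation", "scap_upward_rot",
             "scap_winging", "shoulder_flexion", "shoulder_abduction",
             "shoulder_rotation"]

    def read_coords(ej):
        out = []
        for ec in ej.findall("CoordinateSet/objects/Coordinate"):
            rng = _vec(text(ec, "range", "-3.14 3.14"))
            out.append(Coordinate(
                name=ec.get("name"),
                default=float(text(ec, "default_value", "0")),
                range=(rng[0], rng[1]),
            ))
        return out

    for ej in mdl_el.findall("JointSet/objects/*"):
        jname = ej.get("name")
        parent, child = text(ej, "parent_body"), text(ej, "child_body")
        model.joints[jname] = {"parent": parent, "child": child}
        if ej.tag == "ScapulothoracicJoint":
            radii = _vec(text(ej, "thoracic_ellipsoid_radii_x_y_z"))
            model.st_joint = ScapulothoracicJoint(
                center=_vec(text(ej, "translation", "0 0 0")),
                radii=tuple(radii),
                tilt=float(text(ej, "ellipsoid_tilt", "0")),
                ref_abduction=float(text(ej, "reference_abduction", "0")),
                ref_elevation=float(text(ej, "reference_elevation", "0")),
            )
            for c in read_coords(ej):
                coords[order.index(c.name)] = c
        elif ej.tag == "BallJoint":
            model.fixed_transforms["humerus_offset"] = (
                _xyz_to_rotation(_vec(text(ej, "orientation", "0 0 0"))),
                _vec(text(ej, "translation", "0 0 0")),
            )
            for c in read_coords(ej):
                coords[order.index(c.name)] = c
        elif ej.tag == "WeldJoint":
            if child in ("clavicle", "forearm"):
                model.fixed_transforms[child] = (
                    _xyz_to_rotation(_vec(text(ej, "orientation", "0 0 0"))),
                    _vec(text(ej, "translation", "0 0 0")),
                )
    model.coordinates = [c for c in coords if c is not None]

    for em in mdl_el.findall("ForceSet/objects/Thelen2003Muscle"):
        name = em.get("name")
        params = MuscleParameters(
            name=name,
            group=text(em, "group", "") or "",
            f_max=float(text(em, "max_isometric_force", "0")),
            l_opt=float(text(em, "optimal_fiber_length", "0")),
            l_ts=float(text(em, "tendon_slack_length", "0")),
            pennation=float(text(em, "pennation_angle_at_optimal", "0")),
            source_bundles=text(em, "source_bundles", "") or "",
        )
        params.validate()  # raises naming the muscle, e.g. negative f_max
        points = [
            PathPoint(body=text(ep, "body"), location=_vec(text(ep, "location")))
            for ep in em.findall("GeometryPath/PathPointSet/objects/PathPoint")
        ]
        wraps: list[str | None] = [None] * (len(points) - 1)
        for ew in em.findall("GeometryPath/PathWrapSet/objects/PathWrap"):
            wraps[int(text(ew, "segment_index", "0"))] = text(ew, "wrap_object")
        model.muscles[name] = Muscle(
            params=params, path=MusclePath(points=points, wraps=wraps)
        )

    for emk in mdl_el.findall("MarkerSet/objects/Marker"):
        model.markers[emk.get("name")] = Marker(
            name=emk.get("name"),
            body=text(emk, "body"),
            location=_vec(text(emk, "location")),
            weight=float(text(emk, "weight", "1")),
        )
    model.validate()
    return model
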