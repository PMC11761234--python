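"""Pose normalization: a standard head frame from soft-tissue landmarks.

The standard frame is defined operationally from two bilateral landmark
pairs (a soft-tissue surrogate for the craniometric Frankfort horizontal,
which needs skeletal porion/orbitale and is not observable on a surface
scan):

* origin = midpoint of the tragion pair (Tr_L, Tr_R);
* X axis = the Tr_L - Tr_R direction (anatomical left positive);
* Y axis = unit normal of the plane through Tr_L, Tr_R and the midpoint of
  the exocanthion pair (Ex_L, Ex_R), signed superior;
* Z = X x Y (anterior positive).

After the transform the midsagittal plane of the landmark construction is
X = 0 and |x(Tr_L)| = |x(Tr_R)|. The construction is idempotent: applying
the computed transform and recomputing yields the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    DegenerateGeometryError,
    FaceMesh,
    InvalidInputError,
    LandmarkSet,
)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> rotation @ p + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise InvalidInputError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise InvalidInputError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidInputError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: FaceMesh, frame_tag: str | None = None) -> FaceMesh:
        return FaceMesh(
            self.apply(mesh.vertices),
            mesh.faces.copy(),
            mesh.frame_tag if frame_tag is None else frame_tag,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def frankfort_pose(
    landmarks: LandmarkSet,
    axial_pair: str = "Tr",
    plane_pair: str = "Ex",
) -> RigidTransform:
    """Transform placing landmarks into the standard (Frankfort-surrogate) frame.

    Requires both sides of ``axial_pair`` (default tragion) and
    ``plane_pair`` (default exocanthion). Raises if required landmarks are
    missing or the three defining points are collinear/coincident.
    """
    required = [f"{axial_pair}_L", f"{axial_pair}_R", f"{plane_pair}_L", f"{plane_pair}_R"]
    missing = [n for n in required if n not in landmarks]
    if missing:
        raise InvalidInputError("pose landmarks missing: " + ", ".join(missing))
    tl = landmarks[f"{axial_pair}_L"]
    tr = landmarks[f"{axial_pair}_R"]
    ex_mid = 0.5 * (landmarks[f"{plane_pair}_L"] + landmarks[f"{plane_pair}_R"])
    origin = 0.5 * (tl + tr)
    x_axis = tl - tr
    nx = np.linalg.norm(x_axis)
    if nx < 1e-9:
        raise DegenerateGeometryError(f"{axial_pair}_L and {axial_pair}_R coincide")
    x_axis = x_axis / nx
    d = ex_mid - origin
    # normal of the plane spanned by the transverse axis and the Ex midpoint
    y_axis = np.cross(d, x_axis)
    ny = np.linalg.norm(y_axis)
    if ny < 1e-9 * max(1.0, np.linalg.norm(d)) or np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError(
            "pose landmarks are collinear; surrogate plane undefined"
        )
    y_axis = y_axis / ny
    # sign: superior Y. Use menton (inferior) when present, else keep the
    # orientation that puts the Ex midpoint anterior (positive Z).
    if "Me" in landmarks:
        if np.dot(y_axis, landmarks["Me"] - origin) > 0:
            y_axis = -y_axis
        z_axis = np.cross(x_axis, y_axis)
    else:
        z_axis = np.cross(x_axis, y_axis)
        if np.dot(z_axis, d) < 0:
            y_axis = -y_axis
            z_axis = -z_axis
    R = np.vstack([x_axis, y_axis, z_axis])
    return RigidTransform(R, -R @ origin)


def midsagittal_offset(landmarks: LandmarkSet) -> float:
    """Least-squares X offset of the midsagittal plane over bilateral pairs.

    In the standard frame the midsagittal plane is X = 0 by construction of
    the axial pair; this reports the mean midpoint-x over *all* bilateral
    pairs, usable as a small correction or as a sanity diagnostic.
    """
    mids = []
    for name in landmarks.names():
        if name.endswith("_L"):
            other = name[:-1] + "R"
            mids.append(0.5 * (landmarks[name][0] + landmarks[other][0]))
    if not mids:
        raise InvalidInputError("no bilateral pairs available")
    return float(np.mean(mids))


def crop_extent(mesh: FaceMesh, bounds) -> FaceMesh:
    """Sub-mesh of faces whose three vertices all lie inside axis-aligned bounds.

    ``bounds`` is ((xmin, xmax), (ymin, ymax), (zmin, zmax)); use +-inf for
    open sides. The vertex array is compacted and face indices remapped.
    """
    b = np.asarray(bounds, dtype=np.float64)
    if b.shape != (3, 2):
        raise InvalidInputError("bounds must be ((xmin,xmax),(ymin,ymax),(zmin,zmax))")
    v = mesh.vertices
    inside = np.all((v >= b[:, 0]) & (v <= b[:, 1]), axis=1)
    keep_faces = np.all(inside[mesh.faces], axis=1)
    if not np.any(keep_faces):
        raise InvalidInputError("crop bounds exclude the entire mesh")
    faces = mesh.faces[keep_faces]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return FaceMesh(v[used], remap[faces], frame_tag=mesh.frame_tag)
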