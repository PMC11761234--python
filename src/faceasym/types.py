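"""Core domain types: meshes, landmark sets, regions, axes, severity grades.

All coordinates are millimetres. The repo-wide coordinate convention is:
X = transverse (subject's anatomical left positive), Y = vertical (superior
positive), Z = anteroposterior (anterior positive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


class FaceAsymError(Exception):
    """Base class for package errors."""


class InvalidInputError(FaceAsymError):
    """Malformed or inconsistent user input."""


class DegenerateGeometryError(FaceAsymError):
    """Geometric construction is degenerate (collinear/coincident points...)."""


# ---------------------------------------------------------------------------
# Landmark vocabulary
# ---------------------------------------------------------------------------

#: Bilateral landmark stems; each appears with an ``_L`` and ``_R`` suffix.
BILATERAL_LANDMARKS: tuple[str, ...] = (
    "Sal", "Ch", "Go", "As", "Mt", "Tr", "Zg", "Ex", "He",
)

#: Midline landmarks; no side suffix.
MIDLINE_LANDMARKS: tuple[str, ...] = ("Me", "Gn", "Li", "Stb")

_KNOWN_NAMES = frozenset(
    [f"{stem}_{side}" for stem in BILATERAL_LANDMARKS for side in "LR"]
    + list(MIDLINE_LANDMARKS)
)


def is_bilateral(stem: str) -> bool:
    return stem in BILATERAL_LANDMARKS


def resolve_landmark(stem: str, side: str | None = None) -> str:
    """Map a landmark stem and side to the concrete identifier.

    Bilateral stems get the ``_L``/``_R`` suffix; midline stems resolve
    as-is regardless of side.
    """
    if stem in BILATERAL_LANDMARKS:
        if side not in ("left", "right"):
            raise InvalidInputError(
                f"bilateral landmark {stem!r} needs side 'left' or 'right'"
            )
        return f"{stem}_{'L' if side == 'left' else 'R'}"
    return stem


class SeverityGrade(enum.IntEnum):
    """Three-level ordinal asymmetry severity; mild < moderate < severe."""

    mild = 0
    moderate = 1
    severe = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class RegionId(str, enum.Enum):
    """The five facial regions of interest."""

    labial = "labial"
    mandibular_angle = "mandibular_angle"
    cheek = "cheek"
    chin = "chin"
    articular = "articular"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class AxisId(str, enum.Enum):
    """Anatomical axis labels in the normalized frame."""

    X = "X"
    Y = "Y"
    Z = "Z"

    @property
    def index(self) -> int:
        return "XYZ".index(self.value)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GradingCriterion:
    """Half-open three-band severity criterion on a scalar statistic.

    Bands: [0, lower_cut) -> mild, [lower_cut, upper_cut) -> moderate,
    [upper_cut, inf) -> severe.
    """

    name: str
    statistic: str  # RMSE | MFM | AAI
    lower_cut: float
    upper_cut: float
    units: str  # "mm" or "percent"

    def __post_init__(self) -> None:
        if not (0 < self.lower_cut < self.upper_cut):
            raise InvalidInputError(
                f"criterion {self.name!r}: need 0 < lower_cut < upper_cut, "
                f"got {self.lower_cut}, {self.upper_cut}"
            )

    def classify(self, value: float) -> SeverityGrade:
        if value < 0 or not np.isfinite(value):
            raise InvalidInputError(
                f"{self.statistic} value must be finite and >= 0, got {value}"
            )
        if value < self.lower_cut:
            return SeverityGrade.mild
        if value < self.upper_cut:
            return SeverityGrade.moderate
        return SeverityGrade.severe


class FaceMesh:
    """Triangulated facial surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array, 0-based vertex indices
    frame_tag : ``"raw"`` or ``"normalized"``
    """

    __slots__ = ("vertices", "faces", "frame_tag")

    def __init__(self, vertices, faces, frame_tag: str = "raw") -> None:
        v = np.asarray(vertices, dtype=np.float64)
        f = np.asarray(faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidInputError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise InvalidInputError("faces must be an (m, 3) triangle array")
        if len(v) < 4 or len(f) < 1:
            raise InvalidInputError(
                "mesh needs at least 4 vertices and 1 face, got "
                f"{len(v)} vertices / {len(f)} faces"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("mesh has non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise InvalidInputError("face references vertex index out of range")
        if np.any(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ):
            raise InvalidInputError("degenerate face with repeated vertex index")
        self.vertices = v
        self.faces = f
        self.frame_tag = frame_tag

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self, frame_tag: str | None = None) -> "FaceMesh":
        return FaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.frame_tag if frame_tag is None else frame_tag,
        )

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length where defined)."""
        tri = self.vertices[self.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1)
        good = norms > 0
        vn[good] /= norms[good, None]
        return vn

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FaceMesh({self.n_vertices} vertices, {self.n_faces} faces, "
            f"frame={self.frame_tag!r})"
        )


class LandmarkSet:
    """Named 3D soft-tissue landmarks with the ``_L``/``_R`` side convention.

    Bilateral identifiers must be present for both sides or neither.
    Unknown names are rejected unless ``permissive=True`` (the full clinical
    template carries 34 landmarks; only the ones used by the angular
    parameters have registered names here).
    """

    def __init__(
        self,
        entries: Mapping[str, Iterable[float]],
        permissive: bool = False,
    ) -> None:
        pts: dict[str, np.ndarray] = {}
        for name, xyz in entries.items():
            if name in pts:
                raise InvalidInputError(f"duplicate landmark {name!r}")
            p = np.asarray(xyz, dtype=np.float64).reshape(-1)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise InvalidInputError(
                    f"landmark {name!r} must be a finite 3-vector, got {xyz!r}"
                )
            if not permissive and name not in _KNOWN_NAMES:
                raise InvalidInputError(
                    f"unknown landmark name {name!r} (use permissive=True to "
                    "accept names outside the registered vocabulary)"
                )
            pts[name] = p
        missing = []
        for name in pts:
            if name.endswith("_L") or name.endswith("_R"):
                other = name[:-1] + ("R" if name.endswith("_L") else "L")
                if other not in pts:
                    missing.append(other)
        if missing:
            raise InvalidInputError(
                "bilateral landmarks missing their opposite side: "
                + ", ".join(sorted(missing))
            )
        self._points = pts

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self):
        return iter(self._points)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[name]
        except KeyError:
            raise InvalidInputError(f"landmark {name!r} not present") from None

    def get(self, stem: str, side: str | None = None) -> np.ndarray:
        """Side-resolved lookup: ``get('Go', 'left') -> entry 'Go_L'``."""
        return self[resolve_landmark(stem, side)]

    def names(self) -> list[str]:
        return sorted(self._points)

    def items(self):
        return self._points.items()

    def as_dict(self) -> dict[str, list[float]]:
        return {k: [float(x) for x in v] for k, v in sorted(self._points.items())}

    def transformed(self, transform) -> "LandmarkSet":
        """Apply a RigidTransform to every landmark."""
        moved = {k: transform.apply(v) for k, v in self._points.items()}
        return LandmarkSet(moved, permissive=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return self.names() == other.names() and all(
            np.array_equal(self._points[k], other._points[k]) for k in self._points
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LandmarkSet({len(self)} landmarks)"


@dataclass(frozen=True)
class RegionMask:
    """Vertex-index mask of one region of interest on a specific mesh."""

    region: RegionId
    side: str  # left | right | bilateral
    vertex_indices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        idx = np.asarray(self.vertex_indices, dtype=np.int64)
        if idx.size == 0:
            raise InvalidInputError(
                f"region mask {self.region.value}/{self.side} is empty"
            )
        object.__setattr__(self, "vertex_indices", np.unique(idx))

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_indices)
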