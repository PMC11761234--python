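"""Regions of interest on a normalized face mesh.

The five clinical regions (labial, mandibular angle, cheek, chin,
articular) are defined anatomically by grooves and bony edges that a
surface scan does not label, so every curved boundary is operationalized
as a landmark-derived threshold in the normalized frame: horizontal
(Y) levels, transverse (X) extents, anteroposterior (Z) planes, and one
radius cut for the fan-shaped mandibular-angle region. Each surrogate is
a named config value with a documented default.

Boundary handling is half-open (lower bound inclusive, upper bound
exclusive) so masks are deterministic. The regions may overlap and need
not cover the face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import FaceMesh, InvalidInputError, LandmarkSet, RegionId, RegionMask


@dataclass(frozen=True)
class RoiConfig:
    """Surrogate thresholds for region boundaries (mm).

    lateral_margin_mm     widens landmark-derived X extents (labiofacial
                          groove and mental-protuberance side surrogates)
    chin_drop_mm          how far below menton the chin slab extends
    chin_depth_mm         how far behind menton/gnathion the chin region
                          reaches (excludes the submental/neck surface)
    earlobe_drop_mm       earlobe level below tragion (no earlobe landmark
                          exists in the vocabulary)
    gonion_radius_mm      radius of the fan around gonion for the
                          mandibular-angle region
    groove_fraction       mentolabial-groove level as a fraction of the way
                          from labiale inferius down to menton
    mandible_fraction     cheek lower edge as a fraction of the way from
                          the gonion level down to the menton level
    """

    lateral_margin_mm: float = 5.0
    chin_drop_mm: float = 5.0
    chin_depth_mm: float = 20.0
    earlobe_drop_mm: float = 15.0
    gonion_radius_mm: float = 28.0
    groove_fraction: float = 0.5
    mandible_fraction: float = 0.5


def _require(landmarks: LandmarkSet, names: list[str]) -> None:
    missing = [n for n in names if n not in landmarks]
    if missing:
        raise InvalidInputError("region landmarks missing: " + ", ".join(missing))


def _side_sign(side: str) -> float:
    if side == "left":
        return 1.0
    if side == "right":
        return -1.0
    raise InvalidInputError(f"side must be 'left' or 'right', got {side!r}")


def _mask(mesh, keep, region, side) -> RegionMask:
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        raise InvalidInputError(
            f"region {region.value}/{side} selects no vertices on this mesh"
        )
    return RegionMask(region, side, idx)


def _groove_y(landmarks: LandmarkSet, config: RoiConfig) -> float:
    """Mentolabial-groove level: between labiale inferius and menton."""
    lower_lip = landmarks["Li"] if "Li" in landmarks else landmarks["Stb"]
    return float(
        lower_lip[1] + config.groove_fraction * (landmarks["Me"][1] - lower_lip[1])
    )


def define_labial(
    mesh: FaceMesh, landmarks: LandmarkSet, config: RoiConfig | None = None
) -> RegionMask:
    """Labial slab: nose floor (subalare level) down to the mentolabial
    groove, laterally bounded near the cheilion pair."""
    config = config or RoiConfig()
    _require(landmarks, ["Sal_L", "Sal_R", "Ch_L", "Ch_R", "Me"])
    if "Li" not in landmarks and "Stb" not in landmarks:
        raise InvalidInputError("region landmarks missing: Li (or Stb)")
    v = mesh.vertices
    y_top = 0.5 * (landmarks["Sal_L"][1] + landmarks["Sal_R"][1])
    y_bot = _groove_y(landmarks, config)
    x_hi = max(landmarks["Ch_L"][0], landmarks["Ch_R"][0]) + config.lateral_margin_mm
    x_lo = min(landmarks["Ch_L"][0], landmarks["Ch_R"][0]) - config.lateral_margin_mm
    keep = (v[:, 1] >= y_bot) & (v[:, 1] < y_top) & (v[:, 0] >= x_lo) & (v[:, 0] < x_hi)
    return _mask(mesh, keep, RegionId.labial, "bilateral")


def define_chin(
    mesh: FaceMesh, landmarks: LandmarkSet, config: RoiConfig | None = None
) -> RegionMask:
    """Chin slab below the mentolabial groove around the mental
    protuberance (menton/gnathion/mental-tubercle landmarks)."""
    config = config or RoiConfig()
    _require(landmarks, ["Me", "Gn", "Mt_L", "Mt_R"])
    if "Li" not in landmarks and "Stb" not in landmarks:
        raise InvalidInputError("region landmarks missing: Li (or Stb)")
    v = mesh.vertices
    y_top = _groove_y(landmarks, config)
    y_bot = landmarks["Me"][1] - config.chin_drop_mm
    x_lim = (
        max(abs(landmarks["Mt_L"][0]), abs(landmarks["Mt_R"][0]))
        + config.lateral_margin_mm
    )
    z_back = min(landmarks["Me"][2], landmarks["Gn"][2]) - config.chin_depth_mm
    keep = (
        (v[:, 1] >= y_bot)
        & (v[:, 1] < y_top)
        & (np.abs(v[:, 0]) < x_lim)
        & (v[:, 2] >= z_back)
    )
    return _mask(mesh, keep, RegionId.chin, "bilateral")


def define_cheek(
    mesh: FaceMesh,
    landmarks: LandmarkSet,
    side: str,
    config: RoiConfig | None = None,
) -> RegionMask:
    """Cheek: zygion level down to the mandibular lower edge (between the
    gonion and menton levels), lateral of the nasofacial-groove surrogate
    (a vertical plane just lateral of the cheilion)."""
    config = config or RoiConfig()
    sign = _side_sign(side)
    suffix = "L" if side == "left" else "R"
    _require(landmarks, [f"Zg_{suffix}", f"Ch_{suffix}", f"Go_{suffix}", "Me"])
    v = mesh.vertices
    y_top = landmarks[f"Zg_{suffix}"][1]
    go_y = landmarks[f"Go_{suffix}"][1]
    y_bot = go_y + config.mandible_fraction * (landmarks["Me"][1] - go_y)
    x_inner = abs(landmarks[f"Ch_{suffix}"][0]) + config.lateral_margin_mm
    keep = (
        (v[:, 1] >= y_bot)
        & (v[:, 1] < y_top)
        & (sign * v[:, 0] >= x_inner)
    )
    return _mask(mesh, keep, RegionId.cheek, side)


def define_mandibular_angle(
    mesh: FaceMesh,
    landmarks: LandmarkSet,
    side: str,
    config: RoiConfig | None = None,
) -> RegionMask:
    """Fan around gonion: below the earlobe level, at or behind the
    zygomatic-posterior-edge plane (zygion Z), within a radius of gonion."""
    config = config or RoiConfig()
    sign = _side_sign(side)
    suffix = "L" if side == "left" else "R"
    _require(landmarks, [f"Go_{suffix}", f"Zg_{suffix}", f"Tr_{suffix}"])
    v = mesh.vertices
    go = landmarks[f"Go_{suffix}"]
    y_top = landmarks[f"Tr_{suffix}"][1] - config.earlobe_drop_mm
    z_front = landmarks[f"Zg_{suffix}"][2]
    r = np.linalg.norm(v - go, axis=1)
    keep = (
        (v[:, 1] < y_top)
        & (v[:, 2] < z_front)
        & (r < config.gonion_radius_mm)
        & (sign * v[:, 0] > 0)
    )
    return _mask(mesh, keep, RegionId.mandibular_angle, side)


def define_articular(
    mesh: FaceMesh,
    landmarks: LandmarkSet,
    side: str,
    config: RoiConfig | None = None,
) -> RegionMask:
    """Articular strip in front of the ear: helix-top level down to the
    earlobe level, between the tragus plane and the zygomatic posterior
    edge (tragion Z to zygion Z)."""
    config = config or RoiConfig()
    sign = _side_sign(side)
    suffix = "L" if side == "left" else "R"
    _require(landmarks, [f"He_{suffix}", f"Tr_{suffix}", f"Zg_{suffix}"])
    v = mesh.vertices
    y_top = landmarks[f"He_{suffix}"][1]
    y_bot = landmarks[f"Tr_{suffix}"][1] - config.earlobe_drop_mm
    z_back = landmarks[f"Tr_{suffix}"][2]
    z_front = landmarks[f"Zg_{suffix}"][2]
    keep = (
        (v[:, 1] >= y_bot)
        & (v[:, 1] < y_top)
        & (v[:, 2] >= z_back)
        & (v[:, 2] < z_front)
        & (sign * v[:, 0] > 0)
    )
    return _mask(mesh, keep, RegionId.articular, side)


def region_masks(
    mesh: FaceMesh, landmarks: LandmarkSet, config: RoiConfig | None = None
) -> dict[RegionId, RegionMask]:
    """All five regions, with left/right halves merged for the side-split
    ones (grading is per region over both sides)."""
    config = config or RoiConfig()
    out: dict[RegionId, RegionMask] = {
        RegionId.labial: define_labial(mesh, landmarks, config),
        RegionId.chin: define_chin(mesh, landmarks, config),
    }
    for region, fn in (
        (RegionId.cheek, define_cheek),
        (RegionId.mandibular_angle, define_mandibular_angle),
        (RegionId.articular, define_articular),
    ):
        left = fn(mesh, landmarks, "left", config)
        right = fn(mesh, landmarks, "right", config)
        out[region] = RegionMask(
            region,
            "bilateral",
            np.concatenate([left.vertex_indices, right.vertex_indices]),
        )
    return out
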