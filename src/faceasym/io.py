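"""Readers and writers: Wavefront OBJ meshes, landmark files, result tables.

OBJ support is deliberately minimal and predictable: ``v`` and ``f`` records
only, polygons fan-triangulated, texture/normal records tolerated and
ignored, 1-based OBJ indices converted to 0-based at this boundary.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .types import FaceMesh, InvalidInputError, LandmarkSet


class ParseError(InvalidInputError):
    """File could not be parsed; message names the offending line."""


def read_obj(path: str | Path) -> FaceMesh:
    """Read a Wavefront OBJ file into a :class:`FaceMesh`.

    Polygonal faces with more than three vertices are split into triangles
    by fanning from the first face vertex. Negative (relative) indices are
    resolved against the vertices seen so far.
    """
    path = Path(path)
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise ParseError(f"{path.name}:{lineno}: vertex needs 3 coords")
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: bad vertex coordinate ({exc})"
                    ) from None
            elif tag == "f":
                idx = []
                for tok in parts[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise ParseError(
                            f"{path.name}:{lineno}: malformed face index {tok!r}"
                        ) from None
                    if i == 0:
                        raise ParseError(
                            f"{path.name}:{lineno}: OBJ face index 0 is invalid"
                        )
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                if len(idx) < 3:
                    raise ParseError(
                        f"{path.name}:{lineno}: face needs at least 3 vertices"
                    )
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append([idx[0], idx[k], idx[k + 1]])
            # vt/vn/usemtl/... ignored
    if not vertices or not faces:
        raise InvalidInputError(f"{path.name}: no usable v/f records (empty mesh)")
    return FaceMesh(np.array(vertices), np.array(faces), frame_tag="raw")


def write_obj(mesh: FaceMesh, path: str | Path, precision: int = 8) -> None:
    """Write a :class:`FaceMesh` as OBJ (v/f records, 1-based indices)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


def read_landmarks(
    path: str | Path,
    dialect: str = "auto",
    permissive: bool = False,
) -> LandmarkSet:
    """Read landmarks from JSON ``{name: [x, y, z]}`` or MeshLab picked-points XML.

    ``dialect`` is ``"json"``, ``"picked_points"`` or ``"auto"`` (sniff from
    the file suffix/content).
    """
    path = Path(path)
    if dialect == "auto":
        if path.suffix.lower() in (".pp", ".xml"):
            dialect = "picked_points"
        else:
            dialect = "json"
    if dialect == "json":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path.name}: invalid JSON ({exc})") from None
        if not isinstance(data, dict):
            raise ParseError(f"{path.name}: expected a JSON object of name: [x,y,z]")
        return LandmarkSet(data, permissive=permissive)
    if dialect == "picked_points":
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:
            raise ParseError(f"{path.name}: invalid XML ({exc})") from None
        entries: dict[str, list[float]] = {}
        for pt in root.iter("point"):
            name = pt.get("name")
            if name is None:
                raise ParseError(f"{path.name}: <point> without name attribute")
            try:
                entries[name] = [float(pt.get(ax)) for ax in ("x", "y", "z")]
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path.name}: <point name={name!r}> needs numeric x/y/z"
                ) from None
        return LandmarkSet(entries, permissive=permissive)
    raise InvalidInputError(f"unknown landmark dialect {dialect!r}")


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write landmarks as JSON ``{name: [x, y, z]}``."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(landmarks.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_table(rows: pd.DataFrame, path: str | Path, format: str = "auto") -> None:
    """Write a result table as CSV or JSON (records orient)."""
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    if rows.empty:
        raise InvalidInputError("refusing to write an empty result table")
    path = Path(path)
    if format == "auto":
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        rows.to_csv(path, index=False)
    elif format == "json":
        rows.to_json(path, orient="records", indent=1)
    else:
        raise InvalidInputError(f"unknown table format {format!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.read_json(path, orient="records")
    return pd.read_csv(path)
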