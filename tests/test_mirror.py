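"""Reflection, trimmed ICP, point-to-surface deviations, summaries."""

import numpy as np
import pytest

from faceasym.mirror import (
    DeviationField,
    ICPParams,
    SurfaceQuery,
    best_fit_align,
    closest_point_on_triangles,
    compute_deviation,
    export_colormap,
    mirror_mesh,
    summarize_region,
)
from faceasym.pose import RigidTransform
from faceasym.types import FaceMesh, InvalidInputError

from conftest import random_rigid


def test_mirror_negates_x_and_preserves_orientation():
    mesh = FaceMesh(
        [[3.0, 1.0, -2.0], [0, 0, 0], [0, 1, 0], [1, 0, 0]], [[1, 2, 3]]
    )
    out = mirror_mesh(mesh)
    assert np.array_equal(out.vertices[0], [-3.0, 1.0, -2.0])
    assert np.array_equal(out.faces[0], [3, 2, 1])


def test_mirror_is_an_involution(base_case):
    twice = mirror_mesh(mirror_mesh(base_case.mesh))
    assert np.array_equal(twice.vertices, base_case.mesh.vertices)
    assert np.array_equal(twice.faces, base_case.mesh.faces)


def test_symmetric_face_mirrors_onto_itself(base_case):
    mirrored = mirror_mesh(base_case.mesh)
    orig = {tuple(v) for v in base_case.mesh.vertices}
    refl = {tuple(v) for v in mirrored.vertices}
    assert orig == refl


def test_closest_point_on_triangles_matches_dense_sampling(rng):
    # oracle: dense barycentric sampling of each triangle
    w = np.linspace(0, 1, 60)
    grid = np.array([(a, b, 1 - a - b) for a in w for b in w if a + b <= 1.0])
    for _ in range(25):
        tri = rng.uniform(-5, 5, size=(3, 3))
        p = rng.uniform(-8, 8, size=3)
        got = closest_point_on_triangles(p, tri[None, ...])[0]
        d_got = np.linalg.norm(got - p)
        dense = grid @ tri
        d_min = np.linalg.norm(dense - p, axis=1).min()
        assert d_got <= d_min + 1e-9
        # the returned point must lie on the triangle plane patch
        bary = np.linalg.lstsq(
            np.vstack([tri[1] - tri[0], tri[2] - tri[0]]).T,
            (got - tri[0]),
            rcond=None,
        )[0]
        assert -1e-6 <= bary[0] and -1e-6 <= bary[1] and bary.sum() <= 1 + 1e-6


def test_icp_recovers_planted_rigid_transform(small_case, rng):
    mesh = small_case.mesh
    T = random_rigid(rng)
    # keep rotations moderate so nearest-neighbour correspondences converge
    ang = np.radians(5.0)
    R = np.array(
        [[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]]
    )
    T = RigidTransform(R, np.array([1.0, 2.0, 3.0]))
    target = T.apply_mesh(mesh)
    result = best_fit_align(mesh, target)
    assert result.converged
    err = result.transform.compose(T.inverse())
    assert err.rotation_angle_deg() <= 0.01
    assert np.linalg.norm(
        result.transform.apply(mesh.vertices.mean(0)) - T.apply(mesh.vertices.mean(0))
    ) <= 0.01


def test_icp_identity_when_source_equals_target(small_case):
    result = best_fit_align(small_case.mesh, small_case.mesh)
    assert result.rms <= 1e-9
    assert result.transform.rotation_angle_deg() <= 1e-7


def test_icp_rejects_degenerate_input(small_case):
    tiny = FaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], [[0, 1, 2]])
    line = FaceMesh(
        [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], [[0, 1, 2]]
    )
    # a 2-vertex target cannot even be built; 2 effective points must fail
    with pytest.raises(InvalidInputError):
        best_fit_align(
            tiny,
            FaceMesh([[0, 0, 0], [0, 0, 0], [0, 0, 0], [1, 1, 1]], [[0, 1, 3]]),
            ICPParams(max_iterations=5),
        )
    del line


def test_icp_subsampling_requires_seed():
    with pytest.raises(InvalidInputError, match="seed"):
        ICPParams(subsample=100)


def test_deviation_zero_for_identical_meshes(small_case):
    field = compute_deviation(small_case.mesh, small_case.mesh)
    assert field.closest_distance.max() <= 1e-12
    assert np.abs(field.signed_distance).max() <= 1e-12


def _plane(z, n=6):
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    v = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
    return FaceMesh(v, faces)


def test_deviation_between_parallel_planes_is_the_gap():
    field = compute_deviation(_plane(0.0), _plane(1.0))
    assert np.allclose(field.closest_distance, 1.0)
    assert np.allclose(np.abs(field.displacement[:, 2]), 1.0)
    assert np.allclose(field.displacement[:, :2], 0.0)


def test_deviation_field_invariants(small_case):
    mirrored = mirror_mesh(small_case.mesh)
    field = compute_deviation(small_case.mesh, mirrored)
    assert np.allclose(
        np.abs(field.signed_distance), field.closest_distance, atol=1e-9
    )
    assert np.allclose(
        np.linalg.norm(field.displacement, axis=1),
        field.closest_distance,
        atol=1e-9,
    )


def test_region_summary_closed_forms():
    d = np.array([0.5, 2.1, 0.0])
    disp = np.column_stack([np.zeros(3), d, np.zeros(3)])
    field = DeviationField(np.abs(d), d.copy(), disp)
    s = summarize_region(field, [0, 1, 2])
    assert s.mfm == pytest.approx(2.1)
    assert s.rmse == pytest.approx(np.sqrt((0.25 + 4.41 + 0) / 3))
    assert s.mfm_axis[0] == 0.0
    assert s.mfm_axis[1] == pytest.approx(2.1)

    ones = np.ones(3)
    field1 = DeviationField(ones, ones.copy(), np.column_stack([ones, 0 * ones, 0 * ones]))
    s1 = summarize_region(field1, [0, 1, 2])
    assert s1.rmse == pytest.approx(1.0)
    assert s1.mfm == pytest.approx(1.0)


def test_region_summary_mfm_dominates_rmse(small_case, rng):
    mirrored = mirror_mesh(small_case.mesh)
    field = compute_deviation(small_case.mesh, mirrored)
    idx = rng.choice(small_case.mesh.n_vertices, 200, replace=False)
    s = summarize_region(field, idx)
    assert s.mfm >= s.rmse
    for k in range(3):
        assert s.mfm_axis[k] <= s.mfm + 1e-9
        assert s.mfm_axis[k] >= s.rmse_axis[k] - 1e-12


def test_region_summary_rejects_empty_region(small_case):
    field = compute_deviation(small_case.mesh, small_case.mesh)
    with pytest.raises(InvalidInputError):
        summarize_region(field, [])


def test_surface_query_finds_exact_vertices(small_case):
    q = SurfaceQuery(small_case.mesh)
    pts = small_case.mesh.vertices[::97]
    closest, dist, _ = q.query(pts)
    assert dist.max() <= 1e-12
    assert np.allclose(closest, pts)


def test_colormap_export(tmp_path, small_case):
    mirrored = mirror_mesh(small_case.mesh)
    field = compute_deviation(small_case.mesh, mirrored)
    out = tmp_path / "map.ply"
    export_colormap(field, small_case.mesh, out)
    head = out.read_bytes()[:200].decode("ascii", errors="replace")
    assert head.startswith("ply")
    assert "binary_little_endian" in head
    assert f"element vertex {small_case.mesh.n_vertices}" in head

    bad = DeviationField(
        np.zeros(3), np.zeros(3), np.zeros((3, 3))
    )
    with pytest.raises(InvalidInputError):
        export_colormap(bad, small_case.mesh, tmp_path / "bad.ply")


def test_zero_field_maps_to_mid_scale_color(tmp_path, small_case):
    n = small_case.mesh.n_vertices
    field = DeviationField(np.zeros(n), np.zeros(n), np.zeros((n, 3)))
    out = tmp_path / "flat.ply"
    export_colormap(field, small_case.mesh, out)
    raw = out.read_bytes()
    header_end = raw.index(b"end_header\n") + len(b"end_header\n")
    vtype = np.dtype([("xyz", "<f4", 3), ("rgb", "u1", 3)])
    vdata = np.frombuffer(raw, dtype=vtype, count=n, offset=header_end)
    # a symmetric diverging scale at its centre: all vertices share one colour
    assert len(np.unique(vdata["rgb"], axis=0)) == 1


def test_colormap_scale_endpoints_track_the_field_extreme(tmp_path, small_case):
    n = small_case.mesh.n_vertices
    signed = np.zeros(n)
    signed[0] = 12.194
    signed[1] = -12.194
    field = DeviationField(np.abs(signed), signed, np.column_stack(
        [signed, np.zeros(n), np.zeros(n)]))
    out = tmp_path / "extreme.ply"
    export_colormap(field, small_case.mesh, out)
    raw = out.read_bytes()
    off = raw.index(b"end_header\n") + len(b"end_header\n")
    vtype = np.dtype([("xyz", "<f4", 3), ("rgb", "u1", 3)])
    vdata = np.frombuffer(raw, dtype=vtype, count=n, offset=off)
    import matplotlib

    cmap = matplotlib.colormaps["coolwarm"]
    top = (np.asarray(cmap(1.0))[:3] * 255).astype(np.uint8)
    bottom = (np.asarray(cmap(0.0))[:3] * 255).astype(np.uint8)
    assert np.array_equal(vdata["rgb"][0], top)
    assert np.array_equal(vdata["rgb"][1], bottom)
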