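"""Mesh geometry: volumes, surfaces, 3D/2D Hausdorff distances."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from ctvdelta import (
    GeometryReport,
    OpenMeshError,
    TriangularMesh,
    compare_pair,
    hausdorff_2d_axial,
    hausdorff_3d,
    mesh_surface_area,
    mesh_volume,
    slice_mesh,
    summarize_cohort,
)
from ctvdelta.mesh import SurfaceDistanceQuery, _surface_samples

from conftest import tm


# ---------------------------------------------------------------------------
# volume and surface area
# ---------------------------------------------------------------------------


def test_cube_volume_and_area_exact(unit_cube):
    assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)
    assert mesh_surface_area(unit_cube) == pytest.approx(6.0, abs=1e-12)


def test_icosphere_volume_and_area_within_half_percent(icosphere_factory):
    ico = icosphere_factory(10.0, subdivisions=4)
    assert mesh_volume(ico) == pytest.approx(4 / 3 * np.pi * 1000, rel=0.005)
    assert mesh_surface_area(ico) == pytest.approx(4 * np.pi * 100, rel=0.005)


def test_flat_closed_mesh_has_zero_volume():
    # a doubled triangle: every edge shared by exactly two faces, zero thickness
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    faces = np.array([[0, 1, 2], [2, 1, 0]])
    mesh = TriangularMesh(verts, faces)
    assert mesh.is_closed
    assert mesh_volume(mesh) == pytest.approx(0.0, abs=1e-12)


def test_open_mesh_raises_with_edge_count():
    single = TriangularMesh(
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float), [[0, 1, 2]]
    )
    with pytest.raises(OpenMeshError, match="3 open edges"):
        mesh_volume(single)
    # area still fine on open meshes
    assert mesh_surface_area(single) == pytest.approx(0.5)


def test_volume_rigid_invariance_and_scaling(unit_cube):
    rot = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3])[:3, :3]
    moved = TriangularMesh(unit_cube.vertices @ rot.T + [5.0, -3.0, 2.0], unit_cube.faces)
    assert mesh_volume(moved) == pytest.approx(1.0, rel=1e-9)
    assert mesh_surface_area(moved) == pytest.approx(6.0, rel=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
def test_volume_scales_cubically_surface_quadratically(scale):
    cube = tm(trimesh.creation.box(extents=(1.0, 1.0, 1.0)))
    scaled = TriangularMesh(cube.vertices * scale, cube.faces)
    assert mesh_volume(scaled) == pytest.approx(scale**3, rel=1e-9)
    assert mesh_surface_area(scaled) == pytest.approx(6 * scale**2, rel=1e-9)


# ---------------------------------------------------------------------------
# 3D Hausdorff distance
# ---------------------------------------------------------------------------


def test_hausdorff_identity_is_zero(icosphere_factory):
    s = icosphere_factory(10.0, subdivisions=2)
    assert hausdorff_3d(s, s) == pytest.approx(0.0, abs=1e-9)


def test_hausdorff_concentric_spheres(icosphere_factory):
    hd = hausdorff_3d(icosphere_factory(10.0, 3), icosphere_factory(15.0, 3))
    assert hd == pytest.approx(5.0, abs=0.05)


def test_hausdorff_translation_equals_shift(icosphere_factory):
    a = icosphere_factory(10.0, 3)
    b = TriangularMesh(a.vertices + [3.0, 0.0, 0.0], a.faces)
    assert hausdorff_3d(a, b) == pytest.approx(3.0, abs=0.05)


def test_hausdorff_symmetric_exactly(icosphere_factory):
    a = icosphere_factory(10.0, 2)
    b = TriangularMesh(icosphere_factory(12.0, 2).vertices + [1.0, 2.0, 0.5],
                       icosphere_factory(12.0, 2).faces)
    assert hausdorff_3d(a, b) == hausdorff_3d(b, a)


def test_hausdorff_triangle_type_bound(icosphere_factory):
    a = icosphere_factory(10.0, 2)
    b = icosphere_factory(12.0, 2)
    c = icosphere_factory(15.0, 2)
    assert hausdorff_3d(a, c) <= hausdorff_3d(a, b) + hausdorff_3d(b, c) + 1e-9


def test_empty_mesh_rejected(icosphere_factory):
    empty = TriangularMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    with pytest.raises(ValueError):
        hausdorff_3d(empty, icosphere_factory(10.0, 1))


# -- brute-force oracle ------------------------------------------------------


def _reference_point_triangle_distance(p, a, b, c):
    """Independent scalar point-triangle distance (Eberly region method)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + v * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + w * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + w * (c - b)))
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return np.linalg.norm(p - (a + v * ab + w * ac))


def _bruteforce_directed(points, mesh):
    tri = mesh.vertices[mesh.faces]
    return max(
        min(_reference_point_triangle_distance(p, *t) for t in tri) for p in points
    )


def test_sampled_hd_matches_bruteforce_all_pairs(icosphere_factory):
    """On small meshes the pruned query equals the exhaustive point-triangle scan."""
    a = icosphere_factory(10.0, 1)  # 42 vertices
    b = TriangularMesh(icosphere_factory(8.0, 1).vertices + [2.0, 1.0, -1.0],
                       icosphere_factory(8.0, 1).faces)
    for src, dst in ((a, b), (b, a)):
        pts = _surface_samples(src, density=0.05, seed=0)
        fast = SurfaceDistanceQuery(dst).distances(pts).max()
        brute = _bruteforce_directed(pts, dst)
        assert fast == pytest.approx(brute, abs=1e-9)


# ---------------------------------------------------------------------------
# slicing and 2D Hausdorff
# ---------------------------------------------------------------------------


def test_slice_icosphere_equator_is_circle(icosphere_factory):
    contours = slice_mesh(icosphere_factory(10.0, 4), z=0.0)
    assert len(contours) == 1
    radii = np.linalg.norm(contours[0].points, axis=1)
    assert radii == pytest.approx(10.0, abs=0.05)
    assert np.allclose(contours[0].points[0], contours[0].points[-1])


def test_slice_outside_bounding_box_empty(icosphere_factory):
    assert slice_mesh(icosphere_factory(10.0, 2), z=20.0) == []


def test_slice_torus_through_hole_gives_two_contours():
    torus = tm(trimesh.creation.torus(major_radius=10.0, minor_radius=3.0))
    # the torus axis is z; cut with a vertical plane by swapping axes
    rolled = TriangularMesh(torus.vertices[:, [0, 2, 1]], torus.faces)
    assert len(slice_mesh(rolled, z=0.0)) == 2


def test_hd2d_identical_meshes_zero(icosphere_factory):
    s = icosphere_factory(10.0, 3)
    res = hausdorff_2d_axial(s, s)
    assert res.summary_mm == pytest.approx(0.0, abs=1e-9)
    assert res.unmatched_slices == 0


def test_hd2d_coaxial_cylinders_constant():
    a = tm(trimesh.creation.cylinder(10.0, 21.0, sections=256))
    b = tm(trimesh.creation.cylinder(14.0, 21.0, sections=256))
    res = hausdorff_2d_axial(a, b, slice_spacing=2.0)
    assert res.summary_mm == pytest.approx(4.0, abs=0.05)
    for hd in res.per_slice_mm.values():
        assert hd == pytest.approx(4.0, abs=0.05)


def test_hd2d_concentric_spheres_per_slice_closed_form(icosphere_factory):
    """Per-slice HD of circles of radius sqrt(R²−z²) is the radius gap."""
    res = hausdorff_2d_axial(
        icosphere_factory(10.0, 4), icosphere_factory(15.0, 4), slice_spacing=2.0
    )
    for z, hd in res.per_slice_mm.items():
        expected = np.sqrt(225 - z**2) - np.sqrt(100 - z**2)
        assert hd == pytest.approx(expected, abs=0.1), f"slice z={z}"
    # summary is the max over shared slices, attained nearest the small pole
    assert res.summary_mm == pytest.approx(max(res.per_slice_mm.values()))
    assert res.unmatched_slices > 0  # slices cut only by the large sphere


def test_hd2d_disjoint_z_extents_error(icosphere_factory):
    a = icosphere_factory(5.0, 2)
    b = TriangularMesh(a.vertices + [0.0, 0.0, 50.0], a.faces)
    with pytest.raises(ValueError, match="no axial slice"):
        hausdorff_2d_axial(a, b)


# ---------------------------------------------------------------------------
# pair comparison and cohort summary
# ---------------------------------------------------------------------------


def test_compare_identical_pair_all_zero(icosphere_factory):
    s = icosphere_factory(10.0, 3)
    rep = compare_pair(s, s)
    assert rep.volume_difference_fraction == pytest.approx(0.0, abs=1e-12)
    assert rep.hd3d_mm == pytest.approx(0.0, abs=1e-9)
    assert rep.hd2d_mm == pytest.approx(0.0, abs=1e-9)


def test_compare_pair_sphere_volume_fraction(icosphere_factory):
    rep = compare_pair(icosphere_factory(10.0, 3), icosphere_factory(10.29, 3))
    assert rep.volume_difference_fraction == pytest.approx(1.029**3 - 1, abs=0.002)


def test_summarize_cohort_basic():
    def rep(hd):
        return GeometryReport(
            volume_s_cm3=1.0, volume_l_cm3=1.1, surface_s_cm2=1.0,
            surface_l_cm2=1.0, hd3d_mm=hd, hd2d_mm=hd,
            volume_difference_fraction=0.1,
        )

    single = summarize_cohort([rep(2.0)])
    assert single.loc["hd3d_mm", "median"] == 2.0
    assert single.loc["hd3d_mm", "sd"] == 0.0

    three = summarize_cohort([rep(1.0), rep(2.0), rep(3.0)])
    assert three.loc["hd3d_mm", "median"] == 2.0
    assert three.loc["hd3d_mm", "sd"] == pytest.approx(1.0)
    assert three.loc["hd3d_mm", "min"] == 1.0
    assert three.loc["hd3d_mm", "max"] == 3.0

    with pytest.raises(ValueError):
        summarize_cohort([])
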