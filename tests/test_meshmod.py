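import math

import numpy as np
import pytest
import trimesh

from etsim.meshmod import (
    ContourStack,
    Mesh,
    contours_to_mesh,
    isosurface,
    mesh_measures,
    smooth_mesh,
)
from etsim.phantom import GridSpec, PhantomSpec, Primitive, analytic_measures, rasterize


def circle(r, n=100, cx=0.0, cy=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([cx + r * np.cos(t), cy + r * np.sin(t)], axis=1)


def unit_cube_mesh():
    box = trimesh.creation.box(extents=(1, 1, 1))
    return Mesh(vertices=np.asarray(box.vertices), triangles=np.asarray(box.faces),
                watertight=True)


class TestContoursToMesh:
    def test_circle_stack_builds_cylinder(self):
        planes = [(float(5 * k), [circle(20.0)]) for k in range(10)]
        mesh = contours_to_mesh(ContourStack(planes=planes))
        assert mesh.watertight
        m = mesh_measures(mesh)
        assert m.volume_nm3 == pytest.approx(math.pi * 20**2 * 45, rel=0.02)

    def test_two_squares_build_cuboid(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        mesh = contours_to_mesh(ContourStack(planes=[(0.0, [sq]), (1.0, [sq.copy()])]))
        assert mesh.watertight
        assert mesh_measures(mesh).volume_nm3 == pytest.approx(1.0, rel=0.01)

    def test_single_plane_rejected(self):
        with pytest.raises(ValueError, match=">= 2 planes"):
            contours_to_mesh(ContourStack(planes=[(0.0, [circle(5.0)])]))

    def test_unordered_planes_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            ContourStack(planes=[(1.0, [circle(5)]), (0.0, [circle(5)])])

    def test_branching_starts_second_chain(self, caplog):
        planes = [
            (0.0, [circle(10.0)]),
            (5.0, [circle(10.0)]),
            (10.0, [circle(6.0, cx=-8), circle(6.0, cx=8)]),
            (15.0, [circle(6.0, cx=-8), circle(6.0, cx=8)]),
        ]
        with caplog.at_level("WARNING", logger="etsim.meshmod"):
            mesh = contours_to_mesh(ContourStack(planes=planes))
        assert mesh.watertight
        assert any("chain" in r.message for r in caplog.records)

    def test_volume_converges_with_plane_spacing(self):
        # a sphere-like stack (nonlinear radius profile) must converge to
        # the closed form as the plane spacing shrinks; a cone would be
        # exact at any spacing because the stitching is linear in z
        R = 20.0
        def stack(n):
            zs = np.linspace(-R + 1e-3, R - 1e-3, n)
            return ContourStack(
                planes=[(float(z), [circle(math.sqrt(R**2 - z**2))]) for z in zs])
        exact = 4 / 3 * math.pi * R**3
        coarse = mesh_measures(contours_to_mesh(stack(6))).volume_nm3
        fine = mesh_measures(contours_to_mesh(stack(60))).volume_nm3
        assert abs(fine - exact) / exact < abs(coarse - exact) / exact
        assert fine == pytest.approx(exact, rel=0.01)


class TestIsosurface:
    def test_sphere_volume_and_area(self, sphere_volume):
        vol, prim = sphere_volume
        mesh = isosurface(vol, 0.5)
        assert mesh.watertight
        m = mesh_measures(mesh)
        truth = analytic_measures(prim)
        assert m.volume_nm3 == pytest.approx(truth.volume_nm3, rel=0.02)
        assert m.surface_area_nm2 == pytest.approx(truth.surface_area_nm2, rel=0.05)

    def test_threshold_outside_range_rejected(self, sphere_volume):
        vol, _ = sphere_volume
        with pytest.raises(ValueError, match="threshold"):
            isosurface(vol, 2.0)
        with pytest.raises(ValueError, match="threshold"):
            isosurface(vol, -1.0)

    def test_end_to_end_cylinder_quantification(self):
        # the pipeline the quantification claims rest on:
        # primitive -> rasterize -> isosurface -> mesh measures
        prim = Primitive(kind="solid-cylinder", center=(100, 100, 0), axis=(0, 1, 0),
                         radius_nm=40, length_nm=120)
        spec = PhantomSpec(primitives=(prim,), field_of_view_nm=(200, 200))
        vol = rasterize(spec, GridSpec(voxel_nm=2.0, shape=(100, 100, 60)))
        mesh = isosurface(vol, 0.5)
        m = mesh_measures(mesh)
        truth = analytic_measures(prim)
        assert m.volume_nm3 == pytest.approx(truth.volume_nm3, rel=0.03)
        assert m.surface_area_nm2 == pytest.approx(truth.surface_area_nm2, rel=0.05)


class TestSmoothMesh:
    def test_zero_iterations_is_identity(self, sphere_volume):
        vol, _ = sphere_volume
        mesh = isosurface(vol, 0.5)
        out = smooth_mesh(mesh, iterations=0)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.array_equal(out.triangles, mesh.triangles)

    def test_counts_unchanged_and_volume_drift_below_1pct(self, sphere_volume):
        vol, _ = sphere_volume
        mesh = isosurface(vol, 0.5)
        out = smooth_mesh(mesh, iterations=10, strength=0.5)
        assert len(out.vertices) == len(mesh.vertices)
        assert len(out.triangles) == len(mesh.triangles)
        v0 = mesh_measures(mesh).volume_nm3
        v1 = mesh_measures(out).volume_nm3
        assert abs(v1 - v0) / v0 <= 0.01

    def test_noisy_sphere_area_relaxes(self, sphere_volume):
        vol, _ = sphere_volume
        mesh = isosurface(vol, 0.5)
        rng = np.random.default_rng(0)
        noisy = Mesh(mesh.vertices + rng.normal(0, 0.5, mesh.vertices.shape),
                     mesh.triangles, watertight=True)
        areas = [mesh_measures(smooth_mesh(noisy, it)).surface_area_nm2
                 for it in (0, 2, 5, 10)]
        # early iterations remove noise area strictly; later ones plateau
        assert areas[1] < areas[0] and areas[2] < areas[1]
        assert areas[3] <= areas[2] * 1.005

    def test_open_mesh_rejected(self):
        open_mesh = Mesh(vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                         triangles=np.array([[0, 1, 2]]), watertight=False)
        with pytest.raises(ValueError, match="watertight"):
            smooth_mesh(open_mesh, iterations=1)


class TestMeshMeasures:
    def test_unit_cube(self):
        m = mesh_measures(unit_cube_mesh())
        assert m.volume_nm3 == pytest.approx(1.0, rel=1e-12)
        assert m.surface_area_nm2 == pytest.approx(6.0, rel=1e-12)

    def test_regular_tetrahedron(self):
        # vertices of a regular tetrahedron with edge length sqrt(8)
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        edge = math.sqrt(8)
        m = mesh_measures(Mesh(v, f, watertight=True))
        assert m.volume_nm3 == pytest.approx(edge**3 / (6 * math.sqrt(2)), rel=1e-12)
        assert m.surface_area_nm2 == pytest.approx(math.sqrt(3) * edge**2, rel=1e-12)

    def test_icosphere_volume_within_1pct(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        m = mesh_measures(Mesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                               watertight=True))
        assert m.volume_nm3 == pytest.approx(4 * math.pi / 3, rel=0.01)

    def test_agrees_with_trimesh(self, sphere_volume):
        vol, _ = sphere_volume
        mesh = isosurface(vol, 0.5)
        m = mesh_measures(mesh)
        tm = mesh.to_trimesh()
        assert m.volume_nm3 == pytest.approx(abs(tm.volume), rel=1e-9)
        assert m.surface_area_nm2 == pytest.approx(tm.area, rel=1e-9)

    def test_rigid_motion_invariance(self):
        mesh = unit_cube_mesh()
        m0 = mesh_measures(mesh)
        ang = np.deg2rad(33.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = Mesh(mesh.vertices @ R.T + np.array([5.0, -2.0, 7.0]),
                     mesh.triangles, watertight=True)
        m1 = mesh_measures(moved)
        assert m1.volume_nm3 == pytest.approx(m0.volume_nm3, rel=1e-9)
        assert m1.surface_area_nm2 == pytest.approx(m0.surface_area_nm2, rel=1e-9)

    def test_open_mesh_volume_rejected(self):
        open_mesh = Mesh(vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                         triangles=np.array([[0, 1, 2]]), watertight=False)
        with pytest.raises(ValueError, match="watertight"):
            mesh_measures(open_mesh)

    def test_self_intersecting_contour_rejected(self):
        bow = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], float)
        with pytest.raises(ValueError, match="self-intersecting"):
            ContourStack(planes=[(0.0, [bow]), (1.0, [bow])])
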