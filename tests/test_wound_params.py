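import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from woundmetrics.camera_geometry import Plane
from woundmetrics.config import DegenerateInputError, DomainError
from woundmetrics.som_mesh import QuadMesh
from woundmetrics.wound_params import (WoundReport, alpha_shape_area, area_3d,
                                       capped_surface, fit_skin_plane,
                                       main_axes, perimeter_3d,
                                       projected_area, trace_perimeter_2d,
                                       wound_depth, wound_volume)


def hemisphere_mesh(r=10.0, rows=64, cols=64, depth=None):
    """Quad grid exactly on a spherical-cap cavity (sphere radius r,
    cap depth ``depth``): rows = polar rings from the deepest point to the
    rim, cols = azimuth with a duplicated seam column so the mesh closes.
    Depth-positive convention: rim at z = 0, pole at z = depth."""
    depth = r if depth is None else depth
    phi_max = np.arccos(1 - depth / r)
    phi = np.linspace(0, phi_max, rows)[:, None]
    th = np.linspace(0, 2 * np.pi, cols)[None, :]
    x = r * np.sin(phi) * np.cos(th)
    y = r * np.sin(phi) * np.sin(th)
    z = (r * np.cos(phi) - (r - depth)) * np.ones_like(th)
    return QuadMesh(np.stack([x, y, z], axis=-1))


def grid_mesh(xs, ys, fz=lambda x, y: np.zeros_like(x)):
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    return QuadMesh(np.stack([xx, yy, fz(xx, yy)], axis=-1))


class TestSkinPlane:
    def test_exact_plane(self, rng):
        pts = np.column_stack([rng.uniform(-5, 5, (200, 2)),
                               np.full(200, 10.0)])
        plane = fit_skin_plane(pts)
        assert np.abs(plane.signed_distance(pts)).max() < 1e-9
        assert abs(abs(plane.n0[2]) - 1) < 1e-12

    def test_tls_recovery_under_noise(self, rng):
        n_true = np.array([0.1, -0.05, 1.0])
        n_true /= np.linalg.norm(n_true)
        xy = rng.uniform(-20, 20, (1000, 2))
        pts = np.column_stack([xy, (3.0 - xy @ n_true[:2]) / n_true[2]])
        pts += rng.normal(0, 0.1, pts.shape)
        plane = fit_skin_plane(pts)
        cosang = abs(plane.n0 @ n_true)
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 1.0
        rms = np.sqrt((plane.signed_distance(pts) ** 2).mean())
        assert rms == pytest.approx(0.1, rel=0.15)

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(3.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateInputError):
            fit_skin_plane(pts)

    def test_orientation_follows_wound(self, rng):
        skin = np.column_stack([rng.uniform(-5, 5, (100, 2)), np.zeros(100)])
        wound = np.array([[0.0, 0.0, 2.0]])
        plane = fit_skin_plane(skin, wound)
        assert plane.signed_distance(wound)[0] > 0


class TestDepth:
    def test_flat_wound_zero(self):
        mesh = grid_mesh(np.linspace(0, 5, 8), np.linspace(0, 5, 8))
        assert wound_depth(mesh, Plane(n0=[0, 0, 1], d0=0.0)) == 0.0

    def test_hemisphere_depth(self):
        mesh = hemisphere_mesh(r=6.0)
        plane = Plane(n0=[0, 0, 1], d0=0.0)
        assert wound_depth(mesh, plane) == pytest.approx(6.0, abs=0.01)

    def test_equals_bruteforce_max(self, rng):
        v = rng.normal(0, 3, (10, 12, 3))
        mesh = QuadMesh(v)
        plane = Plane(n0=[0.2, 0.1, 1.0], d0=-1.0)
        brute = max(0.0, max(plane.signed_distance(p)
                             for p in v.reshape(-1, 3)))
        assert wound_depth(mesh, plane) == pytest.approx(brute, abs=1e-12)


class TestTracePerimeter:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        b = trace_perimeter_2d(m)
        assert b.shape == (1, 2) and tuple(b[0]) == (2, 2)

    @pytest.mark.parametrize("w,h", [(5, 3), (10, 7), (2, 2)])
    def test_rectangle_boundary_count(self, w, h):
        m = np.zeros((h + 4, w + 4), bool)
        m[2:2 + h, 2:2 + w] = True
        b = trace_perimeter_2d(m)
        assert len(b) == 2 * w + 2 * h - 4

    def test_boundary_is_a_cycle(self):
        m = np.zeros((30, 30), bool)
        yy, xx = np.mgrid[:30, :30]
        m[(xx - 15) ** 2 + (yy - 14) ** 2 < 100] = True
        b = trace_perimeter_2d(m)
        steps = np.abs(np.diff(np.vstack([b, b[:1]]), axis=0))
        assert steps.max() <= 1  # 8-connected chain incl. closing step

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            trace_perimeter_2d(np.zeros((5, 5), bool))


class TestPerimeter3d:
    def _planar_scene(self, mask, spacing):
        H, W = mask.shape
        pm = np.arange(H * W).reshape(H, W)
        xx, yy = np.meshgrid(np.arange(W) * spacing, np.arange(H) * spacing)
        pts = np.stack([xx.ravel(), yy.ravel(), np.zeros(H * W)], 1)
        return pm, pts

    def test_circle_circumference(self):
        spacing = 0.2
        H = W = 240
        yy, xx = np.mgrid[:H, :W]
        mask = ((xx - 120.0) ** 2 + (yy - 120.0) ** 2) <= 100.0 ** 2  # r=20mm
        pm, pts = self._planar_scene(mask, spacing)
        b = trace_perimeter_2d(mask)
        p = perimeter_3d(b, pm, pts, outward_offset=spacing / 2)
        assert p == pytest.approx(2 * np.pi * 20, rel=0.02)

    def test_square_perimeter(self):
        spacing = 0.2
        mask = np.zeros((80, 80), bool)
        mask[15:65, 15:65] = True  # 10 x 10 mm
        pm, pts = self._planar_scene(mask, spacing)
        b = trace_perimeter_2d(mask)
        p = perimeter_3d(b, pm, pts, outward_offset=spacing / 2)
        assert p == pytest.approx(40.0, rel=0.02)

    def test_scaling_homogeneity(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 15:45] = True
        pm, pts = self._planar_scene(mask, 0.25)
        b = trace_perimeter_2d(mask)
        p1 = perimeter_3d(b, pm, pts, smooth_sigma=0.0)
        p2 = perimeter_3d(b, pm, pts * 2, smooth_sigma=0.0)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_too_few_lifted_points(self):
        pm = -np.ones((10, 10), dtype=int)
        with pytest.raises(DomainError):
            perimeter_3d(np.array([[1, 1], [2, 2], [3, 3]]), pm,
                         np.zeros((0, 3)))


class TestArea3d:
    def test_flat_unit_square(self):
        mesh = grid_mesh(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert area_3d(mesh) == pytest.approx(1.0, abs=1e-12)

    def test_hemisphere_zone_area(self):
        mesh = hemisphere_mesh(r=10.0, rows=64, cols=64)
        assert area_3d(mesh) == pytest.approx(2 * np.pi * 100, rel=0.02)

    def test_matches_triangulation_oracle(self):
        mesh = hemisphere_mesh(r=10.0, rows=64, cols=64)
        tm = mesh.to_trimesh()
        assert area_3d(mesh) == pytest.approx(tm.area, rel=0.01)
        flat = grid_mesh(np.linspace(0, 2, 6), np.linspace(0, 3, 7))
        assert area_3d(flat) == pytest.approx(flat.to_trimesh().area,
                                              rel=1e-12)


class TestProjectedArea:
    def test_unit_square(self, rng):
        pts2 = rng.uniform(0, 1, (4000, 2))
        area, _ = alpha_shape_area(pts2, alpha=0.2)
        assert area == pytest.approx(1.0, rel=0.02)

    def test_disk_area(self, rng):
        r = np.sqrt(rng.uniform(0, 1, 20000)) * 15
        th = rng.uniform(0, 2 * np.pi, 20000)
        pts3 = np.stack([r * np.cos(th), r * np.sin(th), np.zeros(20000)], 1)
        a = projected_area(pts3, Plane(n0=[0, 0, 1], d0=0.0))
        assert a == pytest.approx(np.pi * 15 ** 2, rel=0.02)

    def test_alpha_shape_bounded_by_hull(self, rng):
        pts2 = rng.normal(0, 3, (2000, 2))
        hull = ConvexHull(pts2).volume  # 2D: volume == area
        a_small, _ = alpha_shape_area(pts2, alpha=1.0)
        a_inf, _ = alpha_shape_area(pts2, alpha=1e9)
        assert a_small <= hull + 1e-9
        assert a_inf == pytest.approx(hull, rel=1e-9)

    def test_tilted_plane_projection(self, rng):
        # unit disk tilted 30 degrees: projected area on its own plane = pi
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        r = np.sqrt(rng.uniform(0, 1, 8000))
        th = rng.uniform(0, 2 * np.pi, 8000)
        pts = np.stack([r * np.cos(th), r * np.sin(th), np.zeros(8000)], 1) @ R.T
        plane = Plane(n0=R[:, 2], d0=0.0)
        assert projected_area(pts, plane) == pytest.approx(np.pi, rel=0.02)


class TestMainAxes:
    def test_rectangle_extents(self, rng):
        pts = np.stack([rng.uniform(0, 20, 8000), rng.uniform(0, 10, 8000),
                        np.zeros(8000)], 1)
        amaj, amin, _ = main_axes(pts, Plane(n0=[0, 0, 1], d0=0.0))
        assert amaj == pytest.approx(20, rel=0.02)
        assert amin == pytest.approx(10, rel=0.02)

    def test_in_plane_rotation_invariance(self, rng):
        base = np.stack([rng.uniform(0, 20, 8000), rng.uniform(0, 10, 8000),
                         np.zeros(8000)], 1)
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        a1 = main_axes(base, Plane(n0=[0, 0, 1], d0=0.0))[:2]
        a2 = main_axes(base @ R.T, Plane(n0=[0, 0, 1], d0=0.0))[:2]
        assert np.allclose(a1, a2, rtol=0.02)

    def test_isotropic_disk(self, rng):
        r = np.sqrt(rng.uniform(0, 1, 20000)) * 7
        th = rng.uniform(0, 2 * np.pi, 20000)
        pts = np.stack([r * np.cos(th), r * np.sin(th), np.zeros(20000)], 1)
        amaj, amin, _ = main_axes(pts, Plane(n0=[0, 0, 1], d0=0.0))
        assert amaj == pytest.approx(amin, rel=0.03)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            main_axes(np.zeros((10, 3)), Plane(n0=[0, 0, 1], d0=0.0))


class TestVolume:
    def test_flat_wound_zero(self):
        mesh = grid_mesh(np.linspace(0, 5, 8), np.linspace(0, 5, 8))
        assert wound_volume(mesh, Plane(n0=[0, 0, 1], d0=0.0)) == 0.0

    def test_hemisphere_cap_volume(self):
        mesh = hemisphere_mesh(r=6.0, rows=96, cols=96)
        plane = Plane(n0=[0, 0, 1], d0=0.0)
        v = wound_volume(mesh, plane)
        assert v == pytest.approx(2 / 3 * np.pi * 6 ** 3, rel=0.03)

    def test_monte_carlo_oracle(self, rng):
        # independent MC estimate of the capped hemisphere region
        r = 6.0
        mesh = hemisphere_mesh(r=r, rows=96, cols=96)
        plane = Plane(n0=[0, 0, 1], d0=0.0)
        v_mesh = wound_volume(mesh, plane)
        box_lo, box_hi = np.array([-r, -r, 0.0]), np.array([r, r, r])
        pts = rng.uniform(box_lo, box_hi, (100000, 3))
        rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        inside = pts[:, 2] <= np.sqrt(np.maximum(r * r - rho2, 0))
        inside &= rho2 <= r * r
        v_mc = inside.mean() * np.prod(box_hi - box_lo)
        assert v_mesh == pytest.approx(v_mc, rel=0.02)

    def test_capped_surface_watertight(self):
        mesh = hemisphere_mesh(r=5.0, rows=32, cols=32)
        m = capped_surface(mesh, Plane(n0=[0, 0, 1], d0=0.0))
        assert m.is_watertight


class TestReportInvariants:
    def test_axis_ordering_enforced(self):
        with pytest.raises(DomainError):
            WoundReport(1, 1, 1, 1, axis_major_mm=2, axis_minor_mm=5,
                        volume_mm3=1)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            WoundReport(-1, 1, 1, 1, 2, 1, 1)


class TestGeometricInvariance:
    """Homogeneity and rigid invariance of all six parameters."""

    def _setup(self, rng):
        mesh = hemisphere_mesh(r=6.0, rows=48, cols=48)
        plane = Plane(n0=[0, 0, 1], d0=0.0)
        r = np.sqrt(rng.uniform(0, 1, 5000)) * 6
        th = rng.uniform(0, 2 * np.pi, 5000)
        pts = np.stack([r * np.cos(th), r * np.sin(th), np.zeros(5000)], 1)
        return mesh, plane, pts

    def _params(self, mesh, plane, pts):
        return np.array([
            wound_depth(mesh, plane),
            area_3d(mesh),
            wound_volume(mesh, plane),
            projected_area(pts, plane),
            *main_axes(pts, plane)[:2],
        ])

    def test_homogeneity_s2(self, rng):
        mesh, plane, pts = self._setup(rng)
        base = self._params(mesh, plane, pts)
        mesh2 = QuadMesh(mesh.vertices * 2)
        plane2 = Plane(n0=plane.n0, d0=plane.d0 * 2)
        scaled = self._params(mesh2, plane2, pts * 2)
        expected = base * np.array([2, 4, 8, 4, 2, 2])
        assert np.allclose(scaled, expected, rtol=1e-6)

    def test_rigid_invariance(self, rng):
        mesh, plane, pts = self._setup(rng)
        base = self._params(mesh, plane, pts)
        R = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        t = np.array([7.0, -3.0, 15.0])
        mesh2 = QuadMesh(mesh.vertices @ R.T + t)
        n2 = R @ plane.n0
        plane2 = Plane(n0=n2, d0=plane.d0 + t @ n2)
        moved = self._params(mesh2, plane2, pts @ R.T + t)
        assert np.allclose(moved, base, rtol=1e-3)

    def test_area3d_at_least_projected(self, rng):
        mesh, plane, pts = self._setup(rng)
        # the cap surface is larger than its planar footprint
        assert area_3d(mesh) >= projected_area(pts, plane)
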