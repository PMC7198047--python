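import numpy as np
import pytest

from woundmetrics.camera_geometry import (DisparityMap, PinholeCamera, Plane,
                                          StereoRig, back_project_ray,
                                          calibrate_projector, disparity_ncc,
                                          project_point, ray_plane_intersect,
                                          reconstruction_resolution,
                                          rectify_pair, triangulate_rectified)
from woundmetrics.config import DegenerateInputError, DomainError


def make_cam(fx=1000.0, fy=1000.0, cx=500.0, cy=500.0, w=1000, h=1000, dist=()):
    return PinholeCamera(fx, fy, cx, cy, w, h, dist)


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self):
        cam = make_cam()
        for z in (1.0, 57.3, 4000.0):
            assert np.allclose(project_point(cam, np.array([0, 0, z])),
                               (cam.cx, cam.cy))

    def test_similar_triangles(self):
        cam = make_cam()
        uv = project_point(cam, np.array([10.0, 0.0, 100.0]))
        assert np.allclose(uv, (600.0, 500.0))

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(DomainError):
            project_point(make_cam(), np.array([0.0, 0.0, -1.0]))

    @pytest.mark.parametrize("dist", [(), (-0.1, 0.02, 0.001, -0.001, 0.0)])
    def test_project_backproject_roundtrip(self, rng, dist):
        cam = make_cam(dist=dist)
        pts = rng.uniform([-20, -20, 80], [20, 20, 300], (50, 3))
        uv = project_point(cam, pts)
        rays = back_project_ray(cam, uv)
        # the ray through the pixel must pass within 1e-9 mm of the point
        t = (pts * rays).sum(1) / (rays * rays).sum(1)
        closest = rays * t[:, None]
        assert np.abs(closest - pts).max() < 1e-9

    def test_fov_consistency(self):
        cam = PinholeCamera.from_fov(80.0, 54.0, 2208, 1242)
        assert cam.fov_h == pytest.approx(80.0, rel=1e-9)
        assert np.isclose(cam.fx, 2208 / (2 * np.tan(np.radians(40))))


class TestTriangulation:
    def test_depth_from_disparity(self):
        cam = make_cam(fx=1315.0, fy=1315.0)
        rig = StereoRig(cam, cam, baseline_mm=45.0)
        p = triangulate_rectified(rig, np.array([500.0, 500.0]), 236.7)
        assert p[2] == pytest.approx(250.0, abs=0.1)

    def test_project_triangulate_roundtrip(self, rng):
        cam = make_cam(fx=1315.0, fy=1315.0)
        rig = StereoRig(cam, cam, baseline_mm=45.0)
        pts = rng.uniform([-30, -30, 150], [30, 30, 350], (40, 3))
        uv_l = project_point(rig.left, pts)
        uv_r = project_point(rig.right, pts - [rig.baseline_mm, 0, 0])
        disp = uv_l[:, 0] - uv_r[:, 0]
        rec = triangulate_rectified(rig, uv_l, disp)
        assert np.abs(rec - pts).max() < 1e-6

    def test_double_disparity_halves_depth(self):
        cam = make_cam()
        rig = StereoRig(cam, cam, baseline_mm=45.0)
        z1 = triangulate_rectified(rig, np.array([500.0, 500.0]), 30.0)[2]
        z2 = triangulate_rectified(rig, np.array([500.0, 500.0]), 60.0)[2]
        assert z1 == 2 * z2

    def test_nonpositive_disparity_rejected(self):
        cam = make_cam()
        rig = StereoRig(cam, cam, baseline_mm=45.0)
        with pytest.raises(DomainError):
            triangulate_rectified(rig, np.array([500.0, 500.0]), 0.0)


class TestResolution:
    def test_lateral_from_fov(self):
        cam = PinholeCamera.from_fov(90.0, 90.0, 1000, 1000)
        rig = StereoRig(cam, cam, baseline_mm=45.0,
                        working_distance_mm=(50, 400))
        dx, dy, _ = reconstruction_resolution(rig, 100.0)
        assert dx == pytest.approx(0.2, rel=1e-6)

    def test_depth_resolution_value(self):
        cam = make_cam()
        rig = StereoRig(cam, cam, baseline_mm=45.0,
                        working_distance_mm=(150, 350))
        _, _, dz = reconstruction_resolution(rig, 250.0)
        assert dz == pytest.approx(1.3889, abs=1e-4)

    def test_depth_scales_quadratically_lateral_linearly(self):
        cam = make_cam()
        rig = StereoRig(cam, cam, baseline_mm=45.0,
                        working_distance_mm=(100, 500))
        r1 = reconstruction_resolution(rig, 150.0)
        r2 = reconstruction_resolution(rig, 300.0)
        assert r2[2] == pytest.approx(4 * r1[2])
        assert r2[0] == pytest.approx(2 * r1[0])
        assert r2[1] == pytest.approx(2 * r1[1])
        assert all(v > 0 for v in r1 + r2)

    def test_out_of_range_warns(self):
        cam = make_cam()
        rig = StereoRig(cam, cam, baseline_mm=45.0)
        with pytest.warns(UserWarning):
            reconstruction_resolution(rig, 10.0)


class TestRectification:
    def _yawed_rig(self, deg):
        from scipy.spatial.transform import Rotation
        cam = make_cam()
        R = Rotation.from_euler("y", deg, degrees=True).as_matrix()
        T = R @ np.array([-45.0, 0.0, 0.0])
        return StereoRig(cam, cam, baseline_mm=45.0, rotation=R, translation=T)

    def test_parallel_rig_identity(self, rng):
        cam = make_cam()
        rig = StereoRig(cam, cam, baseline_mm=45.0)
        img = rng.uniform(0, 255, (1000, 1000)).astype(np.uint8)
        l, r, rect_rig, _ = rectify_pair(img, img, rig)
        assert l.shape == img.shape and r.shape == img.shape
        assert rect_rig.is_parallel
        # identity mapping up to interpolation at the borders
        assert np.mean(np.abs(l[5:-5, 5:-5].astype(float) -
                              img[5:-5, 5:-5])) < 1.0

    def test_yawed_rig_epipolar_error(self, rng):
        rig = self._yawed_rig(2.0)
        pts = rng.uniform([-20, -20, 180], [20, 20, 300], (20, 3))
        uv_l = project_point(rig.left, pts)
        uv_r = project_point(rig.right, pts @ rig.rotation.T + rig.translation)
        img = np.zeros((1000, 1000), np.uint8)
        _, _, _, (Hl, Hr) = rectify_pair(img, img, rig)

        def warp_px(H, uv):
            uvh = np.hstack([uv, np.ones((len(uv), 1))]) @ H.T
            return uvh[:, :2] / uvh[:, 2:]

        rl, rr = warp_px(Hl, uv_l), warp_px(Hr, uv_r)
        assert np.abs(rl[:, 1] - rr[:, 1]).max() < 0.1  # same row

    def test_coincident_centres_rejected(self):
        cam = make_cam()
        rig = StereoRig(cam, cam, baseline_mm=45.0)
        rig.translation = np.zeros(3)
        with pytest.raises(DegenerateInputError):
            rectify_pair(np.zeros((10, 10)), np.zeros((10, 10)), rig)


class TestDisparityNCC:
    def test_identical_images_zero_disparity(self, rng):
        img = rng.uniform(0, 255, (60, 120))
        dm = disparity_ncc(img, img, window=7, search_range=(0, 20))
        assert dm.valid.any()
        assert np.allclose(dm.values[dm.valid], 0.0, atol=1e-6)

    def test_constructed_shift_recovered(self, rng):
        img = rng.uniform(0, 255, (80, 200))
        right = np.roll(img, -7, axis=1)  # feature moves left by 7 px
        dm = disparity_ncc(img, right, window=9, search_range=(0, 20))
        inner = dm.valid.copy()
        inner[:, :20] = inner[:, -20:] = False  # avoid wrap region
        med = np.median(dm.values[inner])
        assert med == pytest.approx(7.0, abs=0.1)

    def test_uniform_images_all_invalid(self):
        img = np.full((40, 80), 128.0)
        dm = disparity_ncc(img, img, window=7, search_range=(0, 10))
        assert not dm.valid.any()

    def test_search_range_exceeding_width_rejected(self):
        with pytest.raises(DomainError):
            disparity_ncc(np.zeros((10, 20)), np.zeros((10, 20)),
                          window=5, search_range=(0, 30))

    def test_shape_mismatch_in_map(self):
        with pytest.raises(DomainError):
            DisparityMap(np.zeros((4, 4)), np.zeros((4, 5), bool))


class TestRayPlane:
    def test_axis_ray(self):
        p = ray_plane_intersect(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                                Plane(n0=[0, 0, 1], d0=100.0))
        assert np.allclose(p, [0, 0, 100])

    def test_reprojection_roundtrip(self, rng):
        cam = make_cam()
        plane = Plane(n0=[0.1, -0.2, 1.0], d0=210.0)
        uv = rng.uniform(100, 900, (30, 2))
        rays = back_project_ray(cam, uv)
        pts = ray_plane_intersect(np.zeros((30, 3)), rays, plane)
        uv2 = project_point(cam, pts)
        assert np.abs(uv2 - uv).max() < 1e-9

    def test_parallel_ray_rejected(self):
        with pytest.raises(DomainError):
            ray_plane_intersect(np.zeros(3), np.array([1.0, 0.0, 0.0]),
                                Plane(n0=[0, 0, 1], d0=10.0))


class TestProjectorCalibration:
    def _synthetic(self, rng, noise=0.0):
        from scipy.spatial.transform import Rotation
        true_cam = PinholeCamera(1600.0, 1590.0, 420.0, 235.0, 854, 480)
        R = Rotation.from_euler("xyz", [3, -12, 1], degrees=True).as_matrix()
        t = np.array([-48.0, 3.0, 12.0])
        pts3d, pix = [], []
        for k, (nz, d0) in enumerate([((0.0, 0.0, 1.0), 200.0),
                                      ((0.2, 0.0, 1.0), 230.0),
                                      ((0.0, -0.25, 1.0), 180.0)]):
            plane = Plane(n0=np.array(nz), d0=d0)
            uu, vv = np.meshgrid(np.linspace(100, 750, 8),
                                 np.linspace(60, 420, 5))
            uv = np.stack([uu.ravel(), vv.ravel()], 1)
            rays_p = back_project_ray(true_cam, uv)
            rays_c = rays_p @ R  # into reference-camera frame
            origin = -R.T @ t
            pts = ray_plane_intersect(np.broadcast_to(origin, rays_c.shape),
                                      rays_c, plane)
            pts3d.append(pts)
            pix.append(uv + rng.normal(0, noise, uv.shape) if noise else uv)
        return true_cam, R, t, pts3d, pix

    def test_noiseless_recovery(self, rng):
        true_cam, R, t, pts3d, pix = self._synthetic(rng)
        model = calibrate_projector(pts3d, pix, (854, 480))
        assert model.intrinsics.fx == pytest.approx(true_cam.fx, rel=1e-3)
        assert model.intrinsics.fy == pytest.approx(true_cam.fy, rel=1e-3)
        assert np.abs(model.translation - t).max() < 0.01
        angle = np.degrees(np.arccos(np.clip(
            (np.trace(model.rotation @ R.T) - 1) / 2, -1, 1)))
        assert angle < 0.01
        assert model.rms_px < 1e-6

    def test_noise_floor(self, rng):
        _, _, _, pts3d, pix = self._synthetic(rng, noise=0.2)
        model = calibrate_projector(pts3d, pix, (854, 480))
        assert model.rms_px <= 3 * 0.2

    def test_reported_rms_is_self_consistent(self, rng):
        _, _, _, pts3d, pix = self._synthetic(rng, noise=0.3)
        model = calibrate_projector(pts3d, pix, (854, 480))
        pts = np.vstack(pts3d)
        uv = np.vstack(pix)
        pc = pts @ model.rotation.T + model.translation
        uv2 = project_point(model.intrinsics, pc)
        rms = np.sqrt(np.mean(np.sum((uv2 - uv) ** 2, axis=1)))
        assert rms == pytest.approx(model.rms_px, rel=1e-6)

    def test_single_plane_rank_deficient(self, rng):
        _, _, _, pts3d, pix = self._synthetic(rng)
        with pytest.raises(DegenerateInputError):
            calibrate_projector(pts3d[0], pix[0], (854, 480))
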