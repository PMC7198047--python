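"""Pinhole, stereo, and projector geometry.

Conventions (used everywhere in the package):

* pixel coordinates ``(u, v)`` are 0-based with the origin at the centre of
  the top-left pixel, ``u`` growing right (columns) and ``v`` down (rows);
* camera frames are right-handed with ``+z`` forward into the scene; the
  reference frame is the **left** camera;
* the stereo extrinsics map left-frame coordinates into the right camera,
  ``x_r = R x_l + T``; for the parallel rig ``R = I`` and ``T = (-b, 0, 0)``
  with baseline ``b`` in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from skimage.transform import ProjectiveTransform, warp

from .config import DegenerateInputError, DomainError, logger


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PinholeCamera:
    """Ideal or distorted pinhole camera.

    ``dist`` holds radial/tangential coefficients ``(k1, k2, p1, p2, k3)``
    (any prefix accepted, empty means ideal pinhole).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    dist: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise DomainError("focal length must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise DomainError("principal point must lie inside the image")

    @property
    def fov_h(self) -> float:
        """Horizontal field of view, degrees."""
        return float(np.degrees(2 * np.arctan(self.width / (2 * self.fx))))

    @property
    def fov_v(self) -> float:
        """Vertical field of view, degrees."""
        return float(np.degrees(2 * np.arctan(self.height / (2 * self.fy))))

    @classmethod
    def from_fov(cls, fov_h_deg: float, fov_v_deg: float, width: int,
                 height: int, dist: tuple[float, ...] = ()) -> "PinholeCamera":
        """Build a camera from nominal fields of view, f = C / (2 tan(FOV/2))."""
        fx = width / (2 * np.tan(np.radians(fov_h_deg) / 2))
        fy = height / (2 * np.tan(np.radians(fov_v_deg) / 2))
        return cls(fx, fy, (width - 1) / 2, (height - 1) / 2, width, height, dist)

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> None:
    R = np.asarray(R, float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=tol) \
            or np.linalg.det(R) < 0:
        raise DomainError("rotation must be orthonormal with det = +1")


@dataclass
class StereoRig:
    """Calibrated stereo pair; ``x_right = rotation @ x_left + translation``."""

    left: PinholeCamera
    right: PinholeCamera
    baseline_mm: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray | None = None
    working_distance_mm: tuple[float, float] = (150.0, 350.0)

    def __post_init__(self) -> None:
        if self.baseline_mm <= 0:
            raise DomainError("baseline must be positive")
        self.rotation = np.asarray(self.rotation, float)
        _check_rotation(self.rotation)
        if self.translation is None:
            self.translation = np.array([-self.baseline_mm, 0.0, 0.0])
        self.translation = np.asarray(self.translation, float)

    @property
    def is_parallel(self) -> bool:
        return bool(np.allclose(self.rotation, np.eye(3), atol=1e-9))


@dataclass
class ProjectorModel:
    """Projector as an inverse camera: intrinsics + pose in the left camera.

    ``x_proj = rotation @ x_cam + translation`` maps reference-camera
    coordinates into the projector frame.
    """

    intrinsics: PinholeCamera
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rms_px: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        _check_rotation(self.rotation)


@dataclass
class DisparityMap:
    """Per-pixel disparity of the rectified reference (left) image."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise DomainError("disparity and validity mask shapes differ")


@dataclass
class Plane:
    """Plane in Hessian normal form: p . n0 - d0 = 0, ||n0|| = 1."""

    n0: np.ndarray
    d0: float

    def __post_init__(self) -> None:
        self.n0 = np.asarray(self.n0, float)
        n = np.linalg.norm(self.n0)
        if n < 1e-12:
            raise DegenerateInputError("plane normal has zero length")
        self.d0 = float(self.d0 / n)
        self.n0 = self.n0 / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.n0 - self.d0


# ---------------------------------------------------------------------------
# projection and triangulation
# ---------------------------------------------------------------------------

def _apply_distortion(xn: np.ndarray, yn: np.ndarray,
                      dist: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    k1, k2, p1, p2, k3 = (tuple(dist) + (0.0,) * 5)[:5]
    r2 = xn * xn + yn * yn
    radial = 1 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
    xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
    yd = yn * radial + p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
    return xd, yd


def project_point(camera: PinholeCamera, point: np.ndarray) -> np.ndarray:
    """Project 3D point(s) in the camera frame (mm) to pixel coordinates.

    Raises :class:`DomainError` if any point has non-positive depth.
    """
    p = np.atleast_2d(np.asarray(point, float))
    if np.any(p[:, 2] <= 0):
        raise DomainError("point depth must be positive for projection")
    xn, yn = p[:, 0] / p[:, 2], p[:, 1] / p[:, 2]
    if camera.dist:
        xn, yn = _apply_distortion(xn, yn, camera.dist)
    uv = np.stack([camera.fx * xn + camera.cx, camera.fy * yn + camera.cy], axis=1)
    return uv[0] if np.asarray(point).ndim == 1 else uv


def back_project_ray(camera: PinholeCamera, pixel: np.ndarray) -> np.ndarray:
    """Unit direction of the viewing ray through ``pixel`` (camera frame).

    Inverts the distortion numerically if coefficients are present.
    """
    uv = np.atleast_2d(np.asarray(pixel, float))
    xd = (uv[:, 0] - camera.cx) / camera.fx
    yd = (uv[:, 1] - camera.cy) / camera.fy
    if camera.dist:
        xn, yn = xd.copy(), yd.copy()
        for _ in range(25):  # fixed-point undistortion
            xdd, ydd = _apply_distortion(xn, yn, camera.dist)
            xn, yn = xn + (xd - xdd), yn + (yd - ydd)
    else:
        xn, yn = xd, yd
    d = np.stack([xn, yn, np.ones_like(xn)], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d[0] if np.asarray(pixel).ndim == 1 else d


def triangulate_rectified(rig: StereoRig, pix_left: np.ndarray,
                          disparity: np.ndarray) -> np.ndarray:
    """Triangulate rectified left pixel(s) + disparity: Z = f b / d.

    ``disparity`` must be positive; the rig must be parallel (rectified).
    """
    if not rig.is_parallel:
        raise DomainError("rig must be rectified (parallel) for this triangulation")
    d = np.atleast_1d(np.asarray(disparity, float))
    if np.any(d <= 0):
        raise DomainError("disparity must be positive for a valid match")
    uv = np.atleast_2d(np.asarray(pix_left, float))
    cam = rig.left
    Z = cam.fx * rig.baseline_mm / d
    X = (uv[:, 0] - cam.cx) * Z / cam.fx
    Y = (uv[:, 1] - cam.cy) * Z / cam.fy
    pts = np.stack([X, Y, Z], axis=1)
    return pts[0] if np.asarray(pix_left).ndim == 1 else pts


def reconstruction_resolution(rig: StereoRig, D: float) -> tuple[float, float, float]:
    """Lateral and depth resolution (mm) of the rig at working distance ``D``.

    dX = 2 D tan(FOV_H/2) / C_H, dY = 2 D tan(FOV_V/2) / C_V,
    dZ = D^2 / (f b).  Warns (but still computes) outside the working range.
    """
    lo, hi = rig.working_distance_mm
    if not (lo <= D <= hi):
        warnings.warn(f"working distance {D} mm outside range [{lo}, {hi}] mm")
    cam = rig.left
    dx = 2 * D * np.tan(np.radians(cam.fov_h) / 2) / cam.width
    dy = 2 * D * np.tan(np.radians(cam.fov_v) / 2) / cam.height
    dz = D ** 2 / (cam.fx * rig.baseline_mm)
    return float(dx), float(dy), float(dz)


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

def rectifying_rotation(rig: StereoRig) -> np.ndarray:
    """Common rotation aligning both cameras' x-axes with the baseline."""
    c2 = -rig.rotation.T @ rig.translation  # right centre in left frame
    if np.linalg.norm(c2) < 1e-9:
        raise DegenerateInputError("coincident camera centres")
    x = c2 / np.linalg.norm(c2)
    if x[0] < 0:
        x = -x
    z_old = np.array([0.0, 0.0, 1.0])
    y = np.cross(z_old, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.stack([x, y, z])  # rows are the new axes


def rectify_pair(left_img: np.ndarray, right_img: np.ndarray,
                 rig: StereoRig) -> tuple[np.ndarray, np.ndarray, StereoRig, list[np.ndarray]]:
    """Undistort + rectify a stereo pair.

    Returns ``(left_rect, right_rect, rect_rig, [H_left, H_right])`` where the
    homographies map original pixel coordinates to rectified ones.  After
    rectification corresponding points share the image row and the rig is
    parallel with an x-only translation.
    """
    if left_img.shape[:2] != right_img.shape[:2]:
        raise DomainError("stereo images must share dimensions")
    Rrect = rectifying_rotation(rig)
    Knew = rig.left.K.copy()
    Knew[1, 1] = Knew[0, 0] = (rig.left.fx + rig.left.fy) / 2

    out = []
    homos = []
    for img, cam, Rcam in ((left_img, rig.left, np.eye(3)),
                           (right_img, rig.right, rig.rotation)):
        H = Knew @ Rrect @ Rcam.T @ np.linalg.inv(cam.K)
        homos.append(H)
        tf = ProjectiveTransform(matrix=H)
        out.append(warp(img, tf.inverse, preserve_range=True,
                        output_shape=img.shape[:2]).astype(img.dtype))

    b_new = float(np.linalg.norm(rig.rotation.T @ rig.translation))
    cam_new = PinholeCamera(Knew[0, 0], Knew[1, 1], Knew[0, 2], Knew[1, 2],
                            rig.left.width, rig.left.height)
    rect_rig = StereoRig(cam_new, cam_new, b_new, np.eye(3),
                         np.array([-b_new, 0.0, 0.0]), rig.working_distance_mm)
    return out[0], out[1], rect_rig, homos


# ---------------------------------------------------------------------------
# dense matching
# ---------------------------------------------------------------------------

def disparity_ncc(left: np.ndarray, right: np.ndarray, window: int = 11,
                  search_range: tuple[int, int] = (0, 64),
                  ncc_threshold: float = 0.7) -> DisparityMap:
    """Row-wise block matching by zero-normalized cross-correlation.

    For each left pixel the integer disparity maximizing the windowed NCC is
    refined to sub-pixel precision with a 3-point parabola fit over the
    correlation peak.  Low-texture windows and weak peaks are masked invalid.
    """
    if window % 2 == 0 or window < 3:
        raise DomainError("window must be odd and >= 3")
    d_lo, d_hi = search_range
    if d_hi - d_lo >= left.shape[1]:
        raise DomainError("search range exceeds image width")
    L = np.asarray(left, float)
    R = np.asarray(right, float)
    if L.ndim == 3:
        L, R = L.mean(axis=2), R.mean(axis=2)

    size = (window, window)
    Lm = ndimage.uniform_filter(L, size)
    Ls = np.sqrt(np.maximum(ndimage.uniform_filter(L * L, size) - Lm ** 2, 0))
    n_d = d_hi - d_lo + 1
    corr = np.full((n_d,) + L.shape, -np.inf)
    for i, d in enumerate(range(d_lo, d_hi + 1)):
        Rs = np.roll(R, d, axis=1)  # right feature sits d pixels left of left feature
        Rm = ndimage.uniform_filter(Rs, size)
        Rsd = np.sqrt(np.maximum(ndimage.uniform_filter(Rs * Rs, size) - Rm ** 2, 0))
        cov = ndimage.uniform_filter(L * Rs, size) - Lm * Rm
        denom = Ls * Rsd
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(denom > 1e-12, cov / np.maximum(denom, 1e-12), -np.inf)
        if d > 0:
            c[:, :d] = -np.inf  # wrapped columns are invalid
        corr[i] = c

    best = np.argmax(corr, axis=0)
    peak = np.take_along_axis(corr, best[None], axis=0)[0]
    texture_ok = Ls > 1e-6
    valid = np.isfinite(peak) & (peak >= ncc_threshold) & texture_ok

    # sub-pixel parabola over the peak
    ii, jj = np.nonzero(valid)
    b = best[ii, jj]
    disp = (d_lo + b).astype(float)
    inner = (b > 0) & (b < n_d - 1)
    i2, j2, b2 = ii[inner], jj[inner], b[inner]
    c0 = corr[b2 - 1, i2, j2]
    c1 = corr[b2, i2, j2]
    c2 = corr[b2 + 1, i2, j2]
    denom = c0 - 2 * c1 + c2
    ok = np.isfinite(c0) & np.isfinite(c2) & (np.abs(denom) > 1e-12)
    shift = np.zeros_like(c1)
    shift[ok] = 0.5 * (c0[ok] - c2[ok]) / denom[ok]
    shift = np.clip(shift, -0.5, 0.5)
    disp_inner = disp[inner] + shift
    disp[inner] = disp_inner

    values = np.zeros_like(L)
    values[ii, jj] = disp
    valid &= ~(values < 0)
    return DisparityMap(values=values, valid=valid)


# ---------------------------------------------------------------------------
# ray-plane intersection and projector calibration
# ---------------------------------------------------------------------------

def ray_plane_intersect(origin: np.ndarray, direction: np.ndarray,
                        plane: Plane) -> np.ndarray:
    """Intersect ray(s) ``origin + t * direction`` (t >= 0) with a plane."""
    o = np.atleast_2d(np.asarray(origin, float))
    d = np.atleast_2d(np.asarray(direction, float))
    denom = d @ plane.n0
    if np.any(np.abs(denom) <= 1e-9):
        raise DomainError("ray is parallel to the plane: no intersection")
    t = (plane.d0 - o @ plane.n0) / denom
    pts = o + t[:, None] * d
    return pts[0] if np.asarray(origin).ndim == 1 else pts


def _dlt_projection(points3d: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    n = len(points3d)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([points3d, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -pixels[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -pixels[:, 1:2] * Xh
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-8 * s[0]:
        raise DegenerateInputError(
            "correspondences are rank-deficient (all points coplanar?)")
    return Vt[-1].reshape(3, 4)


def calibrate_projector(points3d: np.ndarray | list, pixels: np.ndarray | list,
                        image_size: tuple[int, int]) -> ProjectorModel:
    """Calibrate projector intrinsics + pose from 3D<->pixel correspondences.

    ``points3d`` are mm positions in the reference-camera frame (e.g. digital
    checkerboard corners located by ray-plane intersection over >= 3 plane
    poses); ``pixels`` the corresponding projector pixels.  DLT initialization
    followed by nonlinear re-projection refinement; the RMS re-projection
    error in px is stored on the returned model.
    """
    if isinstance(points3d, (list, tuple)):
        points3d = np.vstack(points3d)
        pixels = np.vstack(pixels)
    points3d = np.asarray(points3d, float)
    pixels = np.asarray(pixels, float)
    if len(points3d) < 6:
        raise DomainError("at least 6 correspondences are required")

    P = _dlt_projection(points3d, pixels)
    M = P[:, :3]
    if np.linalg.det(M) < 0:
        P, M = -P, -M
    K, R = linalg.rq(M)
    sign = np.diag(np.sign(np.diag(K)))
    K, R = K @ sign, sign @ R
    K /= K[2, 2]
    t = np.linalg.solve(K, P[:, 3])
    if np.linalg.det(R) < 0:
        R, t = -R, -t

    w, h = image_size
    rvec0 = Rotation.from_matrix(R).as_rotvec()
    x0 = np.concatenate([[K[0, 0], K[1, 1], K[0, 2], K[1, 2]], rvec0, t])

    def residuals(x):
        fx, fy, cx, cy = x[:4]
        Rm = Rotation.from_rotvec(x[4:7]).as_matrix()
        tv = x[7:10]
        pc = points3d @ Rm.T + tv
        u = fx * pc[:, 0] / pc[:, 2] + cx
        v = fy * pc[:, 1] / pc[:, 2] + cy
        return np.concatenate([u - pixels[:, 0], v - pixels[:, 1]])

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    fx, fy, cx, cy = sol.x[:4]
    Rm = Rotation.from_rotvec(sol.x[4:7]).as_matrix()
    tv = sol.x[7:10]
    # residual vector is [all du..., all dv...]; report per-point euclidean RMS
    n = len(points3d)
    du, dv = sol.fun[:n], sol.fun[n:]
    rms = float(np.sqrt(np.mean(du ** 2 + dv ** 2)))
    cam = PinholeCamera(fx, fy, min(max(cx, 0), w - 1), min(max(cy, 0), h - 1),
                        w, h)
    logger.debug("projector calibration RMS %.4f px", rms)
    return ProjectorModel(intrinsics=cam, rotation=Rm, translation=tv, rms_px=rms)
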