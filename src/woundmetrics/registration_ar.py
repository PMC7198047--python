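"""Inter-visit registration and projector AR overlay.

A small checkerboard marker fixed near the wound provides fiducials.  At
each visit the fiducials are located in both rectified images and
triangulated; the rigid transform between the previous and current fiducial
sets (least-squares, SVD) re-poses the stored wound model in today's scene,
and the previous wound perimeter (or tissue classification splats) is drawn
into the projector's image plane so the projector paints it back onto the
patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk, line as draw_line

from .camera_geometry import (ProjectorModel, StereoRig, project_point,
                              triangulate_rectified)
from .config import DegenerateInputError, DomainError, logger


@dataclass
class RigidTransform:
    """x' = R x + T with a proper rotation (det = +1)."""

    R: np.ndarray
    T: np.ndarray
    rms_mm: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float)
        self.T = np.asarray(self.T, float)
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-9) \
                or np.linalg.det(self.R) < 0:
            raise DomainError("R must be orthonormal with det=+1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.R.T + self.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.T, self.rms_mm)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class MarkerObservation:
    """Fiducial pixels in the rectified left and right images (same order)."""

    pixels_left: np.ndarray   # (n, 2)
    pixels_right: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.pixels_left = np.atleast_2d(np.asarray(self.pixels_left, float))
        self.pixels_right = np.atleast_2d(np.asarray(self.pixels_right, float))
        if self.pixels_left.shape != self.pixels_right.shape:
            raise DomainError("left/right fiducial counts must match")


def checkerboard_fiducials(n_cols: int = 3, n_rows: int = 2,
                           width_mm: float = 12.0, height_mm: float = 8.0
                           ) -> np.ndarray:
    """Inner-corner grid of the registration marker, in its own plane frame.

    The physical marker is a small printed checkerboard (12 x 8 mm default);
    the asymmetric aspect disambiguates its orientation between visits.
    Returns (n_rows * n_cols, 3) points with z = 0, centred at the origin.
    """
    xs = (np.arange(n_cols) - (n_cols - 1) / 2) * width_mm / n_cols
    ys = (np.arange(n_rows) - (n_rows - 1) / 2) * height_mm / n_rows
    xx, yy = np.meshgrid(xs, ys)
    return np.stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)], axis=1)


def triangulate_fiducials(obs: MarkerObservation, rig: StereoRig) -> np.ndarray:
    """3D fiducial positions (mm, left-camera frame), order preserved."""
    n = len(obs.pixels_left)
    if n < 3:
        raise DomainError("registration needs at least 3 fiducials")
    disparity = obs.pixels_left[:, 0] - obs.pixels_right[:, 0]
    if np.any(disparity <= 0):
        raise DomainError("non-positive fiducial disparity")
    pts = triangulate_rectified(rig, obs.pixels_left, disparity)
    c = pts - pts.mean(axis=0)
    if np.linalg.svd(c, compute_uv=False)[1] < 1e-9:
        raise DegenerateInputError("fiducials are collinear")
    return pts


def rigid_lsq(p_prev: np.ndarray, p_curr: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform p_curr ~= R p_prev + T (SVD solution).

    Minimizes the sum of squared residuals over the paired point sets; a
    reflection in the SVD solution is corrected so det(R) = +1.  The RMS
    residual (mm) is stored on the returned transform.
    """
    P = np.asarray(p_prev, float)
    Q = np.asarray(p_curr, float)
    if P.shape != Q.shape or len(P) < 3:
        raise DomainError("need matched point sets with >= 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if min(np.linalg.svd(Pc, compute_uv=False)[1],
           np.linalg.svd(Qc, compute_uv=False)[1]) < 1e-12:
        raise DegenerateInputError("collinear point sets")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    T = cq - R @ cp
    rms = float(np.sqrt(np.mean(np.sum((Q - (P @ R.T + T)) ** 2, axis=1))))
    return RigidTransform(R, T, rms)


def render_projector_overlay(points: np.ndarray, projector: ProjectorModel,
                             style: str = "polyline",
                             radius_px: int = 1) -> np.ndarray:
    """Rasterize 3D content (reference-camera frame) into the projector image.

    ``style="polyline"`` connects consecutive points (closed) — used for the
    previous-visit perimeter; ``style="splat"`` draws a small disk per point
    — used for tissue-classification overlays.  Points behind the projector
    or outside its frustum are clipped; if everything is behind, an empty
    image is returned with a warning.
    """
    cam = projector.intrinsics
    pts = np.atleast_2d(np.asarray(points, float))
    pc = pts @ projector.rotation.T + projector.translation
    img = np.zeros((cam.height, cam.width), dtype=np.uint8)
    in_front = pc[:, 2] > 1e-6
    if not in_front.any():
        logger.warning("all overlay points are behind the projector")
        return img
    uv = np.full((len(pc), 2), np.nan)
    uv[in_front] = project_point(cam, pc[in_front])

    def put(u, v):
        if 0 <= v < cam.height and 0 <= u < cam.width:
            img[v, u] = 255

    if style == "splat":
        for u, v in uv[in_front]:
            rr, cc = draw_disk((v, u), radius_px + 0.5,
                               shape=(cam.height, cam.width))
            img[rr, cc] = 255
    elif style == "polyline":
        n = len(uv)
        for i in range(n):
            a, b = uv[i], uv[(i + 1) % n]
            if np.isnan(a).any() or np.isnan(b).any():
                continue
            r0, c0 = int(round(a[1])), int(round(a[0]))
            r1, c1 = int(round(b[1])), int(round(b[0]))
            rr, cc = draw_line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < cam.height) & (cc >= 0) & (cc < cam.width)
            img[rr[keep], cc[keep]] = 255
    else:
        raise DomainError(f"unknown overlay style {style!r}")
    return img


def ar_compare(prev_fiducials_obs: MarkerObservation,
               curr_fiducials_obs: MarkerObservation,
               prev_content: np.ndarray, rig: StereoRig,
               projector: ProjectorModel, style: str = "polyline"
               ) -> tuple[np.ndarray, np.ndarray, RigidTransform]:
    """Register the previous visit onto the current scene and render the overlay.

    Triangulates both visits' marker fiducials, solves the rigid transform
    from the previous to the current set, applies it to the stored content
    points (perimeter or classification splats), and renders the projector
    image.  Returns ``(overlay image, registered content, transform)``.
    """
    p_prev = triangulate_fiducials(prev_fiducials_obs, rig)
    p_curr = triangulate_fiducials(curr_fiducials_obs, rig)
    if len(p_prev) != len(p_curr):
        raise DomainError("marker mismatch between visits")
    tf = rigid_lsq(p_prev, p_curr)
    registered = tf.apply(prev_content)
    overlay = render_projector_overlay(registered, projector, style=style)
    return overlay, registered, tf


def overlay_ray_points(overlay: np.ndarray, projector: ProjectorModel,
                       surface_plane) -> np.ndarray:
    """3D points where lit overlay pixels' projector rays hit a plane.

    This is the physical interpretation of the overlay: each lit projector
    pixel casts a ray that lands on the skin.  Used to score AR accuracy
    against the true wound perimeter.
    """
    from .camera_geometry import back_project_ray, ray_plane_intersect
    vs, us = np.nonzero(overlay)
    if len(vs) == 0:
        return np.zeros((0, 3))
    dirs_p = back_project_ray(projector.intrinsics,
                              np.stack([us, vs], axis=1).astype(float))
    # ray origins/directions back in the reference-camera frame
    Rinv = projector.rotation.T
    origin = -Rinv @ projector.translation
    dirs = dirs_p @ projector.rotation  # == (Rinv @ d.T).T
    origins = np.broadcast_to(origin, dirs.shape)
    return ray_plane_intersect(origins, dirs, surface_plane)
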