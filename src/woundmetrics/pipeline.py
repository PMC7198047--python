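"""End-to-end measurement pipeline and simulated assessment studies.

``measure_phantom`` chains the full device workflow on a synthetic
acquisition: render the reference-camera view, refine a coarse contour into
the wound mask, expand the skin band, lift both to labeled 3D points, fit
the skin plane and the SOM wound mesh, and compute the six clinical
parameters.  ``simulate_rater_study`` and ``simulate_ar_overlay`` reproduce
the assessment protocols (multi-rater reliability; projector AR accuracy)
on these synthetic scenes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .camera_geometry import PinholeCamera, Plane, ProjectorModel, StereoRig
from .config import PipelineConfig, RefinementError, logger
from .evaluation import summarize_study
from .registration_ar import (MarkerObservation, RigidTransform, ar_compare,
                              checkerboard_fiducials, overlay_ray_points)
from .segmentation import (ContourPolygon, expand_roi, lift_to_3d,
                           refine_contour, subpixel_boundary)
from .som_mesh import fit_som_mesh
from .synthetic_fixtures import (PhantomSpec, SampledScene, render_wound_image,
                                 sample_cloud)
from .wound_params import compute_report, fit_skin_plane


PARAM_NAMES = ("depth_mm", "perimeter_mm", "area3d_mm2", "areaproj_mm2",
               "axis_major_mm", "axis_minor_mm", "volume_mm3")
LINEAR_PARAMS = ("depth_mm", "perimeter_mm", "axis_major_mm", "axis_minor_mm")
AREA_VOLUME_PARAMS = ("area3d_mm2", "areaproj_mm2", "volume_mm3")


def _lift_boundary_ring(contour_xy: np.ndarray, pixel_map: np.ndarray,
                        points: np.ndarray, smooth_sigma: float = 2.0
                        ) -> np.ndarray:
    """Interpolate the sub-pixel 2D wound contour on the 3D point grid."""
    H, W = pixel_map.shape
    P = points[pixel_map.reshape(-1)].reshape(H, W, 3)
    coords = np.stack([contour_xy[:, 1], contour_xy[:, 0]])  # (row, col)
    ring = np.stack([ndimage.map_coordinates(P[..., k], coords, order=1,
                                             mode="nearest")
                     for k in range(3)], axis=1)
    if smooth_sigma > 0 and len(ring) > 8:
        ring = ndimage.gaussian_filter1d(ring, smooth_sigma, axis=0,
                                         mode="wrap")
    return ring


def segment_scene(scene: SampledScene, image: np.ndarray | None,
                  coarse: ContourPolygon | None = None,
                  coarse_inflate: float = 1.15,
                  config: PipelineConfig | None = None) -> np.ndarray:
    """Wound mask for a sampled scene.

    With an image, runs contour refinement from the (inflated) coarse
    outline, falling back to the coarse polygon mask on refinement failure;
    without an image the true footprint mask is used directly.
    """
    config = config or PipelineConfig()
    if image is None:
        return scene.wound_mask
    if coarse is None:
        coarse = ContourPolygon(scene.boundary_px).scaled(coarse_inflate)
    try:
        return refine_contour(image, coarse, config)
    except RefinementError as exc:  # pragma: no cover - fallback path
        logger.warning("contour refinement failed (%s); using coarse mask", exc)
        return coarse.to_mask(scene.shape)


def measure_scene(scene: SampledScene, wound_mask: np.ndarray,
                  config: PipelineConfig | None = None,
                  seed: int | np.random.SeedSequence | None = 0,
                  metadata: dict | None = None,
                  return_intermediates: bool = False):
    """Skin plane + SOM mesh + six parameters for a segmented scene."""
    config = config or PipelineConfig()
    skin_mask = expand_roi(wound_mask, config.skin_expand_factor)
    cloud = lift_to_3d(wound_mask, skin_mask, scene.pixel_map, scene.points)
    plane = fit_skin_plane(cloud.skin_points, cloud.wound_points)

    contour = subpixel_boundary(wound_mask)
    ring = _lift_boundary_ring(contour, scene.pixel_map, scene.points)

    n_w = len(cloud.wound_points)
    g = int(min(min(config.som_grid), np.floor(np.sqrt(n_w))))
    g = max(g, 2)
    mesh = fit_som_mesh(cloud.wound_points, grid=(g, g),
                        epochs=config.som_epochs,
                        lr=(config.som_lr, config.som_lr_final),
                        radius_final=config.som_radius_final,
                        conv_epochs=config.som_conv_epochs,
                        conv_radius=config.som_conv_radius,
                        conv_lr=config.som_conv_lr,
                        seed=seed, boundary_ring=ring)
    report = compute_report(
        mesh, plane, wound_mask, scene.pixel_map, scene.points,
        sample_spacing=scene.spacing, alpha=config.alpha_mm,
        boundary_smooth_sigma=config.boundary_smooth_sigma,
        wound_points=cloud.wound_points, metadata=metadata)
    if return_intermediates:
        return report, {"cloud": cloud, "plane": plane, "mesh": mesh,
                        "mask": wound_mask}
    return report


def measure_phantom(phantom: PhantomSpec, spacing: float = 0.2,
                    depth_noise_sigma: float = 0.1, seed: int = 0,
                    pose: RigidTransform | None = None,
                    use_segmentation: bool = True,
                    config: PipelineConfig | None = None,
                    return_intermediates: bool = False):
    """Full pipeline on a synthetic phantom acquisition -> WoundReport."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    s_noise, s_render, s_som = ss.spawn(3)
    scene = sample_cloud(phantom, spacing, depth_noise_sigma, pose=pose,
                         seed=s_noise)
    image = None
    if use_segmentation:
        image, _ = render_wound_image(phantom, spacing, seed=s_render)
    mask = segment_scene(scene, image, config=config)
    meta = {"phantom": phantom.name, "spacing_mm": spacing,
            "sigma_z_mm": depth_noise_sigma, "seed": seed}
    return measure_scene(scene, mask, config=config, seed=s_som,
                         metadata=meta, return_intermediates=return_intermediates)


def run_accuracy_suite(seeds=range(10), spacing: float = 0.2,
                       depth_noise_sigma: float = 0.1,
                       phantoms=None, use_segmentation: bool = True,
                       config: PipelineConfig | None = None) -> dict:
    """Seeded accuracy/precision study over the four-phantom suite.

    Runs the full pipeline for every (phantom, seed) pair and aggregates,
    per parameter group, the mean absolute relative error against the
    analytic ground truths and the across-seed coefficient of variation
    (both in percent).  This is the package's phantom validation protocol.
    """
    from .synthetic_fixtures import study_phantoms

    phantoms = phantoms if phantoms is not None else study_phantoms(0)
    values = {(ph.name, p): [] for ph in phantoms for p in PARAM_NAMES}
    for ph in phantoms:
        for s in seeds:
            rep = measure_phantom(ph, spacing=spacing,
                                  depth_noise_sigma=depth_noise_sigma,
                                  seed=int(s), use_segmentation=use_segmentation,
                                  config=config)
            for p in PARAM_NAMES:
                values[(ph.name, p)].append(getattr(rep, p))

    def aggregate(params):
        errs, cvs = [], []
        for ph in phantoms:
            for p in params:
                v = np.asarray(values[(ph.name, p)])
                gt = getattr(ph.ground_truth, p)
                errs.append(np.mean(np.abs(v - gt) / gt) * 100)
                cvs.append(np.std(v, ddof=1) / abs(np.mean(v)) * 100
                           if len(v) > 1 else 0.0)
        return float(np.mean(errs)), float(np.mean(cvs))

    lin_err, lin_cv = aggregate(LINEAR_PARAMS)
    av_err, av_cv = aggregate(AREA_VOLUME_PARAMS)
    return {"values": values,
            "linear_accuracy_pct": lin_err, "linear_cv_pct": lin_cv,
            "area_volume_accuracy_pct": av_err, "area_volume_cv_pct": av_cv,
            "n_runs": len(phantoms) * len(list(seeds))}


# ---------------------------------------------------------------------------
# multi-rater study
# ---------------------------------------------------------------------------

def simulate_rater_study(phantoms: list[PhantomSpec], n_raters: int = 11,
                         jitter: float = 1.0, seed: int = 0,
                         spacing: float = 0.2, depth_noise_sigma: float = 0.1,
                         tilt_deg: float = 2.0,
                         use_segmentation: bool = False,
                         config: PipelineConfig | None = None
                         ) -> dict:
    """Emulate the multi-rater assessment: every rater measures every phantom.

    Rater-to-rater variability is modelled as an independent acquisition per
    cell: a small random device tilt (``jitter * tilt_deg`` SD) and a fresh
    reconstruction-noise draw whose sigma grows with ``jitter``.  With
    ``jitter = 0`` all raters see the identical acquisition, so every ICC
    is exactly 1.  Returns measurement matrices (phantoms x raters) per
    parameter, the ground truths, and the summary statistics table.
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    mats = {p: np.zeros((len(phantoms), n_raters)) for p in PARAM_NAMES}
    missing = []
    for i, ph in enumerate(phantoms):
        for r in range(n_raters):
            if jitter == 0:
                cell_seed = np.random.SeedSequence([seed, i])
                pose = None
                sigma = depth_noise_sigma
            else:
                cell = np.random.default_rng([seed, i, r])
                angles = cell.normal(0, np.radians(tilt_deg) * jitter, 2)
                from scipy.spatial.transform import Rotation
                pose = RigidTransform(
                    Rotation.from_euler("xy", angles).as_matrix(), np.zeros(3))
                sigma = depth_noise_sigma * (1 + jitter * cell.uniform(0, 1))
                cell_seed = np.random.SeedSequence([seed, i, r, 1])
            try:
                ss = cell_seed
                s_noise, s_render, s_som = ss.spawn(3)
                scene = sample_cloud(phantoms[i], spacing, sigma, pose=pose,
                                     seed=s_noise)
                image = None
                if use_segmentation:
                    image, _ = render_wound_image(ph, spacing, seed=s_render)
                mask = segment_scene(scene, image, config=config)
                rep = measure_scene(scene, mask, config=config, seed=s_som)
            except Exception as exc:  # pragma: no cover - robustness path
                logger.warning("study cell (%s, rater %d) failed: %s",
                               ph.name, r, exc)
                missing.append((ph.name, r))
                for p in PARAM_NAMES:
                    mats[p][i, r] = np.nan
                continue
            for p in PARAM_NAMES:
                mats[p][i, r] = getattr(rep, p)
    truths = {p: np.array([getattr(ph.ground_truth, p) for ph in phantoms])
              for p in PARAM_NAMES}
    summary = None
    if not missing:
        summary = summarize_study(mats, truths)
    return {"measurements": mats, "truths": truths, "summary": summary,
            "missing": missing}


# ---------------------------------------------------------------------------
# AR overlay accuracy simulation
# ---------------------------------------------------------------------------

def default_device(distance_mm: float = 200.0,
                   projector_offset_mm: float = 50.0
                   ) -> tuple[StereoRig, ProjectorModel]:
    """Synthetic device: parallel stereo rig + offset pico-projector.

    Camera: 2208x1242 px, 80/54 degree fields of view, 45 mm baseline.
    Projector: 854x480 px, ~30 degree horizontal FOV, mounted
    ``projector_offset_mm`` to the side and toed in toward the working
    distance so the wound sits near its principal point.
    """
    cam = PinholeCamera.from_fov(80.0, 54.0, 2208, 1242)
    rig = StereoRig(cam, cam, baseline_mm=45.0)
    proj_cam = PinholeCamera.from_fov(30.0, 17.0, 854, 480)
    yaw = np.arctan2(projector_offset_mm, distance_mm)
    R = np.array([[np.cos(yaw), 0, np.sin(yaw)],
                  [0, 1, 0],
                  [-np.sin(yaw), 0, np.cos(yaw)]])
    C = np.array([projector_offset_mm, 0.0, 0.0])
    projector = ProjectorModel(intrinsics=proj_cam, rotation=R,
                               translation=-R @ C)
    return rig, projector


def _transform_plane(plane: Plane, tf: RigidTransform) -> Plane:
    n = tf.R @ plane.n0
    return Plane(n0=n, d0=plane.d0 + float(tf.T @ n))


def simulate_ar_overlay(phantom: PhantomSpec, n_trials: int = 100,
                        pixel_noise_px: float = 0.2,
                        distance_mm: float = 200.0,
                        marker_offset_mm: float = 9.0, seed: int = 0,
                        scene_motion: RigidTransform | None = None,
                        n_perimeter_points: int = 360) -> dict:
    """Monte-Carlo accuracy of the projected previous-visit perimeter.

    The previous and current visits observe the same marker (6 checkerboard
    fiducials on the skin plane); per trial, fiducial detections in both
    rectified views of both visits receive Gaussian pixel noise, the rigid
    registration is solved, the stored perimeter is re-posed and rasterized
    into the projector, and each lit pixel's ray is intersected with the
    skin plane.  The score is the mean 3D distance from the ray hits to the
    true current perimeter.  ``scene_motion`` optionally moves the patient
    between visits.  Returns mean/max trial errors (mm).
    """
    rig, projector = default_device(distance_mm)
    motion = scene_motion or RigidTransform.identity()
    base = RigidTransform(np.eye(3), np.array([0.0, 0.0, distance_mm]))

    fid = checkerboard_fiducials() + np.array([marker_offset_mm, 0.0, 0.0])
    fid_prev = base.apply(fid)
    fid_curr = motion.apply(fid_prev)

    step = max(1, len(phantom.boundary_xy) // n_perimeter_points)
    b2 = phantom.boundary_xy[::step]
    perim3 = np.column_stack([b2, np.zeros(len(b2))])
    perim_prev = base.apply(perim3)
    perim_curr = motion.apply(perim_prev)

    dense = np.column_stack([phantom.boundary_xy,
                             np.zeros(len(phantom.boundary_xy))])
    from scipy.spatial import cKDTree
    truth_tree = cKDTree(motion.apply(base.apply(dense)))

    plane_curr = _transform_plane(
        Plane(n0=np.array([0.0, 0.0, 1.0]), d0=distance_mm), motion)

    from .camera_geometry import project_point

    def observe(points: np.ndarray, rng) -> MarkerObservation:
        pl = project_point(rig.left, points)
        pr = project_point(rig.right, points - np.array([rig.baseline_mm, 0, 0]))
        pl = pl + rng.normal(0, pixel_noise_px, pl.shape)
        pr = pr + rng.normal(0, pixel_noise_px, pr.shape)
        return MarkerObservation(pl, pr)

    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_trials):
        obs_prev = observe(fid_prev, rng)
        obs_curr = observe(fid_curr, rng)
        overlay, _, _ = ar_compare(obs_prev, obs_curr, perim_prev, rig,
                                   projector)
        hits = overlay_ray_points(overlay, projector, plane_curr)
        if len(hits) == 0:  # pragma: no cover
            continue
        d, _ = truth_tree.query(hits)
        errors.append(float(d.mean()))
    errors = np.array(errors)
    return {"mean_error_mm": float(errors.mean()),
            "max_error_mm": float(errors.max()),
            "per_trial_mm": errors}
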