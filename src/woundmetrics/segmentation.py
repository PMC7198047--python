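"""Semi-automatic wound segmentation.

The clinician draws a coarse closed contour around the wound; a region-based
active contour (Chan-Vese two-phase level set on the grayscale image) refines
it onto the actual wound boundary.  The refined region is expanded by 50% in
area to capture the surrounding skin band used as the reference for the skin
plane; everything else is background.  Finally the 2D regions are lifted to
labeled 3D points through the per-pixel point map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.measure import find_contours
from skimage.segmentation import chan_vese

from .config import (DomainError, PipelineConfig, RefinementError, logger)


LABEL_BACKGROUND, LABEL_WOUND, LABEL_SKIN = 0, 1, 2


@dataclass
class ContourPolygon:
    """Closed 2D polygon in pixel coordinates (x=col, y=row), >= 3 vertices."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise DomainError("contour needs >= 3 (x, y) vertices")
        self.vertices = v

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize as a filled binary mask of the given (rows, cols) shape."""
        from skimage.draw import polygon2mask
        rc = self.vertices[:, ::-1]  # polygon2mask expects (row, col)
        return polygon2mask(shape, rc)

    def scaled(self, factor: float) -> "ContourPolygon":
        """Scale about the centroid (used to inflate a coarse user outline)."""
        c = self.vertices.mean(axis=0)
        return ContourPolygon(c + factor * (self.vertices - c))


@dataclass
class WoundCloud:
    """Colored 3D points with per-pixel provenance and region labels.

    ``pixel_map[v, u]`` indexes into ``points`` (−1 where no valid 3D point);
    ``labels`` assigns each point to background / wound / skin.
    """

    points: np.ndarray                 # (N, 3) mm, reference-camera frame
    pixel_map: np.ndarray              # (H, W) int indices, -1 invalid
    colors: np.ndarray | None = None   # (N, 3) uint8
    labels: np.ndarray | None = None   # (N,) in {0 background, 1 wound, 2 skin}

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.pixel_map = np.asarray(self.pixel_map)
        valid = self.pixel_map[self.pixel_map >= 0]
        if valid.size and (valid.max() >= len(self.points)):
            raise DomainError("pixel_map indexes beyond the point array")
        if self.labels is None:
            self.labels = np.zeros(len(self.points), dtype=np.int8)

    def points_with_label(self, label: int) -> np.ndarray:
        return self.points[self.labels == label]

    @property
    def wound_points(self) -> np.ndarray:
        return self.points_with_label(LABEL_WOUND)

    @property
    def skin_points(self) -> np.ndarray:
        return self.points_with_label(LABEL_SKIN)


def refine_contour(image: np.ndarray, coarse: ContourPolygon,
                   config: PipelineConfig | None = None) -> np.ndarray:
    """Refine a coarse wound outline into an accurate binary wound mask.

    Runs a two-phase Chan-Vese level set on grayscale intensity, initialized
    from the polygon's signed mask, and keeps the largest connected component
    of the wound phase that overlaps the initialization.

    Raises :class:`RefinementError` when no two-phase partition exists (e.g.
    a uniform image) so the caller can fall back to the coarse polygon mask.
    """
    config = config or PipelineConfig()
    gray = rgb2gray(image) if image.ndim == 3 else np.asarray(image, float)
    shape = gray.shape
    init_mask = coarse.to_mask(shape)
    if not init_mask.any() or init_mask.all():
        raise DomainError("coarse polygon must lie inside the image")
    if gray.std() < 1e-6:
        raise RefinementError("uniform image: no two-phase partition")

    init = np.where(init_mask, 1.0, -1.0)
    seg = chan_vese(gray, mu=config.chanvese_mu, lambda1=config.chanvese_lambda1,
                    lambda2=config.chanvese_lambda2, tol=config.chanvese_tol,
                    max_num_iter=config.chanvese_max_iter, dt=0.5,
                    init_level_set=init)
    # chan_vese returns the phase where intensity is closer to c1 (the init
    # interior); make sure we keep the wound phase overlapping the polygon
    if (seg & init_mask).sum() < (~seg & init_mask).sum():
        seg = ~seg
    lab, n = ndimage.label(seg)
    if n == 0:
        raise RefinementError("refinement produced an empty region")
    overlaps = ndimage.sum_labels(init_mask, lab, index=np.arange(1, n + 1))
    best = int(np.argmax(overlaps)) + 1
    if overlaps[best - 1] == 0:
        raise RefinementError("no refined region overlaps the initialization")
    return lab == best


def subpixel_boundary(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel (x, y) boundary of a binary mask via the 0.5 iso-contour."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DomainError("empty mask has no boundary")
    longest = max(contours, key=len)
    return longest[:, ::-1]  # (row, col) -> (x, y)


def expand_roi(wound_mask: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Skin band: dilate the wound until enclosed area reaches ``factor`` x.

    Isotropic morphological dilation (3x3 disk steps) grows the region until
    its area is ``factor`` times the wound area; the band is the dilated
    region minus the wound.  A band clipped by the image border triggers a
    warning (the enclosed-area target may then be unreachable).
    """
    wound_mask = np.asarray(wound_mask, bool)
    area = int(wound_mask.sum())
    if area == 0:
        raise DomainError("empty wound mask")
    target = int(round(factor * area))
    # exact isotropic growth: take the (target - area) nearest outside pixels
    dist = ndimage.distance_transform_edt(~wound_mask)
    outside = dist[~wound_mask]
    n_extra = min(target - area, outside.size)
    if n_extra <= 0:
        return np.zeros_like(wound_mask)
    out_idx = np.flatnonzero(~wound_mask.ravel())
    chosen = out_idx[np.argpartition(outside, n_extra - 1)[:n_extra]]
    region = wound_mask.copy().ravel()
    region[chosen] = True
    region = region.reshape(wound_mask.shape)
    border = np.zeros_like(region)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (region & border).any():
        logger.warning("skin band clipped by the image border")
    if region.sum() < target:
        logger.warning("skin band area target %.0f px not reached (%.0f px)",
                       target, region.sum())
    return region & ~wound_mask


def lift_to_3d(wound_mask: np.ndarray, skin_mask: np.ndarray,
               pixel_map: np.ndarray, points: np.ndarray,
               colors: np.ndarray | None = None) -> WoundCloud:
    """Label 3D points from the 2D wound and skin-band masks.

    Pixels without a valid 3D point are skipped (with a warning if any wound
    pixel is lost); a point can receive only one label because the masks are
    disjoint and the pixel map is single-valued.
    """
    wound_mask = np.asarray(wound_mask, bool)
    skin_mask = np.asarray(skin_mask, bool)
    if wound_mask.shape != skin_mask.shape or wound_mask.shape != pixel_map.shape:
        raise DomainError("masks and pixel_map must share their shape")
    if (wound_mask & skin_mask).any():
        raise DomainError("wound and skin masks must be disjoint")

    labels = np.zeros(len(points), dtype=np.int8)
    w_idx = pixel_map[wound_mask]
    s_idx = pixel_map[skin_mask]
    n_invalid = int((w_idx < 0).sum())
    if n_invalid:
        logger.warning("%d wound pixels have no valid 3D point", n_invalid)
    labels[w_idx[w_idx >= 0]] = LABEL_WOUND
    labels[s_idx[s_idx >= 0]] = LABEL_SKIN
    if not (labels == LABEL_WOUND).any():
        raise DomainError("no valid wound points after lifting")
    return WoundCloud(points=points, pixel_map=pixel_map, colors=colors,
                      labels=labels)
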