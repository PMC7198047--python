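"""Seeded tissue classification on the wound image.

Wound-bed tissues have characteristic colors — red granulation, yellow
slough, black necrosis.  The clinician picks one seed pixel per tissue
present; classification then runs in CIELAB chroma space (a, b only, so a
brightness change or shadow does not move a pixel between classes):
SLIC superpixels partition the wound region, k-means on the superpixel mean
(a, b) with the seed chroma values as initial centroids labels every
superpixel, and the composition is reported as the fraction of the wound's
*3D surface area* covered by each tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from skimage.segmentation import slic
from sklearn.cluster import KMeans

from .config import DegenerateInputError, DomainError, logger


TISSUE_LABELS = ("granulation", "slough", "necrosis")


@dataclass
class TissueSeed:
    """User-picked seed: pixel (x, y) inside the wound mask + tissue label."""

    x: int
    y: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in TISSUE_LABELS:
            raise DomainError(f"unknown tissue label {self.label!r}")


@dataclass
class TissueComposition:
    """Per-tissue fraction of the wound 3D surface; fractions sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        tot = sum(self.fractions.values())
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise DomainError(f"fractions must sum to 1, got {tot}")
        if any(not 0 <= f <= 1 for f in self.fractions.values()):
            raise DomainError("fractions must lie in [0, 1]")


def to_ab_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """CIELAB (a, b) chroma pairs of the masked pixels (sRGB, D65).

    Dropping L removes the brightness contribution, so shadows and
    illumination gradients do not affect downstream clustering.
    """
    lab = rgb2lab(image)
    mask = np.asarray(mask, bool)
    return lab[mask][:, 1:3]


def _lab_image(image: np.ndarray) -> np.ndarray:
    return rgb2lab(image)


def slic_superpixels(image: np.ndarray, mask: np.ndarray, n_segments: int,
                     compactness: float = 10.0) -> np.ndarray:
    """SLIC superpixels restricted to the mask (labels >= 1, 0 outside)."""
    mask = np.asarray(mask, bool)
    n_pix = int(mask.sum())
    if n_segments < 1:
        raise DomainError("n_segments must be >= 1")
    if n_segments > n_pix:
        raise DomainError("more segments requested than masked pixels")
    labels = slic(image, n_segments=n_segments, compactness=compactness,
                  mask=mask, start_label=1, channel_axis=-1 if image.ndim == 3 else None)
    # slic can merge tiny regions; guarantee every masked pixel is labeled
    if (labels[mask] == 0).any():  # pragma: no cover - defensive
        labels[mask & (labels == 0)] = labels[mask].max() or 1
    return labels


def classify_tissue(image: np.ndarray, superpixels: np.ndarray,
                    seeds: list[TissueSeed]) -> dict[int, str]:
    """Label each superpixel by seeded k-means on mean (a, b) chroma.

    k equals the number of distinct seeded tissue classes; centroids start at
    the seed pixels' chroma, making the assignment deterministic.  Each
    superpixel receives the tissue label of the seed class whose centroid its
    mean chroma joins.
    """
    if not seeds:
        raise DomainError("at least one seed is required")
    lab = _lab_image(image)
    ab = lab[..., 1:3]

    by_label: dict[str, list[np.ndarray]] = {}
    for s in seeds:
        if superpixels[s.y, s.x] == 0:
            raise DomainError(f"seed ({s.x}, {s.y}) lies outside the wound mask")
        by_label.setdefault(s.label, []).append(ab[s.y, s.x])
    classes = sorted(by_label)
    init = np.array([np.mean(by_label[lbl], axis=0) for lbl in classes])
    if len(classes) > 1:
        d = np.linalg.norm(init[:, None] - init[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise DegenerateInputError(
                "two seed classes have identical chroma features")

    sp_ids = np.unique(superpixels)
    sp_ids = sp_ids[sp_ids > 0]
    means = np.array([ab[superpixels == i].mean(axis=0) for i in sp_ids])
    if len(classes) == 1:
        return {int(i): classes[0] for i in sp_ids}
    km = KMeans(n_clusters=len(classes), init=init, n_init=1, max_iter=300)
    assign = km.fit_predict(means)
    # map each final centroid back to the seed class it started from
    order = np.argmin(np.linalg.norm(
        km.cluster_centers_[:, None] - init[None, :], axis=-1), axis=1)
    return {int(i): classes[order[a]] for i, a in zip(sp_ids, assign)}


def pixel_area_weights(pixel_map: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Per-pixel 3D surface-area element (mm^2) from the lifted point grid.

    Uses the cross product of the local point differences along the pixel
    grid; edge/invalid pixels fall back to the median weight so foreshortened
    (steep) regions weigh more than face-on ones.
    """
    H, W = pixel_map.shape
    P = np.full((H, W, 3), np.nan)
    valid = pixel_map >= 0
    P[valid] = points[pixel_map[valid]]
    du = np.full((H, W, 3), np.nan)
    dv = np.full((H, W, 3), np.nan)
    du[:, 1:-1] = (P[:, 2:] - P[:, :-2]) / 2
    dv[1:-1, :] = (P[2:, :] - P[:-2, :]) / 2
    w = np.linalg.norm(np.cross(du, dv), axis=-1)
    med = np.nanmedian(w[valid]) if valid.any() else 0.0
    w = np.where(np.isfinite(w), w, med)
    w[~valid] = 0.0
    return w


def tissue_percentages_3d(superpixels: np.ndarray, labels: dict[int, str],
                          pixel_map: np.ndarray, points: np.ndarray
                          ) -> TissueComposition:
    """Tissue fractions weighted by each pixel's 3D surface-area element."""
    weights = pixel_area_weights(pixel_map, points)
    totals: dict[str, float] = {}
    for sp_id, lbl in labels.items():
        sel = superpixels == sp_id
        totals[lbl] = totals.get(lbl, 0.0) + float(weights[sel].sum())
    total = sum(totals.values())
    if total <= 0:
        raise DomainError("zero total wound surface area")
    return TissueComposition({k: v / total for k, v in sorted(totals.items())})


def classify_wound(image: np.ndarray, wound_mask: np.ndarray,
                   seeds: list[TissueSeed], pixel_map: np.ndarray,
                   points: np.ndarray, pixels_per_segment: int = 200,
                   compactness: float = 10.0
                   ) -> tuple[np.ndarray, dict[int, str], TissueComposition]:
    """Full tissue pipeline: superpixels -> seeded k-means -> 3D composition.

    Returns ``(superpixel map, superpixel labels, composition)``.
    """
    n_pix = int(np.asarray(wound_mask, bool).sum())
    n_segments = max(1, n_pix // pixels_per_segment)
    sp = slic_superpixels(image, wound_mask, n_segments, compactness)
    labels = classify_tissue(image, sp, seeds)
    comp = tissue_percentages_3d(sp, labels, pixel_map, points)
    logger.debug("tissue composition: %s", comp.fractions)
    return sp, labels, comp
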