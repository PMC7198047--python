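"""Synthetic wound phantoms with analytic ground truth.

Desk-scale stand-ins for 3D-printed wound models: each phantom is a depth
field over a footprint on a flat skin plane, with a tissue label map and a
ground-truth :class:`~woundmetrics.wound_params.WoundReport` obtained in
closed form or by converged numerical integration.  Four built-ins emulate a
healing-study series:

* ``circular`` — spherical-cap cavity (default footprint radius 6 mm, depth
  3 mm; radius = depth gives a full hemisphere), all granulation;
* ``trapezoid`` — trapezoidal footprint whose floor ramps linearly from
  0 to 7.5 mm depth; an exactly piecewise-linear surface, so its ground
  truth is exact by per-triangle sums;
* ``elliptical`` — elliptic-paraboloid cavity with a three-tissue radial map;
* ``irregular`` — seeded random smooth boundary and bumpy depth field
  rescaled to a 5.4 mm maximum; ground truth by fine-grid integration.

Phantom frames put the skin plane at z = 0 with z = +depth into the cavity
(away from the camera); ``sample_cloud`` applies a rigid pose to emulate a
device acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
from scipy.interpolate import LinearNDInterpolator
from scipy.special import ellipe

from .config import DomainError
from .registration_ar import RigidTransform
from .wound_params import WoundReport


TISSUE_PALETTE = {
    "granulation": (165, 35, 35),
    "slough": (170, 140, 40),
    "necrosis": (30, 25, 25),
    "skin": (225, 185, 160),
}


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Analytic wound phantom: depth field + boundary + tissues + truth."""

    name: str
    boundary_xy: np.ndarray            # dense closed (M, 2) footprint outline
    depth: Callable[[np.ndarray, np.ndarray], np.ndarray]  # depth(x, y) >= 0
    tissue: Callable[[np.ndarray, np.ndarray], np.ndarray]  # label codes
    domain: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    ground_truth: WoundReport
    tissue_names: tuple[str, ...] = ("granulation",)
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gt = self.ground_truth
        if gt.axis_major_mm < gt.axis_minor_mm or gt.area3d_mm2 < gt.areaproj_mm2:
            raise DomainError("inconsistent phantom ground truth")

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Surface z (phantom frame): +depth inside the wound, 0 on skin."""
        return self.depth(np.asarray(x, float), np.asarray(y, float))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        poly = shapely.Polygon(self.boundary_xy)
        return shapely.contains_xy(poly, np.asarray(x, float), np.asarray(y, float))


def _axes_from_region(boundary_xy: np.ndarray, grid_h: float = 0.05
                      ) -> tuple[float, float]:
    """Principal-axis extents of the filled footprint (dense-grid moments)."""
    poly = shapely.Polygon(boundary_xy)
    xmin, ymin, xmax, ymax = poly.bounds
    xs = np.arange(xmin, xmax + grid_h, grid_h)
    ys = np.arange(ymin, ymax + grid_h, grid_h)
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
    pts = np.stack([xx.ravel()[inside], yy.ravel()[inside]], axis=1)
    centred = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    bnd = boundary_xy - pts.mean(axis=0)
    proj = bnd @ Vt.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    return float(ext.max()), float(ext.min())


def _grid_ground_truth(boundary_xy: np.ndarray,
                       depth_fn: Callable, h: float = 0.02
                       ) -> tuple[float, float, float, float]:
    """(area3d, volume, proj_area, max_depth) by midpoint-rule integration.

    Valid for depth fields whose gradient vanishes at the footprint boundary
    (boundary-cell misclassification is then second order).
    """
    poly = shapely.Polygon(boundary_xy)
    xmin, ymin, xmax, ymax = poly.bounds
    pad = 3 * h
    xs = np.arange(xmin - pad, xmax + pad, h)
    ys = np.arange(ymin - pad, ymax + pad, h)
    xx, yy = np.meshgrid(xs, ys)
    z = depth_fn(xx, yy)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    zx, zy = np.gradient(z, h, edge_order=2)
    zy, zx = zx, zy  # np.gradient axis0 = rows = y
    el = np.sqrt(1 + zx ** 2 + zy ** 2)
    area3d = float(el[inside].sum() * h * h)
    volume = float(z[inside].sum() * h * h)
    proj = float(inside.sum() * h * h)
    return area3d, volume, proj, float(z.max())


def _polyline_length(xy: np.ndarray, closed: bool = True) -> float:
    p = np.vstack([xy, xy[:1]]) if closed else xy
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# built-in phantoms
# ---------------------------------------------------------------------------

def phantom_circular(radius: float = 6.0, depth: float = 3.0,
                     margin: float = 6.0) -> PhantomSpec:
    """Spherical-cap cavity; ``depth == radius`` gives a full hemisphere.

    Ground truth in closed form: zone area 2*pi*R*h, cap volume
    pi*h*(3*a^2 + h^2)/6 with sphere radius R = (a^2 + h^2)/(2h).
    """
    a, h = float(radius), float(depth)
    if a <= 0 or h <= 0 or h > a:
        raise DomainError("need 0 < depth <= radius")
    R = (a * a + h * h) / (2 * h)
    theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    boundary = np.stack([a * np.cos(theta), a * np.sin(theta)], axis=1)

    def depth_fn(x, y):
        rho2 = x * x + y * y
        z = np.sqrt(np.maximum(R * R - rho2, 0.0)) - (R - h)
        return np.where(rho2 <= a * a, np.maximum(z, 0.0), 0.0)

    def tissue_fn(x, y):
        return np.zeros(np.broadcast(x, y).shape, dtype=np.int8)

    gt = WoundReport(
        depth_mm=h,
        perimeter_mm=2 * np.pi * a,
        area3d_mm2=2 * np.pi * R * h,
        areaproj_mm2=np.pi * a * a,
        axis_major_mm=2 * a,
        axis_minor_mm=2 * a,
        volume_mm3=np.pi * h * (3 * a * a + h * h) / 6,
    )
    dom = (-a - margin, a + margin, -a - margin, a + margin)
    return PhantomSpec("circular", boundary, depth_fn, tissue_fn, dom, gt,
                       tissue_names=("granulation",),
                       params={"radius": a, "depth": h})


def phantom_trapezoid(base_major: float = 14.0, base_minor: float = 8.0,
                      length: float = 24.0, max_depth: float = 7.5,
                      wall_margin: float = 2.5, plateau: float = 2.0,
                      margin: float = 6.0) -> PhantomSpec:
    """Trapezoidal cavity whose floor ramps linearly from 0 to ``max_depth``.

    The floor ramp ends on a flat landing of length ``plateau`` at maximum
    depth before the end wall, so the deepest region is an area rather than
    a knife-edge crease (a crease maximum cannot be resolved by any
    averaging surface fit at finite sampling).  The surface is piecewise
    linear by construction (Delaunay interpolation over densified rim and
    floor outlines), so area, volume and depth ground truths are exact
    per-triangle sums.
    """
    hw0, hw1 = base_major / 2, base_minor / 2
    outer = shapely.Polygon([(0, -hw0), (length, -hw1), (length, hw1), (0, hw0)])
    floor = outer.buffer(-wall_margin, join_style="mitre")
    if floor.is_empty:
        raise DomainError("wall margin too large for the footprint")

    def densify(poly: shapely.Polygon, step: float = 0.4) -> np.ndarray:
        ring = poly.exterior
        d = np.arange(0, ring.length, step)
        return np.array([ring.interpolate(t).coords[0] for t in d])

    outer_xy = densify(outer)
    floor_xy = densify(floor)
    fx0, _, fx1, _ = floor.bounds

    def ramp(x):
        return max_depth * np.clip((x - fx0) / (fx1 - plateau - fx0), 0, 1)

    verts = np.vstack([outer_xy, floor_xy])
    zvals = np.concatenate([np.zeros(len(outer_xy)), ramp(floor_xy[:, 0])])
    interp = LinearNDInterpolator(verts, zvals, fill_value=0.0)

    def depth_fn(x, y):
        return np.nan_to_num(np.maximum(interp(x, y), 0.0))

    def tissue_fn(x, y):
        # granulation toward the shallow end, slough in the deep half
        return (np.broadcast_arrays(x, y)[0] > length / 2).astype(np.int8)

    # exact ground truth from the interpolator's own triangulation
    tri = interp.tri
    simplices = tri.simplices
    p2 = verts[simplices]
    z3 = zvals[simplices]
    cent = p2.mean(axis=1)
    inside = shapely.contains_xy(outer, cent[:, 0], cent[:, 1])
    p3 = np.dstack([p2, z3[..., None]])
    e1 = p3[:, 1] - p3[:, 0]
    e2 = p3[:, 2] - p3[:, 0]
    tri_area3d = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    f1 = p2[:, 1] - p2[:, 0]
    f2 = p2[:, 2] - p2[:, 0]
    tri_area2d = 0.5 * np.abs(f1[:, 0] * f2[:, 1] - f1[:, 1] * f2[:, 0])
    area3d = float(tri_area3d[inside].sum())
    volume = float((tri_area2d * z3.mean(axis=1))[inside].sum())
    amaj, amin = _axes_from_region(outer_xy)
    gt = WoundReport(
        depth_mm=float(zvals.max()),
        perimeter_mm=outer.exterior.length,
        area3d_mm2=area3d,
        areaproj_mm2=outer.area,
        axis_major_mm=amaj,
        axis_minor_mm=amin,
        volume_mm3=volume,
    )
    xmin, ymin, xmax, ymax = outer.bounds
    dom = (xmin - margin, xmax + margin, ymin - margin, ymax + margin)
    return PhantomSpec("trapezoid", outer_xy, depth_fn, tissue_fn, dom, gt,
                       tissue_names=("granulation", "slough"),
                       params={"max_depth": max_depth})


def phantom_elliptical(semi_major: float = 9.0, semi_minor: float = 6.0,
                       max_depth: float = 4.0, margin: float = 6.0
                       ) -> PhantomSpec:
    """Elliptic-paraboloid cavity with a granulation/slough/necrosis ring map.

    Volume pi*a*b*d/2 and the ellipse perimeter are closed form; the surface
    area integral is non-elementary and uses converged grid integration.
    """
    a, b, d = semi_major, semi_minor, max_depth
    theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    boundary = np.stack([a * np.cos(theta), b * np.sin(theta)], axis=1)

    def t2(x, y):
        return (x / a) ** 2 + (y / b) ** 2

    def depth_fn(x, y):
        return np.maximum(d * (1 - t2(x, y)), 0.0)

    def tissue_fn(x, y):
        t = np.sqrt(np.clip(t2(x, y), 0, None))
        lab = np.full(t.shape, 0, dtype=np.int8)       # granulation rim
        lab[t < 0.7] = 1                               # slough ring
        lab[t < 0.4] = 2                               # necrotic centre
        return lab

    m = 1 - (b / a) ** 2
    perimeter = 4 * a * float(ellipe(m))
    area3d, _, _, _ = _grid_ground_truth(boundary, depth_fn, h=0.01)
    gt = WoundReport(
        depth_mm=d,
        perimeter_mm=perimeter,
        area3d_mm2=area3d,
        areaproj_mm2=np.pi * a * b,
        axis_major_mm=2 * a,
        axis_minor_mm=2 * b,
        volume_mm3=np.pi * a * b * d / 2,
    )
    dom = (-a - margin, a + margin, -b - margin, b + margin)
    return PhantomSpec("elliptical", boundary, depth_fn, tissue_fn, dom, gt,
                       tissue_names=("granulation", "slough", "necrosis"),
                       params={"max_depth": d})


def phantom_irregular(base_radius: float = 8.0, max_depth: float = 5.4,
                      margin: float = 6.0, seed: int = 0) -> PhantomSpec:
    """Seeded smooth random boundary with a bumpy depth field.

    The boundary is a low-order harmonic perturbation of a circle; the depth
    field is a boundary-vanishing envelope modulated by random Gaussian
    bumps, rescaled so its maximum equals ``max_depth`` exactly.  Ground
    truth by fine-grid integration (the envelope's gradient vanishes on the
    boundary, so boundary cells are second order).
    """
    rng = np.random.default_rng(seed)
    ks = np.arange(2, 7)
    amp = rng.uniform(0.03, 0.09, len(ks))
    phs = rng.uniform(0, 2 * np.pi, len(ks))

    def radius_of(theta):
        pert = sum(A * np.cos(k * theta + p) for A, k, p in zip(amp, ks, phs))
        return base_radius * (1 + pert)

    theta = np.linspace(0, 2 * np.pi, 8192, endpoint=False)
    r = radius_of(theta)
    boundary = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)

    n_bumps = 6
    bump_mu = rng.uniform(-0.5, 0.5, (n_bumps, 2)) * base_radius
    bump_s = rng.uniform(1.5, 3.0, n_bumps)
    bump_c = rng.uniform(-0.35, 0.5, n_bumps)

    def raw(x, y):
        th = np.arctan2(y, x)
        rho = np.hypot(x, y)
        t = np.clip(rho / radius_of(th), 0, 1)
        envelope = np.cos(np.pi * t / 2) ** 2
        bumps = np.ones_like(envelope)
        for mu, s, c in zip(bump_mu, bump_s, bump_c):
            bumps = bumps + c * np.exp(-((x - mu[0]) ** 2 + (y - mu[1]) ** 2)
                                       / (2 * s * s))
        return envelope * np.maximum(bumps, 0.05)

    # compress the top of the field (zero slope at the maximum) so the
    # deepest point is a broad feature the sampling can resolve
    raw_ref = raw  # keep a handle for the pre-compression field

    def compressed(x, y):
        u = raw_ref(x, y) / _raw_max[0]
        return 1 - (1 - np.clip(u, 0, 1)) ** 2

    # rescale so the continuous maximum is max_depth (fine-grid argmax)
    lim = base_radius * 1.15
    gx = np.arange(-lim, lim, 0.01)
    xx, yy = np.meshgrid(gx, gx)
    _raw_max = [raw(xx, yy).max()]

    def depth_fn(x, y):
        return max_depth * compressed(np.asarray(x, float), np.asarray(y, float))

    def tissue_fn(x, y):
        x, y = np.broadcast_arrays(np.asarray(x), np.asarray(y))
        return ((x + 0.6 * y) > 0).astype(np.int8)

    area3d, volume, proj, dmax = _grid_ground_truth(boundary, depth_fn, h=0.02)
    amaj, amin = _axes_from_region(boundary)
    gt = WoundReport(
        depth_mm=dmax,
        perimeter_mm=_polyline_length(boundary),
        area3d_mm2=area3d,
        areaproj_mm2=proj,
        axis_major_mm=amaj,
        axis_minor_mm=amin,
        volume_mm3=volume,
    )
    xmin, ymin = boundary.min(axis=0) - margin
    xmax, ymax = boundary.max(axis=0) + margin
    dom = (xmin, xmax, ymin, ymax)
    return PhantomSpec("irregular", boundary, depth_fn, tissue_fn, dom, gt,
                       tissue_names=("granulation", "slough"), seed=seed,
                       params={"max_depth": max_depth})


_BUILTINS = {
    "circular": phantom_circular,
    "trapezoid": phantom_trapezoid,
    "elliptical": phantom_elliptical,
    "irregular": phantom_irregular,
    # study aliases
    "A": phantom_circular,
    "B": phantom_trapezoid,
    "C": phantom_elliptical,
    "D": phantom_irregular,
}


def make_phantom(name: str, seed: int = 0, **params) -> PhantomSpec:
    """Build a named phantom (``circular``/``trapezoid``/``elliptical``/
    ``irregular``, or study aliases ``A``-``D``)."""
    if name not in _BUILTINS:
        raise DomainError(f"unknown phantom {name!r}")
    fn = _BUILTINS[name]
    if fn is phantom_irregular:
        return fn(seed=seed, **params)
    return fn(**params)


def study_phantoms(seed: int = 0) -> list[PhantomSpec]:
    """The four-phantom healing-study suite (A-D analogs)."""
    return [make_phantom(n, seed=seed) for n in ("A", "B", "C", "D")]


# ---------------------------------------------------------------------------
# sampling and rendering
# ---------------------------------------------------------------------------

@dataclass
class SampledScene:
    """Grid-sampled phantom acquisition: points + provenance + true masks."""

    phantom: PhantomSpec
    points: np.ndarray           # (N, 3) mm, camera/world frame
    pixel_map: np.ndarray        # (H, W) index into points
    wound_mask: np.ndarray       # true footprint mask
    skin_mask: np.ndarray        # everything else in the field of view
    spacing: float
    pose: RigidTransform
    boundary_px: np.ndarray      # true footprint outline in pixel coords

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixel_map.shape

    def pixel_to_xy(self, px: np.ndarray) -> np.ndarray:
        xmin, _, ymin, _ = self.phantom.domain
        return np.asarray(px, float) * self.spacing + \
            np.array([xmin, ymin]) + self.spacing / 2


def sample_cloud(phantom: PhantomSpec, spacing: float = 0.2,
                 depth_noise_sigma: float = 0.1,
                 pose: RigidTransform | None = None,
                 seed: int | None = 0) -> SampledScene:
    """Grid-sample the phantom height field with Gaussian depth noise.

    The lateral grid emulates the per-pixel 3D reconstruction: pixel (i, j)
    maps to phantom coordinates ``(xmin + (j+.5) s, ymin + (i+.5) s)`` and
    its 3D point is the surface sample plus N(0, sigma_z) depth noise, then
    rigidly posed.  Every pixel is valid; true wound/skin masks come along.
    """
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    xmin, xmax, ymin, ymax = phantom.domain
    xs = np.arange(xmin + spacing / 2, xmax, spacing)
    ys = np.arange(ymin + spacing / 2, ymax, spacing)
    xx, yy = np.meshgrid(xs, ys)          # row i -> y, col j -> x
    zz = phantom.surface(xx, yy)
    if depth_noise_sigma > 0:
        rng = np.random.default_rng(seed)
        zz = zz + rng.normal(0, depth_noise_sigma, zz.shape)
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    pose = pose or RigidTransform.identity()
    pts = pose.apply(pts)
    H, W = xx.shape
    pixel_map = np.arange(H * W).reshape(H, W)
    wound = phantom.contains(xx.ravel(), yy.ravel()).reshape(H, W)
    skin = ~wound
    boundary_px = (phantom.boundary_xy - [xmin, ymin]) / spacing - 0.5
    return SampledScene(phantom, pts, pixel_map, wound, skin, spacing, pose,
                        boundary_px)


def render_wound_image(phantom: PhantomSpec, spacing: float = 0.2,
                       palette: dict[str, tuple] | None = None,
                       brightness_field: Callable | None = None,
                       noise_sigma: float = 2.0, seed: int | None = 0,
                       supersample: int = 3
                       ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Rasterize the phantom's tissue map on the sampling grid.

    Returns an anti-aliased 8-bit RGB image aligned pixel-for-pixel with
    :func:`sample_cloud` at the same spacing, plus boolean truth masks per
    tissue (pixel-centre labels).  ``brightness_field(x, y)`` multiplies the
    image (shadows/illumination); ``noise_sigma`` is additive Gaussian pixel
    noise in 8-bit counts.
    """
    palette = palette or TISSUE_PALETTE
    xmin, xmax, ymin, ymax = phantom.domain
    xs = np.arange(xmin + spacing / 2, xmax, spacing)
    ys = np.arange(ymin + spacing / 2, ymax, spacing)
    H, W = len(ys), len(xs)
    ss = max(1, int(supersample))
    fine = spacing / ss
    offs = (np.arange(ss) - (ss - 1) / 2) * fine
    img = np.zeros((H, W, 3))
    skin_rgb = np.array(palette["skin"], float)
    tissue_rgb = np.array([palette[n] for n in phantom.tissue_names], float)
    for dy in offs:
        for dx in offs:
            xx, yy = np.meshgrid(xs + dx, ys + dy)
            inside = phantom.contains(xx.ravel(), yy.ravel()).reshape(H, W)
            lab = phantom.tissue(xx, yy)
            sub = np.where(inside[..., None],
                           tissue_rgb[np.clip(lab, 0, len(tissue_rgb) - 1)],
                           skin_rgb)
            img += sub
    img /= ss * ss
    if brightness_field is not None:
        xx, yy = np.meshgrid(xs, ys)
        img = img * np.clip(brightness_field(xx, yy), 0, None)[..., None]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise_sigma, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    xx, yy = np.meshgrid(xs, ys)
    inside = phantom.contains(xx.ravel(), yy.ravel()).reshape(H, W)
    lab = phantom.tissue(xx, yy)
    masks = {name: inside & (lab == i)
             for i, name in enumerate(phantom.tissue_names)}
    return img, masks
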