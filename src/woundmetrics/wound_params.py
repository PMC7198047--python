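"""Clinical wound parameters from the 3D model.

Six morphological parameters are computed from the SOM wound mesh, the skin
reference plane, and the traced 2D wound boundary lifted to 3D:

* **depth** (mm): largest signed distance of a mesh vertex from the skin
  plane ``pi: p.n0 - d0 = 0``, i.e. ``sup_x (n0.x - d0)``;
* **perimeter** (mm): sum of Euclidean distances between contiguous lifted
  boundary points (closed polyline);
* **3D area** (mm^2): total area of the mesh quadrilaterals via the
  two-corner cross-product rule;
* **projected area** (mm^2): area of the 2D alpha-shape of the wound points
  projected onto the skin plane (comparable to acetate tracing);
* **main axes** (mm): extents of the projected points along their two
  principal directions;
* **volume** (mm^3): volume of the watertight region between the wound mesh
  and the skin plane (mesh capped onto the plane, signed-tetrahedron sum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
import trimesh
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree

from .camera_geometry import Plane
from .config import DegenerateInputError, DomainError, logger
from .som_mesh import QuadMesh


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class WoundReport:
    """The six wound parameters plus acquisition metadata."""

    depth_mm: float
    perimeter_mm: float
    area3d_mm2: float
    areaproj_mm2: float
    axis_major_mm: float
    axis_minor_mm: float
    volume_mm3: float
    tissue_fractions: dict[str, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.depth_mm, self.perimeter_mm, self.area3d_mm2,
                self.areaproj_mm2, self.axis_major_mm, self.axis_minor_mm,
                self.volume_mm3]
        if any(v < 0 for v in vals):
            raise DomainError("wound parameters must be non-negative")
        if self.axis_major_mm < self.axis_minor_mm:
            raise DomainError("axis_major must be >= axis_minor")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "WoundReport":
        return cls(**d)


# ---------------------------------------------------------------------------
# skin plane and depth
# ---------------------------------------------------------------------------

def fit_skin_plane(skin_points: np.ndarray,
                   wound_points: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through the surrounding-skin points.

    The unit normal is the smallest principal component of the centred
    points.  Orientation: if ``wound_points`` are given the normal is flipped
    so the wound interior has positive signed distance (the depth supremum
    convention); otherwise it points into the camera half-space (-z).
    """
    pts = np.asarray(skin_points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DomainError("need at least 3 skin points")
    centred = pts - pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise DegenerateInputError("skin points are collinear")
    n0 = Vt[2]
    d0 = float(pts.mean(axis=0) @ n0)
    plane = Plane(n0=n0, d0=d0)
    if wound_points is not None and len(wound_points):
        if np.median(plane.signed_distance(wound_points)) < 0:
            plane = Plane(n0=-plane.n0, d0=-plane.d0)
    elif plane.n0[2] > 0:
        plane = Plane(n0=-plane.n0, d0=-plane.d0)
    return plane


def wound_depth(mesh: QuadMesh, plane: Plane) -> float:
    """Maximum signed distance of any mesh vertex from the skin plane (>= 0)."""
    return float(max(0.0, plane.signed_distance(mesh.points).max()))


# ---------------------------------------------------------------------------
# perimeter
# ---------------------------------------------------------------------------

# clockwise Moore neighbourhood starting north, (drow, dcol)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_perimeter_2d(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary pixels of the wound mask, (x, y) = (col, row).

    Moore-neighbour tracing with Jacob's stopping criterion: the walk stops
    when the start pixel is re-entered from its original entry direction.
    If the mask has several components the largest is traced (with a
    warning).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise DomainError("empty mask")
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        logger.warning("mask has %d components; tracing the largest", n)
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (int(np.argmax(sizes)) + 1)

    H, W = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < H and 0 <= c < W and mask[r, c]

    rs, cs = np.nonzero(mask)
    start = (int(rs[0]), int(cs[0]))  # row-major first foreground pixel
    if mask.sum() == 1:
        return np.array([[start[1], start[0]]])

    # entered the start pixel from its west neighbour (background by scan order)
    def next_on_boundary(cur, backtrack):
        """Clockwise search from the backtrack position around cur."""
        dr, dc = backtrack[0] - cur[0], backtrack[1] - cur[1]
        k0 = _MOORE.index((dr, dc))
        prev = backtrack
        for i in range(1, 9):
            dr, dc = _MOORE[(k0 + i) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if fg(*cand):
                return cand, prev
            prev = cand
        return None, None  # isolated pixel

    boundary = [start]
    backtrack0 = (start[0], start[1] - 1)
    cur, back = next_on_boundary(start, backtrack0)
    if cur is None:
        return np.array([[start[1], start[0]]])
    first_move = cur
    entry_back = back
    max_steps = 4 * mask.size
    for _ in range(max_steps):
        if cur == start and back == backtrack0:
            break  # Jacob: start re-entered from the original direction
        boundary.append(cur)
        cur, back = next_on_boundary(cur, back)
    else:  # pragma: no cover
        logger.warning("boundary trace did not close; returning partial trace")
    arr = np.array(boundary)
    return arr[:, ::-1]  # (row, col) -> (x, y)


def perimeter_3d(boundary_px: np.ndarray, pixel_map: np.ndarray,
                 points: np.ndarray, plane: Plane | None = None,
                 smooth_sigma: float = 1.0, normal_smooth_sigma: float = 3.0,
                 outward_offset: float = 0.0) -> float:
    """3D perimeter: closed sum of distances between lifted boundary points.

    Boundary pixels without a valid 3D point are skipped (their neighbours
    are bridged).  Two corrections address biases of a digitized, noisy
    boundary chain:

    * circular Gaussian smoothing of the closed polyline — ``smooth_sigma``
      (boundary samples) in the skin plane removes the digital staircase
      while preserving in-plane corners; the plane-normal component is
      smoothed harder (``normal_smooth_sigma``) because uncorrelated
      per-point depth noise otherwise inflates every segment, while the
      true out-of-plane profile of a wound rim is smooth.  Without a
      ``plane``, the isotropic ``smooth_sigma`` is applied.
    * ``outward_offset`` (mm, typically half the sample spacing) accounts
      for the traced chain running through pixel *centres* half a sample
      inside the region boundary: offsetting a smooth simple closed curve
      outward by d lengthens it by exactly 2*pi*d (total turning).
    """
    bp = np.asarray(boundary_px, int)
    idx = pixel_map[bp[:, 1], bp[:, 0]]
    lifted = points[idx[idx >= 0]]
    if len(lifted) < 3:
        raise DomainError("fewer than 3 valid 3D boundary points")
    if smooth_sigma > 0 and len(lifted) > 8:
        if plane is not None:
            h = lifted @ plane.n0 - plane.d0
            in_plane = lifted - np.outer(h, plane.n0)
            in_plane = ndimage.gaussian_filter1d(in_plane, smooth_sigma,
                                                 axis=0, mode="wrap")
            h = ndimage.gaussian_filter1d(h, normal_smooth_sigma, mode="wrap")
            lifted = in_plane + np.outer(h, plane.n0)
        else:
            lifted = ndimage.gaussian_filter1d(lifted, smooth_sigma, axis=0,
                                               mode="wrap")
    closed = np.vstack([lifted, lifted[:1]])
    length = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    return length + 2 * np.pi * outward_offset


# ---------------------------------------------------------------------------
# areas
# ---------------------------------------------------------------------------

def area_3d(mesh: QuadMesh) -> float:
    """Total mesh area by the per-quad two-corner cross-product rule.

    For each quad, half the sum of |e_row x e_col| evaluated at the (r, c)
    corner and at the opposite (r+1, c+1) corner.
    """
    v = mesh.vertices
    a = v[1:, :-1] - v[:-1, :-1]   # row edge at (r, c)
    b = v[:-1, 1:] - v[:-1, :-1]   # col edge at (r, c)
    c_ = v[1:, 1:] - v[:-1, 1:]    # row edge at opposite corner
    d = v[1:, 1:] - v[1:, :-1]     # col edge at opposite corner
    n1 = np.linalg.norm(np.cross(a, b), axis=-1)
    n2 = np.linalg.norm(np.cross(c_, d), axis=-1)
    return float(((n1 + n2) / 2).sum())


def plane_basis(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (u, v) with u x v = n0."""
    n = plane.n0
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(a, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def project_to_plane_2d(points: np.ndarray, plane: Plane) -> np.ndarray:
    """Rotate the cloud so the plane is the x-y plane and drop z."""
    u, v = plane_basis(plane)
    p0 = plane.d0 * plane.n0
    rel = np.asarray(points, float) - p0
    return np.stack([rel @ u, rel @ v], axis=1)


def _alpha_complex(pts2d: np.ndarray, alpha: float):
    tri = Delaunay(pts2d)
    simp = tri.simplices
    p = pts2d[simp]
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        circ_r = np.where(area2 > 1e-15, a * b * c / (2 * area2), np.inf)
    return tri, simp, circ_r, area2 / 2


def alpha_shape_area(pts2d: np.ndarray, alpha: float | None = None,
                     dilate: float = 0.0) -> tuple[float, float]:
    """Area of the 2D alpha shape enclosing all points.

    ``alpha`` is a radius in mm (triangles with circumradius <= alpha are
    kept); default is twice the median nearest-neighbour spacing.  If the
    shape does not enclose every point, alpha grows by 1.5x until it does
    (with a warning).  ``dilate`` applies a Minkowski buffer to the shape
    (used to restore the half-sample-spacing rim that point sampling of a
    filled region removes).  Returns ``(area, alpha_used)``.
    """
    pts2d = np.asarray(pts2d, float)
    if len(pts2d) < 3:
        raise DomainError("need >= 3 points for an area")
    if alpha is None:
        # bridge the widest sampling gaps, not just the typical spacing:
        # for grid samples this is ~2x the spacing, for Poisson-like
        # sampling it scales with the largest nearest-neighbour distances
        tree = cKDTree(pts2d)
        dist, _ = tree.query(pts2d, k=2)
        alpha = 2.0 * float(np.quantile(dist[:, 1], 0.995))
    tri, simp, circ_r, areas = _alpha_complex(pts2d, alpha)
    grow = 0
    while True:
        keep = circ_r <= alpha
        covered = np.zeros(len(pts2d), bool)
        covered[simp[keep].ravel()] = True
        if covered.all() and keep.any():
            break
        alpha *= 1.5
        grow += 1
        if grow > 60:
            raise DomainError("alpha shape failed to enclose all points")
    if grow:
        logger.warning("alpha grown %dx to %.3f mm to enclose all points",
                       grow, alpha)
    if dilate > 0:
        polys = shapely.polygons(pts2d[simp[keep]])
        region = shapely.union_all(polys)
        return float(region.buffer(dilate).area), alpha
    return float(areas[keep].sum()), alpha


def projected_area(wound_points: np.ndarray, plane: Plane,
                   alpha: float | None = None,
                   sample_spacing: float | None = None) -> float:
    """Wound footprint area on the skin plane via the 2D alpha shape."""
    pts2d = project_to_plane_2d(wound_points, plane)
    dil = (sample_spacing / 2) if sample_spacing else 0.0
    area, _ = alpha_shape_area(pts2d, alpha=alpha, dilate=dil)
    return area


def main_axes(wound_points: np.ndarray, plane: Plane
              ) -> tuple[float, float, np.ndarray]:
    """Principal-axis extents of the plane-projected wound points.

    Returns ``(axis_major, axis_minor, directions)`` where directions rows
    are the 2D principal directions in the plane basis.
    """
    pts2d = project_to_plane_2d(wound_points, plane)
    if len(pts2d) < 2:
        raise DomainError("need >= 2 points for axes")
    centred = pts2d - pts2d.mean(axis=0)
    if np.allclose(centred, 0):
        raise DegenerateInputError("zero-variance cloud")
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ Vt.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = np.argsort(extents)[::-1]
    return float(extents[order[0]]), float(extents[order[1]]), Vt[order]


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

def wound_volume(mesh: QuadMesh, plane: Plane) -> float:
    """Volume between the wound mesh and the skin plane (mm^3).

    The cavity is closed into a watertight surface: triangulated mesh quads,
    a wall joining the mesh boundary ring to its orthogonal projection on
    the plane, and a planar cap fanned from the projected ring centroid (the
    plane acting as the constraint that keeps the boundary surface from
    collapsing into the cavity).  The enclosed volume is the magnitude of
    the signed-tetrahedron sum over the closed surface.
    """
    if plane.signed_distance(mesh.points).max() <= 0:
        return 0.0
    m = capped_surface(mesh, plane)
    return float(abs(m.volume))


def capped_surface(mesh: QuadMesh, plane: Plane) -> trimesh.Trimesh:
    """Watertight closed surface: wound mesh + wall to the plane + planar cap.

    Closure is topological by construction (surface, wall and cap share
    vertices by index), so the result is watertight even where snapped
    border vertices coincide geometrically.
    """
    r, c = mesh.shape
    verts = mesh.points
    faces = mesh.triangles().tolist()

    ring_idx2d = mesh.boundary_indices()
    ring_flat = ring_idx2d[:, 0] * c + ring_idx2d[:, 1]
    ring_pts = verts[ring_flat]
    proj = ring_pts - np.outer(plane.signed_distance(ring_pts), plane.n0)

    n0 = len(verts)
    verts = np.vstack([verts, proj, proj.mean(axis=0, keepdims=True)])
    nb = len(ring_flat)
    centroid = n0 + nb
    for k in range(nb):
        a, b = ring_flat[k], ring_flat[(k + 1) % nb]
        ap, bp = n0 + k, n0 + (k + 1) % nb
        faces.append([a, b, bp])
        faces.append([a, bp, ap])
        faces.append([ap, bp, centroid])

    m = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not m.is_watertight:
        raise DomainError(
            "capped wound surface is not watertight "
            f"(v={len(m.vertices)}, f={len(m.faces)})")
    trimesh.repair.fix_normals(m)
    return m


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def compute_report(mesh: QuadMesh, plane: Plane, wound_mask: np.ndarray,
                   pixel_map: np.ndarray, points: np.ndarray,
                   sample_spacing: float | None = None,
                   alpha: float | None = None,
                   boundary_smooth_sigma: float = 1.5,
                   wound_points: np.ndarray | None = None,
                   metadata: dict | None = None) -> WoundReport:
    """Run all six parameter computations and assemble a report.

    ``wound_points`` defaults to the points lifted from the wound mask (used
    for the projected area and main axes); the perimeter is lifted from the
    traced mask boundary through ``pixel_map``.
    """
    if wound_points is None:
        idx = pixel_map[np.asarray(wound_mask, bool)]
        wound_points = points[idx[idx >= 0]]
    boundary = trace_perimeter_2d(wound_mask)
    perim = perimeter_3d(boundary, pixel_map, points, plane=plane,
                         smooth_sigma=boundary_smooth_sigma,
                         outward_offset=(sample_spacing or 0.0) / 2)
    amaj, amin, _ = main_axes(wound_points, plane)
    return WoundReport(
        depth_mm=wound_depth(mesh, plane),
        perimeter_mm=perim,
        area3d_mm2=area_3d(mesh),
        areaproj_mm2=projected_area(wound_points, plane, alpha=alpha,
                                    sample_spacing=sample_spacing),
        axis_major_mm=amaj,
        axis_minor_mm=amin,
        volume_mm3=wound_volume(mesh, plane),
        metadata=metadata or {},
    )
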