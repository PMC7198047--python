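"""Self-organizing-map surface meshing.

A rectangular SOM is trained on the wound point cloud: map nodes are mesh
vertices, node weights are 3D coordinates.  Because the grid topology is
fixed, the result is a hole-free quad-mesh, and because every node averages
the points it wins, reconstruction noise is attenuated.

Two boundary treatments compensate a known artifact of SOMs fitted to a
bounded support: border nodes settle roughly half a map cell *inside* the
data edge (they are centroids of their border cells).  By default the border
ring is mirror-extrapolated outward by half the local grid step; when the
sub-pixel wound contour is known its 3D lift can be passed as
``boundary_ring`` and the border nodes are snapped onto it instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .config import DegenerateInputError, DomainError, logger


@dataclass
class QuadMesh:
    """r x c grid of 3D vertices with implicit quad faces between neighbours."""

    vertices: np.ndarray  # (r, c, 3)
    training_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, float)
        if v.ndim != 3 or v.shape[2] != 3 or v.shape[0] < 2 or v.shape[1] < 2:
            raise DomainError("vertices must be an (r, c, 3) grid with r, c >= 2")
        if not np.all(np.isfinite(v)):
            raise DomainError("mesh vertices must be finite")
        self.vertices = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.vertices.shape[:2]

    @property
    def points(self) -> np.ndarray:
        return self.vertices.reshape(-1, 3)

    def boundary_indices(self) -> np.ndarray:
        """(i, j) indices of the border ring, ordered counter-clockwise."""
        r, c = self.shape
        idx = ([(0, j) for j in range(c)] +
               [(i, c - 1) for i in range(1, r)] +
               [(r - 1, j) for j in range(c - 2, -1, -1)] +
               [(i, 0) for i in range(r - 2, 0, -1)])
        return np.array(idx)

    def boundary_ring(self) -> np.ndarray:
        """Ordered 3D positions of the border ring."""
        idx = self.boundary_indices()
        return self.vertices[idx[:, 0], idx[:, 1]]

    def triangles(self) -> np.ndarray:
        """(n, 3) vertex indices splitting each quad into two triangles."""
        r, c = self.shape
        ii, jj = np.meshgrid(np.arange(r - 1), np.arange(c - 1), indexing="ij")
        v00 = (ii * c + jj).ravel()
        v01, v10 = v00 + 1, v00 + c
        v11 = v10 + 1
        return np.vstack([np.stack([v00, v10, v11], 1),
                          np.stack([v00, v11, v01], 1)])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.points, faces=self.triangles(),
                               process=False)

    def export(self, path: str) -> None:
        """Write the triangulated grid as PLY or OBJ (by extension)."""
        self.to_trimesh().export(path)


def mesh_to_surface_samples(mesh: QuadMesh) -> np.ndarray:
    """Quads as an ((r-1)(c-1), 4, 3) array, row-major, consistent winding.

    Corner order is (i,j), (i,j+1), (i+1,j+1), (i+1,j).
    """
    v = mesh.vertices
    return np.stack([v[:-1, :-1], v[:-1, 1:], v[1:, 1:], v[1:, :-1]],
                    axis=2).reshape(-1, 4, 3)


def _pca_grid_init(points: np.ndarray, r: int, c: int) -> np.ndarray:
    """Planar grid spanning the cloud's two leading principal directions."""
    centre = points.mean(axis=0)
    X = points - centre
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    d1, d2 = Vt[0], Vt[1]
    u = X @ d1
    v = X @ d2
    us = np.linspace(u.min(), u.max(), r)
    vs = np.linspace(v.min(), v.max(), c)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    return centre + uu[..., None] * d1 + vv[..., None] * d2


def _parameter_plane_folds(vertices: np.ndarray) -> bool:
    """True if projected quads have inconsistent orientation (folded map)."""
    pts = vertices.reshape(-1, 3)
    X = pts - pts.mean(0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    uv = (X @ Vt[:2].T).reshape(vertices.shape[0], vertices.shape[1], 2)
    e1 = uv[1:, :-1] - uv[:-1, :-1]
    e2 = uv[:-1, 1:] - uv[:-1, :-1]
    cross = e1[..., 0] * e2[..., 1] - e1[..., 1] * e2[..., 0]
    pos = np.count_nonzero(cross > 0)
    neg = np.count_nonzero(cross < 0)
    return min(pos, neg) > 0.02 * (pos + neg)


def _mean_point_mesh_distance(points: np.ndarray, W: np.ndarray) -> float:
    """Mean distance from each point to its nearest mesh vertex (subsampled)."""
    sub = points[:: max(1, len(points) // 2000)]
    d2 = ((sub[:, None, :] - W[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min(axis=1)).mean())


def _som_epoch_numpy(points: np.ndarray, order: np.ndarray, W: np.ndarray,
                     r: int, c: int, step0: int, total: int,
                     lr0: float, lr1: float, radius0: float, radius1: float) -> None:
    Wg = W.reshape(r * c, 3)  # view
    step = step0
    denom = max(total - 1, 1)
    for k in order:
        frac = step / denom
        lr = lr0 * (lr1 / lr0) ** frac
        sigma = radius0 * (radius1 / radius0) ** frac
        x = points[k]
        d2 = ((Wg - x) ** 2).sum(axis=1)
        bmu = int(np.argmin(d2))
        bi, bj = divmod(bmu, c)
        # restrict the update to a 3-sigma window around the BMU
        w = int(np.ceil(3 * sigma))
        i0, i1 = max(bi - w, 0), min(bi + w + 1, r)
        j0, j1 = max(bj - w, 0), min(bj + w + 1, c)
        ii = np.arange(i0, i1, dtype=float) - bi
        jj = np.arange(j0, j1, dtype=float) - bj
        gd2 = ii[:, None] ** 2 + jj[None, :] ** 2
        h = lr * np.exp(-gd2 / (2 * sigma * sigma))
        block = W[i0:i1, j0:j1]
        block += h[..., None] * (x - block)
        step += 1


try:  # JIT-compiled epoch kernel; the numpy path is the reference behaviour
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _som_epoch_jit(points, order, W, r, c, step0, total,
                       lr0, lr1, radius0, radius1):  # pragma: no cover
        denom = total - 1 if total > 1 else 1
        for s in range(order.shape[0]):
            k = order[s]
            frac = (step0 + s) / denom
            lr = lr0 * (lr1 / lr0) ** frac
            sigma = radius0 * (radius1 / radius0) ** frac
            x0, x1, x2 = points[k, 0], points[k, 1], points[k, 2]
            best = 1e300
            bi = 0
            bj = 0
            for i in range(r):
                for j in range(c):
                    d0 = W[i, j, 0] - x0
                    d1 = W[i, j, 1] - x1
                    d2v = W[i, j, 2] - x2
                    d = d0 * d0 + d1 * d1 + d2v * d2v
                    if d < best:
                        best = d
                        bi, bj = i, j
            w = int(np.ceil(3 * sigma))
            i0 = bi - w if bi - w > 0 else 0
            i1 = bi + w + 1 if bi + w + 1 < r else r
            j0 = bj - w if bj - w > 0 else 0
            j1 = bj + w + 1 if bj + w + 1 < c else c
            inv = 1.0 / (2.0 * sigma * sigma)
            for i in range(i0, i1):
                di = float(i - bi)
                for j in range(j0, j1):
                    dj = float(j - bj)
                    h = lr * np.exp(-(di * di + dj * dj) * inv)
                    W[i, j, 0] += h * (x0 - W[i, j, 0])
                    W[i, j, 1] += h * (x1 - W[i, j, 1])
                    W[i, j, 2] += h * (x2 - W[i, j, 2])

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _train_som(points: np.ndarray, r: int, c: int, epochs: int,
               lr0: float, lr1: float, radius0: float, radius1: float,
               W: np.ndarray, rng: np.random.Generator,
               ring: np.ndarray | None = None) -> tuple[np.ndarray, list[float]]:
    n = len(points)
    W = np.ascontiguousarray(W)
    total = epochs * n
    history = []
    epoch_fn = _som_epoch_jit if _HAVE_NUMBA else _som_epoch_numpy
    for e in range(epochs):
        order = rng.permutation(n)
        epoch_fn(points, order, W, r, c, e * n, total,
                 lr0, lr1, radius0, radius1)
        if ring is not None:
            # boundary-constrained fit: re-pin the border each epoch so the
            # interior adapts to a border that ends exactly on the contour
            _snap_border(W, ring)
        history.append(_mean_point_mesh_distance(points, W.reshape(r * c, 3)))
    return W, history


def _extend_border(W: np.ndarray) -> None:
    """Mirror-extrapolate the border ring outward by half the local grid step."""
    W[0, :] += 0.5 * (W[0, :] - W[1, :])
    W[-1, :] += 0.5 * (W[-1, :] - W[-2, :])
    W[:, 0] += 0.5 * (W[:, 0] - W[:, 1])
    W[:, -1] += 0.5 * (W[:, -1] - W[:, -2])


def _border_index_array(r: int, c: int) -> np.ndarray:
    border = ([(0, j) for j in range(c)] + [(i, c - 1) for i in range(1, r)] +
              [(r - 1, j) for j in range(c - 2, -1, -1)] +
              [(i, 0) for i in range(r - 2, 0, -1)])
    return np.array(border)


def _ring_interpolator(ring: np.ndarray):
    """Closed-polyline arc-length interpolator for the boundary ring."""
    closed = np.vstack([ring, ring[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]

    def at(arc: np.ndarray) -> np.ndarray:
        arc = np.mod(arc, L)
        return np.stack([np.interp(arc, s, closed[:, k]) for k in range(3)],
                        axis=1)

    return at, L


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: closest non-decreasing sequence (L2)."""
    vals = []
    counts = []
    for v in y:
        vals.append(float(v))
        counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, c2 = vals.pop(), counts.pop()
            v1, c1 = vals.pop(), counts.pop()
            vals.append((v1 * c1 + v2 * c2) / (c1 + c2))
            counts.append(c1 + c2)
    return np.repeat(vals, counts)


def _snap_border(W: np.ndarray, ring: np.ndarray) -> None:
    """Pin border nodes onto the boundary ring without folding it.

    Each border node takes the arc-length parameter of its nearest ring
    point; the parameter sequence is cyclically unwrapped and made monotone
    (pool-adjacent-violators), so grid neighbours stay neighbours along the
    contour while every node lands close to its natural station.
    """
    r, c = W.shape[:2]
    bidx = _border_index_array(r, c)
    bpos = W[bidx[:, 0], bidx[:, 1]]
    nb = len(bidx)
    at, L = _ring_interpolator(ring)

    dense_arc = np.linspace(0, L, max(4 * nb, 512), endpoint=False)
    dense_pts = at(dense_arc)
    d2 = ((bpos[:, None, :] - dense_pts[None, :, :]) ** 2).sum(-1)
    t = dense_arc[np.argmin(d2, axis=1)]

    # minimal-step cyclic unwrap, then detect orientation by net winding
    steps = np.mod(np.diff(t) + L / 2, L) - L / 2
    u = t[0] + np.concatenate([[0.0], np.cumsum(steps)])
    closing = np.mod(t[0] - u[-1] + L / 2, L) - L / 2
    winding = (u[-1] + closing) - u[0]
    if winding < 0:
        u = -u
    u = _pava_increasing(u)
    # spread exact ties (collapsed runs) so nodes do not pile up
    for k in range(1, nb):
        if u[k] <= u[k - 1]:
            u[k] = u[k - 1] + 1e-9
    if winding < 0:
        u = -u
    W[bidx[:, 0], bidx[:, 1]] = at(np.mod(u, L))


def fit_som_mesh(points: np.ndarray, grid: tuple[int, int] = (64, 64),
                 epochs: int = 10, lr: tuple[float, float] = (0.5, 0.01),
                 radius_final: float = 1.0, seed: int | None = 0,
                 boundary_ring: np.ndarray | None = None,
                 border_mode: str = "extend", conv_epochs: int = 3,
                 conv_radius: float = 0.5, conv_lr: float = 0.05) -> QuadMesh:
    """Fit an r x c SOM quad-mesh to a 3D point cloud.

    Classic online SOM in two phases.  Ordering phase (``epochs`` passes):
    per sample, the best-matching node by Euclidean distance and its
    Gaussian grid neighbourhood move toward the sample, with learning rate
    and radius decaying exponentially from ``lr[0]`` / ``max(grid)/2`` to
    ``lr[1]`` / ``radius_final``.  Convergence phase (``conv_epochs``
    passes at fixed small radius ``conv_radius`` and rate ``conv_lr``):
    nodes settle onto the local mean of their own cells, which removes the
    curvature bias that the wide ordering neighbourhood leaves on curved
    surfaces.  The map is initialized as a planar grid spanning the cloud's
    two leading principal directions; if the trained map is folded in its
    parameter plane, training restarts once from a jittered initialization.

    ``border_mode``: ``"extend"`` (default) mirror-extrapolates the border
    ring by half a grid step, ``"none"`` leaves it; passing ``boundary_ring``
    (an ordered closed 3D polyline) pins border nodes onto it (monotone
    arc-length snap, re-applied each epoch).  Deterministic for a fixed
    seed.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DomainError("points must be (N, 3)")
    r, c = grid
    if r < 2 or c < 2:
        raise DomainError("grid sides must be >= 2")
    if len(points) < r * c:
        raise DomainError(f"need at least r*c={r * c} points, got {len(points)}")
    if epochs < 1:
        raise DomainError("epochs must be >= 1")
    if np.allclose(points.std(axis=0), 0):
        raise DegenerateInputError("degenerate cloud: all points identical")

    rng = np.random.default_rng(seed)
    ring = None if boundary_ring is None else np.asarray(boundary_ring, float)
    W0 = _pca_grid_init(points, r, c)
    radius0 = max(r, c) / 2

    def run(Winit):
        W, hist = _train_som(points, r, c, epochs, lr[0], lr[1],
                             radius0, radius_final, Winit, rng, ring)
        if conv_epochs > 0:
            W, hist2 = _train_som(points, r, c, conv_epochs, conv_lr, conv_lr,
                                  conv_radius, conv_radius, W, rng, ring)
            hist = hist + hist2
        return W, hist

    W, history = run(W0.copy())
    if _parameter_plane_folds(W):
        logger.warning("SOM fold detected; restarting from jittered init")
        scale = 0.05 * (points.max(0) - points.min(0)).max()
        W, history = run(W0 + rng.normal(0, scale, W0.shape))

    if ring is None:
        if border_mode == "extend":
            _extend_border(W)
        elif border_mode != "none":
            raise DomainError(f"unknown border_mode {border_mode!r}")
    return QuadMesh(vertices=W, training_history=history)
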