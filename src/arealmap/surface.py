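"""Shared computational geometry on triangulated cortical surface meshes.

Everything downstream (boundary mapping, parcellation, rotation nulls)
operates on a :class:`SurfaceMesh` — a closed triangulated sphere carrying
anatomical coordinates, unit-sphere coordinates and a medial-wall mask.
Scalar fields ("dense maps") are plain ``numpy`` arrays with one value per
vertex; ``NaN`` marks invalid entries (medial wall or undefined).

The operators here are the primitives of gradient-based areal boundary
detection:

* tangent-plane least-squares gradient magnitude of a scalar field,
* geodesic Gaussian smoothing,
* local minima detection with plateau collapsing,
* minima-seeded Beucher-style watershed flooding with ridge vertices,
* uniform random spherical rotations with nearest-neighbour resampling
  (the "spin test" substrate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Closed triangulated sphere standing in for a registered cortical surface.

    Parameters
    ----------
    vertex_coords : (V, 3) float array
        Anatomical positions in mm.
    sphere_coords : (V, 3) float array
        Unit-norm spherical registration coordinates.
    faces : (F, 3) int array
        Triangles as vertex index triples.
    medial_wall : (V,) bool array
        True on non-cortical vertices excluded from all analyses.
    """

    vertex_coords: np.ndarray
    sphere_coords: np.ndarray
    faces: np.ndarray
    medial_wall: np.ndarray
    edges: np.ndarray = field(init=False)
    edge_lengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.medial_wall = np.asarray(self.medial_wall, dtype=bool)
        v = self.n_vertices
        if self.faces.min() < 0 or self.faces.max() >= v:
            raise ValueError("face indices out of range")
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("sphere_coords must have unit norm")
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [0, 2]]])
        e.sort(axis=1)
        self.edges = np.unique(e, axis=0)
        d = self.vertex_coords[self.edges[:, 0]] - self.vertex_coords[self.edges[:, 1]]
        self.edge_lengths = np.linalg.norm(d, axis=1)
        if v - len(self.edges) + len(self.faces) != 2:
            raise ValueError("mesh is not a closed 2-manifold (Euler check failed)")
        self._cache: dict = {}

    # -- basic views --------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def cortex(self) -> np.ndarray:
        """Boolean mask of analysed (non-medial-wall) vertices."""
        return ~self.medial_wall

    # -- cached derived structures ------------------------------------------

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric sparse matrix of edge lengths (mm) on the full mesh."""
        if "adj" not in self._cache:
            i, j = self.edges[:, 0], self.edges[:, 1]
            w = self.edge_lengths
            a = sparse.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(self.n_vertices, self.n_vertices))
            self._cache["adj"] = a.tocsr()
        return self._cache["adj"]

    def cortex_adjacency(self) -> sparse.csr_matrix:
        """Adjacency with medial-wall vertices disconnected."""
        if "cadj" not in self._cache:
            a = self.adjacency().tolil()
            mw = np.where(self.medial_wall)[0]
            a[mw, :] = 0
            a[:, mw] = 0
            self._cache["cadj"] = a.tocsr()
        return self._cache["cadj"]

    def neighbors(self) -> list[np.ndarray]:
        """1-ring neighbour index arrays, full topology."""
        if "nbrs" not in self._cache:
            a = self.adjacency()
            self._cache["nbrs"] = [a.indices[a.indptr[k]:a.indptr[k + 1]]
                                   for k in range(self.n_vertices)]
        return self._cache["nbrs"]

    def neighbor_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded (V, max_degree) neighbour table + per-vertex degree."""
        if "nbr_table" not in self._cache:
            nbrs = self.neighbors()
            deg = np.array([len(n) for n in nbrs])
            tab = np.full((self.n_vertices, deg.max()), -1, dtype=np.int64)
            for k, n in enumerate(nbrs):
                tab[k, :len(n)] = n
            self._cache["nbr_table"] = (tab, deg)
        return self._cache["nbr_table"]

    def kdtree(self) -> cKDTree:
        if "kdtree" not in self._cache:
            self._cache["kdtree"] = cKDTree(self.sphere_coords)
        return self._cache["kdtree"]

    def smoothing_matrix(self, fwhm_mm: float) -> sparse.csr_matrix:
        key = ("smooth", round(float(fwhm_mm), 9))
        if key not in self._cache:
            self._cache[key] = _build_smoothing_matrix(self, fwhm_mm)
        return self._cache[key]


def validate_mesh(mesh: SurfaceMesh) -> None:
    """Raise if the medial wall is not a single connected component."""
    mw = np.where(mesh.medial_wall)[0]
    if len(mw) == 0:
        return
    sub = mesh.adjacency()[mw][:, mw]
    n_comp, _ = connected_components(sub, directed=False)
    if n_comp != 1:
        raise ValueError(f"medial wall has {n_comp} connected components")


# ---------------------------------------------------------------------------
# Geodesics and neighbourhoods
# ---------------------------------------------------------------------------

def geodesic_distances(mesh: SurfaceMesh, sources, limit: float = np.inf) -> np.ndarray:
    """Graph-geodesic distance (mm) from source vertices over cortex edges.

    Returns an (n_sources, V) array; medial-wall vertices are unreachable
    (``inf``). Distances are shortest paths over mesh edge lengths, the
    standard cheap surrogate for exact polyhedral geodesics.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    return dijkstra(mesh.cortex_adjacency(), directed=False, indices=sources,
                    limit=limit)


def neighborhood(mesh: SurfaceMesh, vertex: int, geodesic_radius_mm: float) -> np.ndarray:
    """Vertices within a geodesic radius of ``vertex``, excluding the medial wall."""
    if not 0 <= vertex < mesh.n_vertices:
        raise ValueError(f"vertex {vertex} out of range")
    d = geodesic_distances(mesh, [vertex], limit=geodesic_radius_mm + 1e-12)[0]
    out = np.where(d <= geodesic_radius_mm)[0]
    return out[~mesh.medial_wall[out]]


# ---------------------------------------------------------------------------
# Gradient magnitude
# ---------------------------------------------------------------------------

def _tangent_basis(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent-plane bases; surface normal = radial direction."""
    n = mesh.sphere_coords
    ref = np.tile([0.0, 0.0, 1.0], (mesh.n_vertices, 1))
    near_pole = np.abs(n[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    return e1, e2


def _gradient_design(mesh: SurfaceMesh):
    """Per-vertex pseudo-inverse of the local linear design [1, t1, t2]."""
    if "grad_design" in mesh._cache:
        return mesh._cache["grad_design"]
    e1, e2 = _tangent_basis(mesh)
    nbrs = mesh.neighbors()
    x = mesh.vertex_coords
    pinvs, rows = [], []
    for i in range(mesh.n_vertices):
        if mesh.medial_wall[i]:
            pinvs.append(None)
            rows.append(None)
            continue
        nb = nbrs[i][~mesh.medial_wall[nbrs[i]]]
        if len(nb) < 3:
            pinvs.append(None)
            rows.append(None)
            continue
        pts = np.concatenate([[i], nb])
        d = x[pts] - x[i]
        t = np.column_stack([np.ones(len(pts)), d @ e1[i], d @ e2[i]])
        pinvs.append(np.linalg.pinv(t))
        rows.append(pts)
    mesh._cache["grad_design"] = (pinvs, rows)
    return pinvs, rows


def gradient_magnitude(mesh: SurfaceMesh, values: np.ndarray) -> np.ndarray:
    """Tangent-plane least-squares gradient magnitude of a scalar field.

    At each cortex vertex a linear function of the two tangent-plane
    coordinates is fit over the vertex and its valid 1-ring; the output is
    the Euclidean norm of the fitted slope (map units / mm). Accepts a
    single map ``(V,)`` or a stack of maps ``(V, C)`` (per-column).
    Vertices with fewer than 3 valid neighbours get ``NaN``.
    """
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    vals = values[:, None] if single else values
    pinvs, rows = _gradient_design(mesh)
    out = np.full_like(vals, np.nan)
    for i in range(mesh.n_vertices):
        if pinvs[i] is None:
            continue
        coef = pinvs[i] @ vals[rows[i]]
        out[i] = np.sqrt(coef[1] ** 2 + coef[2] ** 2)
    return out[:, 0] if single else out


# ---------------------------------------------------------------------------
# Geodesic Gaussian smoothing
# ---------------------------------------------------------------------------

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def _build_smoothing_matrix(mesh: SurfaceMesh, fwhm_mm: float) -> sparse.csr_matrix:
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm_mm * FWHM_TO_SIGMA
    trunc = 3.0 * sigma
    cortex_idx = np.where(mesh.cortex)[0]
    rows, cols, w = [], [], []
    # chunked multi-source Dijkstra keeps the working set O(V * chunk)
    chunk = 256
    adj = mesh.cortex_adjacency()
    for start in range(0, len(cortex_idx), chunk):
        src = cortex_idx[start:start + chunk]
        d = dijkstra(adj, directed=False, indices=src, limit=trunc)
        for a, i in enumerate(src):
            reach = np.where(np.isfinite(d[a]))[0]
            rows.append(np.full(len(reach), i))
            cols.append(reach)
            w.append(np.exp(-0.5 * (d[a, reach] / sigma) ** 2))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    mat = sparse.coo_matrix((w, (rows, cols)),
                            shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()
    norm = np.asarray(mat.sum(axis=1)).ravel()
    norm[norm == 0] = 1.0
    return sparse.diags(1.0 / norm) @ mat


def smooth(mesh: SurfaceMesh, values: np.ndarray, fwhm_mm: float) -> np.ndarray:
    """Geodesic Gaussian smoothing (kernel truncated at 3 sigma, renormalised).

    Accepts ``(V,)`` or ``(V, C)``. NaN entries are treated as invalid and
    excluded from every kernel's normalisation; medial-wall vertices stay NaN.
    """
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    vals = values[:, None] if single else values
    w = mesh.smoothing_matrix(fwhm_mm)
    valid = np.isfinite(vals)
    filled = np.where(valid, vals, 0.0)
    num = w @ filled
    den = w @ valid.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mesh.cortex] = np.nan
    out[den == 0] = np.nan
    return out[:, 0] if single else out


# ---------------------------------------------------------------------------
# Local minima
# ---------------------------------------------------------------------------

def local_minima(mesh: SurfaceMesh, values: np.ndarray) -> np.ndarray:
    """Vertices whose value is <= all valid 1-ring neighbours.

    Plateaus — connected components of equal-valued touching minima — are
    collapsed to a single representative, the lowest vertex index. NaN
    vertices are invalid and never minima (and are ignored as neighbours).
    """
    values = np.asarray(values, dtype=float)
    tab, deg = mesh.neighbor_table()
    return _minima_kernel(values, tab, deg, mesh.medial_wall)


@njit(cache=True)
def _minima_kernel(values, tab, deg, medial):  # pragma: no cover - numba
    v = len(values)
    cand = np.zeros(v, dtype=np.bool_)
    for i in range(v):
        if medial[i] or np.isnan(values[i]):
            continue
        ok = True
        for k in range(deg[i]):
            j = tab[i, k]
            if medial[j] or np.isnan(values[j]):
                continue
            if values[j] < values[i]:
                ok = False
                break
        cand[i] = ok
    # plateau collapse: BFS over equal-valued candidate neighbours
    visited = np.zeros(v, dtype=np.bool_)
    reps = []
    stack = np.empty(v, dtype=np.int64)
    for i in range(v):
        if not cand[i] or visited[i]:
            continue
        rep = i
        top = 0
        stack[top] = i
        top += 1
        visited[i] = True
        while top > 0:
            top -= 1
            u = stack[top]
            if u < rep:
                rep = u
            for k in range(deg[u]):
                j = tab[u, k]
                if cand[j] and not visited[j] and values[j] == values[u]:
                    visited[j] = True
                    stack[top] = j
                    top += 1
        reps.append(rep)
    return np.array(reps, dtype=np.int64)


# ---------------------------------------------------------------------------
# Watershed
# ---------------------------------------------------------------------------

@dataclass
class WatershedResult:
    """Seeded flooding outcome: basin labels with ridge vertices marked 0."""

    basin_label: np.ndarray   # per-vertex int, 0 = ridge or unassigned
    boundary_image: np.ndarray  # True exactly on ridge vertices


@njit(cache=True)
def _heap_push(hv, hi, n, val, idx):  # pragma: no cover - numba
    hv[n] = val
    hi[n] = idx
    k = n
    while k > 0:
        p = (k - 1) // 2
        if hv[k] < hv[p] or (hv[k] == hv[p] and hi[k] < hi[p]):
            hv[k], hv[p] = hv[p], hv[k]
            hi[k], hi[p] = hi[p], hi[k]
            k = p
        else:
            break
    return n + 1


@njit(cache=True)
def _heap_pop(hv, hi, n):  # pragma: no cover - numba
    val, idx = hv[0], hi[0]
    n -= 1
    hv[0], hi[0] = hv[n], hi[n]
    k = 0
    while True:
        l, r = 2 * k + 1, 2 * k + 2
        s = k
        if l < n and (hv[l] < hv[s] or (hv[l] == hv[s] and hi[l] < hi[s])):
            s = l
        if r < n and (hv[r] < hv[s] or (hv[r] == hv[s] and hi[r] < hi[s])):
            s = r
        if s == k:
            break
        hv[k], hv[s] = hv[s], hv[k]
        hi[k], hi[s] = hi[s], hi[k]
        k = s
    return val, idx, n


@njit(cache=True)
def _watershed_kernel(values, tab, deg, medial, seeds, ceiling):  # pragma: no cover
    v = len(values)
    label = np.zeros(v, dtype=np.int64)
    boundary = np.zeros(v, dtype=np.bool_)
    processed = np.zeros(v, dtype=np.bool_)
    cap = 8 * v + 16
    hv = np.empty(cap, dtype=np.float64)
    hi = np.empty(cap, dtype=np.int64)
    n = 0
    for s_i in range(len(seeds)):
        s = seeds[s_i]
        label[s] = s_i + 1
        n = _heap_push(hv, hi, n, values[s], s)
    while n > 0:
        _, u, n = _heap_pop(hv, hi, n)
        if processed[u]:
            continue
        processed[u] = True
        if label[u] == 0:
            # flooded from neighbours: inherit the unique neighbour basin,
            # or become a ridge vertex where >= 2 basins meet
            first = 0
            multi = False
            for k in range(deg[u]):
                j = tab[u, k]
                if processed[j] and label[j] > 0:
                    if first == 0:
                        first = label[j]
                    elif label[j] != first:
                        multi = True
                        break
            if multi:
                boundary[u] = True
            else:
                label[u] = first
        if label[u] > 0:
            for k in range(deg[u]):
                j = tab[u, k]
                if processed[j] or medial[j] or np.isnan(values[j]):
                    continue
                if values[j] > ceiling:
                    continue
                n = _heap_push(hv, hi, n, values[j], j)
    return label, boundary


def watershed(mesh: SurfaceMesh, values: np.ndarray, seeds,
              ceiling: float | None = None) -> WatershedResult:
    """Beucher-style seeded flooding by ascending map value.

    Basins grow from the seed vertices in order of (value, vertex index);
    a vertex reached by two distinct basins becomes a ridge (label 0,
    ``boundary_image`` True). With a ``ceiling``, vertices whose value
    exceeds it are never flooded and remain unassigned (label 0, not ridge).
    The result depends only on the rank order of map values.
    """
    seeds = np.atleast_1d(np.asarray(seeds, dtype=np.int64))
    if len(seeds) == 0:
        raise ValueError("watershed requires at least one seed")
    if len(np.unique(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    if mesh.medial_wall[seeds].any():
        raise ValueError("seeds must be non-medial vertices")
    values = np.asarray(values, dtype=float)
    tab, deg = mesh.neighbor_table()
    ceil = np.inf if ceiling is None else float(ceiling)
    label, boundary = _watershed_kernel(values, tab, deg, mesh.medial_wall,
                                        seeds, ceil)
    return WatershedResult(basin_label=label, boundary_image=boundary)


@njit(cache=True)
def _boundary_images_kernel(matrix, tab, deg, medial):  # pragma: no cover
    """Per column: minima (plateau-collapsed) -> watershed -> accumulate ridges."""
    v, ncols = matrix.shape
    counts = np.zeros(v, dtype=np.float64)
    n_valid_cols = 0
    stack = np.empty(v, dtype=np.int64)
    for c in range(ncols):
        col = matrix[:, c].copy()
        # local minima with plateau collapse (same rule as _minima_kernel)
        cand = np.zeros(v, dtype=np.bool_)
        for i in range(v):
            if medial[i] or np.isnan(col[i]):
                continue
            ok = True
            for k in range(deg[i]):
                j = tab[i, k]
                if medial[j] or np.isnan(col[j]):
                    continue
                if col[j] < col[i]:
                    ok = False
                    break
            cand[i] = ok
        visited = np.zeros(v, dtype=np.bool_)
        nseeds = 0
        seeds = np.empty(v, dtype=np.int64)
        for i in range(v):
            if not cand[i] or visited[i]:
                continue
            rep = i
            top = 0
            stack[top] = i
            top += 1
            visited[i] = True
            while top > 0:
                top -= 1
                u = stack[top]
                if u < rep:
                    rep = u
                for k in range(deg[u]):
                    j = tab[u, k]
                    if cand[j] and not visited[j] and col[j] == col[u]:
                        visited[j] = True
                        stack[top] = j
                        top += 1
            seeds[nseeds] = rep
            nseeds += 1
        if nseeds == 0:
            continue
        n_valid_cols += 1
        _, boundary = _watershed_kernel(col, tab, deg, medial,
                                        seeds[:nseeds], np.inf)
        for i in range(v):
            if boundary[i]:
                counts[i] += 1.0
    return counts, n_valid_cols


def watershed_boundary_fraction(mesh: SurfaceMesh, matrix: np.ndarray) -> np.ndarray:
    """Mean binary watershed boundary image over all columns of ``matrix``.

    Each column is treated as an independent scalar field: its local minima
    seed a full (no-ceiling) watershed, and the resulting binary ridge
    images are averaged across columns. Used to turn a mean gradient matrix
    into a boundary-probability map.
    """
    matrix = np.ascontiguousarray(matrix, dtype=np.float64)
    tab, deg = mesh.neighbor_table()
    counts, n_cols = _boundary_images_kernel(matrix, tab, deg, mesh.medial_wall)
    if n_cols == 0:
        raise ValueError("no column produced watershed seeds")
    out = counts / n_cols
    out[mesh.medial_wall] = np.nan
    return out


# ---------------------------------------------------------------------------
# Random spherical rotations
# ---------------------------------------------------------------------------

def sample_rotation(rng: np.random.Generator) -> Rotation:
    """Uniform random 3-D rotation (uniform unit quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q)


def rotate_map(mesh: SurfaceMesh, values: np.ndarray,
               rotation: Rotation) -> np.ndarray:
    """Resample a per-vertex payload under a rigid sphere rotation.

    Nearest-neighbour resampling on ``sphere_coords`` (label-safe, also used
    for scalars). Destination medial-wall vertices and destinations whose
    rotated source lies on the medial wall come out NaN (floats) — integer
    payloads are returned as floats with NaN marking invalid entries.
    """
    values = np.asarray(values, dtype=float)
    # value at destination d comes from the source position R^-1 @ d
    src_pts = rotation.inv().apply(mesh.sphere_coords)
    _, src_idx = mesh.kdtree().query(src_pts)
    out = values[src_idx]
    out[mesh.medial_wall[src_idx]] = np.nan
    out[mesh.medial_wall] = np.nan
    return out


def random_rotation(mesh: SurfaceMesh, payload: np.ndarray,
                    seed: int) -> np.ndarray:
    """Rotate a payload by a seeded uniform random rotation (see rotate_map)."""
    rng = np.random.default_rng(seed)
    return rotate_map(mesh, payload, sample_rotation(rng))
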