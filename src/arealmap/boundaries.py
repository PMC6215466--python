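"""Cohort-level RSFC boundary map generation.

The chain: per-subject whole-surface connectivity maps (Fisher-z
correlations between every vertex's time series and every other
vertex's), cohort bootstrap averaging, a vertex-by-vertex RSFC
similarity matrix (spatial correlation of connectivity maps), per-column
spatial gradient magnitude, geodesic smoothing, and a minima-seeded
watershed on every column of the mean gradient matrix. Averaging the
binary watershed ridge images over all seed columns yields the cohort
boundary map: the per-vertex probability, in [0, 1], that RSFC patterns
transition abruptly there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface import SurfaceMesh, gradient_magnitude, smooth, watershed_boundary_fraction

Z_CLIP = 1.0 - 1e-7
DEFAULT_N_BOOT = 100
DEFAULT_FWHM_MM = 6.0


@dataclass
class BoundaryMap:
    """Per-vertex RSFC transition probability (NaN on the medial wall)."""

    values: np.ndarray
    n_bootstraps: int = 0
    cohort: str = ""


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with r clipped to +-(1 - 1e-7) so z stays finite."""
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def subject_connectivity(clean, mesh: SurfaceMesh | None = None,
                         dtype=np.float64) -> np.ndarray:
    """Whole-surface Fisher-z connectivity matrix of one subject.

    Row i is vertex i's RSFC map: the Pearson correlation (over retained
    frames, full signed distribution) of its time series with every other
    vertex, Fisher transformed. Zero-variance rows come out NaN; with a
    mesh given, medial-wall rows/columns are NaN as well.
    """
    ts = np.asarray(clean.timeseries if hasattr(clean, "timeseries") else clean,
                    dtype=float)
    if hasattr(clean, "usable") and not clean.usable:
        raise ValueError("subject is not usable (too few retained frames)")
    t = ts.shape[1]
    x = ts - ts.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    bad = sd == 0
    sd[bad] = 1.0
    x /= sd[:, None] * np.sqrt(t)
    r = (x @ x.T).astype(dtype)
    np.clip(r, -1.0, 1.0, out=r)
    z = fisher_z(r)
    z[bad, :] = np.nan
    z[:, bad] = np.nan
    if mesh is not None:
        z[~mesh.cortex, :] = np.nan
        z[:, ~mesh.cortex] = np.nan
    return z


def similarity_matrix(mean_maps: np.ndarray, mesh: SurfaceMesh,
                      block: int = 512) -> np.ndarray:
    """Spatial correlation between every pair of vertex RSFC maps.

    Entry (i, j) is the Pearson r between rows i and j of the mean z-map
    matrix over cortex target columns, excluding the two self-connection
    entries i and j from both rows (their clipped-to-ceiling z values
    would otherwise dominate). Computed blockwise from full-row sums plus
    per-pair correction terms, so the working set stays O(V x block).
    """
    cortex = np.where(mesh.cortex)[0]
    a = np.asarray(mean_maps, dtype=float)[np.ix_(cortex, cortex)]
    n = len(cortex)
    s = a.sum(axis=1)
    ss = (a * a).sum(axis=1)
    out = np.full((mesh.n_vertices, mesh.n_vertices), np.nan)
    diag = np.diag(a)
    npairs = n - 2
    for start in range(0, n, block):
        stop = min(start + block, n)
        idx = np.arange(start, stop)
        q = a[idx] @ a.T                                     # (b, n)
        aij = a[idx]                                         # A[i, j]
        aji = a[:, idx].T                                    # A[j, i] as (b, n)
        aii = diag[idx][:, None]
        ajj = diag[None, :]
        si = s[idx][:, None] - aii - aij
        sj = s[None, :] - ajj - aji
        ssi = ss[idx][:, None] - aii ** 2 - aij ** 2
        ssj = ss[None, :] - ajj ** 2 - aji ** 2
        qq = q - aii * aji - aij * ajj
        cov = qq - si * sj / npairs
        var_i = ssi - si ** 2 / npairs
        var_j = ssj - sj ** 2 / npairs
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(var_i * var_j)
        r[np.arange(len(idx)), idx] = 1.0
        block_out = np.full((len(idx), mesh.n_vertices), np.nan)
        block_out[:, cortex] = np.clip(r, -1.0, 1.0)
        out[cortex[idx]] = block_out
    return out


def gradient_from_mean(mean_z: np.ndarray, mesh: SurfaceMesh,
                       fwhm_mm: float = DEFAULT_FWHM_MM) -> np.ndarray:
    """Single-pass similarity -> per-column gradient -> smoothing."""
    sim = similarity_matrix(mean_z, mesh)
    grad = gradient_magnitude(mesh, sim)
    return smooth(mesh, grad, fwhm_mm)


def cohort_bootstrap_gradient(z_maps: list[np.ndarray], mesh: SurfaceMesh,
                              n_boot: int = DEFAULT_N_BOOT,
                              fwhm_mm: float = DEFAULT_FWHM_MM,
                              seed: int = 0, bootstrap: bool = True) -> np.ndarray:
    """Bootstrap-mean smoothed gradient matrix for one cohort.

    Each bootstrap draws subjects with replacement (same cohort size),
    averages their z-maps, computes the RSFC similarity matrix and the
    smoothed per-column gradient magnitude; the gradient matrices are
    averaged over bootstraps. ``bootstrap=False`` runs the deterministic
    single pass on the plain subject mean (n_boot is ignored).
    """
    if len(z_maps) < 2:
        raise ValueError("need at least 2 usable subjects")
    if not bootstrap:
        mean_z = np.mean(np.stack([np.asarray(z, dtype=float) for z in z_maps]), axis=0)
        return gradient_from_mean(mean_z, mesh, fwhm_mm)
    rng = np.random.default_rng(seed)
    n_subj = len(z_maps)
    acc = None
    for _ in range(n_boot):
        take = rng.integers(0, n_subj, size=n_subj)
        counts = np.bincount(take, minlength=n_subj).astype(float)
        mean_z = np.zeros_like(np.asarray(z_maps[0], dtype=float))
        for k, c in enumerate(counts):
            if c:
                mean_z += c * np.asarray(z_maps[k], dtype=float)
        mean_z /= n_subj
        g = gradient_from_mean(mean_z, mesh, fwhm_mm)
        acc = g if acc is None else acc + g
    return acc / n_boot


def boundary_map(mean_gradient_matrix: np.ndarray, mesh: SurfaceMesh,
                 cohort: str = "", n_bootstraps: int = 0) -> BoundaryMap:
    """Average watershed ridge image over all seed columns of the gradient matrix."""
    vals = watershed_boundary_fraction(mesh, mean_gradient_matrix)
    return BoundaryMap(values=vals, n_bootstraps=n_bootstraps, cohort=cohort)


def binarize_top(values: np.ndarray, top_q: float) -> np.ndarray:
    """Boolean mask of the top-q fraction of valid values of a map."""
    if not 0 < top_q <= 1:
        raise ValueError("top_q must be in (0, 1]")
    valid = np.isfinite(values)
    if top_q == 1.0:
        return valid
    thr = np.quantile(values[valid], 1.0 - top_q)
    return valid & (values >= thr)


def boundary_conjunction(maps: list[BoundaryMap], top_q: float) -> np.ndarray:
    """Vertex-wise count of maps whose own top-q binarisation covers the vertex."""
    sizes = {len(m.values) for m in maps}
    if len(sizes) != 1:
        raise ValueError("boundary maps must share a mesh")
    out = np.zeros(sizes.pop(), dtype=int)
    for m in maps:
        out += binarize_top(m.values, top_q).astype(int)
    return out


def cohort_boundary_pipeline(clean_list, mesh: SurfaceMesh,
                             n_boot: int = DEFAULT_N_BOOT,
                             fwhm_mm: float = DEFAULT_FWHM_MM,
                             seed: int = 0, cohort: str = "",
                             bootstrap: bool = True) -> tuple[BoundaryMap, np.ndarray]:
    """Convenience: usable subjects -> z-maps -> bootstrap gradient -> boundary map.

    Returns the boundary map and the cohort-mean z-map matrix (reused by
    the evaluation statistics).
    """
    z_maps = [subject_connectivity(c, mesh, dtype=np.float32)
              for c in clean_list if c.usable]
    if len(z_maps) < 2:
        raise ValueError("fewer than 2 usable subjects in cohort")
    grad = cohort_bootstrap_gradient(z_maps, mesh, n_boot=n_boot,
                                     fwhm_mm=fwhm_mm, seed=seed,
                                     bootstrap=bootstrap)
    bmap = boundary_map(grad, mesh, cohort=cohort,
                        n_bootstraps=n_boot if bootstrap else 1)
    mean_z = np.mean(np.stack([z.astype(np.float64) for z in z_maps]), axis=0)
    return bmap, mean_z
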