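"""Parcel-graph construction and large-scale system analysis.

Nodes are parcels (mean member time series), edges are Fisher-z
correlations. Graphs are thresholded to a grid of edge densities (3-10%,
fine steps below 5%) keeping only positive, non-short-range edges (node
pairs with centroids closer than 20 mm are excluded as potentially
contaminated by local smoothing). Communities are detected with a native
two-level map-equation (Infomap-style) optimiser — implemented here so
runs are seeded and deterministic and so the codelength can be checked
against exhaustive enumeration on toy graphs — with bootstrap
mode-consensus within each density and a codified cross-density
consensus. System segregation summarises within- vs between-system
connectivity: (Z̄w − Z̄b) / Z̄w.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boundaries import fisher_z
from .evaluation import NullModelResult, dice_coefficient, rotation_null
from .parcellation import Parcellation, parcel_stats
from .surface import SurfaceMesh
from .synthetic import ASSOCIATION, SENSORY_MOTOR

DEFAULT_EXCLUSION_MM = 20.0
DEFAULT_MIN_COMMUNITY = 6
DEFAULT_NETWORK_BOOT = 1000


def default_density_grid() -> np.ndarray:
    """3-5% in 0.1% steps plus 6-10% in 1% steps (fractions)."""
    fine = np.round(np.arange(3.0, 5.0 + 1e-9, 0.1), 10)
    coarse = np.arange(6.0, 10.0 + 1e-9, 1.0)
    return np.concatenate([fine, coarse]) / 100.0


@dataclass
class ParcelGraph:
    z_matrix: np.ndarray          # (P, P) Fisher-z, diagonal NaN
    node_centroids: np.ndarray    # (P, 3) mm
    excluded: np.ndarray          # (P, P) bool, centroid distance < exclusion
    parcel_ids: np.ndarray
    subject_id: str = ""


@dataclass
class SegregationResult:
    z_within: float
    z_between: float
    segregation: float
    scope: str = "overall"


@dataclass
class SystemPartition:
    per_density: dict[float, np.ndarray]
    consensus: np.ndarray
    density_grid: np.ndarray
    system_type: dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Graph construction and thresholding
# ---------------------------------------------------------------------------

def build_graph(parcellation: Parcellation, clean, mesh: SurfaceMesh,
                exclusion_mm: float = DEFAULT_EXCLUSION_MM,
                subject_id: str = "") -> ParcelGraph:
    """Node-to-node Fisher-z matrix from parcel-mean time series."""
    ts = clean.timeseries if hasattr(clean, "timeseries") else np.asarray(clean)
    if hasattr(clean, "usable") and not clean.usable:
        raise ValueError("subject is not usable")
    labels = parcellation.labels
    ids = parcellation.parcel_ids
    node_ts = np.empty((len(ids), ts.shape[1]))
    for k, pid in enumerate(ids):
        members = labels == pid
        if not members.any():
            raise ValueError(f"parcel {pid} is empty")
        node_ts[k] = ts[members].mean(axis=0)
    r = np.corrcoef(node_ts)
    z = fisher_z(np.clip(r, -1, 1))
    np.fill_diagonal(z, np.nan)
    stats = parcel_stats(parcellation, mesh)
    cent = np.array([stats.centroids[int(p)] for p in ids])
    d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=2)
    excluded = d < exclusion_mm
    np.fill_diagonal(excluded, True)
    return ParcelGraph(z_matrix=z, node_centroids=cent, excluded=excluded,
                       parcel_ids=ids, subject_id=subject_id)


def threshold_density(z_matrix: np.ndarray, excluded: np.ndarray,
                      density: float) -> np.ndarray:
    """Top-density positive edge weights as a symmetric matrix (0 = no edge).

    Keeps round(density * n(n-1)/2) candidate edges (positive z, not
    excluded) by descending z, ties broken by (z, node-pair lexicographic).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = z_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z_matrix[iu, ju]
    ok = np.isfinite(w) & (w > 0) & ~excluded[iu, ju]
    want = int(round(density * n * (n - 1) / 2))
    cand = np.where(ok)[0]
    if len(cand) < want:
        warnings.warn(f"only {len(cand)} candidate edges for requested {want}; keeping all")
        keep = cand
    else:
        order = np.lexsort((ju[cand], iu[cand], -w[cand]))
        keep = cand[order[:want]]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return out


# ---------------------------------------------------------------------------
# Two-level map equation (native Infomap-style optimiser)
# ---------------------------------------------------------------------------

def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    return np.where(x > 0, x * np.log2(np.maximum(x, 1e-300)), 0.0)


def map_equation_codelength(weights: np.ndarray, labels: np.ndarray) -> float:
    """Two-level description length (bits) of a random walk under a partition.

    Undirected weighted formulation: node visit rates are strengths over
    total weight; module exit rates are the cut weights. Isolated nodes
    contribute nothing.
    """
    w_tot = weights.sum()
    if w_tot == 0:
        return 0.0
    p = weights.sum(axis=1) / w_tot          # node visit rates (sum 1)
    mods = np.unique(labels)
    q = np.zeros(len(mods))
    pm = np.zeros(len(mods))
    for k, m in enumerate(mods):
        mask = labels == m
        pm[k] = p[mask].sum()
        q[k] = weights[np.ix_(mask, ~mask)].sum() / w_tot
    q_tot = q.sum()
    l = (_plogp(q_tot) - 2 * np.sum(_plogp(q))
         + np.sum(_plogp(q + pm)) - np.sum(_plogp(p)))
    return float(l)


def _greedy_pass(weights: np.ndarray, labels: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Repeated best-improvement single-node moves until convergence."""
    n = len(labels)
    labels = labels.copy()
    best_l = map_equation_codelength(weights, labels)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            neigh_mods = set(labels[np.where(weights[i] > 0)[0]])
            neigh_mods.add(int(labels.max()) + 1)     # fresh singleton
            neigh_mods.discard(labels[i])
            cur = labels[i]
            best_mod, best_val = cur, best_l
            for m in neigh_mods:
                labels[i] = m
                val = map_equation_codelength(weights, labels)
                if val < best_val - 1e-12:
                    best_mod, best_val = m, val
            labels[i] = best_mod
            if best_mod != cur:
                best_l = best_val
                improved = True
    return labels, best_l


def map_equation_partition(weights: np.ndarray, seed: int = 0,
                           n_restarts: int = 10) -> tuple[np.ndarray, float]:
    """Minimise the two-level map equation by seeded greedy node moving.

    Runs ``n_restarts`` restarts (all-singleton start plus random initial
    partitions) and keeps the best codelength. Isolated nodes become
    singleton communities. Deterministic given the seed. Returns
    (community labels 1..K, codelength).
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    degree = weights.sum(axis=1)
    if not (degree > 0).any():
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    best_labels, best_l = None, np.inf
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            init = np.arange(n)
        elif restart == 1 and n > 1:
            init = np.zeros(n, dtype=int)
        else:
            init = rng.integers(0, max(2, n // 2), size=n)
        labels, l = _greedy_pass(weights, init, rng)
        if l < best_l - 1e-12:
            best_labels, best_l = labels, l
    # canonical relabel 1..K by first node occurrence; isolated -> singletons
    out = np.zeros(n, dtype=int)
    nxt = 1
    for i in range(n):
        if degree[i] == 0:
            out[i] = 0
        elif out[i] == 0:
            mask = (best_labels == best_labels[i]) & (degree > 0) & (out == 0)
            out[mask] = nxt
            nxt += 1
    for i in range(n):
        if degree[i] == 0:
            out[i] = nxt
            nxt += 1
    return out, best_l


# ---------------------------------------------------------------------------
# Bootstrap mode communities and cross-density consensus
# ---------------------------------------------------------------------------

def align_partition(reference: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` onto reference ids by maximal-Jaccard matching.

    Each community (descending size) takes the id of the unclaimed
    reference community with maximal Jaccard node overlap; leftovers get
    fresh ids. Makes per-node modes comparable across bootstrap runs.
    """
    out = np.zeros_like(labels)
    used = set()
    ids = sorted(np.unique(labels), key=lambda c: (-np.sum(labels == c), c))
    fresh = int(reference.max()) + 1
    for c in ids:
        mask = labels == c
        best_ref, best_j = None, 0.0
        for r in np.unique(reference):
            rmask = reference == r
            j = np.sum(mask & rmask) / np.sum(mask | rmask)
            if r not in used and (j > best_j + 1e-12 or
                                  (best_ref is not None and j == best_j and r < best_ref)):
                best_ref, best_j = int(r), j
        if best_ref is not None and best_j > 0:
            out[mask] = best_ref
            used.add(best_ref)
        else:
            out[mask] = fresh
            fresh += 1
    return out


def bootstrap_mode_communities(z_matrices: list[np.ndarray], excluded: np.ndarray,
                               density: float, n_boot: int = DEFAULT_NETWORK_BOOT,
                               seed: int = 0, n_restarts: int = 4) -> np.ndarray:
    """Per-node modal community across bootstrap resamples of subjects.

    Each bootstrap averages resampled subjects' z-matrices, thresholds at
    the given density and partitions the graph; partitions are aligned to
    the first bootstrap's labels before the per-node mode is taken.
    """
    if len(z_matrices) < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(seed)
    stack = np.stack([np.asarray(z, dtype=float) for z in z_matrices])
    reference = None
    votes = []
    for b in range(n_boot):
        take = rng.integers(0, len(stack), size=len(stack))
        mean_z = stack[take].mean(axis=0)
        w = threshold_density(mean_z, excluded, density)
        labels, _ = map_equation_partition(w, seed=int(rng.integers(2 ** 31)),
                                           n_restarts=n_restarts)
        if reference is None:
            reference = labels
            votes.append(labels)
        else:
            votes.append(align_partition(reference, labels))
    votes = np.stack(votes)
    out = np.empty(votes.shape[1], dtype=int)
    for i in range(votes.shape[1]):
        vals, counts = np.unique(votes[:, i], return_counts=True)
        out[i] = vals[np.argmax(counts)]      # ties -> lowest label
    return out


def cross_density_consensus(per_density: dict[float, np.ndarray],
                            min_size: int = DEFAULT_MIN_COMMUNITY) -> np.ndarray:
    """Collapse per-density modal assignments into one consensus labelling.

    Community ids are first chained onto a common label space (each
    density aligned to the previous, sparser one). A (density, community)
    assignment is valid if the community has >= ``min_size`` nodes at that
    density and appears at >= 2 densities. Starting from the sparsest
    density, each node keeps its sparsest valid assignment; a node with no
    valid assignment at the sparsest density takes its assignment at the
    nearest less-sparse (denser) density where its community is valid;
    any node still unresolved takes its majority assignment across
    densities (the codified replacement for manual reassignment).
    """
    densities = sorted(per_density)
    aligned = {}
    prev = None
    for d in densities:
        lab = np.asarray(per_density[d])
        aligned[d] = lab if prev is None else align_partition(prev, lab)
        prev = aligned[d]
    n = len(aligned[densities[0]])
    presence: dict[int, set[float]] = {}
    for d in densities:
        for c in np.unique(aligned[d]):
            presence.setdefault(int(c), set()).add(d)

    def valid(d, c):
        return (np.sum(aligned[d] == c) >= min_size
                and len(presence.get(int(c), ())) >= 2)

    out = np.zeros(n, dtype=int)
    for i in range(n):
        for d in densities:                    # sparsest first, then denser
            c = int(aligned[d][i])
            if valid(d, c):
                out[i] = c
                break
        else:
            hist = [int(aligned[d][i]) for d in densities]
            vals, counts = np.unique(hist, return_counts=True)
            out[i] = vals[np.argmax(counts)]
            warnings.warn(f"node {i}: no valid community at any density; "
                          "majority-across-densities assignment used")
    if (out == 0).any():
        raise ValueError("consensus failed to assign some nodes")
    return out


# ---------------------------------------------------------------------------
# System matching (labels + spin-null Dice)
# ---------------------------------------------------------------------------

def match_systems(consensus: np.ndarray, reference_of_node: np.ndarray,
                  parcellation: Parcellation, mesh: SurfaceMesh,
                  n_rot: int = 100, seed: int = 0,
                  merge_map: dict[int, int] | None = None
                  ) -> tuple[dict[int, int], dict[int, NullModelResult]]:
    """Label consensus communities by maximal node overlap with reference systems.

    Returns (community -> reference system id, per-system spin-null Dice).
    ``merge_map`` optionally merges reference systems (e.g. two somatomotor
    subsystems) before matching. The null rotates the reference system
    vertex map.
    """
    reference_of_node = np.asarray(reference_of_node).copy()
    if merge_map:
        for old, new in merge_map.items():
            reference_of_node[reference_of_node == old] = new
    communities = np.unique(consensus)
    label_of: dict[int, int] = {}
    for c in communities:
        mask = consensus == c
        refs, counts = np.unique(reference_of_node[mask], return_counts=True)
        label_of[int(c)] = int(refs[np.argmax(counts)]) if len(refs) else 0

    # vertex-level system maps
    labels = parcellation.labels
    ids = parcellation.parcel_ids
    sys_vertex = np.zeros(mesh.n_vertices, dtype=int)
    ref_vertex = np.zeros(mesh.n_vertices, dtype=int)
    for k, pid in enumerate(ids):
        sys_vertex[labels == pid] = label_of[int(consensus[k])]
        ref_vertex[labels == pid] = reference_of_node[k]

    z_per_system: dict[int, NullModelResult] = {}
    for s in np.unique(ref_vertex[ref_vertex > 0]):
        target = sys_vertex == s

        def stat(rot_ref, s=s, target=target):
            rot_mask = rot_ref == s
            if rot_mask.sum() < 0.5 * np.sum(ref_vertex == s):
                return np.nan                # mostly clipped into the wall
            return dice_coefficient(target, rot_mask)

        res = rotation_null(stat, ref_vertex, mesh, n_rot=n_rot, seed=seed,
                            payload_kind="labels")
        res.actual = dice_coefficient(target, ref_vertex == s)
        z_per_system[int(s)] = res
    return label_of, z_per_system


# ---------------------------------------------------------------------------
# System segregation
# ---------------------------------------------------------------------------

def system_segregation(z_matrix: np.ndarray, node_systems: np.ndarray,
                       system_type: dict[int, str] | None = None,
                       scope: str = "overall") -> SegregationResult:
    """Within- vs between-system connectivity contrast (Z̄w − Z̄b)/Z̄w.

    Negative edges are excluded from both means. ``scope`` is one of
    ``overall`` (pooled within-system pairs vs pooled between-system
    pairs), ``association`` / ``sensory-motor`` (per-system within and
    between means over systems of that type vs *all* other systems,
    averaged over systems), and ``association-to-sensory`` (between mean
    restricted to pairs crossing the two types).
    """
    z = np.asarray(z_matrix, dtype=float)
    sysv = np.asarray(node_systems)
    iu, ju = np.triu_indices(len(sysv), k=1)
    w = z[iu, ju]
    ok = np.isfinite(w) & (w > 0)
    same = sysv[iu] == sysv[ju]

    def pooled(mask):
        vals = w[ok & mask]
        return float(vals.mean()) if len(vals) else np.nan

    if scope == "overall":
        zw = pooled(same)
        zb = pooled(~same)
    else:
        if system_type is None:
            raise ValueError("typed scopes require system_type")
        if scope in (ASSOCIATION, SENSORY_MOTOR):
            focal = [s for s in np.unique(sysv) if system_type.get(int(s)) == scope]
            other_filter = None
        elif scope == "association-to-sensory":
            focal = [s for s in np.unique(sysv) if system_type.get(int(s)) == ASSOCIATION]
            other_filter = SENSORY_MOTOR
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if len(focal) < 1:
            raise ValueError("no systems of the requested type")
        zw_list, zb_list = [], []
        for s in focal:
            in_s = sysv == s
            zw_list.append(pooled(same & in_s[iu]))
            if other_filter is None:
                cross = (in_s[iu] & ~in_s[ju]) | (in_s[ju] & ~in_s[iu])
            else:
                other = np.isin(sysv, [t for t in np.unique(sysv)
                                       if system_type.get(int(t)) == other_filter])
                cross = (in_s[iu] & other[ju]) | (in_s[ju] & other[iu])
            zb_list.append(pooled(cross))
        zw = float(np.nanmean(zw_list))
        zb = float(np.nanmean(zb_list))
    if not np.isfinite(zw) or zw <= 0:
        raise ValueError("segregation undefined: mean within-system connectivity <= 0")
    if not np.isfinite(zb):
        zb = 0.0
    return SegregationResult(z_within=zw, z_between=zb,
                             segregation=(zw - zb) / zw, scope=scope)


def segregation_age_trend(segregation: np.ndarray, ages: np.ndarray):
    """Age trend of per-subject segregation: Pearson r plus cubic OLS F."""
    import statsmodels.api as sm
    from scipy.stats import pearsonr

    seg = np.asarray(segregation, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(seg) < 10:
        raise ValueError("need >= 10 subjects")
    if seg.std() == 0:
        raise ValueError("constant segregation; correlation undefined")
    r, p = pearsonr(seg, ages)
    a = (ages - ages.mean()) / ages.std()
    design = np.column_stack([np.ones_like(a), a, a ** 2, a ** 3])
    fit = sm.OLS(seg, design).fit()
    return {"r": float(r), "p": float(p),
            "cubic_f": float(fit.fvalue), "cubic_f_p": float(fit.f_pvalue),
            "cubic_coefs": [float(c) for c in fit.params],
            "df": (int(fit.df_model), int(fit.df_resid))}
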