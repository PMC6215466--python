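"""Boundary-map and parcellation comparison statistics with rotation nulls.

Every chance-corrected statistic here shares one null-model recipe: the
payload (a boundary map or a parcellation) is rigidly rotated on the
sphere ``n_rot`` times, the statistic is recomputed per rotation, and

    Z = (actual - mean(null)) / sd(null).

Units that land on the medial wall under a rotation (a vertex for map
payloads, a parcel whose member fraction on the wall exceeds a
configurable tolerance for label payloads) are replaced by that unit's
mean over the valid rotations before aggregation, so the null is not
biased by wall clipping.

Also here: parcel homogeneity (percent variance explained by the first
principal component of member connectivity maps), the adjacent-parcel
silhouette coefficient, Jaccard parcel matching with matched-pair RSFC
similarity, the adjusted Rand index, within-parcel task-beta dispersion,
a vertex-wise regression of boundary differences on thickness and
deformation differences, and a one-way ANOVA recomputed from printed
group summaries (the worked example uses published lifespan-cohort MMSE
summaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .boundaries import BoundaryMap, binarize_top
from .surface import SurfaceMesh, rotate_map, sample_rotation

DEFAULT_N_ROTATIONS = 100
PARCEL_WALL_TOLERANCE = 0.25   # rotated parcel invalid if >25% lands on the wall


# ---------------------------------------------------------------------------
# Published cohort summary used as the worked ANOVA example: Mini-Mental
# State Examination (MMSE) scores of five adult-lifespan age cohorts
# (replication sample), as printed: mean (SD) and cohort N.
# ---------------------------------------------------------------------------
MMSE_COHORT_SUMMARIES = {
    "YA": {"age_range": (20, 34), "mean": 28.66, "sd": 1.19, "n": 62},
    "ME": {"age_range": (35, 49), "mean": 28.77, "sd": 1.12, "n": 49},
    "ML": {"age_range": (50, 64), "mean": 28.42, "sd": 1.14, "n": 43},
    "OE": {"age_range": (65, 79), "mean": 27.84, "sd": 1.22, "n": 38},
    "OL": {"age_range": (80, 93), "mean": 27.43, "sd": 1.10, "n": 30},
}


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class NullModelResult:
    actual: float
    null_values: np.ndarray
    n_rotations: int
    tail: str = "upper"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=0))

    @property
    def z(self) -> float:
        sd = self.null_sd
        if sd == 0:
            return np.inf if self.actual >= self.null_mean else -np.inf
        return (self.actual - self.null_mean) / sd

    @property
    def p(self) -> float:
        null = np.asarray(self.null_values)
        if self.tail == "upper":
            return float(np.mean(null >= self.actual))
        return float(np.mean(null <= self.actual))


@dataclass
class HomogeneityResult:
    per_parcel: dict[int, float]
    mean_homogeneity: float


@dataclass
class SilhouetteResult:
    per_vertex: np.ndarray
    mean_coef: float


@dataclass
class ParcelMatch:
    pairs: list[tuple[int, int, float]]     # (parcel_A, parcel_B, jaccard)
    mean_overlap: float
    rsfc_similarity: dict[tuple[int, int], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Boundary map comparison
# ---------------------------------------------------------------------------

def _values(m) -> np.ndarray:
    return m.values if isinstance(m, BoundaryMap) else np.asarray(m, dtype=float)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice = 2|A∩B| / (|A|+|B|) on boolean masks; empty union -> 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.sum(a & b) / denom


def dice_boundary(map_a, map_b, top_q: float) -> float:
    """Dice overlap of the two maps' own top-q binarisations."""
    va, vb = _values(map_a), _values(map_b)
    if va.shape != vb.shape:
        raise ValueError("boundary maps must share a mesh")
    return dice_coefficient(binarize_top(va, top_q), binarize_top(vb, top_q))


def map_correlation(map_a, map_b) -> float:
    """Pearson r over vertices valid in both maps."""
    va, vb = _values(map_a), _values(map_b)
    ok = np.isfinite(va) & np.isfinite(vb)
    x, y = va[ok], vb[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Rotation null engine
# ---------------------------------------------------------------------------

def rotation_null(statistic, payload: np.ndarray, mesh: SurfaceMesh,
                  n_rot: int = DEFAULT_N_ROTATIONS, seed: int = 0,
                  payload_kind: str = "map", tail: str = "upper") -> NullModelResult:
    """Spin-test null for any statistic of a rotated surface payload.

    ``statistic(values)`` receives the rotated payload and returns either
    a scalar or a 1-D per-unit array (NaN marking invalid units); per-unit
    NaNs are replaced by the unit's mean over valid rotations before each
    rotation is aggregated by the mean. ``payload_kind`` is ``"map"``
    (scalar field; rotated medial-wall vertices are pre-substituted by
    their cross-rotation means) or ``"labels"`` (integer parcellation;
    rotated wall vertices become 0 and the statistic handles parcel-level
    validity itself).
    """
    rng = np.random.default_rng(seed)
    payload = np.asarray(payload, dtype=float)
    rotations = [sample_rotation(rng) for _ in range(n_rot)]
    rotated = [rotate_map(mesh, payload, rot) for rot in rotations]

    if payload_kind == "map":
        stack = np.stack(rotated)                       # (n_rot, V)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vertex_means = np.nanmean(stack, axis=0)
        for r in range(n_rot):
            hole = ~np.isfinite(stack[r]) & mesh.cortex & np.isfinite(vertex_means)
            stack[r, hole] = vertex_means[hole]
        rotated = list(stack)
    elif payload_kind == "labels":
        rotated = [np.where(np.isfinite(r), r, 0).astype(int) for r in rotated]
    else:
        raise ValueError("payload_kind must be 'map' or 'labels'")

    per_rot = [np.atleast_1d(np.asarray(statistic(r), dtype=float))
               for r in rotated]
    null_matrix = np.stack(per_rot)                     # (n_rot, n_units)
    if null_matrix.shape[1] > 1 or np.isnan(null_matrix).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            unit_means = np.nanmean(null_matrix, axis=0)
        dead = ~np.isfinite(unit_means)
        if dead.any():
            warnings.warn(f"{int(dead.sum())} unit(s) invalid in every rotation; excluded")
        filled = np.where(np.isnan(null_matrix), unit_means[None, :], null_matrix)
        null_values = np.nanmean(filled[:, ~dead], axis=1)
    else:
        null_values = null_matrix[:, 0]

    actual_units = np.atleast_1d(np.asarray(
        statistic(payload if payload_kind == "map" else payload.astype(int)),
        dtype=float))
    actual = float(np.nanmean(actual_units))
    return NullModelResult(actual=actual, null_values=null_values,
                           n_rotations=n_rot, tail=tail)


# ---------------------------------------------------------------------------
# Homogeneity
# ---------------------------------------------------------------------------

def parcel_homogeneity_values(labels: np.ndarray, mean_maps: np.ndarray,
                              mesh: SurfaceMesh,
                              wall_tolerance: float = PARCEL_WALL_TOLERANCE,
                              reference_labels: np.ndarray | None = None) -> np.ndarray:
    """Per-parcel percent variance explained by PC1 of member RSFC maps.

    Parcels are taken from ``reference_labels`` (default: ``labels``)'s id
    set so rotated copies stay aligned unit-by-unit; a parcel with fewer
    than 2 surviving cortex members, or losing more than ``wall_tolerance``
    of its reference size, is NaN (invalid for this rotation).
    """
    ref = labels if reference_labels is None else reference_labels
    ids = np.unique(ref[ref > 0])
    ref_sizes = {int(p): int(np.sum(ref == p)) for p in ids}
    target_cols = np.where(mesh.cortex)[0]
    out = np.full(len(ids), np.nan)
    for k, pid in enumerate(ids):
        members = np.where((labels == pid) & mesh.cortex)[0]
        if len(members) < 2 or len(members) < (1 - wall_tolerance) * ref_sizes[int(pid)]:
            continue
        m = mean_maps[np.ix_(members, target_cols)]
        m = m[:, np.isfinite(m).all(axis=0)]
        # PCA with target vertices as observations and members as variables:
        # centre each member map over targets, then PC1 share of the member
        # covariance = fraction of map variance the parcel's vertices share
        mc = m - m.mean(axis=1, keepdims=True)
        gram = mc @ mc.T
        total = np.trace(gram)
        if total <= 0:
            warnings.warn(f"parcel {pid} has rank-0 connectivity; homogeneity 100")
            out[k] = 100.0
            continue
        top = np.linalg.eigvalsh(gram)[-1]
        out[k] = 100.0 * top / total
    return out


def homogeneity(parcellation, mean_maps: np.ndarray,
                mesh: SurfaceMesh) -> HomogeneityResult:
    labels = parcellation.labels if hasattr(parcellation, "labels") else parcellation
    vals = parcel_homogeneity_values(labels, mean_maps, mesh)
    ids = np.unique(labels[labels > 0])
    per = {int(p): float(v) for p, v in zip(ids, vals) if np.isfinite(v)}
    return HomogeneityResult(per_parcel=per,
                             mean_homogeneity=float(np.mean(list(per.values()))))


def z_homogeneity(labels: np.ndarray, mean_maps: np.ndarray, mesh: SurfaceMesh,
                  n_rot: int = DEFAULT_N_ROTATIONS, seed: int = 0) -> NullModelResult:
    """Spin-null Z of mean parcel homogeneity (rotating the parcellation)."""
    labels = np.asarray(labels)

    def stat(rot_labels):
        return parcel_homogeneity_values(rot_labels, mean_maps, mesh,
                                         reference_labels=labels)

    return rotation_null(stat, labels, mesh, n_rot=n_rot, seed=seed,
                         payload_kind="labels", tail="upper")


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------

def _row_correlations(mean_maps: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Correlation between all vertex RSFC maps over finite cortex columns."""
    cortex = np.where(mesh.cortex)[0]
    a = mean_maps[np.ix_(cortex, cortex)]
    keep = np.isfinite(a).all(axis=0)
    r = np.corrcoef(a[:, keep])
    out = np.full((mean_maps.shape[0], mean_maps.shape[0]), np.nan)
    out[np.ix_(cortex, cortex)] = r
    return out


def parcel_adjacency(labels: np.ndarray, mesh: SurfaceMesh) -> dict[int, set[int]]:
    """Immediately adjacent parcels, bridging unassigned boundary zones.

    Unassigned cortex vertices (watershed ridges and above-ceiling zones)
    are attributed to their geodesically nearest parcel; two parcels are
    adjacent when their extended territories share a mesh edge.
    """
    from scipy.sparse.csgraph import dijkstra as _dijkstra

    ids = np.unique(labels[labels > 0])
    extended = np.asarray(labels).copy()
    unassigned = (extended == 0) & mesh.cortex
    if unassigned.any() and len(ids):
        sources = np.where(extended > 0)[0]
        d = _dijkstra(mesh.cortex_adjacency(), directed=False, indices=sources,
                      min_only=True, return_predecessors=True)
        dist, _, src = d
        reach = unassigned & np.isfinite(dist)
        extended[reach] = extended[src[reach]]
    adj: dict[int, set[int]] = {int(p): set() for p in ids}
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    touch = (extended[i] > 0) & (extended[j] > 0) & (extended[i] != extended[j])
    for a, b in zip(extended[i][touch], extended[j][touch]):
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    return adj


def silhouette(parcellation, mean_maps: np.ndarray,
               mesh: SurfaceMesh) -> SilhouetteResult:
    """Adjacent-parcel silhouette of vertex RSFC maps.

    Dissimilarity is 1 - Pearson r between whole-surface maps. ``a_i``
    averages over own-parcel members (self excluded); ``b_i`` pools the
    members of all immediately adjacent parcels into a single mean (not
    the classic per-cluster minimum). Coefficient = (b-a)/max(a, b).
    """
    labels = parcellation.labels if hasattr(parcellation, "labels") else parcellation
    corr = _row_correlations(mean_maps, mesh)
    dis = 1.0 - corr
    adj = parcel_adjacency(labels, mesh)
    out = np.full(mesh.n_vertices, np.nan)
    members = {int(p): np.where(labels == p)[0] for p in np.unique(labels[labels > 0])}
    for pid, verts in members.items():
        if len(verts) < 2:
            continue
        neigh = adj.get(pid, set())
        if not neigh:
            warnings.warn(f"parcel {pid} has no adjacent parcel; vertices excluded")
            continue
        pool = np.concatenate([members[q] for q in sorted(neigh)])
        for v in verts:
            own = verts[verts != v]
            a_i = np.nanmean(dis[v, own])
            b_i = np.nanmean(dis[v, pool])
            m = max(a_i, b_i)
            out[v] = 0.0 if m == 0 else (b_i - a_i) / m
    return SilhouetteResult(per_vertex=out,
                            mean_coef=float(np.nanmean(out)))


# ---------------------------------------------------------------------------
# Parcel matching, overlap and matched RSFC similarity
# ---------------------------------------------------------------------------

def _contingency(labels_a: np.ndarray, labels_b: np.ndarray):
    ids_a = np.unique(labels_a[labels_a > 0])
    ids_b = np.unique(labels_b[labels_b > 0])
    table = np.zeros((len(ids_a), len(ids_b)), dtype=np.int64)
    pos_a = {p: k for k, p in enumerate(ids_a)}
    pos_b = {p: k for k, p in enumerate(ids_b)}
    both = (labels_a > 0) & (labels_b > 0)
    for a, b in zip(labels_a[both], labels_b[both]):
        table[pos_a[a], pos_b[b]] += 1
    return ids_a, ids_b, table


def match_parcels(parc_a, parc_b) -> ParcelMatch:
    """Match every A-parcel to its maximal-Jaccard B-parcel (ties: lower B id)."""
    la = parc_a.labels if hasattr(parc_a, "labels") else np.asarray(parc_a)
    lb = parc_b.labels if hasattr(parc_b, "labels") else np.asarray(parc_b)
    if la.shape != lb.shape:
        raise ValueError("parcellations must share a mesh")
    ids_a, ids_b, inter = _contingency(la, lb)
    size_a = np.array([(la == p).sum() for p in ids_a])
    size_b = np.array([(lb == p).sum() for p in ids_b])
    union = size_a[:, None] + size_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    pairs = []
    for k, pa in enumerate(ids_a):
        j = int(np.argmax(jac[k]))        # argmax returns the first (lowest) tie
        pairs.append((int(pa), int(ids_b[j]), float(jac[k, j])))
    mean_overlap = float(np.mean([p[2] for p in pairs])) if pairs else 0.0
    return ParcelMatch(pairs=pairs, mean_overlap=mean_overlap)


def parcel_mean_maps(labels: np.ndarray, mean_maps: np.ndarray) -> dict[int, np.ndarray]:
    """Whole-surface RSFC map per parcel: mean over member vertices' maps."""
    return {int(p): np.nanmean(mean_maps[labels == p], axis=0)
            for p in np.unique(labels[labels > 0])}


def matched_rsfc_similarity(match: ParcelMatch, maps_a: dict[int, np.ndarray],
                            maps_b: dict[int, np.ndarray]) -> ParcelMatch:
    """Pearson r of cohort-average RSFC maps of each matched parcel pair."""
    sims = {}
    for pa, pb, _ in match.pairs:
        x, y = maps_a[pa], maps_b[pb]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            warnings.warn(f"degenerate maps for pair ({pa}, {pb}); skipped")
            continue
        sims[(pa, pb)] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    match.rsfc_similarity = sims
    return match


def z_overlap_and_rsfc(parc_a, parc_b, maps_a: dict[int, np.ndarray],
                       maps_b: dict[int, np.ndarray], mesh: SurfaceMesh,
                       n_rot: int = DEFAULT_N_ROTATIONS, seed: int = 0,
                       wall_tolerance: float = PARCEL_WALL_TOLERANCE
                       ) -> tuple[NullModelResult, NullModelResult]:
    """Spin-null Z of mean matched overlap and of mean matched-pair RSFC r.

    Parcellation B is rotated; matching is recomputed per rotation. A
    parcel of A whose matched rotated parcel lost more than the wall
    tolerance is NaN for that rotation (substituted by the engine).
    """
    la = parc_a.labels if hasattr(parc_a, "labels") else np.asarray(parc_a)
    lb = parc_b.labels if hasattr(parc_b, "labels") else np.asarray(parc_b)
    ids_a = np.unique(la[la > 0])
    ref_sizes_b = {int(p): int((lb == p).sum()) for p in np.unique(lb[lb > 0])}

    def per_unit(rot_lb, which):
        m = match_parcels(la, rot_lb)
        if which == "rsfc":
            m = matched_rsfc_similarity(m, maps_a, maps_b)
        out = np.full(len(ids_a), np.nan)
        pos = {int(p): k for k, p in enumerate(ids_a)}
        surv = {int(p): int((rot_lb == p).sum()) for p in np.unique(rot_lb[rot_lb > 0])}
        for pa, pb, jac in m.pairs:
            if surv.get(pb, 0) < (1 - wall_tolerance) * ref_sizes_b.get(pb, 1):
                continue
            if which == "overlap":
                out[pos[pa]] = jac
            else:
                out[pos[pa]] = m.rsfc_similarity.get((pa, pb), np.nan)
        return out

    z_ov = rotation_null(lambda r: per_unit(r, "overlap"), lb, mesh,
                         n_rot=n_rot, seed=seed, payload_kind="labels")
    z_rs = rotation_null(lambda r: per_unit(r, "rsfc"), lb, mesh,
                         n_rot=n_rot, seed=seed, payload_kind="labels")
    return z_ov, z_rs


# ---------------------------------------------------------------------------
# Adjusted Rand index
# ---------------------------------------------------------------------------

def adjusted_rand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Pair-counting ARI over vertices assigned (label > 0) in both maps."""
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    ok = (la > 0) & (lb > 0)
    la, lb = la[ok], lb[ok]
    if len(la) == 0:
        raise ValueError("no jointly assigned vertices")
    if len(np.unique(la)) == 1 and len(np.unique(lb)) == 1:
        warnings.warn("both labelings constant; ARI defined as identity check")
        return 1.0
    return float(adjusted_rand_score(la, lb))


def z_ari(labels_a: np.ndarray, labels_b: np.ndarray, mesh: SurfaceMesh,
          n_rot: int = DEFAULT_N_ROTATIONS, seed: int = 0) -> NullModelResult:
    """Spin-null Z of the ARI (rotating labelling B)."""
    la = np.asarray(labels_a)

    def stat(rot_lb):
        return adjusted_rand(la, rot_lb)

    return rotation_null(stat, np.asarray(labels_b), mesh, n_rot=n_rot,
                         seed=seed, payload_kind="labels")


# ---------------------------------------------------------------------------
# Task-beta dispersion
# ---------------------------------------------------------------------------

def parcel_beta_sd(labels: np.ndarray, betas: np.ndarray,
                   reference_labels: np.ndarray | None = None,
                   wall_tolerance: float = PARCEL_WALL_TOLERANCE) -> np.ndarray:
    """Per-parcel SD of beta values over members, averaged over conditions."""
    betas = np.asarray(betas, dtype=float)
    if betas.ndim == 1:
        betas = betas[:, None]
    ref = labels if reference_labels is None else reference_labels
    ids = np.unique(ref[ref > 0])
    ref_sizes = {int(p): int(np.sum(ref == p)) for p in ids}
    out = np.full(len(ids), np.nan)
    for k, pid in enumerate(ids):
        members = labels == pid
        vals = betas[members]
        vals = vals[np.isfinite(vals).all(axis=1)]
        if len(vals) < 2 or len(vals) < (1 - wall_tolerance) * ref_sizes[int(pid)]:
            continue
        out[k] = float(np.mean(vals.std(axis=0, ddof=0)))
    return out


def task_sd(parcellation, betas: np.ndarray, mesh: SurfaceMesh,
            n_rot: int = DEFAULT_N_ROTATIONS, seed: int = 0) -> NullModelResult:
    """Mean within-parcel task-beta SD with a lower-tail spin null.

    A parcellation aligned with the functional topography captures more
    uniform evoked activity, so its mean SD is *smaller* than rotated
    nulls; the Z is reported on the lower tail.
    """
    labels = parcellation.labels if hasattr(parcellation, "labels") else np.asarray(parcellation)

    def stat(rot_labels):
        return parcel_beta_sd(rot_labels, betas, reference_labels=labels)

    return rotation_null(stat, labels, mesh, n_rot=n_rot, seed=seed,
                         payload_kind="labels", tail="lower")


# ---------------------------------------------------------------------------
# Boundary-difference regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    params: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    interaction: dict | None = None


def boundary_diff_regression(delta_boundary: np.ndarray,
                             delta_thickness: np.ndarray,
                             delta_deformation: np.ndarray,
                             include_interaction: bool = False) -> RegressionResult:
    """OLS of |Δboundary| on |Δthickness| + |Δdeformation| over valid vertices."""
    import statsmodels.api as sm

    y = np.abs(np.asarray(delta_boundary, dtype=float))
    x1 = np.abs(np.asarray(delta_thickness, dtype=float))
    x2 = np.abs(np.asarray(delta_deformation, dtype=float))
    ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    names = ["const", "thickness", "deformation"]
    cols = [np.ones_like(y), x1, x2]
    if include_interaction:
        names.append("thickness:deformation")
        cols.append(x1 * x2)
    design = np.column_stack(cols)
    cond = np.linalg.cond(design)
    if cond > 1e8:
        warnings.warn(f"ill-conditioned design (cond={cond:.2g})")
    fit = sm.OLS(y, design).fit()
    inter = None
    if include_interaction:
        inter = {"t": float(fit.tvalues[3]), "p": float(fit.pvalues[3])}
    return RegressionResult(
        params=dict(zip(names, map(float, fit.params))),
        tvalues=dict(zip(names, map(float, fit.tvalues))),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
        f_stat=float(fit.fvalue), f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model), df_resid=int(fit.df_resid),
        interaction=inter)


# ---------------------------------------------------------------------------
# One-way ANOVA from printed summaries
# ---------------------------------------------------------------------------

def anova_from_summary(group_means, group_sds, group_ns):
    """One-way ANOVA F from group means, SDs and sizes.

    SSB = Σ nᵢ(mᵢ − grand mean)², SSW = Σ (nᵢ−1)sdᵢ²,
    F = (SSB/(k−1)) / (SSW/(N−k)). Returns (F, df_between, df_within, p).
    """
    m = np.asarray(group_means, dtype=float)
    s = np.asarray(group_sds, dtype=float)
    n = np.asarray(group_ns, dtype=float)
    if len(m) < 2 or (n < 2).any():
        raise ValueError("need >= 2 groups with n >= 2")
    if (s < 0).any():
        raise ValueError("standard deviations must be non-negative")
    total = n.sum()
    k = len(m)
    grand = (n * m).sum() / total
    ssb = (n * (m - grand) ** 2).sum()
    ssw = ((n - 1) * s ** 2).sum()
    df_b, df_w = k - 1, int(total) - k
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def mmse_anova():
    """Worked example: cohort MMSE ANOVA from the printed lifespan summaries."""
    rows = list(MMSE_COHORT_SUMMARIES.values())
    return anova_from_summary([r["mean"] for r in rows],
                              [r["sd"] for r in rows],
                              [r["n"] for r in rows])
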