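"""Comparison statistics: Dice, spin nulls, homogeneity, silhouette,
matching, ARI, task dispersion, regression, summary ANOVA."""

import itertools

import numpy as np
import pytest
from scipy import stats

import arealmap as am
from arealmap import evaluation as ev
from arealmap.boundaries import BoundaryMap
from arealmap.evaluation import (NullModelResult, adjusted_rand,
                                 anova_from_summary, boundary_diff_regression,
                                 dice_boundary, dice_coefficient,
                                 map_correlation, match_parcels,
                                 matched_rsfc_similarity, rotation_null)


# ---------------------------------------------------------------------------
# Dice and map correlation
# ---------------------------------------------------------------------------

def test_dice_formula_cases():
    a = np.zeros(10, bool)
    b = np.zeros(10, bool)
    a[[1, 2, 3]] = True
    b[[3, 4]] = True
    assert np.isclose(dice_coefficient(a, b), 0.4)        # 2*1/(3+2)
    assert dice_coefficient(a, a) == 1.0
    assert dice_coefficient(a, np.zeros(10, bool)) == 0.0
    assert dice_coefficient(np.zeros(10, bool), np.zeros(10, bool)) == 0.0
    assert dice_coefficient(a, b) == dice_coefficient(b, a)


def test_dice_boundary_identical_and_disjoint(mesh2):
    rng = np.random.default_rng(0)
    vals = np.where(mesh2.cortex, rng.random(mesh2.n_vertices), np.nan)
    m = BoundaryMap(values=vals)
    for q in (0.1, 0.5, 0.9):
        assert dice_boundary(m, m, q) == 1.0
    flipped = BoundaryMap(values=np.where(mesh2.cortex, -vals, np.nan))
    assert dice_boundary(m, flipped, 0.2) < 0.2


def test_map_correlation_cases(mesh2):
    rng = np.random.default_rng(1)
    vals = np.where(mesh2.cortex, rng.standard_normal(mesh2.n_vertices), np.nan)
    m = BoundaryMap(values=vals)
    assert np.isclose(map_correlation(m, m), 1.0)
    assert np.isclose(map_correlation(m, BoundaryMap(values=-vals)), -1.0)
    other = np.where(mesh2.cortex, rng.standard_normal(mesh2.n_vertices), np.nan)
    ok = mesh2.cortex
    x, y = vals[ok], other[ok]
    brute = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert abs(map_correlation(m, BoundaryMap(values=other)) - brute) < 1e-12
    with pytest.raises(ValueError):
        map_correlation(m, BoundaryMap(values=np.where(ok, 1.0, np.nan)))


# ---------------------------------------------------------------------------
# Spin-null engine
# ---------------------------------------------------------------------------

def test_null_model_z_formula_on_hand_built_lists():
    res = NullModelResult(actual=0.8, null_values=np.array([0.2, 0.4, 0.6]),
                          n_rotations=3)
    assert np.isclose(res.null_mean, 0.4)
    assert np.isclose(res.z, (0.8 - 0.4) / np.std([0.2, 0.4, 0.6]))
    assert res.p == 0.0
    same = NullModelResult(actual=0.4, null_values=np.array([0.4, 0.4]),
                           n_rotations=2)
    assert same.z == np.inf                 # degenerate null, sentinel
    below = NullModelResult(actual=0.1, null_values=np.array([0.4, 0.4]),
                            n_rotations=2)
    assert below.z == -np.inf


def test_rotation_null_constant_statistic(mesh2):
    rng = np.random.default_rng(2)
    vals = np.where(mesh2.cortex, rng.random(mesh2.n_vertices), np.nan)
    res = rotation_null(lambda m: 1.0, vals, mesh2, n_rot=10, seed=0)
    assert res.null_sd == 0.0 and res.actual == 1.0 and res.z == np.inf
    assert len(res.null_values) == 10
    assert ev.DEFAULT_N_ROTATIONS == 100


def test_rotation_null_mean_statistic_near_zero_z(mesh2):
    """The mean of a map is rotation invariant up to wall clipping."""
    rng = np.random.default_rng(3)
    vals = np.where(mesh2.cortex, rng.standard_normal(mesh2.n_vertices), np.nan)
    res = rotation_null(lambda m: np.nanmean(m), vals, mesh2, n_rot=25, seed=1)
    assert abs(res.actual - res.null_mean) < 3 * res.null_sd + 0.05


# ---------------------------------------------------------------------------
# Homogeneity
# ---------------------------------------------------------------------------

def _two_parcel_setup(mesh):
    labels = np.zeros(mesh.n_vertices, dtype=int)
    cortex = np.where(mesh.cortex)[0]
    labels[cortex[:20]] = 1
    labels[cortex[20:40]] = 2
    return labels, cortex


def test_homogeneity_identical_maps_give_100(mesh2):
    labels, cortex = _two_parcel_setup(mesh2)
    rng = np.random.default_rng(4)
    base = rng.standard_normal(mesh2.n_vertices)
    maps = np.zeros((mesh2.n_vertices, mesh2.n_vertices))
    for k, v in enumerate(np.where(labels > 0)[0]):
        maps[v] = (1.0 + 0.1 * k) * base        # identical up to scale
    res = ev.homogeneity(labels, maps, mesh2)
    assert np.allclose(list(res.per_parcel.values()), 100.0)


def test_homogeneity_two_orthogonal_patterns_give_50(mesh2):
    labels = np.zeros(mesh2.n_vertices, dtype=int)
    cortex = np.where(mesh2.cortex)[0]
    members = cortex[:20]
    labels[members] = 1
    # two exactly orthogonal, zero-mean, equal-norm patterns on the cortex
    rng = np.random.default_rng(20)
    n_cols = len(cortex)
    u = rng.standard_normal(n_cols)
    u -= u.mean()
    v = rng.standard_normal(n_cols)
    v -= v.mean()
    v -= (v @ u) / (u @ u) * u
    v *= np.linalg.norm(u) / np.linalg.norm(v)
    p1 = np.zeros(mesh2.n_vertices)
    p2 = np.zeros(mesh2.n_vertices)
    p1[cortex], p2[cortex] = u, v
    maps = np.zeros((mesh2.n_vertices, mesh2.n_vertices))
    maps[members[:10]] = p1
    maps[members[10:]] = p2
    res = ev.homogeneity(labels, maps, mesh2)
    assert abs(res.per_parcel[1] - 50.0) < 1e-6


def test_homogeneity_shift_and_scale_invariance(mesh2):
    labels, _ = _two_parcel_setup(mesh2)
    rng = np.random.default_rng(5)
    maps = rng.standard_normal((mesh2.n_vertices, mesh2.n_vertices))
    a = ev.homogeneity(labels, maps, mesh2).mean_homogeneity
    b = ev.homogeneity(labels, 3.0 * maps + 11.0, mesh2).mean_homogeneity
    assert np.isclose(a, b, rtol=1e-9)


def test_planted_parcellation_homogeneity_beats_spin_null(mesh3, truth3, boundary3):
    _, mean_z = boundary3
    res = ev.z_homogeneity(truth3.parcellation, mean_z, mesh3, n_rot=25, seed=2)
    assert res.z > 1.65


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------

def test_silhouette_true_labels_beat_rotated_labels(mesh3, truth3, boundary3):
    from arealmap.surface import rotate_map
    from scipy.spatial.transform import Rotation
    _, mean_z = boundary3
    true_coef = ev.silhouette(truth3.parcellation, mean_z, mesh3).mean_coef
    rot = Rotation.from_euler("x", 30, degrees=True)
    rotated = rotate_map(mesh3, truth3.parcellation.astype(float), rot)
    rotated = np.where(np.isfinite(rotated), rotated, 0).astype(int)
    rot_coef = ev.silhouette(rotated, mean_z, mesh3).mean_coef
    assert true_coef > rot_coef
    assert -1.0 <= rot_coef <= true_coef <= 1.0


# ---------------------------------------------------------------------------
# Parcel matching / Jaccard
# ---------------------------------------------------------------------------

def test_match_identical_parcellations(mesh2):
    labels, _ = _two_parcel_setup(mesh2)
    m = match_parcels(labels, labels)
    assert m.mean_overlap == 1.0
    assert all(j == 1.0 and a == b for a, b, j in m.pairs)


def test_match_halved_parcels():
    a = np.array([1] * 8 + [2] * 8)
    b = np.array([1] * 4 + [2] * 4 + [3] * 4 + [4] * 4)
    m = match_parcels(a, b)
    assert [j for _, _, j in m.pairs] == [0.5, 0.5]


def test_match_against_bruteforce_jaccard_table():
    rng = np.random.default_rng(6)
    a = rng.integers(0, 4, 200)
    b = rng.integers(0, 5, 200)
    m = match_parcels(a, b)
    for pa, pb, j in m.pairs:
        best = max(((q, np.sum((a == pa) & (b == q)) / np.sum((a == pa) | (b == q)))
                    for q in np.unique(b[b > 0])), key=lambda t: (t[1], -t[0]))
        assert pb == best[0] and abs(j - best[1]) < 1e-12


def test_matched_rsfc_similarity_same_cohort():
    labels = np.array([1] * 5 + [2] * 5)
    rng = np.random.default_rng(7)
    maps = rng.standard_normal((10, 30))
    pm = ev.parcel_mean_maps(labels, maps)
    m = matched_rsfc_similarity(match_parcels(labels, labels), pm, pm)
    assert all(np.isclose(r, 1.0) for r in m.rsfc_similarity.values())


def test_overlap_correlates_with_matched_rsfc_similarity(mesh3, truth3, boundary3):
    """Pairs that overlap more spatially also have more similar RSFC maps."""
    from arealmap.surface import rotate_map
    from scipy.spatial.transform import Rotation
    _, mean_z = boundary3
    rot = Rotation.from_euler("z", 12, degrees=True)
    rotated = rotate_map(mesh3, truth3.parcellation.astype(float), rot)
    rotated = np.where(np.isfinite(rotated), rotated, 0).astype(int)
    maps_a = ev.parcel_mean_maps(truth3.parcellation, mean_z)
    maps_b = ev.parcel_mean_maps(rotated, mean_z)
    m = matched_rsfc_similarity(match_parcels(truth3.parcellation, rotated),
                                maps_a, maps_b)
    jac, sim = zip(*[(j, m.rsfc_similarity[(a, b)]) for a, b, j in m.pairs
                     if (a, b) in m.rsfc_similarity])
    assert np.corrcoef(jac, sim)[0, 1] > 0.2


def test_spin_null_z_for_overlap_and_ari(mesh3, truth3, boundary3):
    """A parcellation matched against itself beats rotated nulls."""
    _, mean_z = boundary3
    maps = ev.parcel_mean_maps(truth3.parcellation, mean_z)
    z_ov, z_rs = ev.z_overlap_and_rsfc(truth3.parcellation, truth3.parcellation,
                                       maps, maps, mesh3, n_rot=10, seed=0)
    assert z_ov.actual == 1.0 and z_ov.z > 2.0
    assert np.isclose(z_rs.actual, 1.0) and z_rs.z > 2.0
    res = ev.z_ari(truth3.parcellation, truth3.parcellation, mesh3,
                   n_rot=10, seed=0)
    assert res.actual == 1.0 and res.z > 2.0


# ---------------------------------------------------------------------------
# Adjusted Rand index
# ---------------------------------------------------------------------------

def _pair_count_ari(a, b):
    """Exhaustive pair-counting oracle."""
    n = len(a)
    s_both = s_a = s_b = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        s_both += same_a and same_b
        s_a += same_a
        s_b += same_b
    total = n * (n - 1) / 2
    expected = s_a * s_b / total
    max_index = (s_a + s_b) / 2
    return (s_both - expected) / (max_index - expected)


def test_ari_identical_and_pathological_cases():
    a = np.array([1, 1, 2, 2])
    assert adjusted_rand(a, a) == 1.0
    assert np.isclose(adjusted_rand(a, np.array([1, 2, 1, 2])), -0.5)
    assert np.isclose(_pair_count_ari([1, 1, 2, 2], [1, 2, 1, 2]), -0.5)
    with pytest.warns(UserWarning):
        assert adjusted_rand(np.array([1, 1]), np.array([3, 3])) == 1.0


def test_ari_matches_pair_counting_oracle():
    rng = np.random.default_rng(8)
    a = rng.integers(1, 4, 40)
    b = rng.integers(1, 5, 40)
    assert abs(adjusted_rand(a, b) - _pair_count_ari(a, b)) < 1e-10


def test_ari_chance_level_for_independent_labelings():
    rng = np.random.default_rng(9)
    a = rng.integers(1, 11, 1000)
    b = rng.integers(1, 11, 1000)
    assert abs(adjusted_rand(a, b)) < 0.05


def test_ari_excludes_unassigned_pairwise():
    a = np.array([0, 1, 1, 2, 2, 0])
    b = np.array([5, 5, 5, 7, 7, 7])
    # only positions 1..4 count, where the labelings agree perfectly
    assert adjusted_rand(a, b) == 1.0


# ---------------------------------------------------------------------------
# Task-beta dispersion
# ---------------------------------------------------------------------------

def test_task_sd_zero_for_piecewise_constant(mesh2):
    labels, _ = _two_parcel_setup(mesh2)
    betas = np.column_stack([labels * 2.0, labels - 1.0])
    res = ev.task_sd(labels, betas, mesh2, n_rot=5, seed=0)
    assert res.actual == 0.0


def test_task_sd_white_noise_is_partition_invariant(mesh2):
    labels, _ = _two_parcel_setup(mesh2)
    rng = np.random.default_rng(10)
    betas = rng.standard_normal((mesh2.n_vertices, 2))
    res = ev.task_sd(labels, betas, mesh2, n_rot=25, seed=1)
    assert abs(res.actual - 1.0) < 0.25      # SD of unit noise
    assert abs(res.z) < 3.0


def test_task_sd_alignment_property(mesh3, truth3, cohort3):
    from arealmap.surface import rotate_map
    from scipy.spatial.transform import Rotation
    betas = cohort3[0].task_betas
    aligned = ev.task_sd(truth3.parcellation, betas, mesh3, n_rot=20, seed=3)
    rot = Rotation.from_euler("y", 40, degrees=True)
    rotated = rotate_map(mesh3, truth3.parcellation.astype(float), rot)
    rotated = np.where(np.isfinite(rotated), rotated, 0).astype(int)
    misaligned = ev.task_sd(rotated, betas, mesh3, n_rot=20, seed=3)
    assert aligned.z < misaligned.z          # lower-tail: aligned is better


# ---------------------------------------------------------------------------
# Boundary-difference regression
# ---------------------------------------------------------------------------

def test_regression_exact_linear_case():
    rng = np.random.default_rng(11)
    dt = rng.standard_normal(500)
    dd = rng.standard_normal(500)
    db = 2.0 * np.abs(dt)
    res = boundary_diff_regression(db, dt, dd)
    assert np.isclose(res.params["thickness"], 2.0, atol=1e-10)
    assert abs(res.params["deformation"]) < 1e-10


def test_regression_matches_normal_equations():
    rng = np.random.default_rng(12)
    db, dt, dd = (rng.standard_normal(80) for _ in range(3))
    res = boundary_diff_regression(db, dt, dd)
    x = np.column_stack([np.ones(80), np.abs(dt), np.abs(dd)])
    beta = np.linalg.solve(x.T @ x, x.T @ np.abs(db))
    assert np.allclose([res.params["const"], res.params["thickness"],
                        res.params["deformation"]], beta, atol=1e-8)


def test_regression_type_one_error_calibrated():
    """Independent noise outcome: F significant at alpha=0.01 rarely."""
    rng = np.random.default_rng(13)
    dt = rng.standard_normal(400)
    dd = rng.standard_normal(400)
    hits = sum(boundary_diff_regression(rng.standard_normal(400), dt, dd).f_pvalue < 0.01
               for _ in range(100))
    assert hits <= 5                          # >= 95% non-significant


# ---------------------------------------------------------------------------
# Summary ANOVA
# ---------------------------------------------------------------------------

def test_anova_equal_means_give_zero():
    f, dfb, dfw, p = anova_from_summary([5.0, 5.0, 5.0], [1.0, 2.0, 1.5],
                                        [10, 12, 9])
    assert f == 0.0 and dfb == 2 and dfw == 28


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(14)
    a = rng.standard_normal(12) + 0.8
    b = rng.standard_normal(15)
    f, _, _, _ = anova_from_summary([a.mean(), b.mean()],
                                    [a.std(ddof=1), b.std(ddof=1)],
                                    [12, 15])
    t, _ = stats.ttest_ind(a, b)
    assert np.isclose(f, t ** 2, rtol=1e-10)


def test_anova_validates_inputs():
    with pytest.raises(ValueError):
        anova_from_summary([1.0], [0.5], [10])
    with pytest.raises(ValueError):
        anova_from_summary([1.0, 2.0], [-0.5, 0.5], [10, 10])


def test_mmse_worked_example_reproduces_published_f():
    f, dfb, dfw, p = ev.mmse_anova()
    assert (dfb, dfw) == (4, 217)
    assert abs(f - 9.318) / 9.318 < 0.005
    assert p < 0.001
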