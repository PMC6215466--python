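"""Parcel graphs, map-equation communities, consensus, segregation."""

import numpy as np
import pytest

import arealmap as am
from arealmap import network as nw, synthetic
from arealmap.boundaries import Z_CLIP, fisher_z
from arealmap.network import (align_partition, bootstrap_mode_communities,
                              cross_density_consensus, default_density_grid,
                              map_equation_codelength, map_equation_partition,
                              system_segregation, threshold_density)
from arealmap.parcellation import Parcellation


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

class _FakeClean:
    usable = True

    def __init__(self, ts):
        self.timeseries = np.asarray(ts, dtype=float)


def _toy_graph(mesh, n_parcels=5, frames=60, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.zeros(mesh.n_vertices, dtype=int)
    cortex = np.where(mesh.cortex)[0]
    for k in range(n_parcels):
        labels[cortex[10 * k:10 * (k + 1)]] = k + 1
    ts = rng.standard_normal((mesh.n_vertices, frames))
    return Parcellation(labels=labels), _FakeClean(ts)


def test_build_graph_matches_mean_then_correlate_oracle(mesh2):
    parc, clean = _toy_graph(mesh2)
    g = nw.build_graph(parc, clean, mesh2, exclusion_mm=0.0)
    for a, pa in enumerate(parc.parcel_ids):
        for b, pb in enumerate(parc.parcel_ids):
            if a == b:
                continue
            ra = clean.timeseries[parc.labels == pa].mean(axis=0)
            rb = clean.timeseries[parc.labels == pb].mean(axis=0)
            expected = np.arctanh(np.clip(np.corrcoef(ra, rb)[0, 1],
                                          -Z_CLIP, Z_CLIP))
            assert abs(g.z_matrix[a, b] - expected) < 1e-10


def test_build_graph_clips_identical_nodes_and_excludes_near_pairs(mesh2):
    parc, clean = _toy_graph(mesh2)
    # make parcels 1 and 2 share their mean series
    ts = clean.timeseries.copy()
    ts[parc.labels == 2] = ts[parc.labels == 1].mean(axis=0)
    g = nw.build_graph(parc, _FakeClean(ts), mesh2, exclusion_mm=0.0)
    assert np.isclose(g.z_matrix[0, 1], np.arctanh(Z_CLIP))
    assert nw.DEFAULT_EXCLUSION_MM == 20.0
    g2 = nw.build_graph(parc, clean, mesh2, exclusion_mm=1e6)
    assert g2.excluded[np.triu_indices(len(g2.parcel_ids), 1)].all()


# ---------------------------------------------------------------------------
# Density thresholding
# ---------------------------------------------------------------------------

def test_threshold_density_exact_count_and_nesting():
    rng = np.random.default_rng(1)
    n = 40
    z = rng.standard_normal((n, n))
    z = (z + z.T) / 2
    np.fill_diagonal(z, np.nan)
    excl = np.zeros((n, n), bool)
    w5 = threshold_density(z, excl, 0.05)
    assert (w5 > 0).sum() // 2 == round(0.05 * n * (n - 1) / 2) == 39
    prev = set()
    for d in (0.03, 0.05, 0.08, 0.10):
        w = threshold_density(z, excl, d)
        edges = {(i, j) for i, j in zip(*np.where(np.triu(w) > 0))}
        assert prev <= edges
        prev = edges


def test_threshold_density_warns_when_starved():
    z = np.full((6, 6), -1.0)
    z[0, 1] = z[1, 0] = 0.5
    np.fill_diagonal(z, np.nan)
    with pytest.warns(UserWarning):
        w = threshold_density(z, np.zeros((6, 6), bool), 0.9)
    assert (w > 0).sum() == 2


def test_default_density_grid_structure():
    grid = default_density_grid()
    assert np.isclose(grid[0], 0.03) and np.isclose(grid[-1], 0.10)
    assert len(grid) == 21 + 5
    fine = grid[(grid >= 0.03) & (grid <= 0.05)]
    assert np.allclose(np.diff(fine), 0.001)


# ---------------------------------------------------------------------------
# Map equation
# ---------------------------------------------------------------------------

def _set_partitions(n):
    a = [0] * n
    while True:
        yield np.array(a)
        i = n - 1
        while i > 0:
            if a[i] <= max(a[:i]):
                a[i] += 1
                for j in range(i + 1, n):
                    a[j] = 0
                break
            a[i] = 0
            i -= 1
        else:
            return


def test_two_cliques_and_complete_graph():
    w = np.zeros((10, 10))
    for grp in (range(5), range(5, 10)):
        for i in grp:
            for j in grp:
                if i < j:
                    w[i, j] = w[j, i] = 1.0
    w[0, 5] = w[5, 0] = 0.05
    labels, _ = map_equation_partition(w, seed=0, n_restarts=8)
    assert len(np.unique(labels)) == 2
    assert len(np.unique(labels[:5])) == 1 and len(np.unique(labels[5:])) == 1

    complete = np.ones((6, 6)) - np.eye(6)
    labels, _ = map_equation_partition(complete, seed=0, n_restarts=8)
    assert len(np.unique(labels)) == 1


def test_codelength_attains_exhaustive_minimum_on_toy_graphs():
    """50 random graphs with <= 8 nodes: greedy matches brute-force optimum."""
    rng = np.random.default_rng(0)
    for inst in range(50):
        n = int(rng.integers(5, 9))
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        mask = rng.random(len(iu)) < 0.55
        vals = rng.uniform(0.1, 1.0, len(iu)) * mask
        w[iu, ju] = vals
        w += w.T
        if w.sum() == 0:
            continue
        best = min(map_equation_codelength(w, p) for p in _set_partitions(n))
        _, l = map_equation_partition(w, seed=inst, n_restarts=12)
        assert l <= best + 1e-9


def test_partition_deterministic_and_isolated_nodes_singleton():
    w = np.zeros((5, 5))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    a, la = map_equation_partition(w, seed=3)
    b, lb = map_equation_partition(w, seed=3)
    assert np.array_equal(a, b) and la == lb
    assert a[4] not in (a[0], a[2])        # isolated node is its own community
    with pytest.raises(ValueError):
        map_equation_partition(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# Bootstrap mode + consensus
# ---------------------------------------------------------------------------

def test_bootstrap_mode_on_identical_subjects():
    rng = np.random.default_rng(2)
    base = rng.standard_normal((20, 100))
    base[:10] += 2.0 * rng.standard_normal(100)     # two planted blocks
    base[10:] += 2.0 * rng.standard_normal(100)
    z = fisher_z(np.clip(np.corrcoef(base), -1, 1))
    np.fill_diagonal(z, np.nan)
    excl = np.zeros((20, 20), bool)
    mode = bootstrap_mode_communities([z, z, z], excl, 0.2, n_boot=8, seed=1)
    single, _ = map_equation_partition(threshold_density(z, excl, 0.2), seed=1)
    assert nw and len(np.unique(mode)) == len(np.unique(single))
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(mode, single) == 1.0
    assert nw.DEFAULT_NETWORK_BOOT == 1000


def test_align_partition_recovers_permuted_labels():
    ref = np.array([1, 1, 1, 2, 2, 2, 3, 3])
    perm = np.array([7, 7, 7, 9, 9, 9, 4, 4])
    assert np.array_equal(align_partition(ref, perm), ref)


def test_consensus_identity_and_dissolution_rules():
    densities = [0.03, 0.05, 0.08]
    stable = np.array([1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
    per_density = {d: stable for d in densities}
    assert np.array_equal(cross_density_consensus(per_density, min_size=6), stable)

    # a 3-node community present only at the sparsest density dissolves
    # into the assignment held at the next denser threshold
    sparse = np.array([9, 9, 9, 1, 1, 1, 2, 2, 2, 2, 2, 2])
    dense = np.array([1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
    per_density = {0.03: sparse, 0.05: dense, 0.08: dense}
    out = cross_density_consensus(per_density, min_size=6)
    assert np.array_equal(out, dense)
    assert nw.DEFAULT_MIN_COMMUNITY == 6


# ---------------------------------------------------------------------------
# System matching
# ---------------------------------------------------------------------------

def test_match_systems_identity_and_label_invariance(mesh3, truth3, boundary3):
    parc = Parcellation(labels=truth3.parcellation)
    ref = np.array([truth3.system_of_parcel[p] for p in parc.parcel_ids])
    label_of, z_sys = nw.match_systems(ref, ref, parc, mesh3, n_rot=10, seed=0)
    assert all(label_of[c] == c for c in np.unique(ref))
    assert all(np.isclose(res.actual, 1.0) for res in z_sys.values())
    # permuting consensus labels leaves the matching intact
    perm = ref + 100
    label_perm, _ = nw.match_systems(perm, ref, parc, mesh3, n_rot=5, seed=0)
    assert all(label_perm[c + 100] == c for c in np.unique(ref))


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

def test_segregation_formula_cases():
    sysv = np.array([1, 1, 2, 2])
    z = np.full((4, 4), 0.1)
    z[0, 1] = z[1, 0] = 0.5
    z[2, 3] = z[3, 2] = 0.5
    np.fill_diagonal(z, np.nan)
    res = system_segregation(z, sysv)
    assert np.isclose(res.z_within, 0.5) and np.isclose(res.z_between, 0.1)
    assert np.isclose(res.segregation, 0.8)

    z_eq = np.full((4, 4), 0.3)
    np.fill_diagonal(z_eq, np.nan)
    assert np.isclose(system_segregation(z_eq, sysv).segregation, 0.0)

    z_zero = z.copy()
    z_zero[z_zero == 0.1] = -0.2            # negative edges excluded -> Zb = 0
    assert np.isclose(system_segregation(z_zero, sysv).segregation, 1.0)


def test_segregation_typed_scopes():
    sysv = np.array([1, 1, 2, 2, 3, 3])
    types = {1: synthetic.SENSORY_MOTOR, 2: synthetic.ASSOCIATION,
             3: synthetic.ASSOCIATION}
    rng = np.random.default_rng(3)
    z = np.abs(rng.standard_normal((6, 6))) * 0.1
    z = (z + z.T) / 2
    for i in range(0, 6, 2):
        z[i, i + 1] = z[i + 1, i] = 0.8
    np.fill_diagonal(z, np.nan)
    overall = system_segregation(z, sysv)
    assoc = system_segregation(z, sysv, types, scope=synthetic.ASSOCIATION)
    a2s = system_segregation(z, sysv, types, scope="association-to-sensory")
    for res in (overall, assoc, a2s):
        assert res.segregation <= 1.0
    with pytest.raises(ValueError):
        system_segregation(z, sysv, None, scope=synthetic.ASSOCIATION)


def test_noiseless_segregation_matches_closed_form(mesh2):
    """No coupling, no noise: within-system r is exactly 1/2, between 0."""
    truth = am.plant_parcellation(mesh2, 12, 3, seed=4)
    spec = synthetic.CohortSpec(n_subjects=8, frames=400, jitter_mm=0.0,
                                between_system_coupling=0.0, noise_sd=0.0,
                                motion_spike_rate=0.0, seed=5)
    ids = truth.parcel_ids
    node_sys = np.array([truth.system_of_parcel[p] for p in ids])
    segs, zws = [], []
    for s in synthetic.simulate_cohort(mesh2, truth, spec):
        node_ts = np.array([s.timeseries[truth.parcellation == p].mean(axis=0)
                            for p in ids])
        z = fisher_z(np.clip(np.corrcoef(node_ts), -1, 1))
        np.fill_diagonal(z, np.nan)
        res = system_segregation(z, node_sys)
        segs.append(res.segregation)
        zws.append(res.z_within)
    assert abs(np.mean(zws) - np.arctanh(0.5)) / np.arctanh(0.5) < 0.05
    # the positive-edge-only rule leaves a truncated-noise floor in Zb,
    # so segregation sits below 1 even for exactly uncorrelated systems
    assert np.mean(segs) > 0.75


def test_segregation_age_trend_linear_and_permutation_null():
    rng = np.random.default_rng(6)
    ages = rng.uniform(20, 90, 120)
    seg = 1.0 - 0.005 * ages
    res = nw.segregation_age_trend(seg, ages)
    assert np.isclose(res["r"], -1.0)
    assert abs(res["cubic_coefs"][2]) < 1e-9 and abs(res["cubic_coefs"][3]) < 1e-9

    noisy = seg + 0.1 * rng.standard_normal(120)
    high = 0
    for _ in range(100):
        perm = rng.permutation(ages)
        high += abs(nw.segregation_age_trend(noisy, perm)["r"]) >= 0.2
    assert high <= 5
    with pytest.raises(ValueError):
        nw.segregation_age_trend(np.ones(20), ages[:20])
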