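"""Synthetic cohorts with planted areal and system structure.

Real cohort-level boundary-mapping studies work on surface-sampled BOLD
data that is not publicly available, so every stage of this package is
exercised on simulated cohorts whose ground truth is known by
construction. The generator emulates the statistical structure the
analysis assumes:

* a spherical icosahedral mesh standing in for the registered 32k
  standard surface (rotation nulls are exact on a sphere),
* a planted geodesic-Voronoi parcellation whose parcels nest inside
  large-scale systems of two types (sensory-motor vs association),
* band-limited BOLD-like signals (white noise filtered to the 0.009-0.08
  Hz analysis band at TR = 2 s) with block correlation structure:
  within-parcel > within-system > between-system,
* age-graded degradation knobs: per-subject boundary jitter (border
  blurring) and between-system coupling (desegregation),
* motion traces with Poisson spikes that inject transient artifact,
* thickness and deformation maps spatially coupled to boundary shifts,
* per-parcel task beta maps.

All outputs are deterministic functions of the supplied seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import signal
from sklearn.cluster import KMeans

from .surface import SurfaceMesh, geodesic_distances, validate_mesh

# Signal model amplitudes (z-scored latents). With unit white noise these
# give within-parcel r = 2/3, within-system/between-parcel r = 1/3 and
# near-zero between-system correlation in the default cohort.
SYSTEM_AMP = 1.0
PARCEL_AMP = 1.0

SENSORY_MOTOR = "sensory-motor"
ASSOCIATION = "association"

# Analysis band (Hz) matching the RSFC preprocessing band.
BAND_LOW_HZ = 0.009
BAND_HIGH_HZ = 0.08


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

def make_sphere_mesh(subdivisions: int, radius_mm: float = 25.0,
                     medial_cap_deg: float = 25.0, seed: int = 0) -> SurfaceMesh:
    """Icosphere with a polar cap marked as medial wall.

    The icosahedron is subdivided ``subdivisions`` times and projected to a
    sphere of ``radius_mm``; vertices within ``medial_cap_deg`` angular
    radius of the +z pole form the medial wall (a single connected
    component, so rotation-null medial-wall handling is exercised).
    Anatomical coordinates equal the sphere coordinates scaled by the
    radius — the identity "registration". The geometry is deterministic;
    ``seed`` is accepted for interface symmetry with the other generators.
    """
    if not 2 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in [2, 6]")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    polar_angle = np.degrees(np.arccos(np.clip(unit[:, 2], -1, 1)))
    medial = polar_angle <= medial_cap_deg
    mesh = SurfaceMesh(vertex_coords=radius_mm * unit, sphere_coords=unit,
                       faces=np.asarray(ico.faces), medial_wall=medial)
    validate_mesh(mesh)
    return mesh


# ---------------------------------------------------------------------------
# Planted parcellation / systems
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted areal structure used as recovery target in every test.

    ``parcellation`` holds per-vertex integer labels (0 on the medial
    wall), ``system_of_parcel`` maps each parcel to its system and
    ``system_type`` each system to sensory-motor or association.
    ``boundary_vertices`` are the vertices with a 1-ring neighbour in a
    different parcel.
    """

    parcellation: np.ndarray
    system_of_parcel: dict[int, int]
    system_type: dict[int, str]
    boundary_vertices: np.ndarray
    seed_vertices: np.ndarray
    seed: int = 0

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.unique(self.parcellation[self.parcellation > 0])

    def system_labels(self) -> np.ndarray:
        """Per-vertex system labels (0 = medial wall)."""
        out = np.zeros_like(self.parcellation)
        for p, s in self.system_of_parcel.items():
            out[self.parcellation == p] = s
        return out


def _boundary_vertices(mesh: SurfaceMesh, labels: np.ndarray) -> np.ndarray:
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    both = (labels[i] > 0) & (labels[j] > 0)
    diff = both & (labels[i] != labels[j])
    return np.unique(np.concatenate([i[diff], j[diff]]))


def plant_parcellation(mesh: SurfaceMesh, n_parcels: int, n_systems: int,
                       seed: int = 0, n_sensorimotor: int | None = None) -> GroundTruth:
    """Geodesic-Voronoi parcels from farthest-point-sampled seeds.

    Seeds are placed by iterative farthest-point sampling on the cortex,
    which bounds parcel size imbalance; Voronoi assignment uses graph
    geodesics. Parcels are grouped into ``n_systems`` spatially coherent
    systems by k-means on the seed coordinates; the first
    ``n_sensorimotor`` systems (default 2 of 5, scaled proportionally)
    are typed sensory-motor, the rest association.
    """
    cortex_idx = np.where(mesh.cortex)[0]
    if not n_parcels >= n_systems >= 2:
        raise ValueError("need n_parcels >= n_systems >= 2")
    if n_parcels > len(cortex_idx) // 4:
        raise ValueError("too many parcels for this mesh")
    rng = np.random.default_rng(seed)

    # farthest-point sampling
    seeds = [int(rng.choice(cortex_idx))]
    mind = geodesic_distances(mesh, seeds[0])[0]
    if not np.isfinite(mind[cortex_idx]).all():
        raise ValueError("mesh cortex is disconnected")
    for _ in range(n_parcels - 1):
        cand = cortex_idx[int(np.argmax(mind[cortex_idx]))]
        seeds.append(int(cand))
        mind = np.minimum(mind, geodesic_distances(mesh, cand)[0])
    seeds = np.array(sorted(seeds))

    d = geodesic_distances(mesh, seeds)
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[cortex_idx] = np.argmin(d[:, cortex_idx], axis=0) + 1

    if n_sensorimotor is None:
        n_sensorimotor = max(1, round(n_systems * 2 / 5))
    km = KMeans(n_clusters=n_systems, n_init=10, random_state=seed)
    sys_of_seed = km.fit_predict(mesh.sphere_coords[seeds])
    # deterministic system ids 1..S ordered by lowest member seed vertex
    order = {}
    for k, s in enumerate(sys_of_seed):
        order.setdefault(s, seeds[k])
    ranked = sorted(order, key=lambda s: order[s])
    remap = {s: r + 1 for r, s in enumerate(ranked)}
    system_of_parcel = {p + 1: remap[sys_of_seed[p]] for p in range(n_parcels)}
    system_type = {s: (SENSORY_MOTOR if s <= n_sensorimotor else ASSOCIATION)
                   for s in range(1, n_systems + 1)}
    return GroundTruth(parcellation=labels,
                       system_of_parcel=system_of_parcel,
                       system_type=system_type,
                       boundary_vertices=_boundary_vertices(mesh, labels),
                       seed_vertices=seeds, seed=seed)


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative knobs for one age cohort.

    ``jitter_mm`` scales per-subject displacement of areal borders (border
    blurring grows with cohort age); ``between_system_coupling`` is the
    correlation injected between system latents (desegregation grows with
    age). ``motion_spike_rate`` is the expected number of motion spikes
    per frame.
    """

    name: str = "cohort"
    age_range: tuple[float, float] = (20.0, 34.0)
    n_subjects: int = 20
    frames: int = 200
    tr: float = 2.0
    jitter_mm: float = 1.0
    between_system_coupling: float = 0.1
    noise_sd: float = 1.0
    motion_spike_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.frames < 80:
            raise ValueError("frames must be >= 80")
        if not 0 <= self.between_system_coupling < 1:
            raise ValueError("between_system_coupling must be in [0, 1)")
        if self.jitter_mm < 0 or self.noise_sd < 0:
            raise ValueError("jitter_mm and noise_sd must be non-negative")


@dataclass
class SubjectData:
    """One simulated subject's raw inputs to the pipeline."""

    timeseries: np.ndarray        # (V, T)
    motion: np.ndarray            # (T, 6): tx ty tz (mm), rx ry rz (rad)
    thickness: np.ndarray         # (V,) mm
    deformation: np.ndarray       # (V,) dimensionless resampling density
    task_betas: np.ndarray        # (V, n_conditions)
    age: float
    effective_parcels: np.ndarray = field(repr=False, default=None)
    spike_frames: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng: np.random.Generator, n_series: int, frames: int,
                       tr: float) -> np.ndarray:
    """White noise band-pass filtered to the analysis band, z-scored."""
    x = rng.standard_normal((n_series, frames))
    nyq = 0.5 / tr
    b, a = signal.butter(2, [BAND_LOW_HZ / nyq, BAND_HIGH_HZ / nyq], "bandpass")
    y = signal.filtfilt(b, a, x, axis=1)
    y -= y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _border_geometry(mesh: SurfaceMesh, truth: GroundTruth):
    """Distance-to-border proxy and the neighbouring parcel of each vertex.

    Using seed geodesics: the half-gap (d2 - d1) / 2 between the closest
    and second-closest parcel seeds approximates distance to the planted
    Voronoi border, and the second-closest seed's parcel is the natural
    reassignment target under boundary jitter.
    """
    d = geodesic_distances(mesh, truth.seed_vertices)
    order = np.argsort(d, axis=0)
    d1 = d[order[0], np.arange(mesh.n_vertices)]
    d2 = d[order[1], np.arange(mesh.n_vertices)]
    with np.errstate(invalid="ignore"):
        border_dist = (d2 - d1) / 2.0
    border_dist[~mesh.cortex] = np.inf
    alt_label = order[1] + 1
    alt_label[~mesh.cortex] = 0
    return border_dist, alt_label


def _base_maps(mesh: SurfaceMesh, truth: GroundTruth, n_conditions: int = 2):
    """Cohort-independent structural/task bases derived from the truth seed."""
    rng = np.random.default_rng(truth.seed + 77_001)
    n_p = len(truth.parcel_ids)
    thickness_base = 2.5 + 0.1 * rng.standard_normal(n_p + 1)
    beta_amp = rng.standard_normal((n_p + 1, n_conditions))
    # de-differentiation weights: each parcel mixes the foreign systems'
    # latents with its own Dirichlet weight profile when
    # between_system_coupling > 0. Parcel-specific diffuse weights raise
    # between-system connectivity without creating an alternative
    # clusterable module structure and without a single global factor
    # (which global-signal regression would remove). Shared across cohorts
    # so the desegregation pattern is consistent over the lifespan.
    sys_ids = sorted(set(truth.system_of_parcel.values()))
    n_sys = len(sys_ids)
    pos = {s: k for k, s in enumerate(sys_ids)}
    mix_w = np.zeros((n_p + 1, n_sys))
    for p in range(1, n_p + 1):
        own = pos[truth.system_of_parcel[p]]
        foreign = [k for k in range(n_sys) if k != own]
        mix_w[p, foreign] = rng.dirichlet(np.ones(n_sys - 1))
    return thickness_base, beta_amp, mix_w


def simulate_cohort(mesh: SurfaceMesh, truth: GroundTruth,
                    spec: CohortSpec, n_conditions: int = 2) -> list[SubjectData]:
    """Simulate one cohort of subjects on a planted parcellation.

    Per subject: (a) latent band-limited signals per system and per parcel
    combine with white vertex noise into a block-correlated time-series
    matrix; (b) borders are jittered by probabilistic reassignment of
    near-border vertices to the neighbouring parcel, with probability
    decaying over ``jitter_mm`` and biased by a smooth cohort-level field,
    so each cohort's average borders are genuinely displaced (not just
    blurred) in a cohort-consistent direction; (c) desegregation: each
    parcel's system signal mixes a fixed partner system's latent with
    weight ``between_system_coupling`` — a de-differentiation mechanism
    with no global common component, so it survives global-signal
    regression; (d) the motion trace is a smooth random walk plus Poisson
    spikes that also inject a transient global artifact into the series;
    (e) thickness thins with age, concentrated in association-system
    parcels and near borders; (f) deformation magnitude co-varies with
    the cohort's border-displacement field; (g) task betas are per-parcel
    condition amplitudes plus vertex noise.
    """
    rng = np.random.default_rng(spec.seed)
    V, T = mesh.n_vertices, spec.frames
    labels = truth.parcellation
    sys_ids = sorted(set(truth.system_of_parcel.values()))
    n_sys = len(sys_ids)
    sys_of_parcel = np.zeros(len(truth.parcel_ids) + 1, dtype=int)
    for p, s in truth.system_of_parcel.items():
        sys_of_parcel[p] = s
    assoc_parcel = np.array([truth.system_type.get(sys_of_parcel[p], "") == ASSOCIATION
                             for p in range(len(sys_of_parcel))])
    border_dist, alt_label = _border_geometry(mesh, truth)
    thickness_base, beta_amp, mix_w = _base_maps(mesh, truth, n_conditions)
    smooth_w = mesh.smoothing_matrix(6.0)
    cortex = mesh.cortex
    sys_arr = np.array(sys_ids)

    # cohort-level border-displacement bias: a smooth field that biases the
    # flip coin consistently across the cohort's subjects
    bias_raw = smooth_w @ rng.standard_normal(V)
    sd = bias_raw[cortex].std() or 1.0
    flip_bias = 0.5 + 0.4 * np.tanh(bias_raw / sd)      # in (0.1, 0.9)

    subjects = []
    ages = np.sort(rng.uniform(*spec.age_range, size=spec.n_subjects))
    for s_i in range(spec.n_subjects):
        age = float(ages[s_i])

        # (b) subject-specific boundary jitter with cohort-level bias
        eff = labels.copy()
        if spec.jitter_mm > 0:
            p_flip = flip_bias * np.exp(-border_dist / spec.jitter_mm)
            flip = cortex & (rng.random(V) < p_flip)
            eff[flip] = alt_label[flip]

        # (a)+(c) latent signals with diffuse de-differentiation mixing
        sys_lat = _bandlimited_noise(rng, n_sys, T, spec.tr)
        c = spec.between_system_coupling
        par_lat = _bandlimited_noise(rng, len(truth.parcel_ids) + 1, T, spec.tr)
        ts = spec.noise_sd * rng.standard_normal((V, T))
        on = eff > 0
        own_idx = np.searchsorted(sys_arr, sys_of_parcel)
        parcel_sys_signal = (np.sqrt(1.0 - c) * sys_lat[own_idx]
                             + np.sqrt(c) * (np.sqrt(mix_w) @ sys_lat))
        parcel_sys_signal[0] = 0.0
        ts[on] += SYSTEM_AMP * parcel_sys_signal[eff[on]]
        ts[on] += PARCEL_AMP * par_lat[eff[on]]

        # (d) motion
        motion = np.zeros((T, 6))
        motion[:, :3] = np.cumsum(0.01 * rng.standard_normal((T, 3)), axis=0)
        motion[:, 3:] = np.cumsum(2e-4 * rng.standard_normal((T, 3)), axis=0)
        n_spikes = rng.poisson(spec.motion_spike_rate * T)
        spike_frames = np.sort(rng.choice(np.arange(2, T - 2),
                                          size=min(n_spikes, T // 4),
                                          replace=False)) if n_spikes else np.array([], dtype=int)
        for t in spike_frames:
            delta = rng.uniform(0.4, 0.8)
            axis = rng.integers(0, 3)
            motion[t, axis] += delta          # one-frame pulse: FD>thr at t and t+1
            # spatially heterogeneous artifact: a global shift (removable by
            # global-signal regression) plus strong vertex-specific noise
            # (removable only by scrubbing the frame)
            artifact = delta * (5.0 + 2.0 * rng.random(V)) \
                + 8.0 * delta * rng.standard_normal(V)
            ts[:, t] += artifact
            ts[:, t + 1] += 0.5 * artifact    # temporal spread of the artifact

        # (e) thickness
        thin_w = np.zeros(V)
        on_assoc = on & assoc_parcel[eff]
        thin_w[on_assoc] = 0.5 + 0.5 * np.exp(-border_dist[on_assoc] / 5.0)
        thick_noise = smooth_w @ (0.05 * rng.standard_normal(V))
        thickness = thickness_base[eff] - 0.01 * (age - 20.0) * thin_w + thick_noise
        thickness[~cortex] = np.nan

        # (f) deformation tracks the cohort's border-displacement field
        deform_noise = smooth_w @ (0.02 * rng.standard_normal(V))
        deformation = (1.0 + 0.2 * spec.jitter_mm * flip_bias
                       * np.exp(-border_dist / 5.0) + deform_noise)
        deformation[~cortex] = np.nan

        # (g) task betas
        betas = beta_amp[eff] + 0.5 * rng.standard_normal((V, n_conditions))
        betas[~cortex] = np.nan

        subjects.append(SubjectData(timeseries=ts, motion=motion,
                                    thickness=thickness, deformation=deformation,
                                    task_betas=betas, age=age,
                                    effective_parcels=eff,
                                    spike_frames=spike_frames))
    return subjects


# ---------------------------------------------------------------------------
# Text-format writers (TSV trio + sidecars)
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "vertices.tsv", mesh.vertex_coords, delimiter="\t", fmt="%.8g")
    np.savetxt(out / "faces.tsv", mesh.faces, delimiter="\t", fmt="%d")
    np.savetxt(out / "medialwall.tsv", mesh.medial_wall.astype(int), fmt="%d")
    np.savetxt(out / "sphere.tsv", mesh.sphere_coords, delimiter="\t", fmt="%.12g")


def read_mesh(in_dir: str | Path) -> SurfaceMesh:
    p = Path(in_dir)
    verts = np.loadtxt(p / "vertices.tsv", delimiter="\t")
    sphere_file = p / "sphere.tsv"
    sphere = (np.loadtxt(sphere_file, delimiter="\t") if sphere_file.exists()
              else verts / np.linalg.norm(verts, axis=1, keepdims=True))
    return SurfaceMesh(vertex_coords=verts, sphere_coords=sphere,
                       faces=np.loadtxt(p / "faces.tsv", delimiter="\t", dtype=int),
                       medial_wall=np.loadtxt(p / "medialwall.tsv").astype(bool))


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "truth_parcels.tsv", truth.parcellation, fmt="%d")
    sidecar = {"system_of_parcel": {str(k): int(v) for k, v in truth.system_of_parcel.items()},
               "system_type": {str(k): v for k, v in truth.system_type.items()},
               "seed_vertices": [int(s) for s in truth.seed_vertices],
               "seed": truth.seed}
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1))


def write_subject(subj: SubjectData, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "timeseries.tsv", subj.timeseries, delimiter="\t", fmt="%.6g")
    np.savetxt(out / "motion.tsv", subj.motion, delimiter="\t", fmt="%.8g",
               header="tx\tty\ttz\trx\try\trz", comments="")
    np.savetxt(out / "thickness.tsv", subj.thickness, fmt="%.6g")
    np.savetxt(out / "deformation.tsv", subj.deformation, fmt="%.6g")
    np.savetxt(out / "task_betas.tsv", subj.task_betas, delimiter="\t", fmt="%.6g")
    (out / "subject.json").write_text(json.dumps({"age": subj.age}))
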