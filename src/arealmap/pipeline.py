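"""End-to-end study orchestration on synthetic lifespan cohorts.

``run_study`` reproduces the full design at desk scale: simulate five
age cohorts with age-graded border jitter and between-system coupling,
preprocess every subject, build cohort boundary maps and parcellations,
run the cross-cohort comparisons (Dice, ARI, homogeneity and silhouette
Z with spin nulls, young-cohort parcellation applied to older data),
then the network stage (parcel graphs, map-equation communities with
mode and cross-density consensus, system matching and segregation) and
the segregation-age trend. All stage outputs and seeds are collected in
a run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import boundaries, evaluation, network, parcellation as parc_mod, preprocess, synthetic


@dataclass
class StudyConfig:
    """Desk-scale study layout; every stage default is overridable.

    The five cohorts span 20-93 years; border jitter and between-system
    coupling increase with cohort age, the generator's rendering of
    border blurring and system desegregation in older cohorts.
    """

    subdivisions: int = 4
    radius_mm: float = 25.0
    medial_cap_deg: float = 25.0
    n_parcels: int = 40
    n_systems: int = 5
    n_subjects: int = 10
    frames: int = 200
    tr_s: float = 2.0
    cohort_ages: tuple = ((20, 34), (35, 49), (50, 64), (65, 79), (80, 93))
    cohort_names: tuple = ("YA", "ME", "ML", "OE", "OL")
    jitter_mm: tuple = (0.75, 1.5, 2.25, 3.4, 4.5)
    coupling: tuple = (0.03, 0.08, 0.13, 0.19, 0.25)
    noise_sd: float = 1.0
    motion_spike_rate: float = 0.02
    n_boot: int = 8                      # boundary bootstraps at desk scale
    fwhm_mm: float = 6.0
    threshold_q: float = 0.35
    presmooth_fwhm_mm: float = 6.0       # boundary-map smoothing before parcels
    n_rot: int = 25                      # spin-null rotations at desk scale
    net_boot: int = 20                   # network bootstraps at desk scale
    densities: tuple = (0.03, 0.04, 0.05, 0.07, 0.10)
    exclusion_mm: float = 20.0
    min_community: int = 6
    seed: int = 0

    def cohort_specs(self) -> list[synthetic.CohortSpec]:
        specs = []
        for k, name in enumerate(self.cohort_names):
            specs.append(synthetic.CohortSpec(
                name=name, age_range=tuple(self.cohort_ages[k]),
                n_subjects=self.n_subjects, frames=self.frames, tr=self.tr_s,
                jitter_mm=self.jitter_mm[k],
                between_system_coupling=self.coupling[k],
                noise_sd=self.noise_sd,
                motion_spike_rate=self.motion_spike_rate,
                seed=self.seed * 1000 + 17 * k + 1))
        return specs


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds, "stages": self.stages,
             "warnings": self.warnings}, indent=1, default=str))


def run_cohort(mesh, truth, spec: synthetic.CohortSpec, config: StudyConfig):
    """Simulate, preprocess and boundary-map one cohort."""
    subjects = synthetic.simulate_cohort(mesh, truth, spec)
    params = preprocess.PreprocessParams(tr_s=spec.tr)
    clean = [preprocess.preprocess_subject(s, mesh, params) for s in subjects]
    usable = [c for c in clean if c.usable]
    bmap, mean_z = boundaries.cohort_boundary_pipeline(
        usable, mesh, n_boot=config.n_boot, fwhm_mm=config.fwhm_mm,
        seed=spec.seed + 5, cohort=spec.name)
    parc = parc_mod.parcellate(bmap, mesh, threshold_q=config.threshold_q,
                               presmooth_fwhm_mm=config.presmooth_fwhm_mm)
    return {"spec": spec, "subjects": subjects, "clean": clean,
            "boundary": bmap, "mean_z": mean_z, "parcellation": parc,
            "mean_thickness": np.mean([s.thickness for s in subjects], axis=0),
            "mean_deformation": np.mean([s.deformation for s in subjects], axis=0)}


def run_study(config: StudyConfig | None = None, out_dir: str | Path | None = None,
              verbose: bool = False) -> dict:
    """Full synthetic study; returns a results dict (and writes artifacts)."""
    config = config or StudyConfig()
    t0 = time.time()
    mesh = synthetic.make_sphere_mesh(config.subdivisions, config.radius_mm,
                                      config.medial_cap_deg)
    truth = synthetic.plant_parcellation(mesh, config.n_parcels,
                                         config.n_systems, seed=config.seed)
    manifest = RunManifest(config=asdict(config), seeds={"master": config.seed})

    cohorts = {}
    for spec in config.cohort_specs():
        if verbose:
            print(f"[{time.time() - t0:7.1f}s] cohort {spec.name}", flush=True)
        cohorts[spec.name] = run_cohort(mesh, truth, spec, config)

    ya = cohorts[config.cohort_names[0]]
    results: dict = {"mesh": mesh, "truth": truth, "cohorts": cohorts,
                     "manifest": manifest}

    # cross-cohort boundary/parcellation comparison
    comparison = {}
    for name in config.cohort_names[1:]:
        c = cohorts[name]
        comparison[name] = {
            "dice_top50": evaluation.dice_boundary(ya["boundary"], c["boundary"], 0.5),
            "map_r": evaluation.map_correlation(ya["boundary"], c["boundary"]),
            "ari": evaluation.adjusted_rand(ya["parcellation"].labels,
                                            c["parcellation"].labels),
        }
        own = evaluation.z_homogeneity(c["parcellation"].labels, c["mean_z"], mesh,
                                       n_rot=config.n_rot, seed=config.seed + 31)
        ya_applied = evaluation.z_homogeneity(ya["parcellation"].labels, c["mean_z"],
                                              mesh, n_rot=config.n_rot,
                                              seed=config.seed + 31)
        comparison[name]["z_homogeneity_own"] = own.z
        comparison[name]["z_homogeneity_ya"] = ya_applied.z
        comparison[name]["silhouette_own"] = evaluation.silhouette(
            c["parcellation"], c["mean_z"], mesh).mean_coef
        comparison[name]["silhouette_ya"] = evaluation.silhouette(
            ya["parcellation"], c["mean_z"], mesh).mean_coef
    results["comparison"] = comparison

    # network stage per cohort + per-subject segregation for the age trend
    seg_rows = []
    net = {}
    for name in config.cohort_names:
        c = cohorts[name]
        parc = c["parcellation"]
        graphs = [network.build_graph(parc, cl, mesh, config.exclusion_mm)
                  for cl in c["clean"] if cl.usable]
        z_list = [g.z_matrix for g in graphs]
        excluded = graphs[0].excluded
        per_density = {}
        for d in config.densities:
            per_density[d] = network.bootstrap_mode_communities(
                z_list, excluded, d, n_boot=config.net_boot,
                seed=config.seed + int(d * 1000))
        consensus = network.cross_density_consensus(per_density,
                                                    min_size=config.min_community)
        # reference systems on the cohort parcels: majority planted system
        ref = _reference_systems(parc, truth)
        sys_type = {s: t for s, t in truth.system_type.items()}
        net[name] = {"consensus": consensus, "reference": ref,
                     "per_density": per_density}
        usable_ages = [s.age for s, cl in zip(c["subjects"], c["clean"]) if cl.usable]
        for g, age in zip(graphs, usable_ages):
            try:
                seg = network.system_segregation(g.z_matrix, consensus)
                seg_rows.append({"cohort": name, "age": age,
                                 "segregation": seg.segregation})
            except ValueError:
                manifest.warnings.append(f"segregation undefined for a {name} subject")
    results["network"] = net
    if len(seg_rows) >= 10:
        results["age_trend"] = network.segregation_age_trend(
            np.array([r["segregation"] for r in seg_rows]),
            np.array([r["age"] for r in seg_rows]))
    results["segregation_rows"] = seg_rows

    manifest.stages["runtime_s"] = round(time.time() - t0, 1)
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def desk_lifespan_config(seed: int) -> StudyConfig:
    """Reduced-scale lifespan study used for the directional aging analyses.

    642-vertex mesh, 24 parcels in 4 systems, 10 subjects per cohort.
    The minimum community size and the centroid exclusion radius are
    scaled with the mesh (the full-scale values would dissolve entire
    planted systems / a third of all node pairs at this resolution).
    """
    return StudyConfig(subdivisions=3, radius_mm=18.0, n_parcels=24,
                       n_systems=4, n_subjects=10, frames=150, n_boot=4,
                       n_rot=100, net_boot=20, min_community=4,
                       densities=(0.05, 0.08, 0.12, 0.16), exclusion_mm=14.0,
                       jitter_mm=(0.75, 1.5, 2.25, 3.4, 4.5), seed=seed)


def recovery_analysis(seed: int, n_rot: int = 100, n_boot: int = 6,
                      verbose: bool = False) -> dict:
    """Planted-structure recovery at full desk scale (2562 vertices).

    One default cohort (40 parcels, 5 systems, 20 subjects, 200 frames) is
    simulated, preprocessed and boundary-mapped; the derived parcellation
    is scored against the planted truth, and the spin-null Z of the
    planted parcellation's homogeneity and of each planted system's Dice
    (via detected consensus communities) are computed.
    """
    from . import evaluation

    mesh = synthetic.make_sphere_mesh(4)
    truth = synthetic.plant_parcellation(mesh, 40, 5, seed=seed)
    spec = synthetic.CohortSpec(name="default", n_subjects=20, frames=200,
                                seed=seed + 1)
    subjects = synthetic.simulate_cohort(mesh, truth, spec)
    params = preprocess.PreprocessParams()
    clean = [preprocess.preprocess_subject(s, mesh, params) for s in subjects]
    bmap, mean_z = boundaries.cohort_boundary_pipeline(
        [c for c in clean if c.usable], mesh, n_boot=n_boot, seed=seed + 7)
    parc = parc_mod.parcellate(bmap, mesh, threshold_q=0.35,
                               presmooth_fwhm_mm=6.0)

    border = np.zeros(mesh.n_vertices, bool)
    border[truth.boundary_vertices] = True
    interior = mesh.cortex & ~border
    ratio = float(np.nanmean(bmap.values[border])
                  / np.nanmean(bmap.values[interior]))
    ari = evaluation.adjusted_rand(parc.labels, truth.parcellation)
    z_hom = evaluation.z_homogeneity(truth.parcellation, mean_z, mesh,
                                     n_rot=n_rot, seed=seed + 11)

    graphs = [network.build_graph(parc, c, mesh) for c in clean if c.usable]
    z_list = [g.z_matrix for g in graphs]
    per_density = {d: network.bootstrap_mode_communities(
        z_list, graphs[0].excluded, d, n_boot=20, seed=seed + int(d * 1000))
        for d in (0.03, 0.05, 0.07, 0.10)}
    consensus = network.cross_density_consensus(per_density)
    ref = _reference_systems(parc, truth)
    _, z_sys = network.match_systems(consensus, ref, parc, mesh,
                                     n_rot=n_rot, seed=seed + 13)
    return {"mesh": mesh, "truth": truth, "parcellation": parc,
            "boundary": bmap, "mean_z": mean_z,
            "ari": float(ari), "n_parcels": int(parc.n_parcels),
            "border_interior_ratio": ratio, "z_homogeneity": float(z_hom.z),
            "z_system": {s: float(r.z) for s, r in z_sys.items()}}


def lifespan_analysis(seed: int, n_reps: int = 10) -> dict:
    """Replicated reduced-scale lifespan studies, aggregated.

    Runs ``n_reps`` seeded replicates of the desk lifespan design and
    aggregates: mean boundary Dice / map correlation / parcellation ARI
    per cohort comparison, the own-vs-young-parcellation Z contrasts for
    the sign test, pooled per-subject segregation against age, and the
    boundary-difference regression of the oldest cohort.
    """
    from scipy import stats as sstats

    from . import evaluation

    names = ("ME", "ML", "OE", "OL")
    dice = {n: [] for n in names}
    map_r = {n: [] for n in names}
    ari = {n: [] for n in names}
    hom_wins_by = {n: [] for n in names}
    sil_wins_by = {n: [] for n in names}
    seg_vals, seg_ages = [], []
    ol_reg_ps = []
    for rep in range(n_reps):
        res = run_study(desk_lifespan_config(seed * 1000 + rep))
        for n in names:
            c = res["comparison"][n]
            dice[n].append(c["dice_top50"])
            map_r[n].append(c["map_r"])
            ari[n].append(c["ari"])
            hom_wins_by[n].append(c["z_homogeneity_own"] > c["z_homogeneity_ya"])
            sil_wins_by[n].append(c["silhouette_own"] > c["silhouette_ya"])
        for row in res["segregation_rows"]:
            seg_vals.append(row["segregation"])
            seg_ages.append(row["age"])
        ya, ol = res["cohorts"]["YA"], res["cohorts"]["OL"]
        reg = evaluation.boundary_diff_regression(
            ol["boundary"].values - ya["boundary"].values,
            ol["mean_thickness"] - ya["mean_thickness"],
            ol["mean_deformation"] - ya["mean_deformation"])
        ol_reg_ps.append(reg.f_pvalue)

    hom_wins = [w for n in names for w in hom_wins_by[n]]
    sil_wins = [w for n in names for w in sil_wins_by[n]]
    r, p = sstats.pearsonr(seg_vals, seg_ages)
    sign_p_hom = float(sstats.binomtest(sum(hom_wins), len(hom_wins),
                                        0.5, alternative="greater").pvalue)
    sign_p_sil = float(sstats.binomtest(sum(sil_wins), len(sil_wins),
                                        0.5, alternative="greater").pvalue)
    aged = [w for n in ("OE", "OL") for w in hom_wins_by[n]]
    aged_sil = [w for n in ("OE", "OL") for w in sil_wins_by[n]]
    sign_p_hom_aged = float(sstats.binomtest(sum(aged), len(aged), 0.5,
                                             alternative="greater").pvalue)
    sign_p_sil_aged = float(sstats.binomtest(sum(aged_sil), len(aged_sil), 0.5,
                                             alternative="greater").pvalue)
    return {"mean_dice": {n: float(np.mean(v)) for n, v in dice.items()},
            "mean_map_r": {n: float(np.mean(v)) for n, v in map_r.items()},
            "mean_ari": {n: float(np.mean(v)) for n, v in ari.items()},
            "sign_p_homogeneity": sign_p_hom, "sign_p_silhouette": sign_p_sil,
            "sign_p_homogeneity_aged": sign_p_hom_aged,
            "sign_p_silhouette_aged": sign_p_sil_aged,
            "hom_wins": int(sum(hom_wins)), "sil_wins": int(sum(sil_wins)),
            "hom_wins_by_cohort": {n: int(sum(v)) for n, v in hom_wins_by.items()},
            "sil_wins_by_cohort": {n: int(sum(v)) for n, v in sil_wins_by.items()},
            "n_comparisons": len(hom_wins),
            "segregation_age_r": float(r), "segregation_age_p": float(p),
            "n_subjects_pooled": len(seg_vals),
            "ol_regression_p": [float(x) for x in ol_reg_ps]}


def regression_type_one_rate(seed: int, n_runs: int = 100,
                             n_vertices: int = 400, alpha: float = 0.05) -> float:
    """Type-I rate of the boundary-difference regression under the null."""
    from . import evaluation

    rng = np.random.default_rng(seed)
    dt = rng.standard_normal(n_vertices)
    dd = rng.standard_normal(n_vertices)
    hits = sum(evaluation.boundary_diff_regression(
        rng.standard_normal(n_vertices), dt, dd).f_pvalue < alpha
        for _ in range(n_runs))
    return hits / n_runs


def _reference_systems(parc, truth) -> np.ndarray:
    """Majority planted system per derived parcel (node-level reference)."""
    sys_vertex = truth.system_labels()
    out = np.zeros(len(parc.parcel_ids), dtype=int)
    for k, pid in enumerate(parc.parcel_ids):
        vals, counts = np.unique(sys_vertex[parc.labels == pid], return_counts=True)
        keep = vals > 0
        if keep.any():
            out[k] = vals[keep][np.argmax(counts[keep])]
    return out


def _write_outputs(results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    synthetic.write_mesh(results["mesh"], out / "mesh")
    synthetic.write_truth(results["truth"], out / "mesh")
    for name, c in results["cohorts"].items():
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        np.savetxt(cdir / "boundary.tsv", c["boundary"].values, fmt="%.6g")
        parc_mod.write_parcellation(c["parcellation"], cdir / "parcels.tsv")
    if "segregation_rows" in results:
        import pandas as pd
        pd.DataFrame(results["segregation_rows"]).to_csv(
            out / "segregation.tsv", sep="\t", index=False)
    summary = {"comparison": _jsonable(results.get("comparison", {})),
               "age_trend": _jsonable(results.get("age_trend", {}))}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    results["manifest"].save(out / "manifest.json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
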