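# arealmap

Cohort-level parcellation of the cortical surface from resting-state
functional correlations (RSFC), with the full downstream evaluation and
network-analysis battery, exercised end to end on synthetic cohorts with
planted areal structure.

## Who this is for

Researchers who study how the brain's areal organisation varies — across
age groups, cohorts, or datasets — using RSFC *boundary mapping*: the
family of methods that locates putative cortical area borders at points
where whole-surface connectivity patterns change abruptly. Real
surface-sampled BOLD data for such studies is rarely shareable, so this
package pairs the complete analysis chain with a synthetic-cohort
generator whose ground truth is known by construction; every stage is
therefore testable, and the package doubles as a validation rig for the
method itself.

## The method

For each cohort of subjects:

1. **Preprocessing** — framewise displacement FD(t) = Σ|Δparam| (rotations
   converted to arc length on a 50 mm sphere), scrubbing at FD > 0.3 mm
   (± 1 frame), nuisance regression (motion + global signal + first
   derivatives), zero-phase band-pass 0.009–0.08 Hz, exclusion below 75
   retained frames.
2. **Boundary mapping** — per subject, the V×V Fisher-z correlation matrix
   of every vertex's time series with every other; over 100 bootstrap
   samples of subjects: average the z-maps, form the RSFC similarity
   matrix (spatial correlation of connectivity maps), take the per-column
   spatial gradient magnitude on the mesh, smooth at 6 mm FWHM; average
   gradients over bootstraps. A minima-seeded watershed runs on every
   column of the mean gradient matrix; averaging the binary ridge images
   gives the cohort boundary map — per-vertex transition probability in
   [0, 1].
3. **Parcellation** — watershed on the boundary map with a flooding
   ceiling at the 35th percentile of boundary values; basins are parcels,
   ridge and above-ceiling vertices stay unassigned.
4. **Evaluation** — Dice overlap of thresholded boundary maps, parcel
   homogeneity (% variance explained by PC1 of member connectivity maps),
   adjacent-parcel silhouette, Jaccard parcel matching, adjusted Rand
   index, within-parcel task-beta dispersion — each against a spin-test
   null: the payload is rigidly rotated on the sphere n times and
   Z = (actual − mean(null)) / sd(null).
5. **Network analysis** — parcels as nodes, Fisher-z edges; densities
   3–10% (negative and < 20 mm edges excluded); two-level map-equation
   (Infomap-style) community detection with 1000-sample bootstrap mode
   consensus and a cross-density consensus; system segregation
   (Z̄w − Z̄b)/Z̄w overall and by system type; age trends of per-subject
   segregation.

The synthetic generator plants Voronoi parcels nested in systems on an
icosphere, synthesises band-limited BOLD-like signals with
within-parcel > within-system > between-system correlation structure, and
exposes two aging knobs: border jitter (cohort-consistent displacement +
subject blurring) and between-system coupling (de-differentiation).

## Worked example

```python
import arealmap as am
from arealmap import boundaries, evaluation, parcellation, preprocess, synthetic

mesh = am.make_sphere_mesh(3, radius_mm=18.0)                  # 642-vertex sphere
truth = am.plant_parcellation(mesh, 24, 4, seed=0)             # 24 parcels, 4 systems
spec = synthetic.CohortSpec(name="YA", n_subjects=10, frames=150, seed=42)
subjects = synthetic.simulate_cohort(mesh, truth, spec)
clean = [preprocess.preprocess_subject(s, mesh, preprocess.PreprocessParams())
         for s in subjects]
bmap, mean_z = boundaries.cohort_boundary_pipeline(clean, mesh, n_boot=8, seed=7)
parc = parcellation.parcellate(bmap, mesh, threshold_q=0.35, presmooth_fwhm_mm=6.0)

print("parcels found :", parc.n_parcels)
print("ARI vs truth  :", evaluation.adjusted_rand(parc.labels, truth.parcellation))
zh = evaluation.z_homogeneity(parc.labels, mean_z, mesh, n_rot=50, seed=11)
print(f"homogeneity   : {zh.actual:.1f}% (null {zh.null_mean:.1f}%, Z = {zh.z:.2f})")
```

prints

```
parcels found : 24
ARI vs truth  : 1.0
homogeneity   : 57.1% (null 47.2%, Z = 6.20)
```

All 24 planted areas are recovered exactly (adjusted Rand index 1.0
against the planted labels), and the parcels' connectivity homogeneity
(57.1% of member-map variance on the first principal component) sits 6.2
null standard deviations above rotated versions of the same parcellation
— the parcellation captures real structure, not chance.

A published lifespan cohort table (MMSE scores by age cohort) serves as a
worked ANOVA example for the summary-statistics route:

```python
f, df_b, df_w, p = evaluation.mmse_anova()    # F(4,217) = 9.312, p = 5.8e-07
```

A command-line interface mirrors the stages:
`areal simulate | preprocess | boundaries | parcellate | evaluate | network | run-study`.

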