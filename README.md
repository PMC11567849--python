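# txconn

Transcription–connectivity association toolkit: a tested, reusable
implementation of the analysis chain that links rTMS-induced changes in
seed-based functional connectivity to spatial gene-expression patterns,
behavioral composites, and protein–protein interaction (PPI) network
structure — together with synthetic-data generators that reproduce the
statistical structure of every input, so the whole chain can be exercised
and validated without any patient scans or atlas downloads.

## Who this is for

Researchers doing imaging transcriptomics on interventional cohorts
(two groups × two scan sessions) who need the full pipeline — or any of its
stages — as library functions with known calibration properties, and a
ground-truthed simulator for power analysis and method validation.

## What it computes

1. **Seed-based connectivity** (`txconn.connectivity`).  For each scan, voxel
   time series are residualized against nuisance confounds (six motion
   parameters, mean white-matter and CSF series), the mean series of a
   spherical seed (default: left angular gyrus, MNI −45, −67, 38, radius
   6 mm) is Pearson-correlated with every voxel, and *r* is mapped through
   the Fisher transform *z* = atanh(*r*) = ½ ln((1+*r*)/(1−*r*)).

2. **Group × timepoint interaction** (`txconn.interaction`).  A voxelwise
   2×2 mixed ANOVA (group between subjects, session within) computed in
   closed form: the interaction *F* equals the squared two-sample *t* on the
   per-subject difference scores, df = (1, n₁+n₂−2) — identical to a GLM
   with subject dummy coding.  Family-wise error over the map is controlled
   by an AlphaSim-style Monte-Carlo cluster-extent threshold: smooth
   Gaussian null fields matched to the residual FWHM are thresholded at the
   voxel *p*, and the smallest extent *k* with P(max cluster ≥ *k*) ≤ α
   defines the surviving clusters.

3. **Behavioral composites** (`txconn.behavior`).  An episodic-memory
   z-sum over AVLT-IR/SR/LR and VR-DR; a sleep-quality index as PC1 of five
   standardized sleep scales (ISI, AIS, PSQI, SRSS, ESS) with a median
   split into low/high-sleep-quality groups; and covariate-adjusted
   (partial) Pearson correlations between interaction-mask connectivity and
   behavior.

4. **Transcription–neuroimaging association** (`txconn.transcriptomics`).
   Expression samples (genes × samples with MNI coordinates, AHBA-style) are
   restricted to the interaction mask; each sample receives the mean
   connectivity-change value in a 6 mm sphere; every gene is correlated
   with those regional values across samples; genes are selected by
   Benjamini–Hochberg FDR (*q* < 0.001); and the significant-gene count is
   referred to a **spatially constrained permutation null**: surrogate
   imaging vectors drawn from a Gaussian process fitted to the empirical
   variogram and rank-remapped to the original values, preserving both the
   marginal distribution and the spatial autocorrelation,
   with p = (k+1)/(n+1).

5. **PPI subnetwork and hubs** (`txconn.ppi`).  STRING-dialect edge tables
   (scores 0–1 or integer 0–999, auto-detected) filtered at confidence 0.7;
   the candidate-gene subnetwork re-filtered at 0.9 with isolated nodes
   removed; edge-count enrichment against random same-size gene sets
   (exhaustive enumeration when feasible); hub genes as the top decile by
   degree.

6. **Synthetic generators** (`txconn.synthetic`).  BOLD cohorts with a
   planted pure-interaction effect (seed-coupling weight changes ±d·σ from
   baseline to follow-up, opposite in the two groups), phenotype tables
   whose sleep scales share a latent group-separating factor and whose
   memory improvements track the planted connectivity change, expression
   matrices with spatially autocorrelated noise genes and a planted subset
   at a target correlation, and Erdős–Rényi PPI backgrounds with a denser
   planted module.  All generators are pure functions of (design, seed).

## Worked example

```python
import numpy as np
import txconn as tc

# 1. simulate a small rTMS cohort with one planted interaction cluster
design = tc.SyntheticDesign(
    grid_shape=(14, 14, 14), n_per_group=12, n_timepoints_series=60,
    planted_clusters=(tc.PlantedCluster(center_voxel=(10, 10, 7),
                                        radius_mm=5.0, effect_size=1.5),),
    rng_seed=11,
)
images, phenotype = tc.generate_cohort(design)

# 2. seed-based Fisher-z connectivity maps (left angular gyrus seed)
seed = tc.SeedSpec(center_mni=design.seed_center_mni, radius_mm=6.0)
zmaps = [tc.seed_fc_zmap(img, seed, mask=design.brain_mask) for img in images]

# 3. voxelwise group-by-time mixed ANOVA + Monte-Carlo cluster correction
result = tc.interaction_analysis(zmaps, design.brain_mask, design.affine,
                                 n_iter=1000, rng_seed=21)
print("estimated smoothness (mm):", np.round(result.est_fwhm_mm, 2))
print("extent threshold (voxels):", result.extent_threshold_voxels)
print(result.cluster_table[["label", "size_voxels", "size_mm3", "peak_stat"]])

planted = design.cluster_mask(design.planted_clusters[0])
dice = 2 * (result.corrected_mask & planted).sum() / (
    result.corrected_mask.sum() + planted.sum())
print(f"Dice overlap with the planted cluster: {dice:.2f}")

# 4. sleep PCA median split on the phenotype table
base = phenotype[phenotype.timepoint == "baseline"].set_index("subject")
split = tc.sleep_pca_split(base[["ISI", "AIS", "PSQI", "SRSS", "ESS"]])
print(split["group"].value_counts().to_dict())
```

prints

```
estimated smoothness (mm): [5.74 5.86 5.82]
extent threshold (voxels): 24
   label  size_voxels  size_mm3   peak_stat
0      9           31     837.0  394.490662
Dice overlap with the planted cluster: 0.76
{'CI+LSQ': 12, 'CI+HSQ': 12}
```

The smoothness estimator recovers the generator's 6 mm noise FWHM; one
31-voxel (837 mm³) cluster survives the 24-voxel Monte-Carlo extent
threshold and overlaps the planted 19-voxel cluster at Dice 0.76; the PCA
median split divides the 24 subjects evenly, recovering the latent
sleep-quality grouping.

## Command-line pipeline

Each stage is also a `txconn` subcommand operating on files
(NIfTI + TSV + JSON):

```sh
txconn simulate       --out study/data --seed 3
txconn connectivity   --data study/data --out study/fc --seed-mni -45,-67,38 --radius 6
txconn interaction    --zmaps study/fc --mask study/data/brain_mask.nii --out study/inter
txconn behavior       --phenotype study/data/phenotype.tsv \
                      --mask-mean study/inter/mask_mean_z.tsv --out study/behav
txconn transcriptomics --expression study/data/expression.tsv \
                      --samples study/data/samples.tsv \
                      --mask study/inter/interaction_mask.nii \
                      --summary study/inter/cohort_change_z.nii --out study/tx
txconn ppi            --edges study/data/ppi_edges.tsv \
                      --genes study/tx/gene_association.tsv --out study/ppi
```

## Documentation

`docs/methods.md` describes the statistical model of every stage, the
generator's assumptions and what they do and do not emulate, numerical
choices, and known limitations.
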