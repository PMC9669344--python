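# Methods

`flairjoint` implements a two-channel discrimination model for FLAIR lesion
masks: a **radiomics channel** that scores each lesion's local appearance and
merges lesion scores into a subject score, and a **spatial-distribution
channel** that scores where lesions sit and how large they are.  The two
channels are combined by logistic regression.  The intended contrast is
autoimmune encephalitis (AE: typically several smaller, often bilateral,
medial-temporal-weighted lesions) versus WHO grade II diffuse astrocytoma
(AS: typically one larger unilateral mass, frontal-weighted).

## Radiomics channel

### Feature catalog

Each lesion (a 26-connected component of the mask, at least 8 mm³) yields a
351-value vector in four families:

* **morphology (29)** — mesh volume, voxel-counting volume, surface area and
  the derived compactness/sphericity set, PCA axis lengths with elongation
  and flatness, maximum 3-D diameter, volume/area densities against five
  reference solids (axis-aligned and oriented bounding boxes, approximate and
  minimum-volume enclosing ellipsoids, convex hull), centre-of-mass shift,
  integrated intensity, and Moran's I / Geary's C spatial autocorrelation.
* **intensity statistics (20)** — 18 first-order statistics of the raw
  masked intensities plus local and global intensity peak (mean over a
  1 cm³ sphere).
* **histogram (30)** — 23 statistics of the discretized grey-level
  histogram (including entropy, uniformity, mode and the histogram-gradient
  quartet) and 7 intensity-volume-histogram features.
* **texture (272)** — six matrix families at distance 1:
  GLCM (25 features × 4 aggregations), GLRLM (16 × 4), GLSZM (16 × 2),
  GLDZM (16 × 2), NGTDM (5 × 2), NGLDM (17 × 2).  Directional families use
  the 13-direction 3-D set and the 4-direction in-plane set; aggregations are
  per-slice-per-direction averaging (`2d_avg`), matrix merging over slices
  and directions (`25d_mrg`), per-direction averaging in 3-D (`3d_avg`) and
  full 3-D merging (`3d_mrg`); zonal families come in per-slice (`2d`) and
  volumetric (`3d`) forms.

The family composition is an interpretation: only the family counts
(29/20/30/272) are fixed externally, so the catalog adopts standardized
IBSI-style definitions that realise those counts, and ships them as a JSON
manifest (`FeatureCatalog.to_manifest`) so every table is self-describing.

### Numerical choices

* **Discretization** — fixed bin number, default 64 bins, mapping the masked
  range onto 1..N (`floor(N·(x−min)/(max−min))+1`, capped at N).  Bin-number
  discretization is scale- and shift-invariant, which suits synthetic
  intensity units; fixed bin size is available.
* **Surface mesh** — marching cubes at iso-level 0.5 on the mask field
  lightly smoothed with a Gaussian (σ = 0.6 voxel).  The raw binary field
  produces a staircase surface whose area overestimates a smooth boundary by
  roughly 8%, biasing sphericity for every lesion; light smoothing restores
  near-unit sphericity for digital balls at the cost of a small volume
  shrinkage for very small lesions (the mesh falls back to the raw field
  when smoothing would erode the lesion below the iso-level, and to a
  voxel-as-box convention for single voxels).
* **Degenerate inputs** — constant regions set skewness/kurtosis/CoV to 0,
  single-level histograms have entropy 0 and uniformity 1, texture units
  with no pairs/runs/zones are skipped in averages (0.0 when no unit exists
  anywhere).  No feature is ever NaN: the LASSO stage requires finite design
  matrices.
* **Intensity peaks** are computed over mask-interior sphere neighbourhoods,
  making them intrinsic to the lesion rather than dependent on how much
  scan context surrounds the crop.
* **Moran's I / Geary's C** are exact up to 1,500 voxels and use a
  fixed-seed subsample beyond that, keeping results deterministic.
* **MVEE** uses Khachiyan's algorithm on convex-hull vertices with a 1e-3
  relative optimality tolerance — adequate for a density-ratio feature.

## Lesion-to-subject scoring (RIL → T → RIS)

Features are standardized with training-set means/SDs (frozen thereafter).
Redundancy is removed by average-linkage hierarchical clustering on
1 − |Spearman ρ| cut at |ρ| ≥ 0.90 (configurable), keeping each cluster's
highest-variance member.  An L1-penalized logistic regression with
stratified k-fold cross-validation (default k = 10) selects features; the
**Radiomics Index for Lesion (RIL)** is the fitted linear score (intercept
included — a constant shifts RIL and the threshold equally, leaving court
membership unchanged).

The **penalty is chosen by the 1-SE rule**: the strongest penalty whose mean
CV deviance is within one standard error of the optimum.  The CV-minimum
rule was evaluated and rejected as the default because it admits several
spurious selections on pure-noise designs (in simulation, only ~2/3 of null
fits stayed at ≤ 2 selected features, versus > 90% under 1-SE, with planted
1.5 SD effects still recovered essentially always).  `penalty_rule="cv-min"`
remains available.

A threshold **T** maximizes the Youden index (J = sensitivity +
specificity − 1) over midpoints of adjacent sorted unique training RILs;
ties break toward higher sensitivity, then the lower cutoff; the
classification rule is positive iff score ≥ T.

The **Radiomics Index for Subject (RIS)** merges a scan's lesion RILs by
courts: the positivity court holds lesions with RIL ≥ T, the negativity
court RIL < T.  Whichever court has the larger summed distance Σ|RIL − T|
speaks for the scan (an exact tie goes to the positive court, consistent
with the ≥ in the classification rule), and the RIS is the winning court's
mean RIL.  A single-lesion scan's RIS is its RIL.

## Spatial-distribution channel (SDI)

From the atlas-space mask each scan yields 27 values: lesion-voxel counts in
the 16 atlas regions (12 supratentorial + 4 infratentorial), the lesion
count, mean/maximum/summed component sizes (mm³), and lesion counts in seven
half-open size bins [8, 80), [80, 160), [160, 320), [320, 640), [640, 1280),
[1280, 2560), [2560, ∞) mm³.  Components below 8 mm³ are discarded from all
statistics, which aligns the lower bin edge with the segmentation convention
of ignoring tiny lesions and makes the bin counts sum exactly to the lesion
count.  Probabilistic masks binarize at ≥ 0.5 (the boundary value is
included).  Lesion voxels on atlas background are counted in size statistics
but not in region counts (warned).  The **SDI** is produced by the same
standardize → LASSO machinery, applied per scan.

## Joint model and evaluation

RIS and SDI enter a maximum-likelihood logistic regression on the training
split; on (quasi-)separation — routine for well-separated synthetic
cohorts — the fit falls back to a tiny ridge penalty (1e-4) so coefficients
stay finite (Wald p-values are then not reported).  AUC uses the
Mann-Whitney formulation with ties counted ½; accuracy/sensitivity/
specificity are reported at the training-split Youden cutoff, frozen for
test and validation.  Correlated AUCs are compared with the DeLong
placement-value test (p = 1 by convention when both the AUC difference and
its variance vanish).  Cohen's kappa and Fisher's exact test (two-sided,
probability ordering) complete the toolkit.  **The positive class is AS
throughout**, so sensitivity means astrocytoma detection; with the opposite
convention the sensitivity and specificity rows transpose.

## Split scheme

Development subjects are split 3:1 into training and test by stratified
sampling within each cohort × scanner stratum (test count = round(n/4) per
stratum; strata under 4 subjects go wholly to training with a warning;
residual adjustment on the largest strata hits each cohort's global
round(n/4)).  A 59 + 79 development roster therefore yields 103 training and
35 test subjects (44/15 and 59/20 per cohort).  Independent-era subjects
never enter training or the split.  All randomness funnels through one
master seed with per-stage derived seeds, so a rerun is bit-identical.

## Synthetic phantoms: what they emulate and what they do not

The generator builds an ellipsoidal "brain" deterministically parcellated
into 16 regions (two axial bands × six angular sectors supratentorially,
labels 1–12; a ventral band × four sectors infratentorially, labels 13–16).
Per class it draws a lesion count (truncated negative binomial; dispersion 0
means deterministic), a placement region (16-way categorical), a radius
(clipped Gaussian, mm) and grows an irregular blob: a spherical distance
field modulated by smoothed noise, thresholded and clipped to the brain,
with a guarantee that every component reaches 8 mm³.  Lesion texture is
correlated Gaussian noise with a class-specific correlation length and an
optional quadratic skew term, added to a class-specific mean offset over a
noisy background (mean 100, SD 5).

Default study conditions (free choices, documented as such because the
source analysis reports no quantitative lesion-size or count
distributions):

| parameter | AE-like | AS-like |
| --- | --- | --- |
| lesion count | NB(mean 3.0, dispersion 2.0), ≥ 1 | exactly 1 |
| radius (mm) | N(4.5, 1.0), ≥ 2.5 | N(9.0, 1.5), ≥ 5.0 |
| placement | bilateral lower-band sectors 2 and 5 (0.30 each) | sector 7 (0.55), sector 1 (0.25) |
| intensity offset | +30 | +30 |
| texture noise SD | 12 | 8 |
| correlation length | 2 mm | 5 mm |
| histogram skew | 0.8 | 0 |

Grids default to 48 × 56 × 48 voxels at 2 mm isotropic spacing.  Scanner id
is metadata only by default (an optional additive scanner bias exists for
robustness experiments), so the scanner-stratified split machinery is
exercised without confounding.

The phantoms deliberately omit MRI physics: no bias fields, partial-volume
effects, registration error, or inter-scanner intensity nonstandardness.
Passing tests therefore demonstrate that the statistical machinery is
implemented correctly and that the pipeline separates classes whose texture
and spatial statistics differ — not that the model attains any particular
accuracy on clinical MRI.

## Problem sizes used by the test suite and acceptance script

The acceptance script runs the full study at the reference cohort sizes
(59 + 79 development, 22 + 28 independent validation, three scanners) on the
default 48³-scale grid.  The model-ordering experiments use 20 seeds of
12 + 12-subject cohorts on a 40 × 44 × 40 grid with 3-fold CV — small
cohorts chosen so a 40-cohort experiment stays a desk-scale computation;
the parameter-recovery suites use 50 seeded fits at n = 300 (signal) and
n = 200 (null).

## Known limitations

* The catalog is one defensible realisation of the printed family counts;
  other extractors order and define features differently, so values are not
  bit-compatible with any specific external tool.
* Mesh smoothing biases mesh volume downward for lesions only a few voxels
  across; voxel-counting volume is exact at all sizes.
* OMBB (PCA box) and MVEE (Khachiyan at 1e-3) densities are standard
  approximations, not exact minimal solids.
* With strongly separated synthetic classes the joint logistic fit is almost
  always in the ridge-fallback regime, so its coefficients are not
  comparable across runs with different penalties.
* Lesions are extracted per connected component; a multifocal scan's
  components are scored independently before court merging.
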