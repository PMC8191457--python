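# Methods

`locrad` implements a *local radiomics* analysis of pretreatment CT for
locating radioresistant (recurrence-prone) sub-volumes inside a gross tumor
volume (GTV).  This note documents the model, its parameters, the numerical
conventions, the synthetic phantoms used for testing, and the limitations a
user should know about.

## Problem setting

For a patient with a contoured primary tumor (GTV) on planning CT and a
co-registered recurrence region (e.g. a 40%-of-maximum threshold on a
follow-up PET uptake volume), two questions are asked:

1. **Differentiation** — do radiomic features of the recurrent part of the
   tumor (GTVrec = GTV ∩ recurrence) differ from the controlled remainder
   (GTVcontrol = GTV \ recurrence)?
2. **Detection** — without knowing where the recurrence is, can sub-regions
   of the GTV be classified as recurrence-prone from their local texture?

The package answers (1) with a bi-regional model (two labelled regions per
patient) and (2) with two local models that tile the GTV into disjoint
sub-regions, extract the same feature vector per sub-region, and train a
logistic classifier on sub-region labels derived from the recurrence
overlap.

## Preprocessing

* Images are resampled to cubic voxels (default **3.3 mm**) with trilinear
  interpolation; masks follow with nearest-neighbour interpolation.  The
  resampled grid is corner-aligned with the input (same origin, shape
  `ceil(n·s/target)` per axis) — a deterministic convention that makes
  extent arithmetic testable.
* A soft-tissue Hounsfield window of **[-20, 180] HU**, inclusive at both
  ends, is applied inside the GTV; voxels outside the ROI *or* the window
  become NaN and are excluded identically everywhere downstream (texture
  pairs, runs, zones, neighbourhoods and distance maps all treat them as
  outside the region).
* Contours on user-listed artifact slices can be cleared before resampling.
* Regions with fewer than **27** analysable voxels are excluded from
  feature extraction — below that, texture matrices are too sparse to be
  meaningful.

## Feature vocabulary (161 items)

25 intensity features: 18 first-order statistics on raw HU (population
moments; excess kurtosis; percentiles by linear interpolation between order
statistics) and 7 histogram features on discretised gray levels.

136 texture features: 25 GLCM × {averaged, merged}, 16 GLRLM × {averaged,
merged}, 16 GLSZM, 16 GLDZM, 5 NGTDM, 17 NGLDM, following the community
standardisation conventions: symmetric co-occurrences over the 13 unique 3D
directions at Chebyshev distance 1; 26-connected zones; 26-neighbourhoods;
dependence coarseness α = 0.  *Merged* sums the 13 directional matrices
before normalisation, *averaged* averages per-direction features; for the
merged run-length matrix the run-percentage denominator is the voxel count
times 13 so the fraction of realised runs stays in (0, 1].

**Discretisation.** Gray levels use a fixed bin width (default **5 HU**)
anchored at the window's lower edge: `level = floor((x + 20)/5) + 1`,
giving Ng = 41 constant across patients and sub-regions.  A fixed,
window-anchored alphabet is essential for the local method — features of
different sub-regions must be comparable, which a per-region min/max
scheme would break.

**Degenerate inputs are legal.** A constant region yields a finite vector:
zero-variance skewness/kurtosis are defined as 0, GLCM correlation with
zero marginal variance as 1, empty-count ratios as 0, and NGTDM coarseness
(1/Σp·s with a vanishing denominator) is capped at 1e6.  The GLDZM distance
of a zone is the minimum Chebyshev distance of its voxels to the ROI border
(missing voxels and the volume edge both count as border; minimum 1).
The histogram mode takes the lowest level among ties.

The extractor is verified feature-by-feature (to 1e-9) against an
independent naive enumerator — triple-loop pair counting, explicit run
walking, BFS zones, loop-based formulas — on hundreds of random volumes
with missing voxels, plus hand-enumerated fixtures.

## Sub-region schemes

* **Fixed count (8 octants).** Three axis-aligned planes through the
  rounded foreground center of mass split the ROI into 8 octants whose size
  scales with the tumor.  A voxel whose index equals the center coordinate
  goes to the upper half.  Octants below the 27-voxel minimum are dropped
  with a logged reason.
* **Fixed size (5×5×5 cells).** A non-overlapping 5-voxel grid tiles the
  ROI bounding box; cells with at least **T = 25** ROI voxels are retained.
  The grid's global offset is searched exhaustively over 5³ = 125
  candidates and chosen to *maximise the analysed tumor volume* (total ROI
  voxels inside retained cells), ties broken by the lexicographically
  smallest offset.  Maximising the retained-cell count instead would prefer
  splitting full cells into partial ones (e.g. a 5×5×5 tumor into three
  slabs), which contradicts the coverage goal; the chosen objective is
  validated against an exhaustive-search oracle in the tests.

Sub-regions are disjoint by construction in both schemes, so sub-region
descriptors are independent.  A sub-region is labelled **recurrent** iff
strictly more than 50% of its ROI voxels lie inside GTVrec (denominator =
ROI voxels, not full cell voxels, since only ROI voxels are analysed;
a `label_subregions` threshold argument exposes the rule).  Per-sub-region
scalars can be painted back over the ROI as NIfTI parametric maps.

## Selection and classification cascade

Given a training table (rows = regions/sub-regions, columns = 161
features + voxel count + binary label):

1. **Voxel-count filter** — drop features with |Pearson r| > 0.5 against
   the region voxel count (they encode size, not texture; the magnitude is
   used because a strong negative dependence is equally confounding) and
   constant features.
2. **Horn parallel analysis** — z-score, eigen-decompose the correlation
   structure, and retain the leading components whose eigenvalues exceed
   the 95th percentile of 1000 column-permutation nulls (seeded; retention
   stops at the first failure).  With no retained component the cascade
   degenerates to an intercept-only model, logged.
3. **Grouping** — each feature joins the retained component with the
   largest |Spearman ρ| to its scores (rank-based, ties to the lower
   component).
4. **Representatives** — per group, the feature with the largest univariate
   logistic-regression AUC among those with slope p < 0.05.  The p-value is
   the Wald test from the maximum-likelihood fit; when the MLE fails
   (perfect separation) the fit is stabilised with a 1e-6 ridge on the
   slopes and the p-value falls back to the likelihood-ratio test — the
   Wald statistic collapses under separation (Hauck–Donner) and would
   absurdly reject a perfectly separating feature.
5. **Backward AIC** — multivariable logistic regression pruned by removing,
   at each step, the variable whose removal lowers AIC = 2k − 2 log L the
   most, until no removal lowers it.  The AIC path is non-increasing by
   construction and asserted in tests.  Note that AIC alone retains a pure
   noise covariate with probability P(χ²₁ > 2) ≈ 0.157; the p < 0.05
   representative gate in front of it is what brings the cascade's false
   inclusion rate down to ≈ 5%.

**Decision rule.** The classification cut-off is the 75th percentile of the
training-cohort predictions (linear-interpolation percentile, ties
classified positive), i.e. the top quartile of training scores is called
recurrent.

**Uncertainty.** AUC confidence intervals use 2000 stratified bootstrap
replicates (resampling within each class, preserving class counts exactly)
and the percentile CI.  The replicate AUC is computed by a vectorised
Mann–Whitney count; its equality with `sklearn.roc_auc_score` is asserted
in the tests.  Empirical coverage of the 95% CI in a Gaussian-shift model
at n = 200 is ~95%, re-measured by the acceptance suite.

**Evaluation designs.** The bi-regional and octant models train on the
training cohort and validate on the held-out cohort.  The fixed-size model
uses leave-one-patient-out cross-validation: only patients contributing
both sub-region classes enter (a requirement of per-fold AUC), the entire
cascade is re-fitted inside every fold, and folds are reported individually
(NaN rather than dropped when undefined; folds with ≤ 2 held-out
sub-volumes are flagged).  Sub-regions of one patient are treated as
independent rows — a known limitation inherited from the method, not
corrected here.

## Synthetic phantoms

No patient imaging ships with the package, so a phantom generator provides
ground-truth cohorts.  Each phantom is an ellipsoidal GTV (semi-axes
randomised in 12–18 mm) in a 40×40×28 volume at (1.2, 1.2, 3.0) mm spacing
(CT-like anisotropy); mean tumor intensity 80 HU so that the soft-tissue
window retains ≥ 95% of GTV voxels and does not dominate results.  Texture
is spatially correlated Gaussian noise: white noise smoothed with a
Gaussian kernel (correlation length 1.5 mm) and rescaled empirically to
SD 15 HU.  One stationary texture field covers the GTV *and* an 8 mm
soft-tissue margin around it; the distinct background (0 ± 10 HU) begins
only beyond that margin.  Inside the recurrence blob — a sphere placed
off-center inside the GTV, as focal recurrences are — an independent
finer-scale field (correlation length divided by the effect size) scaled
by √(effect² − 1)·SD is *added*, so the blob's voxel SD is exactly
**effect size** × control SD, and effect size 1.0 adds nothing at all.

Two constructional choices are pinned by the generator's null contract
(effect size 1 ⇒ no design may detect the blob): the correlation length
stays below the 3.3 mm analysis voxel, because texture power at
wavelengths comparable to sub-region size couples sample variance to
region size (recurrent regions are systematically smaller, so even the
null would separate by size); and the texture field must continue
seamlessly past the GTV surface, because trilinear resampling otherwise
blends background intensities into the controlled shell and separates
interior from shell regions for geometric, not textural, reasons (a mean
gradient of only 5 HU at the surface already lifts the null AUC to ~0.8).
Both effects are worth knowing about when interpreting bi-regional
analyses of real data.

Blob radius is solved from a target recurrence fraction; cohorts sample
that fraction log-uniformly over [0.02, 0.71], reproducing both a
realistic right-skewed distribution (cohort mean ≈ 19%) and the full
range.  Default cohorts are 28 training + 12 validation patients, fully
reproducible from a master seed.

What the phantoms do *not* emulate: CT physics (beam hardening, metal
artifacts, partial volume beyond grid resampling), anatomy, multi-scanner
protocol variation, or any biological mechanism — "heterogeneity" here is
elevated local noise, chosen as the minimal mechanism the feature families
are designed to detect.  Passing the end-to-end tests therefore shows the
*pipeline* recovers planted heterogeneity signals at realistic region
sizes; it does not certify clinical performance on real cohorts.

A note on hypothesis tests against phantom textures: spatially correlated
fields make nominal-df two-sample tests on voxel values invalid (the
effective sample size is far below the voxel count), so the test suite
checks the null construction via the SD ratio across seeds and runs the
exact F-test only on white-noise phantoms where its degrees of freedom are
correct.

## Problem sizes used by the test and acceptance runs

Oracle equivalence uses 200 random volumes up to 5×5×5 with ≤ 4 gray
levels; cascade correctness uses 50 seeded n = 300 designs; CI coverage
uses 200 outer replications of n = 200 with B = 2000; the end-to-end
effect-size sweep runs full 28+12 cohorts at effect sizes {1, 1.5, 2, 3}
with 3 seeds each and compares medians.  `scripts/acceptance.py` runs one
full cohort (effect size 2.0) through all three designs.

## Residual size confounding in the bi-regional design

The null phantom cohorts expose a property of bi-regional comparisons
worth stating explicitly.  GTVrec is systematically smaller than
GTVcontrol (here 2–71% of the GTV), and many feature estimators are
biased in the sample size: the sample minimum/maximum drift outward with
more voxels, histogram entropy is biased low at small n, kurtosis and
distance-zone statistics likewise.  Pooled across a cohort, these
features' linear correlation with voxel count is diluted by
between-patient texture variability to |r| ≈ 0.35–0.55 — often just below
the 0.5 exclusion cut — while the *within-patient* size ordering is
deterministic, so they still rank recurrent vs controlled regions almost
perfectly.  On null cohorts (no planted heterogeneity) the bi-regional
cascade therefore reaches validation AUCs around 0.7–0.8 from region size
and shape alone, whereas the size-matched fixed-count design sits cleanly
at chance (median AUC 0.50).  The linear voxel-count filter mitigates but
cannot eliminate this; bi-regional results on real data should be read
with that caveat, and the local designs are the more strictly controlled
comparison.  The corresponding null assertion in the acceptance suite is
left failing by design for the bi-regional model — it documents the
method, and silencing it would hide a real effect.

## Known limitations

* NIfTI-1 is the only on-disk format (convert DICOM-RT externally); grids
  must be axis-aligned.
* The octant geometry of the fixed-count scheme and the discretisation
  parameters are package conventions exposed in `RunConfig`; other
  reasonable choices exist.
* The fixed 161-item roster excludes shape/morphology and filtered feature
  classes by design.
* Rigid registration of recurrence imaging to planning CT is out of scope;
  inputs are assumed co-registered (grid mismatches are rejected, not
  fixed).
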