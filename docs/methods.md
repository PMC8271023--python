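# Methods

This note documents the models and procedures implemented in `mibitime`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions used throughout.

## Quantification and positivity

A cell's expression of marker *m* is the mean per-pixel channel value over
the cell's pixels (sum over pixels, divided by cell size in pixels), which
removes the dependence of raw sums on cell area. Positivity thresholds are
derived from the image background: every label-0 pixel in every cohort
image is pooled, and the threshold for marker *m* is the pooled mean
per-pixel expression of channel *m*. Background regions contain no cells,
so this mean estimates the non-specific signal floor per channel. A cell
is positive for *m* when its mean expression **strictly** exceeds the
threshold; the boundary case is negative, because expression
indistinguishable from background carries no evidence of signal. Pooling
is cohort-wide by default (a per-image mode exists for heterogeneous
acquisitions but is off by default). This is deliberately a *low*
threshold — it trades specificity for sensitivity to weak but spatially
structured expression.

Segmentation masks come in two dialects. `instance_labels` (preferred)
gives each cell a unique integer plus a label→type table.
`type_grayscale` encodes cell *type* as the gray value; cells are
recovered as 8-connected components per gray value, which cannot separate
touching same-type cells — a documented limitation retained only for
compatibility with type-encoded masks. Connectivity is 8-neighbor;
component ids are assigned in (gray value, scan order) and are
deterministic. Pixel coordinates are 0-based (row, column); centroids are
unweighted pixel means in pixel units.

## Co-expression and interaction matrices

Co-expression: cell positive for markers *a* and *b* ⇒ one count for the
unordered pair {a, b}; a cell with *k* positive markers contributes
k(k−1)/2 pairs. The matrix is symmetric by construction. Feature vectors
flatten the upper triangle row-major in marker order with canonical
alphabetical names "A+B". The co-expression diagonal (joint positivity of
a marker with itself) is plain positivity, already covered by
positivity-proportion features, so co-expression features exclude the
diagonal by default; both choices are configurable.

Interactions: cell adjacency is defined by the Voronoi tessellation of
centroids — two cells interact iff their Voronoi regions share a border of
**positive length**. Unbounded ridges count as borders; zero-length ridges
(four or more cocircular centroids meeting in a point) do not — a point
contact is not a shared border, and this tie-break is deterministic
without jitter. Degenerate inputs degrade gracefully: duplicate centroids
raise an error naming the cells; fewer than three cells or all-collinear
centroids fall back to nearest-neighbor chain adjacency along the line.
Image-border cells keep their clipped polygons; no edge-effect exclusion
is applied. Each unordered adjacency is visited once and the Cartesian
product of the two cells' positive-marker sets is tallied into a symmetric
matrix whose (A, B) entry counts occurrences of an A-positive cell
bordering a B-positive cell; homotypic pairs land on the diagonal, and
interaction feature vectors include the diagonal by default because
homotypic interactions are analysed in their own right. A fixed-radius
adjacency mode exists purely for comparison experiments; the Voronoi
construction is the method. All cells participate in the tessellation
geometry; marker subsetting happens only at tally time.

Heatmap exports apply a cube-root transform for display only; statistics
always run on raw counts.

## Patient stratification

Feature tables (patients × named pair features) are z-scored per column
with the population standard deviation; zero-variance columns are dropped
with a warning. Clustering is agglomerative with Ward linkage on Euclidean
distance — the standard pairing for clustermaps of z-scored features; both
are configurable, and reported results should state the pair used. The
number of clusters is chosen by maximising the mean silhouette over k ∈
[2, 6] (singleton clusters score 0; ties break toward smaller k for
parsimony). Cluster labels are renumbered by first patient appearance so
assignments are deterministic and order-invariant. Exact reproduction of
any particular published 2-way split is not guaranteed under any default,
since the linkage behind published clustermaps is generally unstated.

## Survival statistics

* **Kaplan–Meier** product-limit curves; censored subjects leave the risk
  set without a step.
* **Log-rank (Mantel–Cox)**, two-sided, hypergeometric variance with tie
  sharing, χ² reference with (groups − 1) df.
* **Cox proportional hazards** via partial-likelihood Newton iterations
  with **Efron** tie handling (the better default under ties). Inference
  is the Wald z test per coefficient — the convention consistent with
  standard reported tables. Constant covariates are inestimable and
  dropped with a warning; categorical covariates (e.g. the immune
  architecture label) are reference-coded; monotone-likelihood /
  separation cases are flagged `converged=False` and refit with a tiny
  ridge penalty so coefficients remain reportable.
* **Benjamini–Hochberg** step-up FDR, applied within each feature family ×
  endpoint. (Note: BH adjustment is order-invariant and rank-monotone but
  *not* idempotent — re-adjusting adjusted values changes them.)
* **Wilcoxon rank-sum**, two-sided; the reported statistic is the
  tie-corrected normal-approximation z, with the p value from exact
  enumeration when both samples have fewer than 8 observations and no
  ties.
* **Harrell's c-index** over event-anchored comparable pairs; score ties
  count 0.5.
* **Random-forest importance**: classification forests (500 trees,
  seeded) on cluster labels report mean decrease in Gini, raw and
  max-normalised. Importance scores depend on forest hyperparameters and
  normalisation and are comparable only within a run.
* **Survival-forest Shapley importance**: a random survival forest
  (log-rank split rule, 200 trees, seeded) is fit on the six standard
  predictors (three cluster variables, grade, age, architecture); the
  per-sample risk score is attributed to predictors by **exact
  interventional Shapley values** — full enumeration over feature
  coalitions with the predictor table itself as the marginalisation
  background (2^d model calls, feasible for d ≤ 14). Local accuracy holds
  exactly: per sample, attributions sum to risk − base. A predictor the
  forest never uses gets attribution exactly 0. Variable importance is
  the mean absolute attribution; goodness-of-fit is the in-sample
  c-index. In-sample concordance of a deep forest is optimistic; the
  package's permutation control (refit on row-shuffled predictors,
  score the original design) is the honest null reference (~0.5).
* **2-D embedding** via UMAP, seeded; the neighbor count is clamped to
  n − 1 with a warning on small cohorts.

Patients lacking a required outcome are excluded from survival stages and
never imputed.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
desk scale. Defaults (the study conditions of the validation suite):
40 patients, 384 × 384-pixel images, ~400 cells per image, a 10-marker
panel (8 functional including the immunoregulatory quartet PD-1, PD-L1,
IDO, Lag3; 2 lineage), planted pair (PD-1, IDO) at colocalization
ρ = 0.9, group hazard ratio 3, 30% censoring.

* **Geometry.** Cell centers are drawn by uniform proposals with
  minimum-distance rejection (blue-noise; spacing 0.7·√(HW/n)); every
  pixel joins its nearest center and each region is then shrunk by one
  pixel, guaranteeing a background skeleton for thresholding. A region
  eroded to nothing is restored at its center pixel. Images must provide
  at least 9 pixels per requested cell.
* **Cell counts.** Per image, round(Normal(mean, 0.1·mean)). The real
  cohorts this emulates show heavier between-patient dispersion
  (coefficient of variation ≈ 0.3); that heterogeneity — like instrument
  artifacts, channel crosstalk and realistic tissue morphology — is
  deliberately not emulated. Passing tests therefore demonstrate
  correctness of the machinery under controlled conditions, not
  robustness to the full variability of real cohorts.
* **Expression.** Per-pixel intensities are gamma (shape 3) with mean 20
  where the cell is positive for the marker, 0.5 where negative, 1.0 in
  background. Negative cells sit *below* background by design: the
  background-mean thresholding rule classifies "above background" as
  positive, so the generator encodes non-expression as sub-background
  signal, making truth recovery well-defined (and ≈100% accurate at
  default separation).
* **Positivity.** Per-(cell type, marker) Bernoulli probabilities (e.g.
  PD-1 on 35% of CD8 T cells, PD-L1 on 30% of tumor cells, CD45 on 90% of
  immune cells; 5% baseline otherwise).
* **Planted phenotype.** Group 1 patients (patient index odd) receive the
  planted pair by *exclusive pairing*: Voronoi-adjacent cell pairs are
  visited in random order and planted (one cell A-positive, the other
  B-positive, random orientation) with probability ρ, each cell joining
  at most one pairing. Exclusivity keeps marker marginals far from
  saturation so the enrichment is genuinely spatial: at ρ = 1 the
  planted-pair interaction count exceeds the 95th percentile of
  phenotype-permutation nulls, and the count is monotone in ρ.
* **Outcomes.** Event times are exponential with rate h₀ (group 0) and
  h₀ × HR (group 1), h₀ = 0.02 per time unit; recurrence and overall
  survival share the group effect with independent draws. Censoring is
  independent uniform: C ~ U(0, c_max) with c_max calibrated by
  root-finding so the expected censored fraction equals the requested
  rate (30% → ~70% events). Clinical covariates (age ~ N(54, 15), grade
  mostly 3, architecture uniform) are outcome-independent noise.
* **Reproducibility.** One global seed; per-patient generators are
  spawned as SeedSequence([seed, patient_index]) substreams, so any
  patient regenerates independently and byte-identically.

At these conditions, measured properties of the suite: Ward clustering of
interaction features recovers the planted groups (ARI = 1.0 at the fixed
seed); two-sided log-rank power on the truth groups is ≈ 0.81 (estimated
at 1000 replicates — at 100 replicates the Monte-Carlo error of ±0.04
makes the estimate unstable around 0.8, so the validation suite uses 1000);
type-I error at α = 0.05 is within Monte-Carlo error of nominal; Cox
recovers log HR = log 3 within 3 standard errors at n = 200.

## Problem sizes

The validation suite and `scripts/acceptance.py` run at the desk scale
described above (40 patients × ~400 cells; 1000-replicate Monte-Carlo
loops; 200 random point sets for the geometry oracle), chosen so the full
analysis of a cohort completes in minutes on one core while keeping every
statistical check at meaningful power.

## Known limitations

* Upstream concerns are out of scope: nuclear segmentation, radial
  expansion of cell boundaries, lineage gating to cell types, and
  instrument processing are consumed as inputs, not reproduced.
* The grayscale mask dialect merges touching same-type cells.
* Silhouette-guided k and Ward/Euclidean defaults need not reproduce any
  specific published patient split.
* Forest importance scales (Gini, |SHAP|) are run-relative; the package
  never compares them numerically across configurations.
* No proportional-hazards diagnostics, competing risks, or time-varying
  covariates.
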