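# Methods

## The analysis in one paragraph

A synchronized cohort's bulk RNA-seq time course (days 2–12 of adulthood)
defines the average aging trajectory of the population. Samples sorted at
day 5 into the top or bottom tenth percentile of a lifespan-predictive
fluorescent biomarker are placed on that trajectory by projection onto a
principal curve through the time-course samples in PC space; their
calibrated arc-length position is their *physiological age*. Differential
expression against biomarker status is then decomposed by refitting the
count model with physiological age in place of chronological age: genes
whose biomarker association survives this substitution, and which show no
average time trend, constitute the age-orthogonal signature of future
lifespan.

## Count model

Per gene, counts are negative-binomial (NB2) with log link and offset
log *s<sub>j</sub>*:

* **Size factors** *s*: median-of-ratios against per-gene geometric means
  over genes nonzero in all samples, rescaled to geometric mean 1. If no
  gene is all-nonzero the reference set falls back to genes positive in at
  least half the samples (warned).
* **Design**: intercept; age, age², age³ with age centered to mean 0 and
  scaled to SD 1 *before* taking powers (one shared scaling — the cubic
  stays interpretable while conditioning is restored by the scaling; raw
  day-scale powers up to 12³ would make the normal equations needlessly
  ill-conditioned); a marker term; batch one-hot with the first level as
  reference. The pooled marker column carries the predicted-longevity code
  (+1 long-lived, −1 short-lived, 0 time course). The per-marker variant
  emits one column per biomarker coded by measured fluorescence level
  (+1 marker-high, −1 marker-low): with level coding, the sign pattern of
  between-marker coefficient correlations reflects each marker's direction
  of lifespan association, which is the structure the signature comparison
  is meant to expose. Degenerate (constant) columns are pruned with a
  warning; a rank-deficient design is an error.
* **Dispersion**: per-gene method-of-moments on normalized counts,
  α̂ = (v − m·mean(1/s))/m² with v the OLS design-residual variance and m
  the mean normalized count; a robust trend α(μ) = a₀/μ + a₁ fit in log
  space (soft-L1 loss) over genes with positive α̂; final dispersion is the
  log-scale midpoint of raw and trend (weight 0.5), clamped to
  [1e-8, 10]. Genes with non-positive α̂ are consistent with Poisson noise
  and take the lower clamp. This moment/trend scheme reproduces the
  mean–variance contract of the heavier Cox-Reid/empirical-Bayes estimators
  at a fraction of their complexity; it is a known source of gene-level
  disagreement with those estimators, which matters for count-level
  comparisons but not for the calibration of the downstream tests (checked
  by simulation: Wald type-I error at nominal 0.05 stays within
  [0.03, 0.07] on a 2000-gene null).
* **Fitting**: IRLS (Fisher scoring) vectorized across genes — working
  weights μ/(1+αμ), ridge 1e-6 on the normal equations, convergence at
  max|Δβ| < 1e-8 or 100 iterations, linear predictor clipped to ±30 around
  the offset. Non-converged genes are flagged, not dropped. Standard errors
  come from the inverse Fisher information X'WX at the optimum (for the NB
  log link this is the standard GLM curvature). Wald p-values use the
  normal reference; q-values are Benjamini–Hochberg per coefficient across
  genes. Zero or non-finite SEs yield NaN p/q and are excluded from the
  adjustment.
* **VST**: x = (2/√a₁)·asinh(√(a₁·y/s)) with a₁ the trend's asymptotic
  dispersion — the closed-form NB variance stabilizer, which tends to
  2√(y/s) as a₁→0. Non-positive a₁ falls back to log2(y/s+1) (warned).
* **Batch correction** (expression matrix only): per-gene OLS on
  [protected design columns + batch indicators], subtracting only the batch
  component. The GLM handles batch through its own term; the corrected
  matrix feeds PCA, the principal curve, and clustering only, so batch is
  never corrected twice in the same fit.

## Physiological age

PCA (3 components by default, matching the dimensionality in which the
trajectory is visually one-dimensional) on the batch-corrected VST matrix of
detected genes, genes centered but not scaled, with a deterministic sign
convention (largest-magnitude loading positive). The principal curve is
Hastie–Stuetzle: the latent parameter initializes as the PC1 coordinate;
each iteration smooths every coordinate against the parameter with a cubic
spline (4 df), resamples 512 vertices, reparameterizes by cumulative arc
length, and re-projects; convergence when the relative change in mean
squared projection distance is below 1e-6. The curve smoother uses 4 df —
deliberately stiffer than the 5-df trajectory smoother — because it is fit
to 11 timepoint groups in 3-D and must not chase replicate noise.

Projection onto the dense polyline refines the nearest vertex by orthogonal
projection onto adjacent segments; ties break toward the smaller arc
position. Calibration is proportional by default: a linear map of arc length
fixed by the mean arc positions of the youngest and oldest chronological
days, extrapolated linearly. A monotone alternative (isotonic regression of
day on arc position, linearly interpolated) is provided because
"proportional to arc length" underdetermines the map when trajectory speed
varies; on the synthetic cohort the two agree closely and the proportional
map is the default. The residual (distance from the curve) is reported with
a sign taken along a configurable reference component (PC2 by default);
group labels are reported alongside so the sign can also be read against
predicted longevity.

## Trajectory clustering

Time-course replicates are averaged per timepoint; each gene's 11-point
trajectory is smoothed by a cubic spline with 5 df and z-standardized
(constant genes map to zero and are flagged). "Cluster 0" is assigned by the
chronological-age model: genes with no age coefficient at q < 0.01. The
rest are clustered by complete linkage on pairwise DTW distances —
squared-difference local cost, symmetric steps, Sakoe–Chiba band of radius
1 index (the series are daily, so 1 index = 1 day), square root of
accumulated cost — and the tree is cut into five clusters. The "df degrees
of freedom" smoother is implemented as a cubic B-spline regression basis
with exactly df coefficients (knots at interior quantiles) fit by least
squares: it has exactly the stated model complexity, reproduces cubics and
lines exactly, is deterministic, and vectorizes across thousands of genes,
at the price of not being a penalized smoother with *effective* df — an
acceptable trade at 11 timepoints.

Centroids are DTW barycenter averages: medoid initialization, then
iterative re-averaging of values along alignment paths; an update that does
not decrease the objective (sum of squared DTW distances) is discarded, so
the objective is non-increasing and iteration stops at 10 rounds or
stagnation. Cluster labels 1–5 are semantic, assigned by correlating each
centroid with canonical shape templates (monotone up, monotone down, early
peak at day 4, late peak at day 9, mid trough at day 7) and solving the
correlation-maximizing one-to-one assignment; for k ≠ 5 each centroid
independently takes its best template. Pairwise DTW is computed by running
the band dynamic program on all gene pairs simultaneously (one matrix per
band cell), which makes the full distance matrix an O(T·window) sequence of
array operations.

## Signatures and enrichment

Signature similarity is the Pearson correlation matrix over per-gene
coefficient vectors: the four per-marker terms plus the linear age term,
pairwise-complete over the shared gene universe. Classification at
q < 1e-4 in the physiological-age model: *age-specific* (any of the three
age terms, not the marker term), *marker-specific* (marker only),
*intersection* (both), *neither*. Marker-specific genes lying in cluster 0
are flagged as the age-orthogonal signature — "no average time trend" is
operationalized as cluster-0 membership, an interpretive choice: it uses the
independent chronological-age fit rather than re-using the physiological-age
q-values being classified.

GSEA consumes a ranked list scored sign(β)·(−log10 q) (q floored at the
smallest positive normal float; ties broken by gene id). The enrichment
score is the weighted Kolmogorov–Smirnov running sum (hit increments
∝ |score|^weight, uniform miss decrements, maximal absolute deviation with
sign). The null preserves set size by sampling random gene sets from the
universe — the appropriate null for a method that consumes one ranked list
rather than per-sample phenotypes; p = (1 + #{same-sign |null ES| ≥ |ES|}) /
(n_same_sign + 1), NES divides by the mean same-sign |null ES|, and BH runs
across sets with the display score's q floored at 1/(n_perm+1) to stay
finite. Over-representation uses the exact upper-tail hypergeometric
probability.

## Survival

Kaplan–Meier product-limit curves and Mantel–Cox log-rank tests (lifelines
underneath, with hand-rolled oracles in the test suite). Records are one row
per individual (day, death/censor); at tied days deaths are processed before
censorings, the standard convention. The median is the first time S ≤ 0.5
(error if never reached); the headline statistic for a sorted pair is the
percent median-lifespan difference, oriented predicted-long minus
predicted-short.

## Synthetic cohort: what it emulates, and what it does not

Each individual i carries an aging rate r\_i = exp(N(0, σ\_r²)), σ\_r = 0.25
— physiological age is the linear reparameterization r\_i·t, the simplest
model of "everyone traverses the same trajectory at different speeds" — plus
a latent factor q\_i ~ N(0,1) independent of r\_i representing
lifespan-correlated transcriptional state that is *not* a position shift
along the trajectory. A shared health axis u\_i = −w\_r(r\_i−1)/σ\_r +
w\_q·q\_i (w\_r = w\_q = 1) drives four biomarkers b = sign·u + N(0, 0.5²),
two positive (lin4, mir243) and two negative (mir240\_786, autofl), so all
markers are noisy readouts of one underlying state, as the redundancy of
real aging biomarkers suggests. Lifespan is base\_lifespan/r\_i up to
lognormal noise (base 15 d, matching wild-type medians at 25 °C; noise SD
0.15), giving biomarker–lifespan correlations around ±0.5 — strong but
imperfect single-timepoint predictors.

Genes follow six trajectory archetypes — flat (20%), monotone up (28%),
monotone down (28%), early peak day 4, late peak day 9, mid trough day 7
(8% each; the monotone classes dominate, as they do in real aging
transcriptomes) — with log-scale amplitudes uniform in [0.5, 2], baselines
log-uniform in [20, 2000], NB dispersions log-uniform in [0.01, 0.4], and
Gaussian bumps of width 1.5 d for the peaked shapes. 150 of the flat genes
are age-orthogonal: they load γ = ±0.8 on q. Bulk samples pool 50
individuals (drawn from the whole cohort for the time course; from the
realized top/bottom nearest-rank decile of one biomarker for day-5 sorted
samples), average expected expression on the natural scale across the pool,
and draw one NB library per sample with per-gene batch factors
(2 batches, log-SD 0.1, replicates cycling over batches) and lognormal
library-size variation (SD 0.15). Defaults: 11 timepoints × 3 replicates
plus 4 markers × high/low × 3 replicates = 57 samples, 3000 genes, 1000
individuals; replicate count per sorted group is a free choice (3) since
a canonical value does not exist. The survival table records post-sort
lifespans of sorted individuals with a 5% random censoring rate —
lifespan is deterministic in r up to lognormal noise rather than
hazard-based, so censoring exercises the estimator's code path, not a
competing-risks model.

What passing tests show — and do not. The generator realizes heterogeneous
aging rates, a redundant biomarker panel, age-orthogonal expression, batch
structure and overdispersed pooled counts, so recovery results demonstrate
that the pipeline's geometry (curve, projection, calibration) and inference
(GLM, classification) work under realistic noise. It does not emulate:
per-individual transcriptomes (a pooled library has no within-pool
covariance beyond what pooling of means induces), trajectory shapes beyond
the six archetypes, secular composition drift (e.g. sample loss of
short-lived individuals at late timepoints), transcriptome-wide correlation
between genes beyond their shared dependence on (r, q), or imaging/sorting
error beyond biomarker noise. Passing recovery tests on this cohort
therefore validates the machinery, not the biology of any particular real
dataset.

One pooling effect is worth knowing about: time-course pools span the full
aging-rate distribution, so at mid-life chronological ages a pool averages
individuals ±2.5 physiological days apart, which flattens trajectory
features narrower than that spread (Jensen averaging of exponentials). The
decile-sorted pools are rate-homogeneous and show such features at full
strength. High-amplitude, high-dispersion peaked/trough genes can therefore
carry a real sorted-vs-timecourse contrast that no single physiological age
explains, and a small fraction of planted "pure aging" genes (~0.2% at
defaults) is classified marker-specific for this reason. This is a genuine
property of pooled designs, not an estimation artifact.

## Numerical choices and degenerate inputs

* Detection filter: a gene is kept when ≥ ceil(0.75·n_samples) samples have
  ≥ 5 counts; ceiling chosen for odd sample counts (stricter of the two
  roundings).
* All randomness flows from one seed through named substreams
  (SeedSequence keyed on a CRC of the stage name), so any stage reproduces
  in isolation.
* DTW band infeasibility (length mismatch beyond the band) is an error, as
  are: empty sorting strata, pool sizes exceeding the stratum, coincident
  calibration anchors, fewer timepoints than spline df + 1, cluster counts
  exceeding clusterable genes, gene sets disjoint from the ranked universe
  (skipped with a warning at collection level), survival groups without
  death events, and medians never reaching S = 0.5.
* Linkage ties and projection ties are resolved deterministically (scipy's
  deterministic agglomeration; smaller arc position wins).
* The IRLS ridge (1e-6) biases coefficients negligibly relative to their
  SEs but guarantees solvability when marker or batch columns are nearly
  collinear after pruning.

## Known limitations

* The dispersion estimator trades per-gene efficiency for simplicity;
  borderline genes near significance thresholds can flip relative to
  empirical-Bayes estimators.
* The Wald test's normal reference is mildly anticonservative at these
  sample sizes (measured type-I ≈ 0.06 at nominal 0.05), inherited from the
  GLM framework it mirrors.
* Physiological age is a single scalar; samples off the trajectory are
  summarized by (arc position, residual) only — no branching or
  multi-dimensional aging states.
* The proportional calibration assumes arc length accrues roughly uniformly
  per day between the anchor days; the monotone mode relaxes this but needs
  well-populated intermediate timepoints.
* GSEA p-values use gene-sampling nulls; they answer "is this set more
  concentrated than a random set of the same size", not a phenotype-label
  permutation question.
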