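# Methods

## The statistical model

The pipeline asks whether a voxel-wise measure of resting-state temporal
coherence (ReHo) carries part of the association between a weighted
polygenic score X and a trait score Y.  At every analysed voxel, with
gender as covariate in all equations and all variables z-scored,

    step 1:  Y ~ X + gender         ->  c   (total effect; tested once)
    step 2:  M ~ X + gender         ->  a   (gene -> ReHo)
    step 3:  Y ~ M + X + gender     ->  b, c'  (ReHo -> trait | gene)

A voxel shows a mediation-family effect when all three steps are
significant at alpha = 0.05; the joint voxel-level null rate is therefore
0.05^3 = 0.000125, and the effect size is the product a*b.  For OLS on a
shared covariate set the decomposition c = c' + a*b is an algebraic
identity (asserted at 1e-10 in the tests).  When a*b and c' have opposite
signs the mediator is a **suppressor**: adding it to the model strengthens
rather than explains the X->Y association.  Suppression is quantified as
100*a*b/c percent of the total effect; the classifier additionally
requires both the a and b paths to be individually significant.

### ReHo

Kendall's coefficient of concordance over the K <= 27 in-mask voxels of
each 3x3x3 neighbourhood: each series is ranked over the T frames (average
ranks for ties), and with column rank sums R_t,

    W = 12 * sum_t (R_t - mean R)^2 / (K^2 (T^3 - T)).

Conventions follow REST/DPARSF: neighbourhoods are clipped to the mask
with K adjusted per voxel rather than requiring complete cubes; no
tie-correction term is applied by default (the corrected denominator is a
config switch); "demean" subtracts the in-mask mean by default (divide is
available); 4 mm FWHM Gaussian smoothing follows demeaning.  The
implementation is a separable box convolution over per-voxel time-series
ranks and is verified exhaustively against the scalar definition.

### Cluster-extent correction

Two independent calibrations of the minimum significant cluster size:

* **Monte-Carlo** (the AlphaSim/3dClustSim idea): simulate white Gaussian
  fields on the grid, smooth to the target FWHM (estimated from residual
  maps by the classic first-difference estimator
  FWHM = dx * sqrt(-2 ln 2 / ln(1 - s2_diff / 2 s2))), standardize each
  field by its empirical in-mask mean/SD, threshold |z| two-sided at the
  joint voxel rate, record the maximal suprathreshold cluster, and return
  the smallest extent whose exceedance probability is <= 0.05.
* **Permutation**: draw 10 loci at random from the 98-locus pool, rebuild
  a gene score, rerun the full three-step scan, record the maximal
  significant cluster; the threshold is the ceil(0.95*(n_perm+1))-th order
  statistic of the null maxima.  Weights for each random draw are
  re-estimated by multiple regression of Y on the drawn codes, mirroring
  how the real score's weights were obtained.  This matters: re-estimated
  weights overfit Y (10 regressors against ~300 subjects), the random
  scores correlate with the outcome, step 1 passes far more often than 5%
  of the time, and the permutation threshold comes out substantially
  larger than the Monte-Carlo one — the ordering observed in practice.
  Unit or reused weights are available behind a flag.

The stricter of the two thresholds is applied downstream.  Clusters use
26-connectivity by default (6/18 configurable).

## Synthetic cohorts

The generator produces the structure the analysis assumes, not realistic
brains:

* Genotypes: two independent Bernoulli(MAF) alleles per locus
  (Hardy-Weinberg), 10 scored loci plus a 98-locus permutation pool.
* Structural model on standardized latents:
  M = a*X + gamma*g + e_M, Y* = c'*X + b*M + gamma*g + e_Y, with defaults
  a = -0.176, b = +0.139, c' = 0.399 (the suppression pattern), gender
  male fraction 0.32 with a -0.205 SD effect, and residual SDs solved so
  the latents have unit population variance — the generating coefficients
  are then recovered directly as standardized regression weights.  The
  trait is rescaled to mean 122.4, SD 15.77 on the 27-189 questionnaire
  scale; clipping affects <1% of subjects at the default SDs (asserted).
* BOLD: out-of-cluster voxels are white noise; in-cluster voxels mix a
  shared band-limited (0.01-0.08 Hz) signal with voxel-private noise at
  weight lambda = logistic(k*M).  The logistic keeps lambda in (0,1) and
  monotone in M.  The slope k defaults to 1.0, a design calibration (no
  published equivalent exists): at k = 1 the cluster-mean W tracks the
  latent mediator at r ~ 0.95, so the imaging arm transmits the planted
  paths with mild attenuation.  The default run length is 240 frames at
  TR = 2 s with 10 frames discarded.
* Motion: random-walk six-parameter traces; expected framewise
  displacement is linear in the step SD.

What the generator does **not** emulate: spatial autocorrelation of
background noise, anatomical geometry, scanner artifacts, slice timing or
misregistration.  Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed structure, not robustness to real
acquisition physics.

## Numerical choices

* Band-pass is an ideal rectangular DFT filter with inclusive edges
  (REST/DPARSF behaviour), not Butterworth; it is exactly idempotent.
  Nuisance regression runs after filtering, per the published stage order.
* The motion inclusion check uses per-axis |translation| <= 2 mm and
  |rotation| <= 2 degrees; the scalar motion index reports both the mean
  and the max of the per-frame Euclidean norms (the index's aggregation is
  not uniquely fixed in the literature).
* Standardization uses ddof = 1 throughout; standardized coefficients are
  invariant to this choice.
* The mediation scan is closed-form vectorised linear algebra
  (Frisch-Waugh partialling for step 3) and is cross-checked exhaustively
  against independent statsmodels fits.
* Voxels with constant time series (or K < 2 in-mask neighbours) are
  marked non-significant / zero and logged, never errors.
* Bootstrap: nonparametric case resampling with batched refits;
  percentile intervals by default, bias-corrected optional; degenerate
  resamples (a zero-variance column, possible with a binary covariate)
  are redrawn and counted, with a warning past 1% of draws.
* Leave-one-out prediction uses the exact hat-matrix identity
  yhat_(-i) = y_i - e_i/(1 - h_ii) for the unstandardized outcome
  equation; verified against explicit refit loops.
* Skewness/kurtosis default to the small-sample-corrected G1/G2
  estimators; the normality summary is the classical one-sample KS
  statistic against a normal with sample-estimated parameters reported as
  Z = sqrt(n)*D (the legacy convention; it is conservative relative to
  Lilliefors and documented as such).

## Monte-Carlo mask geometry

The true grey-matter mask of a cohort is not redistributable, so the
Monte-Carlo calibration uses a compact quasi-spherical mask of exactly the
requested voxel count.  A compact ball truncates fewer clusters at its
boundary than a convoluted cortical sheet of equal volume, so the computed
extent threshold runs about one voxel high: at the reference settings
(50,296 voxels, 3 mm grid, FWHM ~8.2 x 8.2 x 7.9 mm, voxel p = 0.000125)
the converged threshold here is 9 voxels where sheet-geometry analyses
report 8.  Each simulated field is standardized by its empirical in-mask
mean and SD (classic AlphaSim practice).

## Problem sizes used by the test and acceptance runs

Chosen as package defaults for desk-scale verification: the planted-cluster
recovery check uses 20 replicates of 298 subjects on a 20^3 grid with 60
frames and a Monte-Carlo threshold calibrated once at 200 fields; null
calibration of the joint test uses 200 replicates x 1000 voxels; bootstrap
coverage uses 500 replicates x 1000 resamples; the reference threshold
computation uses 5000 fields (1000 in the in-suite variant).

## Known limitations

* The percentile bootstrap CI of the product a*b is strongly conservative
  when both paths are truly zero (its complete-null coverage approaches
  100%, not 95%); this is a property of product-of-coefficients
  inference, not of the implementation, and path-level CIs do not share
  it.  Coverage statements for a*b should be read accordingly.
* The compact-ball Monte-Carlo mask biases the extent threshold upward by
  about one voxel (above).
* The permutation threshold's weight re-estimation policy is a modelling
  choice; published analyses rarely state theirs, and the alternatives
  (unit, reused weights) give systematically smaller thresholds.
* Spatial preprocessing (slice timing, realignment, normalization,
  segmentation) is out of scope; the pipeline consumes already-normalized
  volumes and masks.
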