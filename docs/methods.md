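# Methods

## Model structure and assumptions

PACE assumes a cohort of $N$ dose maps $D_i(x_j)$ on a common grid of $M$
ROI voxels (spatial normalization done upstream), one binary outcome $O_i$
per patient, and optional scalar covariates entering every voxel model
identically. The model has three stages:

1. **Voxelwise logistic backbone.** Per voxel, outcome ~ local dose
   (+ covariates) by maximum-likelihood logistic regression. The voxel models
   are fitted independently; no spatial smoothing or multiple-testing
   machinery is applied. On a test map each voxel yields a probability
   $P(x_j)$, the width of its 95% interval $\mathrm{CI}(x_j)$, and a
   reliability $W(x_j) = 1/\mathrm{CI}(x_j)$, zeroed where the fitted dose
   odds ratio is $< 1$.
2. **Aggregation.** $\mathrm{gEUp}$ is the $W$-weighted power mean of $P$
   with exponent $1/\nu$ (computed in log space; invariant under positive
   rescaling of $W$; bounded by the range of $P$ over voxels with $W > 0$).
3. **Probit sigmoid.** $\Phi\big((\mathrm{gEUp} - Tp_{50})/(\mu\,Tp_{50})\big)$,
   the LKB functional form with dose replaced by probability.

A patient whose $W$ map is identically zero has no defined gEUp; the model
returns the training prevalence and warns. Probabilities are clipped at
$10^{-12}$ in the likelihood.

### Interval and reliability conventions

The reliability weight is defined from the **width** (upper minus lower) of
the 95% interval of $P(x_j)$ on the probability scale; intervals are Wald on
the linear predictor mapped through the inverse logit, which keeps them
inside $[0,1]$. Both choices are conventions (a half-width or an odds-scale
reading would rescale $W$ monotonically); the width on the probability scale
is the only scalar reading that needs no extra definition. A numerically zero
width (saturated voxel) caps $W$ at $10^6$ so a single voxel cannot dominate
the aggregation unboundedly.

### Separation and degenerate voxels

At cohort sizes of order $10^2$ with low event rates, voxelwise fits
frequently (quasi-)separate. Separation suspects (non-convergent fits or
runaway standardized slopes) are refitted with a fixed ridge penalty
($\lambda = 0.5$ on standardized non-intercept coefficients) and flagged per
voxel; this plays the role of a penalized-likelihood fallback and keeps
slopes and intervals finite. Voxels with zero dose variance keep a zero slope
with an unbounded interval, hence $W = 0$. The batched Newton/IRLS solver is
validated against `statsmodels.Logit` in the unit tests.

## Maximum likelihood and profile intervals

Both PACE $(\nu, \mu, Tp_{50})$ and LKB $(n, m, TD_{50})$ have the same
structure: a volume exponent produces a scalar summary per patient, and a
two-parameter probit sigmoid maps it to a probability. The MLE is computed by
**nested optimization**: a deterministic geometric grid (12 points) plus a
bounded scalar refinement over the volume exponent, with the two sigmoid
parameters profiled out exactly by an inner bounded fit (L-BFGS-B from
several deterministic starts, including an unconstrained probit warm start)
at every outer step. Because the inner problem is solved to optimality, the
nested optimum is the joint MLE; the outer grid spans the bounds, which
guards against the multi-modality a random multi-start would otherwise
address, and the whole fit is deterministic — no seed enters the estimation.

Bounds: $\nu \in [0.01, 1]$, $\mu \in [0.01, 2]$, $Tp_{50} \in [0.01,
0.99]$; $n \in [0.01, 1]$, $m \in [0.01, 1]$, $TD_{50}$ within
$[\min, 10 \times \max]$ of the gEUD values observed over the exponent grid.

95% intervals are Wilks profile-likelihood sets
$\{\theta: 2[\ln L_{\max} - \ln L_{\mathrm{prof}}(\theta)] \le 3.841\}$, with
the other two parameters re-optimized at every profiled value (warm-started;
outward walk to bracket the crossing, then Brent root finding). An endpoint
that reaches the parameter bound while still inside the confidence region is
reported at the bound and flagged. No bootstrap or Bayesian alternatives are
provided.

Training predictions are in-sample (backbone and aggregation parameters fit
on the same cohort); honest assessment is delegated to leave-one-out
cross-validation, which refits the **full** model per fold. A `fast` LOO mode
keeps one backbone fit on all patients and refits only the aggregation
parameters; it is cheaper and explicitly optimistic (the held-out outcome
leaks into the backbone) and is never used in the validation results.

## Synthetic study conditions

The simulator emulates 2D dose distributions on a 32×32 square ROI (the
default desk-scale grid; resolution is configurable):

* dose maps: $K \sim U\{1..4\}$ Gaussian peaks, widths $\sigma \sim
  U[0.10, 0.30] \cdot L$ ($L$ = ROI side), heights $U[0.5, 1.5]$ AU, centers
  uniform over the ROI;
* identical-DVH family: per-map rank transform to plotting positions
  $\mathrm{rank}/M$ scaled to $(0, d_{max}]$, which makes the sorted value
  multisets of all maps exactly equal while preserving each map's spatial
  ordering — any DVH summary is constant across such a family;
* radio-sensitivity ground truth: homogeneous, or the sum of two shifted
  Gaussians (S2G);
* outcomes: $O_i = [\mathrm{g^2EUD}_i > D_{th}]$ with
  $\mathrm{g^2EUD} = [\sum_j D^{1/n} RS / \sum_j RS]^n$; the threshold is the
  order statistic matching a target event rate (default 25%; the
  identical-DVH/LKB chance-level experiment uses a balanced rate, where
  "chance level" is 0.5). Train and validation maps are drawn from one
  pooled cohort so a single threshold labels both.

### S2G geometry and identifiability

The S2G defaults are two bumps of width $0.08\,L$ centered at fractions
$(0.15, 0.15)$ and $(0.85, 0.85)$ of the ROI. The separation (~$1.0\,L$) is
deliberately larger than the dose field's correlation length (peaks up to
$0.3\,L$). This is an identifiability requirement, not a tuning choice: when
two RS bumps sit within one dose-peak width of each other, a single peak
covers both, the mid-point dose becomes the best single-voxel predictor of
the outcome, and a model-free diagnostic (per-voxel dose-vs-outcome AUC at
large $N$) is unimodal between the bumps — no voxelwise analysis can then
recover the two-bump structure. The same point appears in the model's own
terms: the learning cohort must show spatially heterogeneous, weakly
correlated dose patterns for the atlas to localize radio-sensitivity.

### What the simulator does not emulate

Outcomes are deterministic functions of the dose map (no label noise beyond
the thresholding), registration error, anatomy, fractionation (EQD2) and
dose-map noise are absent, and the dose fields are smooth isotropic
Gaussians. Passing the in-silico suite therefore demonstrates the estimation
and inference machinery under controlled conditions; it does not certify
clinical performance, where event rates are lower, outcomes noisier and dose
fields structured by treatment technique.

## Radio-sensitivity readout

Probes are single Gaussian hot spots ($\sigma$ = 1.5 voxels, amplitude
defaulting to the maximum training dose, stride 1) swept across the ROI; the
RS estimate at a position is the PACE probability of its probe map (strided
gaps filled by nearest neighbor). The readout is reported in arbitrary units:
only its ordering matters for the level-set comparison. DI$_V$ uses
**rank-based** superlevel sets (the top $\mathrm{round}(v M)$ voxels, ties by
voxel index) so the two sets compared always have equal size, on a $v$ grid
of 0.05–0.95 in steps of 0.05, summarized by the normalized trapezoidal AUC.
Because the model is nonlinear in dose, the readout depends on the probe
amplitude: very small amplitudes barely move the aggregation, while very
large ones read extrapolated slopes where saturated voxels carry near-zero
interval widths; the amplitude is a reported parameter of every readout and
the CLI logs it.

## Evaluation conventions

* ROC AUC by the Mann–Whitney construction (`sklearn`), standard error by
  the Hanley–McNeil formula, 95% CI by a logit-scale Wald interval (keeps the
  CI inside $[0,1]$).
* Paired AUC comparison: Z-test with the correlated-ROC correction, the
  between-model correlation estimated as the average within-class Spearman
  correlation of the two predictors.
* Calibration: 10 equal-count bins by default, observed event fraction
  regressed on mean predicted probability by OLS; slope, intercept (ideal 1
  and 0), their SEs and $R^2$ are reported. Constant predictions make the
  slope undefined and raise an error.
* Classification at threshold 0.5 (configurable): accuracy, balanced
  accuracy, F1.
* Learning curves: default sizes {25, 50, 100, 200, 400, 800}, 10
  replicates, 500 validation maps, threshold 0.5, fully seeded;
  degenerate (single-class) simulated cohorts are redrawn with a fresh child
  seed and counted.

## Problem sizes in the shipped results

The acceptance script uses 800 training / 500 validation maps for the
identical-DVH experiments, 400/500 for the homogeneous-RS experiment (10
seeds each), and four 1,000-map cohorts for the RS readout — sizes at which
the qualitative asymptotic behaviors (chance-level LKB on identical DVHs,
near-perfect LKB in its generative regime, PACE above the 0.8 accuracy
level, DI$_V$ AUC near 0.9) are stably expressed while the whole script runs
in about a minute on one CPU.

## Known limitations

* Univariate voxel models inherit the dose field's spatial correlation: the
  backbone's informativeness map is a correlation-smoothed image of the true
  radio-sensitivity, which bounds the spatial resolution of the RS readout
  (see the S2G geometry note above).
* Wald intervals per voxel are first-order; at small $N$ with rare events
  the ridge fallback deliberately biases separated voxels toward zero slope.
* The probit reading of the response sigmoid matches the LKB benchmark by
  construction; other sigmoid families would change $\mu$'s scale.
* gEUD/g2EUD are computed over ROI voxels directly rather than from a binned
  DVH; a DVH export utility exists for convention's sake, and the two agree
  up to binning.
* LOO with full backbone refits is $O(N)$ backbone fits; at clinical scale
  this is the honest but slow path (the fast mode exists and is labelled
  optimistic).
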