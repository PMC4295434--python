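# Methods

## The whole-report race model

A trial displays six distinct letters (three per hemifield) for `exposure`
ms.  Items race independently with exponential finishing times; the total
processing rate is *C* items/s, split equally (*C*/6 per item) in the
symmetric case, or by hemifield weight *w* as (*C*/3)·*w* per left item and
(*C*/3)·(1−*w*) per right item when simulating biased observers.  Nothing
is encoded during the first *t₀* ms, so the effective race duration is
*t*ₑ = max(0, exposure − *t₀*)/1000 s and each item finishes with
probability *p* = 1 − exp(−(*C*/6)·*t*ₑ).  VSTM holds at most *k*\* items:
for fractional capacity *K*, *k*\* is drawn per trial as ⌊*K*⌋+1 with
probability *K*−⌊*K*⌋ and ⌊*K*⌋ otherwise.  The score (number of correct
reports) is therefore min(*B*, *k*\*) with *B* ~ Binomial(6, *p*), giving a
closed-form pmf: the binomial pmf below the cap, the binomial upper tail at
the cap, zero above, mixed over the two adjacent integer capacities.

**Estimation.** Per participant, trial scores are collapsed into
per-exposure histograms and (*C*, *K*, *t₀*) maximize the multinomial
log-likelihood (probabilities floored at 1e−12; the parameter-free
combinatorial constant is dropped).  The optimizer is bounded Nelder-Mead
from seven deterministic grid starts; ties are broken by the first start to
reach the best log-likelihood, so refits are bit-identical.  Two of the
starts place *K* above 5 deliberately: with *K* ≤ 5 a full report of six has
probability zero, and data containing such trials leave the likelihood flat
in *K* at the floor, so a grid confined below 5 would never move.  Default
box bounds are *C* ∈ [1, 200] items/s, *K* ∈ [0.5, 6], *t₀* ∈ [0, shortest
exposure].  The study pipeline widens the *t₀* box to [0, longest exposure]:
thresholds above the shortest exposure are still identified by the longer
exposures, and clamping them at the shortest exposure piles estimates on the
bound, which in turn degenerates the subject-level MAD screen downstream.
The likelihood is always evaluated with equal hemifield weights; spatial
bias is handled instead by the empirical laterality index (correct left
reports / all correct reports) and the inclusive exclusion rule
0.3 ≤ index ≤ 0.7.

Fitting is deliberately restricted to this three-parameter model: no
partial report, no attentional-weight or pertinence parameters, no
exponential-*K* or variable-*t₀* variants.

## Outlier screening

All screening uses the median absolute deviation scaled by 1.4826 (the
Gaussian-consistency constant) with a ±2.5 cutoff, boundary inclusive.

* **Trial level** (response times only): times are √-transformed before
  filtering — the simplest variance stabilizer for right-skewed
  durations — and the subject score is the mean of the *raw* times that
  survive.  Correct and incorrect trials are pooled, because in
  difficulty-limited tasks an error trial still carries a valid RT.
* **Subject level**: each measure is screened across subjects on its raw
  scale (no transform).  A flag on any measure of a test masks every
  measure of that test for that subject, so a random responder's
  plausible-looking RT cannot survive its implausible accuracy.  TVA
  measures are additionally masked when the laterality check fails.
* **Degenerate MAD** (over half the values identical): only exact matches
  to the median are kept — the limit of the rule as MAD → 0.

A ±2.5 scaled-MAD cut on Gaussian data flags ≈1.24% per tail-pair, which is
why the clean-cohort false-flag rate sits safely under 2% per measure.

## The SEM engine

Models are graphs over observed and latent variables in RAM form: directed
edges in an asymmetric matrix A, variances/covariances in a symmetric S
(endogenous diagonal entries are residual variances; endogenous
off-diagonals are residual covariances), and the implied covariance is
Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ with F selecting observed variables.  Validation
is structural: acyclicity, unique parameters, every latent scaled by a
fixed outgoing loading or fixed variance, and df ≥ 0.

* **Complete-data ML** minimizes F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p;
  χ² = (n−1)·F_min with df = p(p+1)/2 − q.
* **FIML** maximizes the casewise Gaussian log-likelihood over missingness
  patterns (pattern counts, means and scatters are precomputed once, so an
  objective evaluation costs O(#patterns·p³) regardless of n).  The mean
  structure is saturated — one free mean per observed variable — which is
  profile-equivalent to routed intercepts and leaves df equal to the
  complete-data count.  The FIML χ² is the likelihood ratio against the
  saturated model, whose MLE comes from a multivariate-normal EM
  implemented here (tolerance 1e−10 on the log-likelihood).  Note the
  conventions differ by design: complete-data χ² carries the classical
  (n−1) multiplier, FIML effectively an n multiplier; the two agree to
  O(1/n) and each is calibrated, which is what the tests check.
* **Optimizer**: L-BFGS-B with 2-point numerical gradients; variances
  bounded below at 1e−8; a non-positive-definite Σ during the search is
  ridged back to PD with a penalty proportional to the ridge ("ridge
  retreat").  Start values are deterministic and data-informed: fixed edges
  as given, free paths at the crude anchor-to-anchor regression slope
  (latents proxied by the indicator behind their fixed loading), variances
  at half the sample/anchor variance, covariances at 0.  Plain unit starts
  were tried first and routinely stranded the CFA fits in slow flat
  regions because half the loadings have negative sign.
* **Inference**: SEs from the inverse numerical Hessian of (n−1)/2·F (ML)
  or of −loglik (FIML); critical ratio = estimate/SE referred to N(0,1),
  two-sided.  Standardization uses model-implied SDs
  (β_std = β·sd(source)/sd(target)); residual covariances are reported as
  residual correlations; SMC(v) = 1 − residual var/implied var.
* **Fit indices**: χ² p; RMSEA = √(max(0, χ²−df)/(df·(n−1))) with a 90% CI
  by inverting the noncentral-χ² CDF in its noncentrality parameter
  (Brent's method; bounds are the λ solving CDF(χ²; df, λ) = 0.95 and
  0.05).  No relative indices (CFI/TLI), modification indices, multi-group
  models or non-Gaussian estimators.

The study pipeline divides each column by its SD before SEM fitting purely
for optimizer conditioning (raw scales span six orders of magnitude from
accuracies to ms); χ², df, RMSEA and the standardized solution are
invariant to this, which is itself a tested property.

## The two study models

**Model 1 (path analysis, df = 30)**: the three whole-report parameters are
exogenous (free covariances C↔K and K↔t₀); a speed branch
TVA_C→DWM_RT→FM_Time→Read_Time; a capacity branch TVA_K→{Corsi_Span,
DWM_Acc}→FM_Acc; a mixed branch {DWM_RT, Corsi_Span, TVA_t0}→Memo_Time; and
free residual covariances among the three top-level measures.  The branch
memberships are fixed by design; the edge-level topology within them is a
documented assumption and replaceable through the model-spec DSL.

**Model 2 (CFA, df = 17)**: latent Speed → {TVA_C (=1), Read_Time, DWM_RT,
Memo_Time} and Capacity → {TVA_K (=1), Corsi_Span, FM_Acc}; Age → Speed and
Age → Capacity; free residual covariance between the latent residuals and
between the TVA_C/TVA_K residuals.  Estimated by FIML by default (the
screened table has missing cells by construction); complete-case ML on the
pairwise covariance is available as a config option.

## The synthetic cohort

The generator emulates the study conditions end to end.  Ages are truncated
normal (mean 67.8, SD 4.0, range 60–75); z-scores use the truncated
distribution's true moments, so the configured slope is the standardized
slope on the realized ages (standardizing by the nominal SD would shrink an
intended −0.3 to about −0.25).  Latents follow
`slope·z(age) + unit-variance residual` (residuals correlated across
factors by `latent_resid_corr`, default 0), with default slopes −0.3
(Speed) and 0 (Capacity).  Each measure is an affine map of its
standardized latent onto a natural-scale target mean/SD: accuracies, spans
and the capacity parameter load positively on Capacity; completion/response
times load negatively on Speed (faster latent ⇒ smaller times); *t₀* is
latent-free noise.  Default targets are the reference battery's
descriptives (e.g. TVA C 43.21 ± 16.54 items/s, K 3.58 ± 0.67, t₀
21.9 ± 14.5 ms, DWM RT 1468 ± 354 ms).  Default loading magnitudes
(0.75–0.85 for the factor anchors, smaller for peripheral measures) were
chosen once so that the implied age-by-indicator correlations
(slope × loading ≈ 0.21–0.24) fall in the 0.2–0.27 range such batteries
report for their timed measures; weaker loadings are inconsistent with
those printed correlations given a latent slope capped at −0.3.

Trial-level data: 55 usable DWM trials (Bernoulli accuracy, lognormal RT
with within-subject CV 0.25), 27 four-mountains trials (CV 0.30), and
whole-report trials from the race simulator (default design 20/50/80/140/200
ms × 40 trials — the reference task's timing is not published, so this is a
configurable assumption).  Subject-level SDs for trial-based measures are
deflated so subject variance plus trial-sampling variance hits the target
SD.  Planted defects: each RT trial is independently contaminated at rate
0.03 by a shift of ≥ +10 reference MADs; 3% of participants respond at the
DWM guessing level 0.25; 5% of participants receive an extreme hemifield
weight (0.80–0.95, either side) — matching the ~5% laterality-exclusion
rate such cohorts show; 5% of (participant, test) pairs are masked MCAR,
always whole tests jointly.  Control measures that real batteries collect
but drop (4-level reading accuracy; memo misses tied to completion time)
are generated and excluded before analysis.

What the generator does **not** emulate: practice/learning effects,
demographic covariates, non-Gaussian latent distributions, missingness
that depends on ability (MNAR), or stimulus-level confusability.  Passing
tests therefore demonstrate correctness of the machinery and calibration
under the assumed data-generating process, not robustness to violations of
it.

## Problem sizes and numerical choices

Everything is seeded and bit-reproducible: one integer seed drives the
cohort; simulation-based tests fix their own seeds.  The test suite uses
problem sizes chosen to make its statistical assertions sharp but cheap:
parameter recovery uses 50 replicates of 5×200 trials; χ² calibration 500
replicates of a compact one-factor model at n = 112; FIML unbiasedness 30
replicates at n = 5000; screening efficacy 500 replicates per property; the
age-selectivity check 200 replicates of Model 2 fits at n = 112 (these use
the direct subject-level generator — the property under test is the factor
model's inference, and the latent structure is identical to the trial-level
path).  Monte-Carlo agreement between the race simulator and the closed
form is tested by χ² goodness of fit at α = 0.01 with 1e5 trials.

Known limitations: *t₀* estimates are the least stable (they ride on the
shortest exposures; in recovery simulations the median *t₀* error is a few
ms where C and K recover to a few percent); Heywood cases (residual variances at the 1e−8
floor) can occur in small-sample CFA fits and are surfaced via the
warnings list rather than prevented; the FIML Hessian is computed
numerically, so SEs for parameters at a bound may be missing (flagged).
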