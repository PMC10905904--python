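# Methods

This note documents the models, estimators, numerical choices and
limitations of the package. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Task structure and data layout

The same/different task has 320 trials per subject: per background
condition (control / depth-cue), 64 physically equal pairs, 64 pairs with a
20% diameter difference, and 16 + 16 filler pairs at ±5%. Fillers are
near-threshold catch trials; they are flagged in every file and excluded
from every analysis, leaving 256 analyzed trials. The schedule generator
permutes a fixed per-block cell multiset inside eight 40-trial blocks, so
every consecutive block of 40 trials contains every condition × size-ratio
cell by construction; with a fixed seed it is bit-reproducible.

All type-2 fitting consumes the `ConfidenceCountTable`: per stimulus class
("same" = S1, "different" = S2) a length-8 vector of (response, confidence)
cell counts ordered from confidence-4 "same" down to confidence-1 "same",
then confidence-1 "different" up to confidence-4 "different".

Trait ratings: 26 desirable + 26 undesirable + 8 filler words on a [−1, 1]
VAS with step 0.05. Scoring drops fillers, negates undesirable items
(reverse-coding, an involution) and averages the 52 values into the SI
score. The 52 item labels and their valences ship as packaged metadata; the
8 filler labels are placeholders because the original filler words are not
published.

## Type-1 SDT

Equal-variance Gaussian model; hits are "different" responses to S2, false
alarms "different" responses to S1. Proportions of exactly 0 or 1 are
replaced by 1/(2N) and 1 − 1/(2N) (N = trials of that class) before the
z-transform — the standard psychophysics correction, applied only to
extreme cells so interior proportions are untouched. Confidence is
collapsed here; d′ and C are type-1 quantities. Condition effects are
depth − control differences; negative d′ differences mean a stronger
illusion.

## Meta-d′ maximum likelihood

The meta-level observer has stimulus means ±meta-d′/2, unit variance, a
bias-matched type-1 criterion meta-C = C·meta-d′/d′, and three strictly
ordered type-2 criteria on each side of meta-C. The likelihood is the
multinomial of confidence counts *conditional on* each (stimulus, response)
cell; type-1 marginals stay fixed at their observed values, so meta-d′
reflects only the information content of the confidence ratings.

Numerics:

- criteria are parameterized as cumulative exponentiated increments away
  from meta-C, enforcing ordering for any real parameter vector;
- every cell count is padded by 1/(2K) = 0.125 (K = 4 rating levels) before
  fitting to avoid zero-cell degeneracies; padding is a fitting device only
  and never touches stored data;
- L-BFGS-B from five deterministic starts
  (meta-d′ ∈ {0.2, 0.5d′, d′, 1.5d′, 2d′}); ties broken by lowest negative
  log-likelihood, then lowest meta-d′ — the likelihood can be nearly flat
  along a meta-d′/criteria ridge for sparse tables;
- d′ ≤ 0 after correction leaves the M-ratio undefined: the fit returns
  NaN efficiency fields plus an explicit warning, never a silent number.

A derivative-free reference fit (`brute_force_fit`) scans one parameter at
a time over dense grids at resolution 0.01 — meta-d′ with criteria shifted
rigidly with meta-C, each criterion between its ordered neighbours, plus a
common-shift and a common-scale scan over the criterion set, cycling to
convergence. On well-populated tables it agrees with the gradient fit to
one scan step; it exists purely to verify the MLE.

## Hierarchical Bayesian log M-ratio

Generative model, subject *s*: log M-ratio_s ~ Normal(µ [+ β·x_s], σ);
meta-d′_s = exp(log M-ratio_s)·d′_s; confidence cells follow the same
conditional meta-observer as the MLE. d′_s and C_s enter as fixed constants
(a deliberate inference cut: type-1 values remain exactly the conventional
estimates). Priors: µ ~ Normal(0, 1), σ ~ Half-Normal(1), β ~ Normal(0, 1),
criteria weakly informative Normal(0, 10) truncated to ordering through the
increment parameterization (the associated Jacobian is included). The
covariate x is standardized internally, so β is per-SD of the covariate and
adding a constant to x changes nothing.

The sampler is a vectorized Metropolis-within-Gibbs scheme written for this
model: per-subject blocks (log M-ratio + 6 criterion parameters) move by
random-walk Metropolis simultaneously across subjects (the likelihood
factorizes given µ, σ); µ and β are drawn exactly from their conjugate
Gaussian conditional; σ moves by random-walk Metropolis on the log scale
with the Half-Normal prior and log-Jacobian. Step sizes adapt every 50
iterations during burn-in only (targets ≈ 0.30 for blocks, 0.44 for σ), so
the retained chain is Markovian. Subject states initialize from a coarse
deterministic likelihood scan plus per-chain jitter. Convergence is
monitored by split R-hat (arviz) on µ, σ, β; any value above 1.1 sets a
non-convergence flag and warning on the returned posterior.

Summaries: MAP is the mode of a Gaussian KDE (Silverman bandwidth) over the
pooled post-burn-in samples, evaluated on a 2048-point grid; the 95% HDI is
the shortest contiguous interval by a sorted-sample sweep. M-ratio
summaries exponentiate the log-scale samples *before* summarizing, so the
M-ratio MAP is intentionally not exp(log-M-ratio MAP). At 10^5 draws the
KDE mode has Monte-Carlo standard error near 0.05 — the HDI endpoints
(order statistics) are considerably more stable, and tests tolerance them
accordingly.

Default chain settings are 3 chains × 10,000 samples with 1,000 burn-in;
tests and the acceptance script run reduced desk-scale chains (3 × 2,000
with 500 burn-in, and 3 × 1,500 for the 20-replication calibration study)
— problem sizes chosen so the whole pipeline runs comfortably on one CPU
while leaving the estimator regime unchanged. At 256 trials per subject the
subject-level likelihood of log M-ratio is left-skewed, so the group MAP
can sit a few hundredths below the realized cohort mean; with
near-noiseless data (expected counts at 5,000 trials per class) the sampler
recovers subject and group parameters essentially exactly, which is how
correctness and small-sample behaviour are distinguished in the tests.

## Relaxed elastic net

Step 1 minimizes `(1/2n)‖y − Xw‖² + λ·[α‖w‖₁ + (1−α)/2·‖w‖₂²]` — stated
explicitly because λ's meaning differs across software. The LOOCV grid is
α ∈ {0.1, …, 1.0} (10 values) × λ = 10^e, e from −3 to 3 in steps of 2/33
(100 values, endpoints inclusive). Per (α, fold) the full λ path is fit in
one warm-started coordinate-descent call; the intercept is handled by
per-fold centering. Grid ties break toward larger λ (more regularization)
then larger α (more sparsity) — deterministic and conservative. Step 2
refits the selected items by ridge at the same λ (implemented with the
exact α → 0 limit of the same objective); ridge coefficients on
standardized variables are the feature importances. If step 1 selects
nothing, an explicit intercept-only model with metrics is returned.

Standardization uses the population-SD convention and is applied once on
the full sample before cross-validation; this mirrors a whole-sample
standardization design and carries the usual mild leakage caveat.
Prediction metrics (Spearman ρ, R² = 1 − SSE/SST, RMSE) compare the
response with LOOCV predictions of the two-step pipeline. By default the
hyperparameters and selected set are frozen from the full-sample fit and
only ridge weights refit per fold; `cv_mode="nested"` instead repeats the
selection step inside every fold at the tuned hyperparameters. Both modes
are exposed because either reading of "relaxed elastic net with LOOCV" is
defensible; the frozen mode is the parsimonious default.

## PCA, parallel analysis, weighted total importance

PCA is the SVD of the standardized item matrix (correlation-matrix PCA);
loadings are unit-norm right singular vectors, variance proportions the
normalized squared singular values, and each loading column is flipped so
its largest-magnitude entry is positive — signs are non-identifiable, so
any comparison to external loading tables is up to column sign.

Parallel analysis retains leading components whose eigenvalues exceed the
95th percentile (configurable; a mean criterion is also available) of
eigenvalues from 1,000 i.i.d. standard-normal datasets of identical shape,
standardized identically; counting stops at the first failure. This
eigenvalue-vs-random-quantile rule is a reimplementation choice: the exact
extraction variant used with real data in this literature is
under-specified, and both common criteria are options. One subtlety found
while testing: the raw retained count is *not* monotone in signal strength,
because stronger factors shrink the standardized noise share and therefore
suppress spurious extra components; detection of the true components is
the monotone quantity.

Weighted total feature importance is the plain matrix product
`W_j = Σ_i importance_i · loading_ij` with zeros for unselected items,
aligned by item name (misalignment is an error, not a silent reorder). The
package ships the published importance and loading tables for the 52-item
battery as reference data so the printed-table product (PC1 of the d′
model: −0.230756 by hand summation) can be recomputed offline.

## Synthetic cohorts

`simulate_subject_trials` draws type-1 evidence from Normal(±d′/2, 1)
against criterion c; confidence comes from a second meta-level evidence
sample with sensitivity exp(log M-ratio)·d′, drawn by inverse-CDF from the
Normal truncated at the bias-matched meta-C on the side agreeing with the
type-1 response, then cut by the ordered type-2 criteria. This is exactly
the estimators' meta-observer, so generator↔estimator round trips are exact
in expectation (checked at 10^5 trials). Filler trials are emitted at
sensitivity 0 — near threshold — and never analysed.

Cohort defaults mirror the anatomy of the target population: n = 37,
control d′ ~ Normal(2.8, 0.7) truncated positive, depth d′ ~
Normal(0.2, 0.3), criteria ~ Normal(0, 0.15), group log M-ratio
Normal(−0.3, 0.2), type-2 increments ~ 0.5 with log-normal jitter, mean
superiority bias +0.08 on the VAS. Ratings arise from a 3-factor block
loading model (52 × 3; block strengths 1.0/0.7/0.45 on 18/17/17 items),
noise SD 0.5, scaled to the VAS, clipped to [−1, 1] and snapped to the
0.05 grid; undesirable items are emitted un-reversed so scoring exercises
reverse-coding; fillers are uniform grid noise. Equal-strength blocks were
rejected during design: they make leading eigenvalues nearly degenerate and
the components rotationally unidentifiable, whereas real trait-rating data
shows clearly ordered component variances.

`CohortSpec.linked` couples the factors to the outcomes — factor 1 to both
the depth-condition d′ and log M-ratio (negatively), factor 2 to d′ only,
factor 3 to log M-ratio only — with coefficients (−0.7 on d′, −0.35 on
log M-ratio) sized so the rating items explain roughly half the outcome
variance, the regime in which a 37-subject prediction model attains
ρ ≈ 0.7. In linked cohorts the depth-condition true d′ may fall below zero:
a strong contextual illusion can genuinely invert same/different
discrimination. The resulting depth-condition d′ spread (≈ 1.0 SD) matches
the population this pipeline is designed for.

What the generator does *not* emulate: size-ratio-dependent evidence (the
ratio is carried as metadata; evidence depends on d′ alone), sequential
effects, learning or fatigue, response-specific metacognition, and item
content (factor blocks are contiguous index ranges, not psychologically
grouped words). Passing tests therefore certify the estimators under the
assumed generative model, not the behavioural realism of that model.

## Known limitations

- The end-to-end shared-vs-specific architecture check runs at the design's
  n = 37; at that sample size elastic-net item selection is unstable, so
  the qualitative pattern is verified on a fixed cohort seed and should be
  read as a demonstration, not a power claim.
- Meta-d′ here is response-collapsed; response-specific meta-d′ and
  continuous confidence are out of scope.
- The hierarchical model treats d′ and C as known constants; their sampling
  error is not propagated.
- Cohen's d confidence intervals use the normal approximation
  d ± 1.96·√(1/n + d²/2n); Spearman p-values use the t-approximation and
  CIs a seeded percentile bootstrap — adequate at n ≈ 37, approximate in
  general.
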