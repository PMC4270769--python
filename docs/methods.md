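# Methods

## Data model

A *panel* is a complete block: every subject rates every product exactly once
on overall liking (0–100) and on a fixed battery of emotion items (0–4 each),
and — if choice flags are present — exactly one product per subject carries
`chosen = 1`. Anything violating these invariants (missing cells,
out-of-range scores, incomplete blocks, zero or duplicate choices) is a hard
error; nothing is imputed. Delimiter autodetection covers tab and comma with
`.` decimals only; other dialects must be normalised upstream. Alternatives
are ordered lexicographically (A…G) everywhere, which fixes the reference
alternative for the logit constants and the tie-break order for ranks.

## Within-subject demeaning

Participants use intensity scales with different personal offsets. For each
subject and each emotion item we subtract that subject's mean over the
product set, so each subject's rows sum to zero per item. This is a linear
projection; it eliminates any per-subject additive bias exactly (a property
the test suite asserts) and leaves only within-subject, between-product
variation. Emotion items are *not* variance-scaled before the PCA: all items
share the 0–4 support, and rescaling would reweight the battery's
item-to-item variance structure, which is part of the signal.

## PCA and sign orientation

The demeaned trials × items matrix is decomposed by singular value
decomposition; scores are exactly `X @ rotation` with no hidden re-centering
(training-row column means are exactly zero because demeaning is
per-subject). Explained-variance ratios are the squared singular values
normalised to sum to one. Because an SVD determines each component only up
to sign, components are oriented deterministically before use: PC1 is
flipped if its training scores correlate negatively with liking (so the
valence axis always points toward "pleasant"), and every other component is
flipped so its largest-|loading| item loads positively (first index on
ties). A held-out subject's rows are demeaned with *their own* product means
— available before any choice is made and independent of the training data —
and projected through the training rotation.

## Conditional logit

Utilities are `V_ij = α_j + x_ij'β` with one constant per non-reference
alternative and alternative-varying covariates only (no chooser-level
covariates — they cancel from the within-chooser softmax). The
log-likelihood is globally concave; we maximise it by Newton–Raphson from a
cold start at zero with analytic gradient and Hessian and log-sum-exp
utilities for overflow safety. Numerical choices:

- convergence when the score's infinity norm drops below `1e-8`
  (`max_iter = 100`, step-halving on the rare overshoot);
- a covariate with no within-chooser variation cannot affect any choice
  probability; its slope is structurally zero and is excluded from the
  optimization (reported as 0 with infinite variance) instead of producing a
  singular Hessian. Remaining rank deficiency is reported as a collinearity
  error;
- separation (the MLE does not exist) is declared either when the parameter
  norm passes `param_bound = 50` while the likelihood still improves, or
  when the maximised log-likelihood is numerically zero (every observed
  choice predicted with probability ~1);
- the covariance of the estimates is the inverse observed information at the
  optimum; Wald p-values use the normal approximation.

Standardizing predictors to unit SD (n−1 denominator, matching the common
statistical-environment convention) makes slopes comparable across
predictors. Note an exact equivariance: any affine covariate map shared
across alternatives (centering cancels in the within-chooser softmax,
scaling reparameterizes the slopes) leaves fitted probabilities unchanged.
Consequently the choice between fold-wise and pooled ("global") scaling in
cross-validation — which the package exposes as `scaling="fold" | "global"`,
default fold-wise — affects reported coefficient magnitudes but provably not
the predictions; a test asserts this invariance.

## Model ladder and selection

Seven models combine liking with the first one or two components of either
instrument (see `model_ladder.MODEL_PREDICTORS`). The published comparison
sequence (1v2, 1v3, 2v4, 3v5, 4v5, 4v6, 5v7) is reported in full:
same-parameter-count "replacement" pairs carry the raw `2·ΔLL` statistic
flagged as non-nested with no p-value (an opt-in `force_p` switch reproduces
analyses that treat them as χ² tests); nested additions carry
χ²(df = Δparams) p-values. Selection at α = 0.05 requires a combined model
to beat *both* single-predictor parents (the nested pairs 1v4/1v5 are
computed for this purpose alongside the published ones), then allows the
PC2 extension if its addition is significant; if both instrument branches
qualify, the higher log-likelihood wins, and if none qualifies the
liking-only baseline stands. This keeps selection driven purely by nested
tests — replacement comparisons are descriptive — while still reproducing
every printed statistic.

McFadden's adjusted pseudo-r² is `1 − (LL − K)/LL₀` against the ASC-only
(market-share) null on the same choosers. `K` counts all estimated
parameters by default; a `penalty="slopes"` convention is available because
software disagrees on what `K` includes and published values rarely say.

The Hausman–McFadden IIA test removes one alternative (dropping the choosers
who picked it), refits, and forms `q = d'(V_r − V_f)⁻¹d` over the parameters
common to both fits (slopes plus surviving non-reference constants; with 7
alternatives and 2 slopes, df = 7). When the variance difference is not
positive definite — common in finite samples — a Moore–Penrose pseudo-inverse
is used and a warning emitted, and `q` is clamped at zero. The default run
reports all seven removals, since the removed alternative is an analysis
choice. Simulation shows the test's size converging to the nominal 5% from
above as the sample grows (≈10% at n = 400, ≈6% at n = 5000 in our checks);
small-sample over-rejection is a known property of this statistic, so
single-removal p-values at n ≈ 123 deserve caution.

## Leave-one-out cross-validation

For each subject in input order: demean everyone within-subject; fit the PCA
on the n−1 training rows only and orient its signs with training liking; fit
predictor scaling on the training rows; fit the conditional logit on the
training choosers; project and scale the held-out subject's rows; predict
their seven choice probabilities. Probabilities are converted to ranks by
descending probability, ties broken by alternative order; the distribution
of the *chosen product's* rank over subjects (percent at rank 1…7, chance =
1/7 ≈ 14.3%) is the evaluation output. The per-fold building block takes a
training panel that physically excludes the held-out subject, which makes
the no-leakage contract directly testable: corrupting a subject's data and
then dropping them leaves their fold prediction bit-identical. A fold whose
fit fails (e.g. separation in a degenerate toy panel) is recorded and the
run continues.

## Synthetic generator

Per subject × product trial, latent valence and arousal are the product's
mean level plus an independent Gaussian deviation (`subject_sd`, default 1.0
— individual taste differences). Emotion items are
`2 + loading·latents + noise(item_noise_sd = 0.5)`, clipped to [0, 4] and
rounded to the ordinal support by default; the auto-generated loading
pattern is dichotomous in valence (half positive, half negative items, as in
a balanced non-verbal battery) with alternating smaller arousal loadings.
Liking is `50 + 15·valence + noise(SD 10)`, clipped to [0, 100] and rounded
to 0.1 (a VAS in mm). The choice is drawn from a conditional logit on the
true utility `α_j + 0.6·z(liking) + 1.0·valence + 0.0·arousal`: valence is
the strongest driver, liking adds independent information through its own
noise, and arousal has no group-level effect — the qualitative structure the
analysis is designed to detect. Product mean valences
`(-0.2, -0.85, -0.95, -0.55, 0.2, 1.45, 1.1)` were calibrated once, by
simulation over seeds, so the two dominant products attract roughly 40% and
30% of choices, mimicking the strongly skewed popularity typical of real
product sets and exercising the alternative-specific constants. The paired
generator renders a second (39-item) battery on the same latents, liking and
choices, emulating one subject pool completing two questionnaires.

What the generator deliberately does not model: hedonic-asymmetry item
semantics (real verbal batteries are dominated by positive terms with
skewed, often bimodal item distributions), questionnaire order and fatigue
effects, and individual optimal-arousal differences. Passing tests on
synthetic data therefore demonstrate correctness of the estimation and
validation machinery under the assumed two-factor structure, not that real
emotion data satisfies that structure.

## Problem sizes

Test and acceptance runs use the default 123 × 7 design where the full-size
condition matters (ladder, LOOCV, explained variances) and smaller panels
(10–60 subjects) for per-operation checks; the parameter-recovery study uses
500 replicates of 500 choosers × 7 alternatives; null-distribution and
Hausman-calibration simulations use a few hundred replicates at n = 120–1500.
The complete pipeline on the default design runs in seconds on one core.

## Known limitations

- The estimator covers alternative-varying covariates only; chooser-level
  covariates, mixed/nested logit and random coefficients are out of scope.
- The Hausman–McFadden statistic's finite-sample behaviour (over-rejection,
  occasional indefinite variance differences) is inherited from the method
  itself, not worked around beyond the pseudo-inverse fallback.
- Rank ties after probability prediction are measure-zero on real data but
  are resolved deterministically (alternative order) so synthetic edge cases
  are reproducible.
- Unbalanced designs (subjects missing products) are rejected, not handled.
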