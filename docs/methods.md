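# Methods

## The task

The motivational Go/NoGo learning task crosses cue valence with required
action. On each trial one of four cues appears and the subject responds Go
(press) or NoGo (withhold). Half the cues are Win cues (correct responses
mostly yield a reward of +1, incorrect responses mostly nothing), half are
Avoid cues (correct responses mostly avoid a punishment of −1). Feedback is
probabilistic: correct responses obtain the desired outcome with probability
0.8, incorrect responses with probability 0.2. A session has 4 blocks of 80
trials; each block introduces four fresh cues, one per valence-by-action
cell, each shown 20 times in uniformly random order.

`gonogo.task` generates such sessions. Each block draws from its own child
random stream spawned from the session stream, so a block's schedule does not
depend on how many draws earlier blocks consumed. Feedback is sampled i.i.d.
Bernoulli per trial by default; `TaskConfig(exact_feedback_ratio=True)`
instead pre-assigns exactly `round(0.8 × 20)` valid-feedback encounters per
cue, which is useful for deterministic tests. Whether the original experiment
constrained runs of identical cues is unknown; pure uniform shuffling is
used. Cue identities are opaque integers.

## The model family

All models are Q-learners over (cue, action) pairs:

    Q_t(a, s) = Q_{t−1}(a, s) + ε (ρ r − Q_{t−1}(a, s)),

with outcomes r ∈ {−1, 0, +1} scaled by a feedback sensitivity ρ > 0 that
plays the role of an inverse temperature, and a learning rate ε ∈ [0, 1].
Choice probabilities are a softmax over action weights w(a, s), computed with
a max-shift for numerical stability.

Q-values start at the midpoint of each cue's outcome range, V(s)·ρ with
V = +0.5 (Win) / −0.5 (Avoid). Because cue valence must be inferred from
valenced outcomes, a cue's Q-values and the response-bias term are *muted*
(multiplied by zero in action selection) until the first non-zero outcome
for that cue; learning continues during muting, and muting is permanent once
lifted. Muting is tracked per cue (cues are block-unique). The Go bias and
the persistence terms are active from trial 1 — only value-dependent terms
wait for valence information.

The nested family adds bias terms to the base model M1 = {ρ, ε}:

| model | adds | action weight for Go |
|---|---|---|
| M2 | b | Q + b |
| M3 | π | Q + b + π·V(s) |
| M4 | κ (no π) | learning-rate bias (below) |
| M5 | π and κ | both |
| M6 | φ_INT | + φ_INT on the previously chosen action |
| M7 | φ_DIFF | + φ_INT ± φ_DIFF (+ for Win, − for Avoid) |

π·V(s) uses V = ±0.5 as the scaling convention. The persistence terms attach
to whichever action was taken on the previous encounter of the same cue; no
term applies before the first encounter.

The learning bias κ boosts the rate for rewarded Go updates and dampens it
for punished NoGo updates. Because ε is estimated through a logistic
transform, a naive additive bias would act asymmetrically; instead the bias
is applied in the unconstrained (logit) space on the side of ε₀ closer to
its range limit, and the other side mirrors the resulting difference:

    if ε₀ ≤ 0.5: ε_punNoGo = logistic(X_ε − κ); ε_rewGo = ε₀ + (ε₀ − ε_punNoGo)
    if ε₀ > 0.5: ε_rewGo  = logistic(X_ε + κ); ε_punNoGo = ε₀ − (ε_rewGo − ε₀)

κ here is the softplus-constrained value applied in logit units. Both
branches coincide at ε₀ = 0.5 (verified by test), so the ≤ branch is used at
equality and behavior is continuous. The mirrored value cannot leave [0, 1]
(it is clamped anyway as a guard). Neutral outcomes and the remaining
response-outcome cells always use ε₀.

Parameters are estimated in an unconstrained space X: ρ = exp(X_ρ),
ε = logistic(X_ε), κ and φ_DIFF through the softplus y = log(1 + exp(x))
(positive by hypothesis: both biases have a predicted direction), and b, π,
φ_INT unconstrained. Inactive parameters of nested models are fixed at 0 on
the constrained scale, which makes richer models reduce *exactly* to their
nested parents.

The likelihood is implemented twice: a step-by-step reference implementation
(`action_weights`, `update_state`, …) and a compiled single-pass kernel
(`gonogo._fastlik`) used by fitting and recovery. A test asserts agreement
to 1e−10 on full sessions across all seven models; the recovery suites need
thousands of fits, which the kernel makes tractable on one CPU.

## Fitting

Subject-level fits are MAP estimates in X-space under independent Gaussian
priors, with the Laplace approximation for the log model evidence:

    log p(D) ≈ log p(D|X*) + log p(X*) + (d/2) log 2π − ½ log |H|,

H the Hessian of the negative log posterior at the mode (central finite
differences, relative step 5e−3, exact for quadratic objectives up to
roundoff). Optimization is L-BFGS-B with numerical gradients; restart 1 at
the prior mean, further restarts at prior draws (default 10). If H is not
positive definite the smallest power-of-ten diagonal jitter from 1e−8
upward is added and the fit flagged non-converged.

Default priors are the weakly informative X_ρ ~ N(2, 3), X_ε ~ N(0, 2), and
N(0, 3) for b, π, κ; the persistence parameters also get N(0, 3) by analogy,
as no standard value exists for them. The spread is interpreted as a
*variance*; `PriorSpec(spread_is_sd=True)` switches to standard deviations,
since the N(m, s) notation is ambiguous in parts of the literature.

`hierarchical_fit` is an empirical-Bayes EM scheme: alternate per-subject
Laplace fits under the current group prior with moment-matching updates of
the group mean and variance (the variance pools MAP spread around the group
mean with the subjects' posterior variances, floored at 1e−6 so it can never
collapse to zero), until the group mean moves less than 1e−4 (max 100
iterations). After the first sweep, subject fits are warm-started from their
previous optima. This is a moment-matching variant of mean-field variational
Bayes; the contract is the fixed-point behavior (shrinkage, non-decreasing
summed evidence on heterogeneous cohorts), not bit-level agreement with any
particular toolbox.

`joint_model_fit` couples several models: each subject's contribution to a
model's group update is weighted by the responsibility — the posterior
probability that this model generated that subject's data — computed from
the per-subject log evidences under a Dirichlet prior over population model
frequencies. The final evidence matrix feeds random-effects model selection:
variational Dirichlet posterior, exceedance probabilities by Monte-Carlo
(default 1e6 draws, seeded, configurable for test speed), the Bayes omnibus
risk from the free-energy comparison against the equal-frequency null, and
the protected exceedance probability PXP = (1 − BOR)·EP + BOR/K.

## Recovery suites

Parameter recovery samples ground-truth vectors from a generating
population, simulates one session per vector, refits with single-subject MAP
under the default prior (2 restarts — the cheaper per-dataset structure;
hierarchical refitting is available via the library but not the default),
and correlates truth with recovery per parameter. The chance baseline
permutes the assignment of recovered rows to truth rows (row permutation of
the recovered matrix; the alternative reading — independent within-column
permutations — is equivalent in distribution for the on-diagonal statistic)
and takes the 95th percentile (linear interpolation) of the pooled
on-diagonal correlations.

Model recovery samples constrained parameter sets per generating model
(ρ < 400, ε > 0.05, and each bias parameter's absolute constrained value
above the 10th percentile of its population distribution, applied marginally
per parameter — without this, a nested model's data are indistinguishable
from its parent's), simulates a dataset per set, fits all seven models, and
selects the best by log evidence with ties broken toward the simpler model.
Forward confusions condition on the generator, inverse confusions on the
best fitter. The permutation null shuffles the seven evidences within each
dataset and pools the diagonals of both matrices into a single 95th
percentile.

Default scales are 100 simulations / 1,000 permutations (parameter
recovery) and 50 datasets per model (model recovery), the package's
continuous-verification scale; larger runs are a function argument away.

## The generating population

Where a generating population is needed (recovery defaults, demonstration
cohorts), the package uses independent Gaussians in X-space with means
(X_ρ, X_ε, b, π, X_κ, φ_INT, X_φDIFF) = (1.5, −1.0, 1.2, 1.0, 0.5, 0.3, 0.3)
and sds (0.5, 0.5, 0.4, 0.5, 0.5, 0.4, 0.5). These were calibrated against
the descriptive signatures of human behavior in this task: initial Go rates
around 80% (on the first, fully muted encounters p(Go) = logistic(b), which
pins b near 1.2), a clear Win-over-Avoid excess in Go responding, a stronger
outcome effect on response repetition after Go than after NoGo responses,
and more repetitions for Win than Avoid cues. A 100-agent cohort from this
population reproduces all four signatures.

What the generator does *not* emulate: reaction times, attention and fatigue
drifts over a session, within-subject parameter drift, and any correlation
structure between parameters (independent sampling). Passing recovery at
these settings shows the pipeline identifies parameters and models for
agents that actually follow the model with clearly expressed biases; it
does not bound recovery quality for humans whose parameter distribution is
wider or correlated.

## Descriptive statistics

Stay probabilities pair consecutive encounters of the same cue (transitions
never cross blocks, since cues are block-unique; the last encounter
contributes nothing). The outcome-conditioned table keeps only transitions
whose preceding outcome was valenced; the valence-conditioned table uses
all transitions. Cells with no eligible transitions are reported missing,
not zero.

Paired contrasts use Cohen's d = mean(Δ)/sd(Δ) and Hedges'
g = d·J with the paired-design small-sample factor J = 1 − 3/(4N − 5);
confidence intervals bootstrap the difference vector (default 10,000
resamples, seeded), take the 2.5/97.5 percentiles of d, and multiply them by
J. Zero-variance differences raise an error rather than returning an
infinite effect. Mixed-effects logistic regressions and repeated-measures
ANOVAs are standard-library territory (lme4, ez, statsmodels) and are not
re-implemented; this module supplies the descriptive quantities and effect
sizes.

## Numerical choices and limitations

* Softmax and likelihood computations are shift-stable; evidences are finite
  for any finite X.
* L-BFGS-B tolerances: ftol 1e−12, gtol 1e−8; Laplace evidence on conjugate
  Gaussian toys is accurate to better than 1e−8.
* Degenerate permutation distributions (all-equal statistics) return the
  constant with a warning.
* The empirical-Bayes updates are not guaranteed monotone in the summed
  evidence at every step; the iteration trace is recorded and
  non-convergence flagged.
* Model selection with few subjects (< ~10) has a high Bayes omnibus risk by
  construction; PXP is then pulled toward 1/K, which is the intended
  protection, not a defect.
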