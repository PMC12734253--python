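# Methods

## The model

`escalearn` implements a three-level binary Hierarchical Gaussian Filter
(HGF) for negative-reinforcement (escape/avoidance) go/no-go learning,
together with everything needed to study it end to end: a synthetic task
and agent generator, per-subject maximum-a-posteriori (MAP) inversion,
trial-level trajectory extraction, and Bayesian mixed-effects group
models fitted with a conjugate Gibbs sampler.

The generative model is a hierarchy of coupled Gaussian random walks
observed through a Bernoulli emission:

    x1(t) ~ Bernoulli(s(x2(t))),          s = logistic
    x2(t) ~ N(x2(t-1), exp(kappa*x3(t) + omega2))
    x3(t) ~ N(x3(t-1), exp(omega3))

Level 2 (`mu2`, `sigma2`) is the log-odds contingency belief that "go"
is the correct action, with its uncertainty; level 3 (`mu3`, `sigma3`)
is the volatility belief — how changeable those contingencies are
expected to be — with its uncertainty. Filtering inverts this model
trial by trial with the standard binary-HGF closed-form updates: the
model prints only the generic precision-weighted form
`mu_i(t) = mu_i(t-1) + psi_i(t) * delta_{i-1}(t)`, and we instantiate
the variance update with the usual binary-observation equations
(`pi2 = pihat2 + muhat1(1-muhat1)`, the `w2`-weighted level-3 precision
update, and so on), which the one-step hand-derived oracle values in
the test suite pin down exactly.

Two conventions deserve note:

- **Learning-rate definitions.** At level 3 the dynamic learning rate
  is the precision ratio `psi3 = pihat2/pi3`, exactly the generic
  ratio-of-precisions form. At level 2, because the update is
  `mu2 = muhat2 + delta1/pi2`, the binary-observation convention
  `psi2 = 1/pi2 = sigma2` is used (the Bernoulli Fisher information
  `muhat1(1-muhat1)` plays the role of the level-1 precision
  contribution). The generic precision-ratio form applied literally at
  level 2 (`pihat1/pi2`) is available for sensitivity analysis via
  `HGFParams(level2_rate="literal")`; the default convention makes
  `psi2` and `sigma2` identical series, which is the behaviour
  reflected in this literature's reported tables.
- **Hard failure on precision collapse.** A non-positive level-3
  posterior precision (`pi3 <= 0`), an overflowing `exp`, or a
  float-saturated level-1 prediction raise `HGFNumericalError`; the
  parameter set is rejected (mapped to log-joint −inf during fitting),
  never clipped. Probabilities are clamped to `[1e-12, 1-1e-12]` only
  inside the choice likelihood.

Choices are linked to beliefs by the unit-square sigmoid
`P(go) = muhat1^beta / (muhat1^beta + (1-muhat1)^beta)` with inverse
temperature `beta >= 0`; `beta = 0` is pure guessing.

## The synthetic task and cohort

The task has 120 trials and four cues, each deterministically mapped to
one cell of {escape, avoidance} x {go, no-go} (escape trials start with
the aversive sound, which a correct response terminates; avoidance
trials start silent, and a correct response keeps them silent).
Balanced designs place 30 trials in each cell — per-cell counts are not
reported for the original task, so an even split is assumed — and the
cue order is a constrained shuffle (no more than 4 consecutive trials
of the same cue), reproducible from a seed. Contingencies never
reverse within a run; a reversal option exists but is off by default.
Stimulus timing (1 s cue, 2 s response window, 2 s aversive feedback,
750 ms silence, 1 s inter-trial interval) is carried as metadata only;
there is no reaction-time model.

Simulated agents are HGF learners. Because each cue consistently
signals one action, an agent that pooled all cues into a single belief
could never exceed 50% accuracy on a balanced design; agents therefore
track an independent belief state per cue (the `u` stream within a cue
is constant, so beliefs converge on the signalled action and accuracy
rises above chance). A `cue_specific_beliefs=False` switch restores
the pooled single-filter agent. The recorded input column `u` is
always "1 iff go is the correct action for this trial's cue"; whether
the agent's own update consumes that coding or trial correctness is a
config switch (`input_coding`), with "go is correct" the default since
feedback fully reveals the correct action on every trial.

The default cohort is 120 subjects — 58 with a suicidal-ideation (SI)
history, 62 without — with generative parameters drawn per subject:
`omega2 ~ N(-3, 0.5 sd)`, `omega3 = -6`, `log beta ~ N(log 0.65, 0.5
sd)`, and a `+0.5` shift on the SI group's mean `omega2`. The `beta`
scale was calibrated once so that mean escape-trial accuracy lands in
the high-70s percent range reported for the task (the observed value
is 77.7%); with this population the simulated learning curve rises
from ~50% over the first ten trials to above 85% over the last ten.
All of this is config-overridable. What the generator does *not*
emulate: reaction times, mood induction, demographic covariates,
attention lapses, or any within-run contingency change — so passing
tests validate the machinery and the qualitative group structure, not
the behaviour of real participants.

## Inversion

Each subject's trials are split by condition (60 escape, 60 avoidance,
interleaved order preserved) and fitted independently, since the
group-level models include a within-subject condition term; a pooled
per-subject fit is available via `per_condition=False`. Free
parameters are `omega2`, `omega3` (identity scale) and `beta` (log
scale, enforcing positivity) under Gaussian priors anchored at the
binary-HGF toolbox defaults: `omega2 ~ N(-3, 16)`, `omega3 ~ N(-6,
16)`, `log beta ~ N(log 48, 1)`, with `kappa = 1` and the initial
state (`mu2=0, sigma2=0.1, mu3=1, sigma3=1`) fixed. The posterior
mode is found by L-BFGS-B from the prior-mean start plus 4 jittered
restarts (jitter sd = half the prior sd), tolerance 1e-6, max 500
iterations; the best finite optimum is kept and the mode is the point
estimate used downstream (this MAP scheme replaces a variational
free-energy optimization; for point estimates entering group models
the mode is the quantity of interest either way). Subjects for which
every restart lands on a rejected parameter region are flagged
`all-restarts-failed` and excluded downstream with a logged warning.

At 120 trials, `omega3` is weakly identified — MAP estimates sit at
the prior mean to within ~1e-3 — which is why the group-level
intercept for `omega3` is pinned near −6 regardless of the cohort.
This is a property of the task length, not a defect; the recovery
harness documents it (near-zero rank correlation between generative
and fitted `omega3`).

**Recovery design.** `recovery_experiment` validates the inversion
machinery by the standard self-consistent design: agents are simulated
from the same generative model the fit assumes (a single filter over
the interleaved input sequence) with `beta = 2`, high enough choice
consistency that the data are informative. Under this design the
`omega2` rank correlation on a {-4,-3,-2} x 30 grid at 120 trials
exceeds 0.6 and high/low `omega2` pairs (gap 2) rank-order correctly
in >= 90% of simulations. The cohort pipeline, by contrast,
deliberately fits the single-filter model to per-cue-belief agents — a
model mismatch that mirrors fitting a cue-agnostic HGF to real
participants; generative and fitted `omega2` are then essentially
unrelated, so cohort-level `omega2` contrasts should be read as
descriptions of fitted behaviour, not recovered generative truth.

## Trajectories

For every usable subject x condition, the filter is re-run at the MAP
estimates on that condition's input sequence, and eight outcome series
(`mu2`, `mu3`, `sigma2`, `sigma3`, `eps2`, `eps3`, `psi2`, `psi3`) are
stacked into one long table keyed by subject, group (0 = no SI
history), condition (0 = avoidance) and the raw overall task trial
number (1..120, uncentered — the tiny trial slopes this produces match
the scale on which such models are usually reported). There is no
missing trial-level data by construction.

## Group inference

One Gaussian linear mixed model per outcome, eleven in total: three
fixed-parameter models (`omega2`, `omega3`, `beta`; predictors
intercept, SI, escape, SI x escape) and eight trajectory models
(predictors intercept, trial, SI, escape, trial x SI, trial x escape,
SI x escape), each with a random intercept per subject. "Non-informative
priors" are realized conjugately: improper flat priors on fixed
effects, inverse-gamma(0.001, 0.001) on the random-intercept and
residual variances. The sampler is a *collapsed* blocked Gibbs: fixed
effects are drawn with the random intercepts marginalized out (the
per-subject covariance is rank one, so the Woodbury-corrected
cross-products cost nothing), then intercepts given fixed effects,
then the two variances. Collapsing removes the slow random walk
between the global intercept and the subject effects that plagues the
naive blocked sampler; the stationary distribution is unchanged. All
updates run on precomputed sufficient statistics, so the 115,200-row
trial-level models cost the same per iteration as small ones.
Defaults: 4 chains, 1000 warmup, 4000 retained draws per chain;
convergence requires split-Rhat <= 1.05 and autocorrelation-based bulk
ESS >= 400 for every fixed-effect coefficient (plain split-chain
estimators, not rank-normalized — adequate for these Gaussian
posteriors, and cross-checked against an established implementation in
the tests). A coefficient is flagged significant when its central 95%
credible interval excludes zero; no multiplicity correction is
applied, matching the analysis convention being reproduced.

### Known limitation: anti-conservative trial-by-group interactions

Random-intercept-only Gaussian models assume iid residuals within
subject. The trajectory outcomes violate this twice over: they are
strongly autocorrelated within subject, and their trial slopes vary
across subjects (between-subject spread in `omega2` is part of the
generative population). The sampling variance of a group contrast in
slopes is therefore much larger than the model believes, making the
trial x SI interaction anti-conservative on the belief/uncertainty/
learning-rate outcomes: in null cohorts (zero group effects) its 95%
CrI excludes zero far more often than the nominal 5%, and the
miscalibration does not shrink with cohort size (both the spurious
slope contrast and the interval width scale as 1/sqrt(J)). Only the
prediction-error outcomes, which are serially near-independent,
calibrate correctly. This is the classic argument for random slopes
(which the reproduced analysis design deliberately omits) and should
be kept in mind when reading trial x group rows of the coefficient
table; the corresponding null-calibration check in the test suite
documents the failure rather than hiding it. The sampler itself is
verified calibrated on iid data (~95% interval coverage, closed-form
posterior agreement).

## Numerical and design choices

- Seeds: every stage seed derives from one master seed by stable
  CRC-based hashing of (master seed, stage name); per-subject streams
  are spawned so adding subjects does not perturb existing ones.
  End-to-end reruns are byte-identical.
- Optimization sentinel: rejected parameter regions return a large
  finite objective (1e12) to L-BFGS-B rather than inf, keeping line
  searches stable; rejected-evaluation counts are reported in fit
  metadata.
- Choice tie-break at P = 0.5 is resolved by the random draw itself
  (no deterministic bias).
- Rank-deficient designs raise an error naming the collinear columns
  (pivoted-QR diagnosis); degenerate (constant) chains report
  Rhat = 1 and ESS = 0 by convention with a warning.
- Problem sizes in the test suite: the structural, filter-correctness
  and sampler checks run at full scale; recovery uses a 3 x 30 grid at
  120 trials; null-calibration uses 20 replicate 16-subject cohorts
  with shortened chains — sizes chosen to exercise each claim at
  desk scale while the full default cohort (120 subjects, production
  sampler settings) is run once and shared across the end-to-end
  checks.
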