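# Methods

## The task and its data model

The Probabilistic Reward Task (PRT) is a two-alternative signal-detection
task: a cartoon face is flashed with a short or long mouth and the
participant reports which was shown within a 2 s deadline.  One stimulus
(the "rich" stimulus; counterbalanced short/long across participants) is
rewarded three times more often than the other when identified correctly.
A session is two 100-trial blocks with 50 rich and 50 lean trials per
block in randomized order.

Two reward-delivery rules are implemented.  The default draws a
scheduled-reward flag independently per trial (0.60 on rich, 0.20 on lean,
delivered only if the response is correct).  The `queued` rule fixes exact
per-block counts (30 rich, 10 lean) and re-queues a scheduled reward that
was missed by an incorrect response for the next correct response to the
same stimulus type — the classic PRT convention.  Both satisfy the 3:1
asymmetry in expectation; the queued rule satisfies it exactly per block.

RTs are stored in milliseconds on disk and seconds in memory.  Quality
control flags trials with no response or RT outside [0.150, 2.0] s
(configurable) and marks a subject for exclusion above 20% invalid trials.
Invalid trials stay in the table: their feedback still drives learning
(the participant saw it), but they contribute no likelihood terms.

## The Action-DDM

Each response option (rich/lean) carries an expected value Q, updated by
the delta rule for the chosen response only:

    Q_{t+1}(chosen) = Q_t(chosen) + alpha * (r - Q_t(chosen)),  r in {0,1}

The value difference dQ = Q(rich) - Q(lean) modulates a drift-diffusion
choice between the lean (lower, 0) and rich (upper, a) boundaries:

    v_t = s * v_intercept + B_v * dQ          s = +1 rich / -1 lean stimulus
    z_t = softmax(B_z * Q) at the rich option = logistic(B_z * dQ)

so at the session start (dQ = 0) the process is an unbiased DDM with
drift +/- v_intercept.  The six subject-level parameters are the learning
rate alpha in [0,1], the value weights B_v and B_z, the drift intercept
v_intercept, boundary separation a > 0, and non-decision time t >= 0
(seconds).  Likelihood of each valid (response, RT) pair is the Wiener
first-passage-time (WFPT) density at the response's boundary with the
trial's v_t and z_t.

**Drift sign convention.**  The defining equation of v_t leaves open where
the stimulus sign enters.  We sign the intercept only (the default above):
this makes growing dQ raise rich-trial accuracy and lower lean-trial
accuracy, which is the pattern that separates response-outcome learning
from stimulus learning.  The alternative — signing the whole sum,
v_t = s*(v_intercept + B_v*dQ) — is available via `literal_sign=True`
everywhere the likelihood or simulator is called.

**Lesioned variants.**  Five restrictions of the full model form the
comparison lattice: B_v = 0 (`no_value_drift`), B_z = 0
(`no_value_start`), B_v = 1 (`unweighted_drift`), B_z = 1
(`unweighted_start`), and B_v = B_z = B (`shared_B`).  Each is an exact
parameter restriction, so the nesting identities are testable to machine
precision.

## WFPT numerics

The first-passage density is evaluated by the standard small-time /
large-time series pair for the normalized (zero-drift, unit-threshold)
density, choosing whichever expansion needs fewer terms for a truncation
error of 1e-12 in the normalized density; drift and threshold then enter
through the closed-form exponential tilt.  Measured absolute density
error against a fixed-term reference implementation is below 1e-6 over
decision times 0.01–5 s, thresholds 0.5–3 and |v| <= 5, and the density
integrates to 1 within 1e-4 (numerical quadrature).  `rt <= t` returns
-inf (an impossible observation), which is distinct from numerical
underflow of a valid density.

Forward sampling uses Euler–Maruyama with step dt = 1e-4 plus a
Brownian-bridge within-step crossing test (default on).  The bridge test
removes most of the O(sqrt(dt)) boundary-overshoot bias of plain EM:
measured Kolmogorov–Smirnov distance between 2x10^5 sampled paths and the
WFPT density is 0.001–0.003 (0.006 without the bridge test).  First
passages beyond the deadline are recorded as non-responses.

## Synthetic cohorts

Subject parameters are drawn from group-level normal distributions on a
link scale — logit(alpha), log(a), identity elsewhere — optionally
shifted between groups in group-SD units to inject clinical effects
(e.g. a reduced B_z group).  Non-decision times are truncated below at
50 ms, since an identity-link normal admits physically impossible values
in the far tail.

Defaults were calibrated once, by forward simulation, to reproduce the
behavioral scale of a large community PRT sample: mean accuracy ~0.80
(rich ~0.84, lean ~0.79), mean RT ~0.53 s, session response bias ~0.08
log10 units growing by ~+0.03 from block 1 to block 2, and
between-subject SDs of ~0.14 (bias), ~0.26 (discriminability),
~0.09–0.10 (accuracies) and ~0.1 s (RT).  The resulting settings are
logit(alpha) ~ N(-2.0, 1.2), B_v ~ N(0.25, 0.40), B_z ~ N(0.40, 0.55),
v_intercept ~ N(1.5, 0.50), log(a) ~ N(0, 0.20), t ~ N(0.31 s, 0.07 s).
These are calibration choices, not empirical claims.  What the generator
does **not** emulate: perceptual confusability beyond what drift rate
captures, attention lapses and non-stationarity (fatigue, strategy
shifts), contaminant RTs, and any demographic structure — so passing
validation here demonstrates internal consistency of model, simulator and
fitter, not fidelity to any particular human sample.

## Hierarchical estimation

Subject parameters are modeled as normal on the link scale around group
means with group SDs; group means get weakly-informative normal priors,
group SDs half-normal priors.  Sampling is Metropolis-within-Gibbs,
compiled with numba:

- subject parameters: componentwise random-walk Metropolis, step sizes
  Robbins–Monro-adapted during burn-in to ~0.44 acceptance;
- group means: conjugate normal updates;
- group SDs: log-scale Metropolis;
- an interweaved ancillary **rescale move** per parameter,
  (sigma, theta_1..n) -> (c*sigma, mu + c*(theta-mu)) with log-normal c,
  accepted with the exact Jacobian-corrected ratio.

We use the centered parameterization deliberately: with 200 informative
trials per subject it mixes better than a non-centered one and admits the
conjugate mean update; the rescale move supplies the non-centered
direction where the centered sweep is slow (the group-SD "funnel" of
weakly identified parameters such as alpha), and removed the R-hat
excursions (1.1–1.6 -> ~1.03) we observed without it at no change in the
target distribution.

Two chain profiles are provided: `paper` (3 chains, 10,000 iterations,
5,000 burn-in, every 5th retained) and `fast` (3 chains, 4,200
iterations, 1,500 burn-in, thin 3), the latter the default for
desk-scale validation runs.  Convergence is summarized by the
split-chain Gelman-Rubin statistic for every sampled parameter
(threshold 1.1) plus bulk effective sample sizes (arviz).  Note the
split-chain statistic can sit marginally below 1 by its (n-1)/n factor.

The priors are deliberately weak; their prior predictive keeps ~98% of
simulated trials inside the 2 s response window (the remainder are valid
non-responses from the slow tail, e.g. large boundary separations), so
the priors constrain the fit only lightly.

Model comparison uses WAIC from pointwise per-trial log-likelihoods
(posterior thinned to <= 400 draws), reported as elpd with a standard
error; differences from the best model carry the paired pointwise SE and
anything within one SE is flagged a tie, not broken.  The information
criterion follows the textbook (S-1) variance convention; a test
cross-checks against arviz.

## Validation harnesses

**Posterior predictive checks** re-simulate each subject from their
posterior (default 20 datasets x 200 trials, replaying the subject's own
schedule; a redraw mode generates fresh schedules) and compare observed
vs simulated statistics computed by the same code path: accuracy by
stimulus for fast (<0.1 quantile) vs slow (>0.9 quantile) RTs, response
bias and discriminability over eight 25-trial bins, and correct/error RT
means over four 50-trial bins (the sign-flip of error RTs in plots is
presentation only).

**Parameter recovery** simulates one session per row of a ground-truth
table, refits (hierarchically by default; per-subject optionally — both
give essentially identical correlations in our checks) and reports
truth-vs-estimate Pearson r, bias and RMSE per parameter.  Default
truths are drawn from the calibrated group distribution, the one
deliberate deviation from re-deriving truths from fitted real-data
posteriors (unavailable); its spread was calibrated to give comparable
between-subject variance.  At 30 subjects the sampled Pearson r carries
Fisher-z SE 1/sqrt(27) ~= 0.19, so single-cohort correlations for the
weakly identified learning-side parameters scatter widely around their
central values (alpha typically ~0.5, range ~0.3–0.7 across cohort
seeds; v_intercept ~0.94; a ~0.98; t ~0.997); acceptance thresholds are
stated as one-sided 90% bands around the reference values.

**Split-half reliability** computes the block1–block2 Pearson r, the
Spearman-Brown coefficient 2r/(1+r) and the two-way random-effects,
absolute-agreement, single-measure ICC (via pingouin) for any
per-subject measure.

## Problem sizes and numerical choices

Desk-scale experiment sizes: convergence check 20 subjects x 200 trials;
recovery 30 subjects; model recovery 12 subjects per generating model
with 2-chain reduced-length fits; sampler-vs-density comparison 1.2x10^5
paths per parameter set over a (v, a, z) grid.  Signal-detection
statistics use base-10 logs by default (this reproduces the conventional
magnitude range, e.g. discriminability ~0.66 at ~80% accuracy; natural
log available via `base`).  The session-average row of the behavioral
summary pools counts across blocks by default; a block-mean mode is
provided.  Group comparisons default to Welch's t-test (unequal
variances) with Cohen's d; correlations are Pearson with two-sided p,
uncorrected, with optional FDR labeling left to the caller.  Median age
splits assign ties to the younger group.

## Known limitations

- Inter-trial variability parameters of the full Ratcliff DDM (sv, sz,
  st) are intentionally absent — the model couples a single set of
  trial-varying (v_t, z_t) to learned values.
- The learning rate and the value weights are weakly identified from a
  single 200-trial session; hierarchical shrinkage stabilizes but cannot
  sharpen them.  Reliability and recovery of alpha, B_v, B_z are
  correspondingly moderate.
- The Metropolis-within-Gibbs sampler is robust but less efficient than
  gradient-based samplers; the `paper` profile exists for fidelity to the
  original chain settings, not because that many iterations are needed
  for the fast profile's effective sample sizes.
- Real PRT data contain contaminant fast guesses and lapses that the QC
  filter only partially removes; the likelihood has no explicit
  contaminant component.
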