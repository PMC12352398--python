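# Methods

## The task

The simulated task is a timed patch-foraging game. A participant (or
simulated agent) occupies one patch at a time and repeatedly chooses
between *exploit* (dig, collecting a reward) and *leave* (travel to a
fresh patch). Four blocks of 720 s cross two within-patch decay rates
(fast, mean multiplier 0.81; slow, 0.91 per dig) with two travel delays
(short, 2.5 s; long, 9 s). The first dig on every patch is forced and
pays a Gaussian draw (mean 100, SD 10, clamped at 0). Each further dig
pays the previous reward times a decay constant drawn per dig from a
Gaussian with the block's mean and SD 0.07, censored above at exactly 1
(so within-patch rewards never increase) and clamped below at 0 (a
defensive bound, >11 SDs from the mean). Block order is a uniformly
random permutation per session.

**Clock semantics.** Whether feedback and travel intervals count against
the block clock is genuinely open; we charge every event — decision
reaction time, the 1.5-s reward feedback after a dig, and the travel
delay (including one initial travel at block start) — to the 720-s
budget, and end the block at the first decision onset with no time
remaining. This matches a visible countdown timer. The patch in progress
at timeout has no leave action; all patch-level metrics exclude such
truncated patches and count them in an exclusion log, avoiding censoring
bias. A hard cap of 10,000 trials per block guards degenerate
zero-duration configurations. Rewards are kept continuous throughout (no
display rounding).

## The choice model

Decisions are modelled with a logistic marginal-value-theorem rule. At
decision *t* the probability of exploiting is

    P(exploit)_t = 1 / (1 + exp(−[c + β(r_{t−1} − T_t)]))

where `r_{t−1}` is the last reward from the current patch and the
leaving threshold `T_t` equals a delta-rule running estimate of the
environment's reward rate, initialised at 50 at each block start:

    r̂_t = r̂_{t−1} + α (r_t − r̂_{t−1})     after a dig
    r̂_t = r̂_{t−1} + α_l (0 − r̂_{t−1})     after a leave

Free parameters and their boxes: learning rates `α, α_l ∈ [0, 1]`,
sensitivity `β ∈ [0, 2]`, exploitation bias `c ∈ [−50, 50]`. Forced
first digs contribute probability 1 − 1e−5 without the logistic rule; all
exploit probabilities are clamped to [1e−5, 1 − 1e−5].

**Ordering.** The decision at trial *t* uses the threshold formed from
all updates through *t−1*; the update for trial *t*'s outcome follows the
choice. The forced dig updates the estimate like any other exploit.
A leave triggers exactly one delta step toward 0 (event-based, not one
per second of travel).

**Fitting.** Participant-level maximum likelihood: the negative log
likelihood is minimised by L-BFGS-B within the parameter box from
`n_starts` (default 20) uniformly drawn start points, keeping the best;
the procedure is deterministic given its seed. The sequential likelihood
kernel is compiled with numba (pure-python fallback); standard errors
come from a central-difference Hessian at the optimum and are approximate.
Participants with no non-forced decisions are flagged non-identifiable;
non-finite rewards or reaction times reject the participant outright.
The per-participant "reward-rate estimate" summary is the mean of the
per-trial threshold `T_t` under the fitted parameters across all trials
(the summary operator is not uniquely pinned down elsewhere; this choice
is labelled in the output).

**Recovery.** `parameter_recovery` simulates agents at known parameters
and refits them. The default generating distribution is uniform over an
empirically plausible sub-box (α 0.01–0.5, α_l 0–0.2, β 0.05–0.5,
c −2–12): most of the full box yields saturated behaviour in which
parameters are unidentifiable by construction, which would measure the
box rather than the fitter. Even within that sub-box, an agent whose
bias c is high enough (roughly c ≳ 6 with low β) may never leave a
patch; such a session contains no information about the choice rule —
the likelihood is flat in (β, c) — and no analysable patch data, and a
real study would exclude such a participant as disengaged. The recovery
population is therefore additionally conditioned on a lenient
behavioural inclusion criterion (≥ 15 leave decisions per four-block
session; engaged humans produce hundreds), with the number of redrawn
agents reported. Under these conditions rank correlations for β and c
comfortably exceed 0.5 at the study's session size; α_l remains the
weakest-identified parameter whenever leaves are rare, and its recovery
curve is reported, not hidden. Screening never applies to explicitly
supplied generating parameters.

## Optimal residence sweep

`sweep_fixed_actions` plays leave-after-*n* policies through the
simulator (deterministic 1-s reaction times; per-dig cost = RT + 1.5 s
feedback; travel charged per patch switch, consistent with the task
clock) and reports mean total block reward per *n*; `optimal_n_actions`
takes the argmax, breaking ties toward smaller *n* (the conservative
residence estimate) and warning when the optimum sits on the range edge.
The optima reproduce the standard foraging directions: faster decay and
shorter travel both reduce optimal residence.

## Behavioural metrics

* **Patch residence time** — clock time from the first decision onset on
  a patch to the leave response: the sum of decision RTs plus one
  feedback interval per dig. Whether the leave RT and feedback belong in
  "time in patch" is a definitional choice; ours is fixed and recorded
  here and in output metadata.
* **Leaving threshold** — the prospective reward of one further dig at
  the moment of leaving: last observed reward × the condition's *mean*
  decay. The expected value is used because the realised decay draw of
  the forgone dig is unobservable.
* **Vigour slope** — per participant per block, the remaining-time
  coefficient of a Gamma GLM with log link of RT on recorded remaining
  time, averaged over blocks with ≥ 20 decisions (fewer are skipped and
  logged; constant RTs yield slope 0 with a flag). Fitting each block
  separately absorbs decay/travel condition effects at the participant
  level. The full crossed random-effects Gamma GLMM is deliberately
  replaced by this two-stage scheme (per-block slopes, then group-level
  Welch + permutation tests): it targets the same marginal slope
  contrast with transparent inference, at the cost of exact numerical
  equality with a GLMM's conditional estimates.
* **Vigour index** — the negated slope, so that larger values mean
  stronger response acceleration; both raw and oriented values are
  emitted. Sign conventions here are a minefield: the recorded
  `time_remaining_s` counts 720 → 0, while the begin/end RT deciles
  follow the convention of the analysis this mirrors (begin = 1st–10th
  quantile of the remaining-time variable, end = 91st–100th), which maps
  "begin/end" onto the remaining-time axis rather than the physical
  block clock. All group contrasts, recoveries and correlations are
  invariant to this labelling.
* **Group comparison** — Welch two-sample t-test plus a two-sided
  label-permutation test (seeded, add-one corrected). Spearman rank
  correlation for symptom associations; Holm correction is available for
  correlation batteries.

## Synthetic cohort

`CohortSpec` defaults define the study conditions: 44 sED + 56 HC
participants; per group, choice parameters drawn truncated-Gaussian
within the bounds around means/SDs α 0.13/0.12, α_l 0.02/0.08,
β 0.20/0.12, c 4.62/6.64 (sED) and α 0.15/0.12, α_l 0.01/0.05,
β 0.19/0.09, c 4.57/6.00 (HC). Reaction times follow
`RT = exp(b0 + b1·time_remaining) ×` unit-mean Gamma noise with CV 0.30
(a realistic within-subject RT variability; the generator and the Gamma
log-link analysis are conjugate, so slope recovery is well-posed).
Group slope means are b1 = −1.91e−4 (HC) and −5.55e−4 (sED) per second,
with individual SD 2.5e−4 in both groups — derived from the reported
standard error of the group slope difference (5.03e−5 at n = 44/56).
Baselines exp(b0) of 0.39 s (sED) and 0.42 s (HC) reproduce the observed
RT levels at the two ends of the remaining-time axis (sED ≈ 0.39 vs
0.27 s, HC ≈ 0.42 vs 0.37 s). Symptom (eating-attitudes factor) scores
are Gaussian with group means/SDs 1.05/0.61 (sED) and −0.83/0.46 (HC);
within each group the individual slope and the symptom score share a
bivariate-Gaussian latent with correlation 0.25 between the score and
the acceleration index. Condition effects on RT default to zero (hooks
exist); RT noise is independent across decisions (no autocorrelation).
Everything is deterministic given the master seed, via spawned child
streams per participant; the manifest regenerates the cohort bit-exactly.

**What the generator does and does not emulate.** It reproduces the
design, the reward dynamics, MVT-consistent choices with realistic
parameter spread, the group vigour difference and its symptom
correlation. It does not emulate: display rounding, within-participant
RT autocorrelation, condition-dependent RT levels, or any coupling
between choice parameters. Two consequences matter when reading test
results. First, resampling the published parameter means/SDs as
independent truncated Gaussians produces a minority of agents whose bias
c is large enough that they never leave; their patches end only by block
timeout and are excluded (and logged) from patch metrics, which inflates
cohort-level residence/threshold dispersion relative to the human data —
passing tests therefore certify pipeline correctness and qualitative
directions, not the human effect sizes. Second, the event-based learner
is blind to travel time at the individual level, so the short-vs-long
residence contrast emerges only in the pooled per-patch estimator over a
heterogeneous cohort, through exposure weighting (short-travel blocks
contain more patches, disproportionately from short-staying agents);
the direction checks use that estimator, which is also how per-patch
analyses weight real data.

## Problem sizes and numerics

Default scales used by the test suite and the acceptance script: 10,000
patches for first-dig reward statistics; 100 random 200-trial sequences
for likelihood-oracle agreement (tolerance 1e−9 nats); 50 agents for
parameter recovery (10 optimisation starts); 150 simulated blocks per
policy in the sweep; 20 cohorts for noisy vigour recovery (±15% band on
group means); 100 cohorts for the power check (Welch p < .05 in ≥ 90%).
Noiseless vigour fixtures must recover generating slopes to 1e−6, which
the IRLS Gamma fit achieves at zero residual deviance. Probability
clamps ([1e−5, 1 − 1e−5]) bound the likelihood away from −log 0. Ties in
the sweep argmax break toward smaller n. Degenerate inputs (empty
blocks, constant RTs, forced-only participants) return flagged values
rather than raising, except where the schema itself is violated.

## Known limitations

* No hierarchical/Bayesian estimation and no GLMM; group inference is
  two-stage by design.
* The leave learning rate α_l is weakly identified at realistic leave
  frequencies; its recovery curve is reported by `parameter_recovery`.
* The agent model underestimates the travel-time sensitivity that real
  foragers show, as discussed above.
* Real-data reproduction requires separately obtained raw data through
  `io.load_deposited_data`; nothing in the test suite depends on it.
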