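# Methods

## The task

The valence-probe visual discrimination (VPVD) task presents two of
three visual stimuli on every trial. Stimulus A is reinforced on 100%
of the trials on which it is chosen, B on 0%, and the probe stimulus C
on 50%. Standard trials pair A with B; *positive probes* pair C with
the currently correct stimulus, *negative probes* pair C with the
currently incorrect one. Sessions run up to 200 trials. Each disjoint
8-trial bin contains exactly one probe of each type, placed uniformly
at random among positions 2–8 of the bin (never the first position);
when a session length is not a multiple of 8 the trailing partial bin
holds only standard trials. The left/right placement of the two
stimuli is an independent fair coin on every trial. After acquisition
the A/B reward contingencies are swapped between sessions ("reversal");
C is unaffected and reversal is an involution on the stimulus set.
Trial timing (inter-trial intervals, time-outs, tones) is not
modelled; a choice is made on every trial.

## The model family

All nine models share the Rescorla–Wagner update of the chosen
stimulus value,

    Q_{t+1}(c_t) = Q_t(c_t) + α (r_t − Q_t(c_t)),   r_t ∈ {0, 1},

and a two-option softmax whose logit for option *o* on side *s* is

    β Q_t(o) + κ_stim 1[o = previous chosen stimulus]
             + κ_side 1[s = previous chosen side].

Family members free different subsets: a single α or split α_rew /
α_pun (applied after reinforced and non-reinforced trials
respectively), optional κ_stim and κ_side, and — in the richest model —
a discount factor ρ that relaxes the values of the *non-chosen*
stimuli each trial. Excluded parameters are pinned at neutral values
(shared α, κ = 0, ρ = 1), so every member is an exact restriction of
the full model; this nesting is enforced bit-for-bit in tests.

Choices fixed here because the published form of two details is not
available to us:

- **ρ semantics.** Default `rho_mode="forget"`: Q ← ρQ + (1 − ρ)Q₀ for
  non-chosen stimuli, i.e. forgetting toward the initial value, so
  ρ = 1 means "no forgetting" and the full model nests the others
  exactly. A pure-decay variant (Q ← ρQ) is available as a
  `ModelSpec.rho_mode` switch; neither form is asserted to be the
  published one.
- **Stickiness enters the logit additively** as a last-trial indicator
  (the minimal reading of a tendency to repeat a choice regardless of
  outcome), not as a decaying trace, and is not multiplied by β.

Q-values are initialised at Q₀ = 0.5 (the midpoint of the {0,1}
reinforcement scale, unbiased between reward and punishment;
configurable). Values carry across session boundaries in chronological
order — including through the reversal, which is what produces
perseveration — while the previous-choice indicators reset at each
session start. Fitting takes the recorded reinforcements as ground
truth, so the likelihood never needs to know the reversal state.
All softmax arithmetic is done in log space with max-subtraction; the
sequential trial loop is JIT-compiled (numba) and verified against a
naive per-trial reference to ≤ 1e-10 nats.

## Synthetic cohorts

The generator emulates the study design: three dose groups (vehicle /
low / high), 12 subjects per group by default, 200-trial sessions,
acquisition sessions followed by a between-session reversal and 14
post-reversal sessions. Subject parameters are drawn hierarchically on
transformed scales — logit for α and ρ, log for β, identity for κ —
with group means shifted by additive *effects* and a common
between-subject SD of 0.4, then mapped back to natural bounds.

Baseline (vehicle) transformed means: logit α_rew = −0.6 (≈ 0.35),
logit α_pun = −1.0 (≈ 0.27), log β = 1.4 (β ≈ 4.1), κ_side = 0.2,
κ_stim = 0.3, logit ρ = 1.8 (≈ 0.86) — a plausible rodent profile for
this task: moderate learning with reward > punishment rate, mostly
exploitative choice, mild positive stickiness, mild forgetting.

Effect presets encode the reported qualitative drug patterns as
transformed-scale shifts:

- `2a` (5-HT2A antagonist pattern; generating model 9): low dose
  α_pun −1.0, β −0.5, κ_side +0.5, κ_stim +0.4; high dose α_pun −0.8,
  κ_side +0.4.
- `2c` (5-HT2C antagonist pattern; generating model 7): low dose
  κ_side −0.5; high dose κ_side −0.4, β −0.5.
- `null`: no group differences.

What the generator does **not** emulate: attrition, satiety or
motivation drift, latencies, criterion-based session extension, or any
mis-specification between generating and fitted model. Passing
recovery tests therefore demonstrates that the estimation machinery is
self-consistent under the assumed model, not that real rats obey it.

## Hierarchical inference

One joint fit covers all three groups: group-indexed means μ_{g,p} ~
Normal(0, 1) on the transformed scales, between-subject SDs σ_p ~
HalfNormal(1) shared across groups (the simpler of the two plausible
designs; group-specific SDs would double the scale parameters for 12
subjects each), and non-centered subject offsets z_{s,p} ~ Normal(0,1).
These are weakly informative defaults standard for this model family
and are exposed in `PriorConfig`.

Sampling uses an affine-invariant ensemble sampler (90% differential-
evolution moves, 10% snooker moves) over the joint unconstrained
space, with 2·dim + 2 walkers initialised by a small jitter around an
L-BFGS posterior-mode estimate. Defaults: 600 burn-in steps and 400
retained steps per walker.

Convergence is gated on rank-normalised split-R̂ ≤ 1.05 and reported
with bulk ESS for every group-level parameter. Because walkers in an
interacting ensemble are not independent chains (per-walker R̂ stays
elevated long after the ensemble is stationary), the diagnostic pools
the walkers into four draw-ordered pseudo-chains, which still detects
residual drift from insufficient burn-in but not slow per-walker
diffusion; this is a pragmatic compromise and a known limitation.
Non-convergence raises a `ConvergenceWarning` and marks the fit, and
non-converged models are excluded from evidence rankings with an
explicit marker.

Group effects are summarised exactly as the study reports them: the
posterior of the treated-minus-control difference in group means on
the transformed scale, flagged STRONG when 0 falls outside the 95%
highest-density interval and MODERATE when outside the 75% HDI. HDIs
are empirical shortest intervals over sorted draws (verified against a
brute-force window scan and against arviz).

## Model comparison

Marginal likelihoods are estimated by bridge sampling on each model's
unconstrained space: a moment-matched Gaussian proposal fitted to half
the posterior draws, the Meng–Wong fixed-point iteration on the
remaining half (importance sampling as a fallback), and a batch
standard error over five disjoint splits. The prior densities include
all normalising constants and the log-σ Jacobian, so the estimate
targets the true evidence. The estimator is validated against the
closed-form evidence of a conjugate normal–normal problem and the
zero-data identity (evidence = 1 when the target is a normalised
density). Log posterior model probabilities assume equiprobable models
a priori: log p_m = log ML_m − logsumexp(log ML). Rank ties break
toward the smaller model id.

## Conventional behavioural metrics

Post-reversal standard-trial outcomes (sessions concatenated, probes
excluded) are phase-coded by rolling 30-trial windows against
one-tailed binomial cutoffs at α = 0.05, p = 0.5: ≤ 10/30 correct is
significantly below chance (perseverative), ≥ 20/30 significantly
above (learning), otherwise random. Each trial takes the class of the
window ending at it, clamped so phases never regress; trials before
the first complete window inherit its label, and sequences shorter
than one window are labelled random with a warning. Errors to
criterion count incorrect standard trials up to and including the
first disjoint 30-trial block with ≥ 24/30 correct (flagged when never
reached); per-phase error counts are computed on the criterion-
truncated sequence and therefore sum to the total pre-criterion
errors. Session accuracy is percent correct on standard trials and
percent optimal choice on each probe type (missing, not zero, when a
session has no trials of a type). Win-stay/lose-shift uses
consecutive within-session pairs where the previously chosen stimulus
is available again.

## Problem sizes used in the checks

The automated checks run reduced presets chosen to exercise every
stage at useful statistical resolution: parameter/effect recovery uses
3 × 6 subjects with 1 acquisition + 5 reversal sessions of 200 trials
under the `2a` pattern and a model-9 fit; model recovery uses 3 × 4
subjects, 1 + 4 sessions, comparing models {1, 3, 5, 7} on data
generated from model 7 over three seeded replicates; the schedule
validator sweeps 10,000 sessions and the phase coder 1,000 random
sequences. Full-scale presets (12/group, 3 + 14 sessions) are the
package defaults.

## Known limitations

- The ensemble sampler's pooled-pseudo-chain R̂ can be optimistic when
  walkers are initialised tightly around the mode; genuinely
  multimodal posteriors would need independent ensembles.
- Bridge sampling with a single Gaussian proposal degrades in very
  high dimension or under strong non-Gaussianity of the unconstrained
  posterior; the batch SE reports, but does not remove, that noise.
- Group-level effects are evaluated against the generating *group
  means*; with few subjects per group the realised sample mean can sit
  away from the generating mean, so small injected effects are
  sometimes unflagged at reduced scale.
- ρ is weakly identified in short experiments; its posterior leans on
  the prior more than the other parameters.
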