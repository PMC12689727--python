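# Methods

## Model

Each trial of the 2AFC probe-recognition task is modelled as a plain
two-boundary Wiener diffusion under accuracy coding: evidence starts at
*a*/2, accumulates with drift *v* and unit diffusion scale, and the
first boundary crossed (upper = correct, lower = error) at decision time
τ determines the response, with observed RT = τ + *t₀*.  Start-point
bias is never estimated (accuracy coding makes it unidentifiable in the
usual sense and the design gives no reason for a correctness bias), and
inter-trial variability parameters (sv, st, sz) are not part of the
model.  The defective first-passage density is evaluated with the
standard small-time (image sum) and large-time (spectral sine series)
expansions; term counts are chosen from the closed-form error bounds at
an absolute target of 1e-7, and whichever representation needs fewer
terms is used.  The two expansions agree to better than 1e-6 across
drifts in [−5, 5], boundaries in [0.5, 4] and decision times in
[0.01, 5] (tested).

### Condition structure

Trials live in a 4 (prioritization: control / first / middle / last) × 3
(probed serial position) design.  Eight parameterizations map each cell
to drift and non-decision slots via an *attention state*:

* boost family: `prioritized` when the prioritized position is probed,
  else `baseline`;
* tradeoff family: `baseline` (control), `prioritized` (match), or
  `diminished` (mismatch);
* recency-equivalent variants collapse the last position: boost keeps a
  single state; tradeoff distinguishes only whether the focus of
  attention is held alone (control, or last prioritized) or shared (an
  earlier item prioritized).

Boundary separation varies by prioritization condition (4 slots) in the
speed-accuracy-tradeoff variants, else a single slot — it can never
depend on the probed position, which is unknown at decision time.  Slots
are numbered probe-major then state-order (baseline, prioritized,
diminished, foa_alone, foa_shared); only the partition is identified,
but the fixed ordering keeps saved posteriors portable.  Session is not
a model factor.

## Hierarchy, priors, sampler

Subject parameters are drawn from group-level normals on a *sampling
scale*: natural for drift, logarithmic for boundary and non-decision
time (guaranteeing positivity without hard constraints).  Priors are
weakly informative and sit on the sampling scale:

| family | group mean | group SD |
| --- | --- | --- |
| v | Normal(2, 3) | Half-Normal(1) |
| log a | Normal(log 1.5, 0.6) | Half-Normal(0.5) |
| log t₀ | Normal(log 0.4, 0.5) | Half-Normal(0.25) |

These cover the plausible range for 2AFC recognition (drifts 0–5,
boundaries 0.8–3, non-decision 0.2–0.6 s) without pinning any estimate.
Placing the positive-parameter hierarchy on the log scale (rather than
truncated-normal priors on the natural scale) is a deliberate design
choice: it makes the group structure scale-free and the conjugate
group-mean update exact.  A consequence is that the back-transformed
group location exp(μ) is the *median* of the lognormal subject
distribution; the synthetic generator parameterizes the same location,
so recovery comparisons are apples-to-apples.

The sampler is Metropolis-within-Gibbs: scalar random-walk updates for
each (subject, parameter) — touching only the trials mapped to that
parameter, with cached per-trial log-densities — conjugate Gibbs draws
for group means, and log-scale random-walk updates for group SDs.
Proposal scales adapt toward 44% acceptance in 50-iteration windows
during burn-in only and are frozen afterwards, preserving detailed
balance for the retained draws.  Chain *c* is seeded `seed + c`.
Defaults mirror the study protocol: 6 chains × 4,000 iterations, 2,000
burn-in, 12,000 collapsed draws; convergence is flagged at
Gelman-Rubin R̂ < 1.1 (classic between/within form; the threshold is our
choice, the diagnostic is standard).  Initial values come from
per-subject moments (accuracy inverted through the closed-form hit
probability at a = 1.5; t₀ at 0.9 × the subject's minimum RT), jittered
per chain.

Numerical safeguards: per-trial log-densities are floored at −700
(instead of −∞) so proposals with rt ≤ t₀ remain comparable and MCMC
never sees non-finite targets.

## Model comparison

Deviance is −2 × the *subject-level* likelihood only (group densities
excluded; the integration level is a documented convention).  With
D̄ the posterior mean deviance and D(θ̄) the deviance at the posterior
mean of each parameter on its sampling scale,
p_D = D̄ − D(θ̄), DIC = D̄ + p_D, and BPIC = D̄ + 2 p_D — the
doubled-penalty operationalization; the asymptotic alternative form is
noted here as an option and not implemented.  Ties in comparison tables
break toward fewer parameters and are flagged.

## Synthetic-data generator

The generator emulates the study conditions exactly: 3 sessions × 408
trials by default, cells stratified exactly (102 per cell per subject;
per-trial randomization available), 75% reward trials, probes
equiprobable and independent of prioritization, 2.5 s response window.
Data are simulated from the fitted model's own generative process plus
two departures from any real dataset:

* **Censoring**: RTs beyond the window are resampled (truncation) to
  keep cell counts balanced; real omissions would be missing trials.
* **Guessing contaminant** (optional, default off): with probability
  `guess_rate` a trial is a fair coin flip at RT ~ Uniform(0.3, 2.5) s,
  the lapse process the DDM lacks.

The canonical generating truth (`recovery_truth()`) fixes group means to
the winning-model reference pattern — early-position drifts ~1.1–1.9,
recency drifts 3.38 (control) / 4.01 (prioritized) / 2.18 (diminished),
non-decision times 0.36–0.47 s, boundary 1.5 — with between-subject SDs
of 0.3 (drift), 0.15 (log boundary) and 0.10 (log non-decision),
magnitudes typical of hierarchical DDM fits to practiced subjects.
Because the generator *is* the fitted model (plus the optional
contaminant), passing recovery tests demonstrates correctness of the
estimation machinery, not robustness to the many ways real data violate
the DDM (sequential effects, fatigue, parameter drift across sessions).

## Problem sizes used in tests and the acceptance script

Recovery runs use 10 subjects × 408 trials with 3 chains × 1,500
iterations (500 burn-in); model-selection recovery uses 8 subjects and
2 × 900 chains over five replicates of four candidate models (3, 5, 7,
8); the guessing-misfit study uses 8 subjects at a 6% guess rate.  These
sizes were chosen as the smallest at which the recovery statistics are
stable (correlation with truth > 0.95, interval coverage ≥ 90%, BPIC
margins well clear of zero); the full-protocol defaults remain available
throughout the API.

## Degenerate inputs and edge conventions

* Zero-SD screening groups exclude nobody (thresholds collapse onto the
  mean; the tie resolves as "not excluded").
* Screening statistics include all input subjects (no leave-one-out) and
  are computed once — the pass is deliberately not idempotent.
* Trial trimming pools a subject's sessions (one mean/SD per subject).
* PPC cells with no simulated errors report NaN error-RT quantiles
  rather than imputing.
* Empty trial tables have log-likelihood 0; unmapped conditions raise a
  configuration error rather than being skipped.

## Known limitations

* The plain DDM omits inter-trial variabilities and any guessing state;
  the package demonstrates the resulting error-RT misfit signature
  (predictive error RTs too fast, concentrated at the recency position)
  rather than fixing it.
* The Metropolis-within-Gibbs sampler mixes slowly in the
  small-group-SD funnel; with very few subjects, group-SD summaries
  should be read with the R̂ column in hand.
* Reported group locations for boundary and non-decision time are
  lognormal medians, not means; the distinction matters only when
  between-subject SDs are large.
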