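# Methods

This note documents the models, the synthetic-data generator, the fitting
machinery and the numerical choices behind `riskbandit`, in enough detail
to judge what the test suite does and does not establish.

## Task model

Four arms pay integer rewards in [1, 99] points, approximately Gaussian
with means 60/40 and SDs 20/5 in a 2×2 value × risk design (arm 1
risky-high, 2 safe-high, 3 risky-low, 4 safe-low).  "Approximately
Gaussian" is realised as *round-then-clip*: a Gaussian draw is rounded to
the nearest integer and clipped into [1, 99].  Rounding adds 1/12 to the
variance (safe-arm SD 5.008 instead of 5.000); clipping (≈2–3 SDs out for
the risky arms) biases the risky means by <0.2 points (exact clipped-
rounded mean for the risky-high arm: 59.815).  Truncation-by-resampling
was rejected because it shifts the risky-high mean by about a full point.

Schedules are balanced within block: each of the 12 ordered pairs of
distinct arms appears exactly `reps_per_pair` times per block (default 10,
so 120 trials/block, 4 blocks/session), in an independently seeded uniform
shuffle per block with no further run-length constraints.  Block and trial
indices are 1-based everywhere.

## The twelve models

All models share the delta-rule core ΔQ_chosen = α_eff·δ with Q0 = 50 (the
middle of the reward range), softmax choice with inverse temperature β > 0
over the two shown options only, and *no* updates to unchosen arms.
Latent state (Q, S, and the carried-over outcome PE) resets at every block
boundary, because each block uses a fresh stimulus set; the reset is
applied in fitting as well as simulation (an assumption — the convention
used by the original analysis is not recoverable from its description).

Model-specific structure, with free parameters:

| model | structure | free parameters |
|---|---|---|
| RW | plain delta rule | α, β |
| concave-UTIL | U = m + σ(1−e^{−kz})/k, z=(r−m)/σ, k>0 | α, β, k |
| convex-UTIL | same family, k<0 | α, β, k |
| s-shaped-UTIL | U = m + σ·sign(z)|z|^k, k∈[0,1] | α, β, k |
| inverse-s-UTIL | same family, k>1 | α, β, k |
| pos-neg-RATES | α₊ if δ>0 else α₋ | α₊, α₋, β |
| variance-RATES | α_risky (arms 1,3) / α_safe (arms 2,4) | α_risky, α_safe, β |
| attention-RATES | α_eff = α·|δ|^k | α, k, β |
| scaled-PE | δ̃ = δ/S_chosen; ΔQ=α_Q δ̃; ΔS=α_S(|δ̃|−1) | α_Q, α_S, β, S0 |
| PEIRS | A_i = Q_i + tanh(ω·δ_stimulus)·S_i | α_Q, α_S, β, ω, S0 |
| PIRS | gate = pair-mean prediction ½(Q₁+Q₂) | α_Q, α_S, β, ω, S0 |
| OEIRS | gate = previous trial's δ_outcome | α_Q, α_S, β, ω, S0 |

Utility models (σ = m = 50 fixed) apply U only inside the outcome
prediction error (δ = U − Q), so Q lives on the utility scale while the
softmax still consumes Q directly.  The spread rule ΔS = α_S(|δ|−S) tracks
the mean absolute deviation of the prediction error, so a converged risky
arm has S ≈ σ√(2/π) ≈ 15.96 (exactly 15.757 for the integerised, clipped
generator).  The tanh gate operates on raw points (no normalisation); with
δ_stimulus = ±10 after learning, ω ≳ 0.3 is effectively saturated.

Edge conventions, chosen where the defining equations are silent:

* valence rule at δ = 0 uses α₊ (the update is zero either way);
* attention rule at δ = 0 returns rate 0 (avoids 0^k for k < 0); rates
  α·|δ|^k may exceed 1 and are *not* clamped — divergence is discouraged
  only by the fitting prior;
* OEIRS's carried-over outcome PE is 0 at each block start (no previous
  outcome exists);
* scaled-PE's spread is floored at 10⁻³ so δ/S stays defined (the update
  α_S(|δ̃|−1) can otherwise cross zero).

The trial recursion exists twice: a readable reference implementation
(`models.py`, producing full latent traces) and a numba-compiled flat loop
(`_kernels.py`) used by the fitting hot path (~35 µs per 480-trial
likelihood).  Tests assert the two agree to 10⁻⁹ for all twelve models,
and that every non-RW model collapses to RW at its identity limit.

## Priors, transforms, fitting

Parameters are fitted in an unconstrained raw space: logistic sigmoid for
[0,1] rates and the s-shaped exponent, exp for β, S0 and k_concave, −exp
for k_convex, 1+exp for the inverse-s exponent, identity for ω and the
attention exponent.  Raw-space priors are independent Gaussians
(mean, **variance**): logit-rates N(−1, 2); log β N(−2, 2); log k_concave
and log(−k_convex) N(−3, 4); logit k_s N(3, 4); log(k_inv−1) N(−3, 4);
ω N(0, 20); log S0 N(2, 2); attention exponent N(0, 4) (no canonical
prior exists for it; the scale matches the other shape parameters).

Estimation is multi-start MAP: L-BFGS-B with numerical gradients on the
negative log-posterior, start 0 at the prior mean and the rest at prior
draws (default 10 starts; ties broken by first-found; non-finite
objectives — possible under extreme surprise-gated rates — are treated as
infinitely bad).  This is a deliberate, documented substitution for a
variational-Bayes scheme: the comparison currency is the BIC ranking, and
a point-estimate BIC (k·ln n − 2·logL at the MAP, n = 480 trials per
participant) preserves rankings while being deterministic and
dependency-light.  Population comparison is fixed-effects: BIC summed over
participants, lower is better.  Exact BIC *values* are therefore not
comparable to ones derived from free-energy approximations; rankings are
the reproduction surface.

## Synthetic cohorts

The generator is the package's study population.  Defaults per model are
documented in the registry (PEIRS: α_Q=0.3, α_S=0.1, β=0.2, ω=0.5, S0=10;
RW: α=0.3, β=0.2 — the learning rate and temperature a typical fitted
bandit participant shows, and the values used in this package's own
recovery checks); prior-draw cohorts sample raw-space Gaussians through
the transforms.  Cohort size defaults to 27 participants × 480 trials.
Per-participant seeds are the master seed plus a fixed prime stride
(7919·i), so cohorts are bit-reproducible and member-wise independent.

An optional sanity filter redraws a participant's parameters (cap 100)
until the simulated agent passes the behavioural inclusion criterion
(>65% high-value choices on late different-condition trials).  Recovery
studies enable it: wide priors otherwise produce a large fraction of
random responders whose sessions carry no information about any
parameter, and an analysed empirical population is filtered the same way.

What the generator does *not* emulate: reaction times, within-session
drift or lapses, side biases, stimulus-identity effects, or any
between-participant correlation structure (prior draws are independent).
Passing tests therefore show that the pipeline is correct and well-powered
for agents of the assumed families — not that human data would select the
same model.

## Simulation studies and behavioural battery

Risk preference is the fraction of risky choices within a matched-mean
condition.  Aggregation order is fixed: replicate experiments are averaged
within participant first, then across participants (tests assert
permutation invariance).  Within-block traces are smoothed with a centred
20-point moving average whose window shrinks at the edges (no padding).
Preference clouds are summarised by a Gaussian KDE (Silverman bandwidth;
isotropic fixed-bandwidth fallback for degenerate clouds) with contour
levels spaced over each distribution's own density range.

The battery applies, identically to any cohort: the strict >65% inclusion
rule; a binned accuracy trace (participant means first, then mean ± SE of
those means; bin width 10 must divide the block length); two-tailed paired
and one-sample t-tests on condition risk preferences (against each other
and against 0.5); and an emergence-speed test.  The latter replaces a
mixed-effects Monte-Carlo likelihood-ratio test with per-participant
logistic slopes of "preferred choice" on trial number per decision type
(value vs risk), compared by a group-level t-test — same interaction, far
lighter machinery.  "Preferred" in the risk conditions means risky in
both-high and safe in both-low (the asymptotic preferences a positive-ω
gating agent develops); slopes under perfect separation are clipped at ±1
per trial and flagged.

## Problem sizes and numerical choices

Test and driver scales are chosen for single-CPU desk runs while keeping
every estimate's sampling error well inside its decision margin: 20
replicate 27-agent cohorts for the qualitative risk-preference checks; 30
sanity-filtered agents for parameter recovery; 20+20 single-participant
datasets × 12 candidate models for model recovery; 50 replicates in the
simulation driver (the protocol's full 1000 replicates changes the SE, not
the conclusions, and remains available via `n_reps`).  Softmax is
max-subtracted; choice probabilities are floored at 10⁻³⁰⁰ inside the
likelihood; transform round-trips are exact to 10⁻¹⁰ away from range
boundaries, at which the inverse transform raises.

## Known limitations

* ω is weakly identified per participant beyond tanh saturation; recovery
  correlations for ω (~0.6–0.7) are intrinsically lower than for α_Q or β.
* A plain RW cohort at the default α=0.3, β=0.2 shows a small *positive*
  condition difference in risk preference (≈ +0.04): with Q0 = 50 between
  the arm means, choice-contingent sampling is asymmetric around the
  reference, a known sampling-bias route to risk preferences.  It vanishes
  at β=0 and grows with β.  RW is therefore "near-zero" only relative to
  the gating models' ≈ +0.46, not exactly zero.
* BIC values are point-estimate based (see above); only rankings should be
  compared across toolchains.
* The scaled-PE spread floor (10⁻³) is a regularisation without empirical
  content; fits that hit it are effectively delta-rule fits with a huge
  learning gain.
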