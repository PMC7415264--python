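# Methods

This note documents the models, numerical choices and limitations of the
`crossmodal` toolkit in one place. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from human data.

## Observer model

The simulated listener is a stationary 2IFC observer

    P(correct | x) = γ + (1 − γ − λ) · F(x; α, β),

with x the stimulus level in dB SNR, γ = 0.5 (two-interval forced choice
is criterion-free with 50% chance), λ the lapse rate, α the threshold and
β the slope. Both available sigmoids are parameterised so F(α) = 0.5:

* logistic: F(x) = 1 / (1 + e^{−β(x−α)}) — the default, because dB is
  already a logarithmic axis, making the logistic-on-dB the natural
  analogue of the Weibull-on-intensity convention;
* gumbel (log-Weibull): F(x) = 1 − exp(−ln2 · e^{β(x−α)}), the form
  common in adaptive-estimation toolboxes, shifted to its midpoint.

Defaults: λ = 0.02, fixed rather than estimated (standard practice for
simulation work); β = 2 in the experiment generator, a mid-range slope
for signal-in-noise detection (the psychometric function rises from ~55%
to ~95% over roughly 3 dB). The observer has no learning, fatigue,
bias or inter-trial dependence; those are out of scope by design.

SNR follows the RMS-power convention throughout: snr_db =
20·log10(rms_signal / rms_noise).

## Staircases

The two-down one-up rule lowers the level after two consecutive correct
responses and raises it after any error, so its fixed point is the level
where P(correct)² = 0.5, i.e. P = √0.5 ≈ 70.7%. The step schedule is
3 dB until the 2nd reversal, 1 dB to the 5th, 0.5 dB to the 8th, 0.25 dB
to the 10th and 0.1 dB to the 13th, at which the track stops; the
threshold is the mean of the final 10 reversal levels. Semantics that the
schedule wording leaves open were fixed as follows:

* the step for a trial is looked up from the count of *already completed*
  reversals ("3 dB to reversal 2" = step 3 dB while fewer than 2
  reversals exist) — the only reading that keeps all five clauses
  consistent;
* the reversal level recorded is the level presented on the trial at
  which direction flipped (pre-move), the standard convention;
* levels are unbounded above and floored at −60 dB SNR purely as a
  runaway guard; a 1000-trial budget raises an explicit non-convergence
  error. Each track starts at 0 dB SNR.

Calibration (500 seeded tracks, logistic observer α = −15, β = 2, λ = 0,
trials after the 5th reversal pooled): the procedure tracks ≈ 69–70%
correct, within two percentage points of the 70.7% asymptote — the small
undershoot is the familiar finite-step-size bias of transformed up-down
rules — and the mean reversal threshold lands within half a dB of the
analytic 70.7% level. `scripts/acceptance.py` recomputes this figure.

The one-down one-up pre-staircase (constant 1 dB step, six reversals,
mean of the six reversal levels) targets the 50% point, which for 2IFC is
chance; its output is therefore used *only* to centre the Psi prior,
never as an estimate.

## Psi estimator

The posterior lives on a discrete (α, β) grid: α from −40 to +10 dB SNR
in 0.5 dB steps (101 points), β log-spaced over [0.25, 8] with 15 points,
γ and λ fixed (λ = 0.02), candidate stimulus levels equal to the α grid.
These are conventional, testable choices; the toolbox the protocol
originally relied on is not reproduced numerically and grid defaults are
fully configurable. The prior is Normal over α — centred on the
pre-staircase value with a deliberately wide 5 dB SD, since the centre is
coarse — and uniform over β.

Each trial the stimulus is placed at the candidate minimising the
expected one-step-ahead posterior entropy under the posterior predictive
of the response, with ties broken toward the lower (quieter) level; the
point estimate is the posterior mean of the α marginal (not the MAP).
Expected entropies for all candidates are computed with four BLAS
matrix-vector products against likelihood tables cached on the grid
(using H = log s − s⁻¹ Σ a log a for unnormalised mass a), so a 44-trial
session costs ~20 ms; the update itself guards against zero total
likelihood (impossible for λ > 0) and renormalises to 1 within 1e−12.

Session protocol: 45 trials presented, the threshold read from the
posterior after 44 updates (the protocol excludes every session's final
trial), five sessions per estimate. Aggregation across the five sessions
is the mean of the five session estimates — the conservative reading of
"220 trials contributed"; a pooled-posterior mode
(`psi.pool_posteriors`, exact product of session likelihoods against the
shared prior) is provided as the alternative since the protocol wording
does not decide between the two. Recovery: across 200 replicates per
cell of a (α ∈ {−20, −10}) × (β ∈ {1, 3}) grid, the aggregated estimate's
bias is below 0.5 dB in magnitude (measured in the acceptance suite,
typically −0.1 to −0.3 dB; the small negative bias reflects the mean of
the α marginal being pulled toward the grid interior at shallow slopes).

## Trial audio

One Gaussian white-noise sample is shared by both intervals of a trial;
the signal interval adds the acoustic signal RMS-scaled to the target
SNR, then linearly faded in/out, at an onset drawn uniformly from the
spec's window. Two published geometries ship as presets: 4 s noise / 2 s
signal / onset 1–2 s / 500 ms fades, and 2 s / 1 s / 0.5–1 s / 200 ms.
Choices the protocol text leaves open:

* SNR is measured on the un-faded signal over its full support, fades
  applied afterwards — signal RMS power is the controlled variable and
  the fade interaction is unspecified;
* noise amplitude σ = 0.2044 full scale, so per-sample clipping
  probability at |x| > 1 is below 1e−6;
* the envelope pre-step is full-wave rectification (configurable): a
  zero-mean carrier low-passed without rectification has no meaningful
  amplitude envelope. The designed Butterworth filter is 5th-order at
  60 Hz; the forward-backward (zero-lag) pass doubles the effective
  roll-off, which is accepted as part of "zero-lag".

WAV I/O goes through scipy (PCM 16/32 and float); 24-bit PCM writing is
not supported. Stereo files are averaged across channels on read.

## Inference

* **Sign-flip permutation test.** Exchangeable units are subjects, or
  subject-day pairs in day-blocked designs (labels may be swapped within
  a unit, never across days). Each permutation flips every unit's pair
  independently with probability 0.5; p is the proportion of null means
  at or beyond the observed one, with the unpermuted assignment counted
  as one draw among n_perm — so the floor is 1/n_perm (0.0001 at the
  default 10,000) and ties count toward the tail. For n ≤ 12 units the
  test enumerates all 2ⁿ patterns exactly.
* **FDR.** Benjamini–Hochberg step-up at q = 0.05, delegated to
  statsmodels behind the module surface.
* **Bayes factor.** BF = [U⁻¹ ∫₀^U N(m; δ, s) dδ] / N(m; 0, s) with
  U = 5 dB, m the mean difference and s the SEM inflated by the
  small-sample factor (1 + 20/df²). The factor is exposed as a
  configurable callable since different calculators implement slightly
  different corrections. The integral uses adaptive quadrature
  (abs 1e−12 / rel 1e−8, with a point hint at the likelihood peak so
  near-zero SEMs are not missed); the Gaussian-CDF closed form is the
  independent oracle in the tests. A vanishing H0 density reports BF = ∞.
* **Permutation rm-ANOVA.** Classical two-way repeated-measures F ratios
  (each effect against its interaction with units); the null distribution
  shuffles the (object × condition) cell labels jointly within each unit
  — the simplest exchangeability argument consistent with within-subject,
  within-day blocking. Equivalence with any particular published
  permutation-ANOVA package is not claimed; what is verified is the F
  computation (against statsmodels' AnovaRM to 1e−9) and type-I control
  (each effect's rejection rate within [0.03, 0.07] at α = 0.05 over
  1000 null datasets).
* **Power.** Smallest n such that a one-sample t on paired differences
  (noncentrality d√n, df n−1) reaches the target power, from the
  noncentral t distribution; one-tailed by default to match directional
  hypotheses. d = 1.13 at α = 0.05 and power 0.8 gives n = 7.

## Synthetic experiment generator

True thresholds decompose additively:

    truth(s, d, o, c) = baseline_μ[o] + subject_offset_s
                        + condition_effect[c] + day_jitter

with subject offsets ~ N(0, between_subject_sd) drawn once per subject
and day jitter ~ N(0, within_subject_day_sd) per cell. Defaults:
baselines triangle −16 / tambourine −10 dB SNR (the triangle-easier
ordering), between-subject SD 3 dB, day SD 1 dB, video effect −2 dB,
timing-cue and visualizer effects −1 dB, dichoptic effects graded from
−1.5 dB (monocular congruent) to 0 (suppressed); no variance components
or subject-level values are published for these studies, so the defaults
are stand-ins chosen to give a realistic spread, and every one is
configurable. Measurement is simulated by the actual adaptive procedures
(one staircase per cell, or one pre-staircase per observer plus one Psi
session per day-cell, each session one table row so day-blocked inference
works; across-day aggregation is applied downstream). The generator does
not model condition-order effects (the fixed-order design limitation is
inherited, not simulated), dichoptic suppression mechanics (dichoptic
conditions are pure threshold shifts), or audio-domain detection
(responses come from the psychometric model; the audio module is
validated independently). Passing tests therefore demonstrate that the
analysis chain is correct and well calibrated *given* this generative
structure — not that real observers satisfy it.

## Problem sizes and determinism

Monte-Carlo checks use: 500 tracks for staircase calibration, 200
replicates per cell for Psi recovery, 1000 null replicates for
permutation type-I error, and 200 replicate studies for the power of the
18-subject design — sizes at which the binomial/Monte-Carlo error is
comfortably inside each tolerance. All randomness flows through
explicitly passed `numpy.random.Generator` objects; a (design, effects,
seed) triple reproduces a study table and all Monte-Carlo p-values
bit-for-bit.
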