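# Methods

This note records the models, numerical choices and limitations behind
`attnmod`.  It is written for a reader who wants to know exactly what the
package computes and what its passing tests do and do not demonstrate.

## Trial design

A session belongs to one attention system.  Counts are **exact, not
expected**: for every seed, a session of `n_runs × trials_per_run` trials
contains exactly 40% pre-cue, 40% post-cue, 10% cue-only and 10% blank
trials, with cue validity exactly 75% (endogenous) or 50% (exogenous) among
stimulus trials and the response cue on the left for exactly half of them.
`trials_per_run` must therefore be a multiple of 20.  Counterbalancing is
enforced at the session level by default (the stated proportions are
session-level quantities); `balance="run"` enforces them per run.

Timing constants (s): cue 0.067, stimulus 0.050, cue–stimulus ISI 0.050
(exogenous) / 0.250 (endogenous), response cue 0.800, total trial 1.700 /
1.900.  Post-cue trials present stimulus first and cue second with identical
durations, leaving the response-cue window unchanged.  The inter-trial
interval is not dictated by the task itself, so the generator defaults to
the fixed ITI that makes the trial period an integer number of TRs
(TR = 1.75 s ⇒ period 3.5 s: ITI 1.6 s endogenous, 1.8 s exogenous).  This
keeps event onsets on the volume grid, which makes GLM estimability exact
and testable; the ITI is recorded in the design sidecar and configurable.
Each run adds a 14 s lead-in (the 8 volumes later discarded) and a 21 s tail
so late-trial hemodynamic responses are sampled.

## Behavioral observer

Accuracy on a stimulus trial is
`p = λ/2 + (1 − λ) Φ(tilt · s / σ)` with lapse λ (default 0.01), sigma σ in
degrees (default 1.5; the tilt at ~84% correct), and sensitivity factor
s = 1 on valid trials, s = `validity_effect` (default 0.6) on invalid ones —
attention at the probed location improves discriminability.  RTs are shifted
log-normal per validity level (valid faster), which gives the positive,
right-skewed distributions real RTs show.  Fixation breaks are modeled as a
per-trial exclusion flag at 13%, independent of trial type, because only a
mean exclusion rate is meaningful for the simulator.

The staircase is n-down-1-up with n derived from the target accuracy
(`p_target^n = 1/2`; the default 0.794 gives 3-down-1-up), multiplicative
steps of 0.20 log₁₀ units halving after every two reversals down to 0.0125.
The threshold estimate is the geometric mean of the tilts presented after a
burn-in of a quarter of the trials; averaging the whole stationary trace has
lower bias and variance than averaging reversal tilts alone (both are
returned).  A 400-trial staircase against this observer pins the titrated
accuracy near 79.4%; the residual seed-to-seed spread of the *converged
tilt* corresponds to roughly ±2 percentage points of accuracy, which is the
information limit of 400 Bernoulli trials near threshold — accuracy measured
*during* continued titration is far tighter (~±0.3 points over 2000 trials).

d′ uses the convention: clockwise responses to clockwise targets are hits,
to counterclockwise targets false alarms; extreme rates are clipped to
1/(2N) and 1 − 1/(2N).  The three-way repeated-measures ANOVA
(attention × validity × epoch) is computed with `statsmodels.AnovaRM`; a
test cross-checks its validity main effect against the paired-t² identity.
The no-speed-accuracy-trade-off check is a sign constraint (valid both more
accurate and faster), not a formal test.

## BOLD simulator

The HRF is a double gamma (shapes 6 and 16, ratio 1/6), peak-normalized to
1 and peaking near 5 s.  Events enter as impulses on a 50 ms grid convolved
with this kernel, so an isolated event of amplitude *a* evokes a response
peaking at *a* — GLM betas read directly in percent signal change (PSC).

Ground truth per session: contralateral stimulus responses straddle a base
of 0.8 PSC by ±δ/2 (valid/invalid), ipsilateral responses are 0.4 PSC with
no validity effect, cue-only responses are lateralized, blank trials carry
response-cue activity only.  δ follows a **modulation profile** over
hierarchy rank r = 1…6: `increasing` (δ = 0.05·r), `flat` (δ = 0.15) or
`null` (δ = 0).  The default four-regime assignment — endogenous-pre
increasing, exogenous-pre flat, endogenous-post flat, exogenous-post null —
is the hypothesis structure the inference stage is meant to distinguish.
"Contralateral" always means opposite the cued location (left cue → right
hemisphere).  Excluded (fixation-break) trials evoke a distinct
eye-movement response class, matching how the GLM models them.

Per ROI/hemisphere, 100 voxels by default (80% stimulus-responsive, desk
scale; tests use fewer), each with a log-normal-free gain ~N(1, 0.1).
Noise is a per-voxel linear drift (uniform slope, ±1 PSC scale over a run)
plus AR(1) noise (ρ = 0.3, marginal SD 0.5 PSC) — the generator must
*produce* slow drift so the high-pass filter has something to remove.
Cohort heterogeneity: each participant carries seeded log-normal factors on
modulation strength (SD 0.2), overall responsiveness (SD 0.1) and
psychophysical σ (SD 0.15), giving the mixed models genuine random variance.

The localizer simulator emits the **fundamental** of the hemodynamic block
response: a raised cosine at the cycle frequency (1/17.5 Hz) delayed by 5 s,
rather than an HRF-convolved boxcar.  The sinusoid fit estimates exactly
this component, so the noiseless unit-coherence property holds exactly, and
the 5 s lag places responsive phases (~1.8 rad) inside the (0, π) selection
window by construction.  Harmonic energy a convolved boxcar would add is a
realism the tests deliberately trade away for an exact oracle.

## Localizer fit and selection

Per voxel, the series is mean-removed and linearly detrended, then the
discrete Fourier component at the stimulus frequency gives amplitude and
phase (of the best-fit cosine at run start, wrapped to [0, 2π); positive =
delayed).  Coherence is the spectral amplitude at the stimulus frequency
divided by the root-sum-of-squares of all non-DC amplitudes — the
traveling-wave convention, equal to the correlation with the best-fit
sinusoid.  Selection keeps voxels with phase strictly in (0, π) and
coherence strictly greater than 0.2; both strict, and both configurable.
Numerical caveat: linearly detrending a finite sample of a pure sinusoid
leaks ~1e-4 relative spectral energy, so exactness tests use
`detrend=False`; the default path is within 1e-3 of the ideal values.
Under serially correlated (AR(1)) noise the null coherence at the — fairly
low — stimulus frequency is inflated relative to the white-noise null; the
false-positive tests therefore compare against the matched empirical null.

## Preprocessing and GLM

Per run: discard the first 8 volumes, convert to PSC about the per-voxel
temporal mean (or an explicit baseline), then project out constant, linear
trend and the DCT basis functions below 0.01 Hz.  The identical projection
is applied to the design-matrix columns (Frisch–Waugh–Lovell), so filtering
is unbiased for the condition betas: on noiseless data with a known
baseline the full pipeline returns ground truth to ~1e-14, and with the
mean-baseline the only distortion is the PSC scale factor
(1 + mean signal/100 ≈ 1.003, i.e. ~0.3% — far below noise).

The design has twelve task regressors — cue side × validity × epoch (8),
cue-only left/right, blank, eye-movement — plus per-run intercepts; with
`correct_only` (the default in the pipeline) incorrect stimulus trials move
to a separate `incorrect` nuisance column rather than being deleted, which
preserves the cue-only/blank baseline structure.  Estimation is OLS on the
ROI- and hemisphere-averaged time course concatenated across runs;
conditions absent from a session are flagged and dropped, remaining rank
deficiency is an error naming the columns.  No prewhitening: AR(1) noise
exists in the simulator, OLS remains unbiased under it, and the bias tests
cover exactly that; efficiency is not claimed.

## AMI and inference

`AMI = (N + c) / mean(V꜀+c, I꜀+c, Vᵢ+c, Iᵢ+c)` with the constant c = 0.2 by
default (condition amplitudes can be negative; the offset keeps every term
positive, and a non-positive offset denominator is an error telling the
user to raise it).  V꜀/I꜀ are epoch-specific; the ipsilateral terms average
the two epochs by default, reflecting their role as the distractor-stimulus
reference (fully epoch-specific ipsilateral terms are a flag).  Two exact
identities are tested: equal amplitudes give AMI = 1 for any constant, and
the four numerator rotations sum to 4.  AMI → 1 monotonically as c grows.
`ami_sensitivity` re-runs the hierarchy regressions over several constants
and reports whether the set of significant conditions is invariant.

Hierarchy ranks are V1=1, V2=2, V3=3, V3A=4, hV4=5, LO1=6.  The ordering
beyond V3 is not settled in the field; the mapping is a configurable input,
and the regression is on the 6 group-mean points, so its slope F-test has
(1, 4) degrees of freedom.  Per-ROI valid > invalid tests are paired
one-tailed t-tests without multiple-comparison correction by default (a
Holm option exists) — matching how such per-ROI tests are conventionally
reported alongside the model-based analyses that carry the main claims.

The mixed models fit the valid−invalid difference on
`rank × attention` (attention coded ±½ so the intercept is the grand mean)
by maximum likelihood, with by-participant random intercepts and
*independent* random slopes for rank and attention (no random interaction,
no slope correlations — the richest structure 5 participants can support).
P-values are likelihood-ratio tests against the model without each term;
t statistics are reported with the observations-minus-fixed-effects df
convention (60 − 4 = 56 for a 5 × 6 × 2 data set).  On non-convergence the
structure simplifies stepwise (random intercepts only, then the zero-
variance OLS limit), each fallback logged and flagged on the result, and a
singular fit is reported rather than hidden.

## Problem sizes

The package's own test and demo configurations run at desk scale by choice:
5 participants, 2–3 runs per session, 8–12 voxels per ROI/hemisphere, 2–6
localizer runs, 200 Monte-Carlo replicates for the GLM bias check and 5
pipeline replicates for the four-regime pattern check.  All sizes are
configuration fields; the statistical structure (exact counterbalancing,
noise spectra, cohort heterogeneity) does not change with scale.

## What passing tests do and do not show

The generator emulates the *structure* of the study — design proportions and
timings, hemodynamics, drift and serial correlation, laterality, cohort
variability — not real data's spatial autocorrelation, motion or
physiological noise, nor uncertainty in ROI boundaries (ROI labels are
inputs).  Recovery results therefore validate the analysis logic
(identifiability, absence of bias, correct inference behavior under known
truth), not robustness to artifacts the generator does not produce.
GLM-level denoising beyond OLS, retinotopic area delineation, eye-trace
processing and B0/motion correction are out of scope.
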