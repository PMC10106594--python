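# Methods

This note documents the models behind `practicescope`, the choices made
where the design was genuinely open, and what the synthetic cohort does
and does not establish about real data.

## Study design being modeled

Pianists perform a short right-hand octave-leap task (default: 16
alternating C4/C5 eighth notes, 5 repetitions, metronome at 90 bpm) at
*baseline*, then practice it freely for as long as they wish, then
perform it again at *acquisition*. State anxiety is rated on an 11-point
VASA scale at four timepoints (pre/post baseline = VASA 1/2, pre/post
acquisition = VASA 3/4) alongside STAI trait/state questionnaires, and a
single-lead ECG is recorded at 1000 Hz. The default note text is a
configurable stand-in with the task's structural properties (two
octave-separated pitch classes, even note values); it is not a
reconstruction of any published score.

## MIDI performance scoring

Assessment streams are split at inter-onset gaps above a threshold
(default 1.0 s, below the typical inter-repetition pause of ~2.2 s).
Because performers occasionally pause for less than the threshold, a
score-aware refinement splits any segment holding at least half a
repetition too many events at its largest internal gap until the
expected repetition count is reached.

Alignment is greedy per repetition: targets take the nearest unmatched
pitch-equal event within half the nominal inter-onset interval. The grid
anchor is chosen among pitch-compatible pairings of the first three
events/targets by maximal match count (then minimal total deviation), so
a missed or extra opening note cannot derail the grid. On a
metronome-paced alternating-pitch task, same-pitch targets are two IOIs
apart, so tolerance windows never overlap and greedy matching provably
attains the exhaustive minimum-cost optimum; the test suite checks this
against a brute-force oracle on all small perturbed renditions.

Wrong notes are events left unmatched (out-of-set pitches and duplicate
strikes alike); missed notes are unmatched targets; surplus segments
beyond the expected repetitions count as wrong. Rhythmic accuracy is the
pooled sample SD (n−1) of IOIs between matched events at *adjacent*
score positions — gaps spanning a missed note and extraneous strikes do
not contribute, since they measure error types already counted.
Loudness homogeneity is the sample SD of all keystroke velocities.
Fewer than two IOIs/velocities yields NaN (flagged missing), never zero.
Practice time is the MIDI span (last minus first onset) in minutes.

## ECG processing

Zero-phase 4th-order Butterworth low-pass at 30 Hz; R peaks as local
maxima above a blockwise threshold `median + 3·1.4826·MAD` (2 s blocks,
interpolated across block centers) with a 250 ms refractory period, an
amplitude-consistency check (a candidate must reach half the rolling
median candidate amplitude, the classic signal-vs-noise-peak rule) and
parabolic sub-sample peak refinement. RR intervals implying HR outside
25–200 bpm are rejected; instantaneous HR (60/RR at the closing beat) is
resampled at 4 Hz (cubic spline, configurable to linear). Markers:
mean of the 4 Hz series (bpm), CVRR = sample SD(RR)/mean(RR)·100 (%),
and slope HR = OLS slope of the 4 Hz series on time (bpm/min). Spectral
and nonlinear HRV are deliberately out of scope: the recordings modeled
here are a few minutes long.

## Quality composite

The four assessment parameters, pooled over baseline and acquisition (a
single scale must span both phases for change analysis), are
standardized and the first principal component of their correlation
matrix extracted. Loadings are `eigvec·sqrt(eigenvalue)`, oriented so
error-type loadings are positive; indicators with |loading| < 0.4 (the
usual salience convention) are dropped and the component refitted once.
An indicator with more than 80% of observations at its minimum is
flagged ceiling-limited. The score is the loading-weighted sum of
standardized retained indicators — an inverted scale (low = good). The
pipeline divides by the first eigenvalue (the composite's analytic SD),
so model coefficients are in score-SD units; the raw weighted sum is
available via `unit_variance=False`. A principal component rather than
a single-factor model is the default; the two differ negligibly for
three indicators with one dominant dimension.

## Bayesian mixed-effects learning model

For performer *i* and occasion *j* (baseline: t=0; acquisition:
t = minutes practiced):

    y_ij = β0 + β_t t_ij + β_a a_i + β_ta t_ij a_i + b0_i + b1_i t_ij + ε_ij

with correlated `(b0, b1) ~ N(0, Ψ)` and `ε ~ N(0, σ²)`; the anxiety
measure `a` is standardized across participants. The random effects are
integrated out analytically (each performer contributes a bivariate
normal likelihood), leaving 8 parameters sampled by emcee's
affine-invariant ensemble (default 24 walkers, 1500 steps, 500 burn-in;
fixed seed → identical posteriors). Priors, unstated in this design
tradition and therefore chosen weakly informative: `N(0, (2.5·SD_y)²)`
on fixed effects, half-normal `(0, SD_y)` on the three SDs, uniform on
the random-effect correlation. They regularize the random slope, which
two occasions per performer identify only marginally. Marginal /
conditional R² follow the variance-decomposition definition
(fixed-effect variance over total; plus random-effect variance for
conditional), computed per posterior draw. Split-walker R-hat and ESS
are reported; walker ensembles are correlated, so the R-hat here is a
conservative screen rather than an exact independent-chains statistic.
An effect is called meaningful iff its central 95% credible interval
excludes zero. A constant criterion (zero variance) short-circuits to
the exact degenerate fit.

## Latent change score model

Observed `(PERF1, PERF2, VASA1, VASA3, VASA2, VASA4)` are expressed
through six components `(PERF1, VASA1, VASA2, ΔPERF, ΔVASA_pre,
ΔVASA_post)` with unit loadings and unit autoregression (x₂ = x₁ + Δx).
Means are saturated; the free parameters are the component covariance
matrix minus a configurable zero-constraint set. Default constraint:
cov(PERF1, ΔVASA_pre) = 0, giving one over-identifying df — the
substantively weakest link (baseline skill should not shift the
anticipatory-anxiety change beyond what the other paths carry).
Estimation minimizes `F_ML = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p` (BFGS with
the analytic gradient `T'(Σ⁻¹ − Σ⁻¹SΣ⁻¹)T`, smooth eigenvalue penalty
outside the PD cone, Nelder–Mead fallback); `χ² = (n−1)·F_ML`. CFI, TLI
and RFI use the independence baseline (`Σ₀ = diag S`); SRMR is the RMS
of correlation-metric residuals over the 21 unique moments; TLI/RFI are
undefined (NaN) at df = 0 and TLI is capped at 1. RMSEA is deliberately
not reported — it is unstable at small df and n. Derived change-score
correlations get delta-method standard errors from the numeric Hessian
of F_ML (`acov = 2/(n−1)·H⁻¹`) and Wald p-values. No multiple-testing
correction is applied anywhere in the pipeline; reports flag this.

## Synthetic cohort generator

Six latent z-scored traits per participant (trait anxiety, pre-baseline
state anxiety, baseline skill, learning rate, cardiac tone, anxiety
drift) are drawn from a configurable correlation matrix. Defaults:
trait↔state anxiety 0.5, trait anxiety↔skill −0.25, learning
rate↔anxiety drift −0.8 (performers whose anxiety rises over the session
learn least). Baseline "badness" mixes state anxiety (weight =
`effect_anxiety`, default 0.4 — chosen so the anxiety coefficient on the
unit-variance composite lands near the published 0.33–0.48 band) with
skill. Practice lowers badness by
`(effect_time − learning_rate_sd·L)/0.9` per minute (capped at zero:
practice does not worsen playing); 0.9 is the measured composite gain
per latent unit, so `effect_time = −0.05` score units/min reproduces a
realistic learning slope.

Error rates respond *linearly* to badness with a small positive floor
(wrong 3.0 and missed 2.0 per assessment at z = 0, gain 0.6/SD, floor
3%; velocity SD 6.0, gain 0.3/SD). Linearity keeps the composite linear
in the latent trajectory — matching the inferential model's linearity
and yielding a null time×anxiety interaction; the floor produces the
natural ceiling for strong players. Timing jitter (20 ms) deliberately
carries *no* between-person gain: the metronome clamps everyone's
timing, so rhythmic accuracy has no usable between-person signal and
fails composite retention — emulating a ceiling-limited indicator.
Inter-repetition pauses are truncated-normal (M 2.21 s, SD 1.13 s,
min 0.5 s); wrong pitches sit a semitone or tritone off target with
equal probability, guaranteeing off-pitch-set membership.

The four VASA latents: VASA2 mixes baseline anxiety and badness-driven
arousal; both change scores share the anxiety-drift factor
(cor ≈ 0.57), and the post-performance change decreases with baseline
badness (−0.6), so poor starters relax most — together reproducing the
published change-correlation pattern. VASA values discretize a latent
Gaussian (mean 4, SD 2) to integers 0–10; STAI subscales are sums of 20
simulated 4-point items (range 20–80). Practice duration is
`max(2, 26 + 5·anxiety + N(0, 10))` minutes, driven by the standardized
mean of the two pre-practice anxiety latents, giving the published
≈0.4 anxiety↔practice-time correlation; keystroke rate and off-target
fraction vary between participants. ECG is a train of 1 mV Gaussian
R waves (σ = 10 ms) at RR = 60/(HR + drift·t) plus RR noise (30 ms) and
broadband noise at a configurable SNR (default 20 dB; recovery tests
use 10 dB); HR = 72 + 4·anxiety + 6·cardiac tone bpm.

What the generator does *not* emulate: realistic PQRST morphology,
movement artifacts, within-session fatigue or memory consolidation,
ordinal measurement error in STAI items beyond a one-factor structure,
and any nonlinearity of real learning curves beyond the rate cap.
Passing tests therefore show that the pipeline recovers known structure
of this class, not that the published effect sizes would replicate.

## Numerical and testing choices

Problem sizes: population-level checks use 500-participant cohorts
(correlation SE ≈ 0.04); mixed-model recovery uses 200 performers × 200
replicates with a shortened chain (16 walkers, 900 steps) whose coverage
was pilot-checked at 0.96; recovery of the mixed-model coefficients is
assessed on the *mean* posterior estimate across replicates (bias), since
a single replicate's estimate carries sampling error ≈ 0.06 at n = 200;
LCS calibration uses 500 replicates at n = 300. Determinism: every
stochastic path descends from one integer seed via spawned generators;
two identical runs produce byte-identical tables. Known limitations:
the walker-based R-hat is conservative; the LCS delta-method p-values
are asymptotic; CVRR is reported in percent (the dominant convention —
the scale is otherwise arbitrary); and mean HR is the time-domain mean
of the 4 Hz series, which differs from 60/mean(RR) by a Jensen term
that is negligible at physiological variability.
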