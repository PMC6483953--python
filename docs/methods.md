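# Methods

## Signal model and SCR detection

A skin-conductance trace is modelled as

    y(t) = tonic + drift·t + Σ_k a₀·r^k · K(t − t_k − L_k) + ε(t)

where trial k (0-based) starts at onset t_k, L_k is the response latency,
ε is white Gaussian noise, and K is a biexponential (Bateman) kernel
K(t) = e^(−t/τ_d) − e^(−t/τ_r) rescaled to unit peak, which it reaches at
t* = ln(τ_d/τ_r)·τ_rτ_d/(τ_d − τ_r). Defaults τ_r = 0.75 s, τ_d = 2 s are
typical electrodermal morphology values (t* ≈ 1.18 s). Response amplitudes
decay geometrically with ratio r per trial; with deterministic emission the
trials-to-habituation score is then known in closed form — the first k with
a₀·r^k < 0.03 µS — which is what makes end-to-end parameter-recovery tests
exact.

Detection reproduces the classic first-derivative algorithm: the trace is
low-pass filtered (10 Hz, 4th-order Butterworth) and scanned for discrete
derivative sign changes. Filtering is zero-phase (forward–backward,
`sosfiltfilt`) by default so detected event times carry no group delay;
this squares the magnitude response (gain 0.5 rather than 1/√2 at the
cutoff), which is irrelevant to SCRs whose energy sits well below 1 Hz. A
causal single-pass variant is available by flag. For each peak the
algorithm searches backward 4 s for troughs (derivative − → +); when none
exists it accepts "bends", samples with |dy/dt| < 0.001 µS/s — the
quantitative reading we chose for an otherwise undefined notion. Among
candidates it takes the minimum-value one, ties broken toward the latest
(closest to the rise). Amplitude is peak minus trough. The detector is
checked for exact agreement against an independent brute-force
local-extremum scan, and against generator ground truth: on noise-free
traces amplitudes are recovered within 0.4% (the residual is filter
attenuation plus sampling of the kernel maximum), comfortably inside the
5% the recovery tests assert.

## Trial scoring and habituation

An event qualifies for a trial when its response time falls in
[onset + 1 s, onset + 4 s], both bounds inclusive, with amplitude
≥ 0.03 µS. The response time is the trough (onset) time by default; we
read "the response occurred 1–4 s after the stimulus" as a statement about
response onset. Peak-time matching is a flag. When several events qualify,
the largest is kept, since magnitude analyses need one value per trial.
Habituation is scored as the count of trials preceding the first pair of
consecutive response-free trials; when no pair exists the score is the
trial count (15) with a censoring flag — how never-habituating responders
should be coded is genuinely open, so the flag preserves the information.
The non-responder rule defaults to "neither of the first two trials in some
condition holds a qualifying SCR"; the stricter "at least one of the first
two missing" variant is selectable, because the source description is
ambiguous between the two and common practice favours the lenient reading.

Block magnitudes average amplitudes over consecutive 5-trial blocks with
absent trials contributing zero (the magnitude convention; a present-only
amplitude convention is a flag). Baseline skin conductance level is the
plain mean of the last 5 min of a 10-min rest trace, unfiltered —
averaging 300 000 samples is itself a low-pass operation.

## Staircase

One pass descends from 60 dB HL in 5-dB steps to the first "no", then
ascends from one step above that level to the first "yes", which is the
pass threshold; passes repeat until two consecutive agree (each pass
restarting at 60 dB — whether the original procedure restarted is unstated,
and restarting is the conservative reading). A floor at 0 dB (taken as
threshold with a warning) and a ceiling at start + 20 dB (runaway error)
guard pathological observers. For a deterministic step observer with
threshold T the result is exactly 5·⌈T/5⌉.

Simulated observers answer yes with probability
guess + (1 − guess − lapse)·Φ((L − T)/σ), Φ the cumulative normal — the
standard psychometric function; σ = 0 denotes a step observer. For noisy
observers the procedure is biased upward: stopping the descent at the
first "no" and the ascent at the first "yes" concentrates pass thresholds
on the one or two grid levels above T. The per-pass threshold distribution
is exactly computable (products of Bernoulli terms over the finite level
grid), and the repeat-until-agreement distribution follows from a linear
system over the previous pass value; for T = 14, σ = 3 the exact mean
agreed threshold is 18.33 dB with 95.4% of runs agreeing within 6 passes.
The Monte-Carlo tests assert agreement with these exact values rather than
with wishful unbiasedness; estimator bias is provably non-negative when
the guess rate is zero.

## Statistics

Normality screening standardizes bias-corrected sample skewness G₁ and
excess kurtosis G₂ by their exact small-sample standard errors
(SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3))), SE_kurt = 2·SE_skew·√((n²−1)/((n−3)(n+5))));
|z| > 1.96 fails the screen (conventional cutoff). Failing variables try a
log transform (strictly positive data) then square root, keeping a
transform only if it improves the worst |z|; rating scales are declared
ordinal, never transformed, and handled by Spearman correlations.

Outliers beyond Q1 − 3·IQR and Q3 + 3·IQR (type-7 quartiles; fence
positions depend on the quartile rule, hence the documented choice) are
replaced by the nearest non-outlier value ± one measurement unit — 1 for
questionnaire sums, 0.1 for physiological means by default. Anchoring the
upper fence at Q3 is the standard form; a strict mode anchoring it at Q1
exists because the source rule's wording literally says so and we presume
a typo. Winsorization so defined never reorders non-outlier points.

Two-group comparisons are one-way ANOVAs (F = t² in the two-group case — a
property test), with Cohen's d = (m₂ − m₁)/s_pooled; the sign convention
(comparison group minus clinical group) is fixed to match the descriptive
tables the defaults emulate. Bonferroni levels are α/m, reported at two
significant figures half-up (0.05/11 → 0.0045, 0.05/4 → 0.013). The
block-slope analysis is a mixed-design repeated-measures ANOVA (3 blocks
within × 2 groups between) computed by `pingouin.mixed_anova` and
cross-checked in the tests against a hand-written textbook sums-of-squares
partition. Bayes factors are reported as "not computed" placeholders.

## Synthetic cohorts

Group defaults mirror the descriptive tables of the study design the
package emulates: questionnaire scores 35.61 (8.1) vs 24.94 (6.0)
(pooled-SD d ≈ −1.49), tone thresholds 15.45 (5.2) vs 13.87 (4.6), tonic
SCL 32.31 (4.2) vs 31.16 (3.0) µS, rating means/spreads per the published
rows, and non-responder fractions 7/33 and 4/31 (non-responders emit no
SCRs). SCR amplitude a₀ ~ N(0.5, 0.15) µS, decay ratio r ~ N(0.73, 0.06)
(clipped to (0,1]); 0.73 makes the analytic noise-free habituation score 9,
matching the reported group means of ~9.4 trials. The siren condition
differs only by a 0.92 decay-ratio scale, reproducing its faster
habituation. Latency is 1.8 ± 0.3 s (the centre of the 1–4 s scoring
window; the population value is unknown, this is a convention). Tonic
drift is 0.0005 µS/s (≈ 0.03 µS/min) and noise SD 0.01 µS. The
arousal–questionnaire rank correlation (target 0.61) is induced by a
shared standard-normal latent per participant with Pearson loading
2·sin(πρ_s/6), the exact conversion for bivariate normal marginals. A
single master seed spawns per-participant `SeedSequence` substreams, so
any row regenerates independently.

## What the synthetic data do and do not show

The generator produces traces the scoring criteria can score, with exact
ground truth — which is what the tests need. It does not emulate motion
artifacts, electrode drift nonlinearity, spontaneous (non-specific) SCRs as
a separate process, overlapping responses at short ISIs, or acoustic
differences between tone and siren. Two behaviours worth knowing: (i) the
pooled arousal–questionnaire correlation in a two-group cohort exceeds the
within-group target when the group means differ (a mixture effect, not an
error), so the convergence test uses identical group specs; (ii) with
trough-based window matching, measurement noise drags the detected trough
(the windowed minimum) earlier than the true response onset, so some true
responses fail the 1–4 s check — at default noise about 14% of participants
are misclassified relative to generator ground truth, inflating the
realized non-responder rate above the generated fraction. That is a real
fragility of onset-based scoring, not of the implementation; peak-based
matching avoids it at the cost of a different window meaning.

## Problem sizes

The analysis drivers run the full 64-participant cohort at the protocol's
1000 S/s (about 15 s end to end). Unit and property tests use 100–250 S/s
traces and smaller cohorts, which the filter and detector handle
identically as long as the cutoff stays below Nyquist; the acceptance
script uses 200 randomized 10-s traces for the oracle check, all 2¹⁵
presence sequences, a 120-point threshold grid, and 500 null cohorts for
type-I calibration.
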