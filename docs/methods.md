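# Methods

## Scope and model

`sleepreg` implements the standard analysis chain for multi-day wrist
actigraphy at 30-s epochs: activity-count sleep/wake scoring, the Sleep
Regularity Index (SRI) with recording-level validity screening, derived night
metrics, and the two-group statistical stage. It also ships a synthetic
cohort generator whose ground truth makes the whole chain testable.

## Sleep/wake scoring

The scorer is the weighted-moving-window family: the score of epoch *t* is a
scale factor times a weighted sum of activity counts in a window around *t*,
and the epoch is sleep when the score is below 1.0. The UCSD variant is
selected by its taps and a scale factor of 0.10 (the default here). Because
published tap sets differ between devices and epoch lengths, taps live in
`ScoringConfig` as data: the default is the classic seven-minute window
(four minutes of history, the scored minute, two minutes of lookahead)
resampled to 30-s epochs by splitting each one-minute weight over its two
taps. Out-of-window and non-worn taps contribute zero, so edge epochs of
week-long recordings are retained. No result in the test suite depends on
the specific taps, only on the structural contract (monotonicity in counts,
threshold semantics).

**Webster rescoring.** The rules are applied to the scorer's output in a
fixed order, after-wake rules first with the strongest trigger first
(≥15 min → 4 min, ≥10 → 3, ≥4 → 1), then the two sandwich rules (≤6 min
sleep inside ≥10-min wake, ≤10 min inside ≥20-min wake). Rescored epochs
carry an explicit mask and never count toward trigger or flank runs, and
missing epochs break runs. Two consequences are deliberate: exactly one
after-wake rule fires per sleep run (the strongest applicable one, which is
the rules' published intent), and the operation is exactly idempotent — a
naive implementation in which rescored wake extends trigger runs rescans
into the same sleep run on every pass and is not.

**Non-wear.** Maximal zero-count runs of ≥ 90 min (configurable) are marked
non-wear in addition to device flags. Missing epochs are represented
explicitly rather than dropped so day-grid geometry is preserved.

**Sleep periods.** Per calendar night the search window is the diary
interval ± 60 min when present, else the span between evening and morning
event markers, else a fixed 20:00–10:00 nocturnal window; onset/offset are
the first/last sustained (≥ 10 min) sleep runs inside the window. The
fallback order follows the order in which the sources are usually trusted;
tolerance and thresholds are configuration.

## SRI and validity

The SRI compares states exactly 24 h apart across an N×M day grid anchored
at local midnight; partial leading/trailing days are trimmed. Midnight
anchoring (rather than a rolling 24-h anchor from recording start) affects
only the trimming, never the pair alignment, because paired epochs are
always exactly one day apart. Pairs with a missing member are excluded from
numerator and denominator alike (pairwise deletion with renormalisation);
the ≤ 2 h missing-data criterion bounds how much this can matter. Validity
requires ≥ 5 full days and ≤ 2 h missing; the weekend-day rule is a warning
by default and an exclusion under `strict_weekend`, since it is usually
phrased as "ideally". Quintile classes use midpoint-interpolated empirical
quantiles with boundary values assigned to the extreme class; degenerate
(all-equal) cohorts are all "normal", and cohorts under five values are
"unclassified".

## Night metrics

TST and WASO are sleep/wake minutes inside the detected period; efficiency
is TST over time in bed, where time in bed is the diary window when present
and the period duration otherwise. The fragmentation index of commercial
software mixes mobility percentages that are not derivable from binary
states, so two definitions are exposed: the default (wake bouts per hour of
TST, computable from states alone) and a mobility-based alternative
(percent mobile epochs plus percent of immobile bouts ≤ 1 min) when raw
counts are supplied. Neither is asserted as normative. Average sleep per
24 h counts all sleep — nocturnal and naps — over full days.

## Cohort statistics

Welch's t (Welch–Satterthwaite df), Yates-corrected chi-square for 2×2
tables (the uncorrected statistic is a flag away), OLS with Wald-t 95% CIs.
Standardized betas refit on the z-scored response with continuous predictors
z-scored and binary predictors left 0/1 (so a binary standardized beta is a
group contrast in response SDs); this convention is configurable in effect
because the unstandardized fit is always reported alongside. Partial
correlations use the residual-regression method (each variable regressed on
intercept + covariates, residuals correlated, t-test on n − k − 2 df); the
test suite cross-checks it against correlation-matrix inversion and
`pingouin.partial_corr`. All tests are two-sided. ANCOVA assumption checks
(homogeneity-of-slopes interaction F-test, residual normality) are
diagnostics that report, never silent gatekeepers.

The sensitivity power analysis solves for the smallest Cohen's f at which a
noncentral-F test (numerator df = groups − 1, denominator df =
N − groups − covariates) reaches the requested power. Two noncentrality
conventions exist in the literature, λ = f²·N (fixed-effects convention,
default) and λ = f²·(df1 + df2 + 1) (Cohen's tables); both are exposed and
agree to well under 1% at cohort-scale N. The root is bracketed and solved
to a power error below 1e-9. Permutation subsampling refits the group model
on random subsamples of the larger arm, with per-permutation RNG streams
spawned hierarchically from one seed so results are independent of
iteration order.

## Synthetic cohorts

The generator is a clock-gated two-state process, not a circadian
physiology model: a habitual nocturnal window per participant (onset
~23:00 ± 45 min between participants, duration ~480 ± 25 min), nightly
Gaussian jitter of onset and offset with participant-specific SD σ, Poisson
daytime naps (default 1.2/day, mean 70 min, 10:00–18:00), optional non-wear
gaps, zero-inflated low-mean counts in sleep and right-skewed gamma counts
in wake, diary rows equal to true times plus reporting noise, and event
markers with 85% compliance.

Covariate effects on regularity (group −6, age −0.12/yr, female +5, on the
SRI scale, plus N(0, 9) heterogeneity) are injected through the jitter
channel using an analytic map: independent boundary jitter with SD σ costs
`(200/1440)·(4/√π)·σ ≈ 0.3134` SRI units per minute of σ in expectation,
and expected nap minutes cost `(200/1440)·2` SRI units per minute. The map
is inverted per participant to turn a target linear predictor into σ. The
defaults (baseline σ = 120 min at the reference covariates) put cohort SRI
means near 42 (stroke) and 47 (control) with an SD around 14 — the regime
such studies report. The analytic map ignores rare boundary overlaps and
nap collisions, which attenuate realized effects by roughly 10–15% at these
σ levels; the realized effect is therefore measured once from a large
ratio-preserving calibration cohort inside the test suite, and
parameter-recovery checks compare CIs against that realized value, not the
nominal injection.

What the generator does **not** emulate: sleep staging, ultradian structure,
light-driven entrainment, weekday/weekend behavioural differences, or
device-specific count spectra. Passing tests therefore demonstrate that the
pipeline recovers what this generative family encodes — boundary timing
variability, napping, missingness — not that it reproduces any specific
device's classifier.

Two boundary contracts are worth noting. With all irregularity channels off
(zero jitter, no naps, no gaps) the truth grid repeats exactly and the
grid-path SRI is exactly 100; a zero jitter baseline disables the jitter
channel entirely. The full count-scoring path lands just *below* 100 even
then, because the weighted window straddles sleep/wake boundaries whose
random counts move the scored transition by an epoch or two from day to day
— tests assert exactness on the grid path and ≥ 99 on the count path. The
degenerate mode (iid fair-coin states) gives SRI ≈ 0 by construction.

## Numerical and scale choices

Clock times are local and time-zone/DST-free by design. Minute-denominated
rescoring rules convert at 2 epochs/min. scipy's noncentral-F is unreliable
at zero noncentrality, so the power routine falls back to the central F
there. Partial correlations whose residuals are zero up to numerical noise
(a variable exactly linear in its covariates) are reported undefined rather
than spuriously ±1. Parameter-recovery and type-I-error studies run the
statistics stage on SRIs computed from ground-truth grids (200 and 500
cohorts of n = 222), which isolates the quantity under test and keeps the
studies at hundreds of cohorts; the count-scoring path is exercised
end-to-end in dedicated smaller tests.

## Known limitations

The default scorer taps are a canonical stand-in, not a device calibration;
real deployments should drop in the tap set validated for their device. The
fragmentation index is not comparable across its two definitions. Sleep
onset latency is not separated from the nocturnal period. The generator's
questionnaire links (SCI, PHQ-8, SF-SIS vs latent regularity) are linear
with Gaussian noise and exist to give the correlation stage realistic
targets, not to model instrument psychometrics.
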