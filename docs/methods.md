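# Methods

This note documents the models, parameter choices, and numerical
conventions behind `rockpsg`, and states what the synthetic cohorts do
and do not establish about real polysomnography.

## Conventions

All timestamps are seconds from lights out; all epoch indices are
0-based 20-s scoring epochs relative to lights out; analysis windows are
half-open epoch ranges, so "first 2 hours" is epochs [0, 360).  Sleep
onset is defined as the first epoch scored N2, consistently for sleep
latency, SWS/REM latencies, WASO, stage-change counting, and the C1
stimulation off-rule.  WASO counts W epochs strictly after the
sleep-onset epoch; wake before onset contributes to latency only.
Metrics whose defining event is absent (no N2, no REM, ...) are
*undefined* and reported as NaN, never as zero.  The C1 off-rule stops
stimulation at the *end* of the third epoch of the first run of three
consecutive N2 epochs; the run length is exposed as a parameter.

## Spectral analysis

Each 20-s epoch is the average of five non-overlapping 4-s Hann
periodograms (frequency resolution 0.25 Hz), computed with Welch's
method in density scaling.  With this normalization the band-integrated
power of a bin-centered sinusoid of amplitude a equals a²/2 — its
mean-square value — so band powers are absolute µV² quantities.  Band
edges are inclusive on both sides: the 4.5-Hz bin belongs to both delta
and theta, exactly as the bands are tabulated; the alpha band (9–15 Hz)
fully contains sigma (11–15 Hz) and both are integrated independently.
"NREM" for spectra and event densities means stages N1, N2 and N3
(parameterized).  Artifact-flagged epochs never enter any NREM mean;
artifact detection itself is out of scope and flags are taken as input.
The delta build-up curve covers the 180 epochs after sleep onset with a
centered 7-epoch moving average, shrinking the window at the edges.

## Spindle detection

The sigma filter is an 8th-order zero-phase Butterworth band-pass whose
*realized* −3 dB points (of the forward–backward magnitude response,
|H|²) are tuned numerically onto 12 and 15 Hz; a single-pass design at
those corners would land the zero-phase half-power points too far
inside the band.  The realized corners are verified by frequency-domain
probing to within ±0.2 Hz in the test suite.

Thresholds derive from the mean rectified amplitude m of the filtered
signal over all artifact-free NREM *samples* (one grand mean, not a
mean of epoch means): lower = 2 m, upper = 6 m.  Detection operates on
the **peak envelope** of the rectified signal (linear interpolation
between its local maxima).  The raw rectified trace touches zero twice
per sigma cycle, so thresholding it directly would fragment every
spindle into sub-cycle slivers shorter than any plausible duration
bound; the envelope restores the intended amplitude semantics while the
thresholds themselves remain estimated from the raw rectified mean.
Events are envelope excursions above the upper threshold, widened to
the surrounding lower-threshold crossings; excursions sharing a
lower-threshold extent merge into one event (flag-controlled), events
outside 0.3–3.0 s are discarded (both bounds configurable), and an
event belongs to the epoch containing its onset, which must be
artifact-free NREM.  Because both thresholds are proportional to the
signal's own mean amplitude, the detected event set is exactly
invariant under positive rescaling of the input.

## Slow-oscillation detection

The F3–A2 signal is decimated to 128 Hz (anti-aliased FIR, zero-phase)
and filtered forward–backward by a 3rd-order Chebyshev II high-pass
(−3 dB at 0.4 Hz) and a 6th-order Chebyshev II low-pass (−3 dB at
2.3 Hz).  Chebyshev II fixes only the stop-band ripple, and no ripple
value is pinned by the −3 dB observables; 20 dB is used for both
filters and the design corner is tuned numerically until the realized
zero-phase −3 dB point lands on the target (verified within ±0.05 Hz /
±0.1 Hz).  Half-waves are segments between consecutive zero crossings
(sign change between samples; exact zeros inherit the preceding sign;
segments shorter than two samples are degenerate and dropped).  A
segment counts as a slow oscillation when its unsigned peak reaches
37.5 µV; positive and negative half-waves are counted together in the
combined count, with per-polarity tallies also available.  Crossing
times are sub-sample interpolated for reporting only.  Whether counts
are restricted to artifact-free NREM (default, matching the spindle
convention) or all sleep is a flag.

## Statistics

Every EEG feature is compared across conditions with a two-way ANOVA
without interaction — condition fixed, subject as blocking factor — on
complete blocks (subjects with missing cells are removed listwise,
never imputed; balanced blocks make Type I/III sums of squares
coincide).  Post hoc LSD tests are pairwise t statistics using the
omnibus residual mean square and its degrees of freedom with **no**
multiplicity adjustment: that is the definition of Fisher's LSD, not a
missing correction.  Effect sizes are pooled-SD Cohen's d,
d = |m₂ − m₁| / √((s₁² + s₂²)/2), reported raw and multiplied by
Hedges' J = 1 − 3/(4(2n−2) − 1).  This formula reproduces six of the
eight published example effect sizes exactly at two decimals
(0.24, 0.21, 0.23, 0.01, 0.18, 0.18); the remaining two (0.29, 0.08)
compute to 0.31 and 0.09 from the tabulated means and SDs under every
standard two-sample formula and were likely derived from paired
subject-level data unavailable here — they are documented, not targets.
Word-pair measures use the same block ANOVA on non-excluded subjects
with Tukey-adjusted (studentized-range) pairwise p-values plus paired
delayed-vs-immediate contrasts per condition; a full mixed-model
machinery with Kenward–Roger degrees of freedom is deliberately not
reproduced — on balanced complete blocks the block ANOVA is the exact
special case.  Correlations between spindle features and the four
recall measures are two-tailed Pearson coefficients flagged at the
Bonferroni-corrected α = 0.05/4 = 0.0125.

## Synthetic cohorts

Hypnograms are homogeneous per-epoch Markov chains over
{W, N1, N2, N3, REM} starting in W.  The default transition matrix was
calibrated once against the published baseline architecture scale and
then frozen: over 100 simulated baseline nights it yields mean sleep
latency ≈ 7–8 min, sleep efficiency ≈ 96%, N2 ≈ 250 min, N3 ≈ 95 min.
A homogeneous chain has no ultradian cycle, so REM latency is far
shorter than the ~67 min of real nights and WASO runs somewhat high;
both are accepted limitations of the generator, not of the metrics
computed from it.  Artifact flags are i.i.d. Bernoulli (default rate
0.028 ≈ 40 flagged epochs per 8-h night).

EEG is 1/f^β Gaussian noise shaped in the frequency domain (β = 1.0 in
wake/REM, 1.5 in NREM; per-stage RMS defaults W 10, N1 12, N2 15,
N3 25, REM 10 µV), giving deeper stages more low-frequency power.
Injected events with exact ground truth: spindles (Hann-windowed
12.5–14.5 Hz bursts, 0.5–1.5 s, default 20–40 µV) at 2.2 events per
NREM epoch; slow oscillations as single 0.5–1.5 Hz sine cycles — two
half-waves per cycle — at 6.3 half-waves per epoch, with amplitudes
deliberately spanning the 37.5 µV criterion (default 30–75 µV) so that
detector counts fall below injected counts by construction; a 10-Hz,
8-µV alpha tone in wake.  Events are placed at random offsets within
their epoch with a minimum 0.5-s gap and no overlap (crowded epochs
silently drop events, which the ground truth reflects).  Spindles ride
on C3 (0.3× on F3), slow oscillations on F3 (0.5× on C3), and A2
carries 2 µV independent mastoid noise, so the C3−A2 / F3−A2
derivations recover the injected signals.

Condition effects are additive shifts applied only while stimulation is
on (C2: first 360 epochs; C1: until the first 3-consecutive-N2 run):
+0.015 on the N2 dwell probability (renormalizing the row) and a
configurable spindle-density shift defaulting to 0 — matching the
direction of the reported findings, where the spindle-count increase
under C2 was carried by prolonged N2 rather than higher density.
Setting both to zero gives a null simulation.

Word-pair scores are drawn on the half-point grid: immediate recall
N(26, 5) (optionally correlated with a supplied spindle feature through
a Gaussian copula), overnight improvement N(6.7, 3.7) added on top, and
a configurable fraction of subjects forced to the 40-point ceiling
(everyone else capped at 39.5 so forced counts are exact).

All randomness flows from one seed through SHA-256-derived named
streams keyed by (purpose, subject, condition): identical seeds are
bit-identical and adding subjects never perturbs existing nights.

**What passing tests show — and don't.**  Detector recovery
(sensitivity and precision ≥ 0.9) is demonstrated on high-SNR,
non-overlapping injected events over stationary backgrounds; real EEG
has spindle/SO overlap, non-stationary amplitude, arousals, and
artifacts that the generator does not emulate, so recovery rates do not
transfer to real recordings.  Likewise the band-power calibration
checks normalization and masking, not biological spectra.

## Problem sizes and numerical choices

The test suite and examples use scaled-down instances chosen as the
package's own defaults for fast, deterministic verification: 1-h nights
at 128 Hz for detector recovery, 100 nights for the efficiency
calibration, 1000 replicates for the null-calibration of the omnibus
test and the Bonferroni flag, and 1000 random instances for the
brute-force oracle comparisons.  Filter tuning iterates to 10⁻⁴ Hz
(sigma) / 10⁻⁵ Hz (slow-wave) on the realized −3 dB points and caches
per sampling rate.  EDF export uses 16-bit quantization over the
per-channel data range with 1-s records; round trips are exact to one
quantization step and are additionally cross-checked against an
independent EDF reader.
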