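# Methods

This package re-implements, as tested library code, a sleep-stage-resolved
analysis of pallidal local field potentials (LFP) in Parkinson's disease
(PD) versus dystonia: staging consensus, sleep-quality metrics, normalized
spectral and beta-burst quantification, a threshold-based adaptive deep
brain stimulation (aDBS) controller simulation, and nonparametric cohort
statistics. Because the underlying patient recordings are access-restricted,
everything runs on a synthetic polysomnography + LFP generator with full
ground truth, plus the published per-patient clinical table, which is
bundled as a fixture.

## Staging and consensus

Sleep stages use the AASM 5-class vocabulary (W, N1, N2, N3, R) in fixed
30-s epochs; epoch k covers `[30k, 30(k+1))` seconds (half-open, 0-based).
Two hypnograms per night are combined by the consensus rule: an epoch is
kept only when both scorers agree; disagreeing epochs are marked EXCLUDED
and dropped from all signal analyses. A night with fewer than 5 agreeing REM
epochs is analysed for wake and NREM only; all REM-dependent outputs are
reported missing, not zero. N1/N2/N3 pool into the NREM view for the main
analyses; substages are available behind a toggle. A trailing partial signal
epoch is discarded with a warning.

Sleep parameters (TTB, TST, WASO, SL, RSL, stage percentages, SE,
fragmentation, RSWA) are computed from the *primary* hypnogram, not the
consensus: the parameters describe the scored night, while the consensus
only gates which epochs enter the LFP analyses. This matters for the
fragmentation count, where EXCLUDED epochs would artificially break long
wake runs. REM eligibility still uses the consensus.

## Sleep metrics

* TTB is the hypnogram span; TST the non-wake time; SL the time to the first
  sleep epoch; RSL the time to the first REM epoch; WASO the wake time after
  sleep onset; SE = 100·TST/TTB. Stage percentages are relative to TST and
  sum to 100. Nights without sleep (or REM) report SL (or RSL) as missing.
* A fragmentation is a maximal run of W epochs strictly longer than 120 s
  ("more than 2 minutes") that is immediately preceded *and* followed by
  sleep — wake before sleep onset and terminal wake are latency/terminal
  wake, not interruptions. A run of exactly 120 s does not count; the
  boundary is tested.
* RSWA (REM sleep without atonia): the chin EMG is bandpassed 10–70 Hz
  (order-4 Butterworth, zero-phase), variance is computed on mean-removed
  non-overlapping 3-s segments, and a REM segment is flagged when its
  variance exceeds twice the 5th percentile of the NREM segment-variance
  distribution. The NREM reference uses 3-s segments by default (the
  literature specifies 3-s segmentation only for REM; the symmetric choice
  keeps units comparable) — a config switch selects whole-epoch references
  instead. The statistic is scale-invariant by construction.

## Spectral analysis

Signals are notch filtered at the mains frequency and its harmonics
(band-stop Butterworth, order 3, 4 Hz bandwidth, applied forward–backward
for zero phase) and resampled to 500 Hz (polyphase, anti-aliased). Power
spectra use the Welch periodogram with 512-point Hann segments and 50%
overlap, giving a 500/512 ≈ 0.977 Hz grid, restricted to 2–80 Hz. Each
epoch's PSD is normalized to percent of its total power over 2–45 and
55–80 Hz (the notch region is excluded from the normalizer); normalizing an
already-normalized spectrum is rejected rather than silently reapplied.
Normalization is applied per epoch before stage averaging so that epochs
remain comparable under non-stationary gain; stage averages are arithmetic
means in linear power (a log-mean switch exists).

Band powers sum the bins whose centers fall in the band: theta 4–12 Hz,
beta 13–30 Hz, low beta 13–20 Hz (20 Hz exclusive), high beta 20–30 Hz —
the shared 20 Hz bin belongs to high beta only, so the sub-bands partition
beta exactly.

The aperiodic (1/f-like) component is fit as a knee-free power law in
log10-log10 space over 2–45 Hz with an iterative robust scheme: fit a line,
mask points more than 3 MADs *above* the fit (oscillatory peaks), refit.
The periodic residual is log-power minus the fit. This is a deliberately
simple spectral parameterization, validated on synthetic power laws
(exponent recovered within ±0.05 noiselessly, ±0.2 under realistic
estimation noise, peaks isolated in the residual). When several bipolar
contacts are candidates, the channel with the highest awake normalized beta
is selected; exact ties resolve to the lexicographically first name.

## Beta bursts

Burst analysis runs at 200 Hz on 10-cycle complex Morlet envelopes (MNE
backend) at 18 integer center frequencies, 13–30 Hz. Envelopes are z-scored
per recording (a per-stage switch exists); the detection threshold is the
75th percentile of the pooled z-amplitude distribution across all
recordings in the cohort run, per frequency bin. A burst is a maximal
supra-threshold run lasting at least 0.1 s (20 samples, inclusive); its
amplitude is the area between envelope and threshold (z·s), and density is
bursts per second. Durations are histogrammed into six 0.15-s bins from
0.10 s with an open last bin (> 0.85 s). Final statistics are the
unweighted mean over the 18 per-frequency iterations.

Note a subtle point: raising the threshold monotonically reduces total
supra-threshold time and total burst time, but not necessarily the burst
*count* — one long run can split into several counted runs. The tests
assert the time monotonicities only.

## Adaptive stimulation simulation

Time-resolved beta is computed in 5-s sliding windows stepped by 0.5 s
(left-aligned, full support; the last partial window is dropped), each
window Welch-transformed and percent-power normalized, then smoothed with a
Gaussian kernel of sigma = 5 series samples (2.5 s) — sigma is interpreted
in biomarker-series samples, the common convention for series-level
smoothing. The trigger threshold is the 50th percentile of the awake
series. The controller ramps between 0 and 3 V at 0.4 V/s: toward 3 V
while beta exceeds the threshold, toward 0 V otherwise, clipped at the
borders; a full 0→3 V ramp takes exactly 7.5 s. Stimulation counts as ON
while the amplitude is above 0 V (a "beta above threshold" alternative is a
config flag); ON time per stage is the percentage of 0.5-s steps inside
that stage's epochs. Quarter analyses split a stage's steps by cumulative
stage time into four contiguous quarters and compare them with the Friedman
test.

## Statistics

All tests are two-sided. Mann–Whitney U uses exact enumeration when the
combined sample is ≤ 12 and tie-free, and the tie-corrected normal
approximation otherwise; it is verified against an exhaustive-enumeration
oracle at small n. Spearman correlation is Pearson on mid-ranks (asserted
as an identity on tied data). Kruskal–Wallis and Friedman are
tie-corrected; a constant block matrix has no rank variation and reports
statistic 0, P = 1 by convention. Bonferroni correction is min(1, m·p) and
is exposed with configurable m; group comparisons of sleep parameters are
reported uncorrected, matching common practice for descriptive tables.
Medians and IQRs use linear-interpolation (type-7) quantiles; published
IQRs depend on an unstated quantile convention, so only medians are
asserted. One published inconsistency is preserved rather than resolved:
the PD PSQI values in the bundled per-patient table give a median of 12.5,
while the published summary row prints 15.0; the same per-patient values do
reproduce the published PSQI–RBDSQ correlation (rho = 0.821, P = 0.001)
exactly, so the fixture stores the per-patient values untouched.

## The synthetic generator

The generator's job is controllability, not biophysical realism: every
downstream estimator must be checkable against known injected truth.

* **Hypnograms** are semi-Markov chains over the five stages with
  exponential bout dwells quantized to 30-s epochs. The night starts with a
  deterministic wake run (the target sleep latency). Chain-generated wake
  bouts are capped at 120 s (brief arousals); long (> 2 min) wake
  intrusions are injected separately at a Poisson-distributed count,
  overwriting sleep segments flanked by sleep, so the injected count *is*
  the ground-truth fragmentation count. Profile defaults emulate the two
  groups' published architecture (PD-like: 494-min nights, 50-min latency,
  ~14 intrusions; dystonia-like: 509-min nights, 14-min latency, ~9
  intrusions).
* **LFP** is 1/f-shaped Gaussian noise (spectrally shaped in the frequency
  domain, rescaled so the offset parameter sets total background power)
  plus a stage-gated theta sinusoid and Hann-windowed sinusoid packets at a
  beta carrier frequency. The Hann packet has an analytically known
  envelope, which the Morlet-envelope tests exploit. PD-like profiles have
  denser, longer bursts in every stage and less theta; dystonia-like the
  reverse. Burst rate and amplitude also scale with a per-subject level
  used to inject clinical correlations.
* **EMG** is 10–70 Hz bandlimited noise with exact per-3-s-segment
  variances per stage (wake high, NREM intermediate, REM atonia low). A
  target fraction of REM segments is raised to four times the mean NREM
  variance — comfortably above the atonia criterion — and logged; the RSWA
  estimator recovers the target fraction to within sampling error.
* **Cohorts** add a simulated second scorer (independent per-epoch
  relabelling, default rate 0.144, chosen to emulate the published 85.6%
  agreement as a dataset property) and clinical covariates: in the PD-like
  group, PSQI = 10 + 6·log2(s) + noise (clipped to 0–21) for beta level s,
  RBDSQ a noisy monotone function of PSQI, and the off-medication motor
  score tracking s as well; the dystonia-like group's PSQI has no link.
  This makes the published qualitative findings (elevated beta across
  stages, PSQI↔NREM-beta correlation, awake-calibrated aDBS under-dosing
  sleep) recoverable *by construction* — passing tests validate the
  estimators, not the clinical claims.

What the generator does **not** model: sleep microstructure (spindles,
K-complexes), artifacts, cardiac/movement contamination, multi-channel
spatial structure, or REM twitch phenomenology beyond an optional variance
transient. Passing tests therefore say nothing about automatic staging or
artifact robustness on real recordings.

## Problem sizes and numerical choices

Repeated-seed checks run on deliberately small problems chosen so the whole
suite completes quickly while estimator variance stays well below the
tested tolerances: RSWA recovery on a 30-min mixed-architecture night (20
seeds), burst-duration group ranking on 8-min NREM recordings (50 seeds),
the PSQI↔beta power check on 12-subject, 10-min-night cohorts (50 seeds),
and the null calibration on 20-subject, 5-min-night cohorts (200 seeds,
Kolmogorov–Smirnov test against uniform at alpha = 0.01). The analysis
scripts use 30-min nights for signal-heavy steps and full-length (~8-h)
nights for hypnogram/EMG-only steps. Published group-level
electrophysiology numbers (e.g. 4.98%/30.00% stimulation-on time, the
85.6% agreement, Table-2 medians) depend on the restricted recordings and
are treated as directional references only.

Numerical details: all randomness flows through one seeded numpy Generator
per entry point (bit-identical reruns); percent-power normalization sums to
100 exactly by construction; filters are zero-phase (sosfiltfilt) to avoid
envelope distortion; resampling is polyphase with rational rate ratios;
degenerate inputs (constant envelopes, zero power, empty groups, zero rank
variance) raise informative errors rather than producing NaNs silently.
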