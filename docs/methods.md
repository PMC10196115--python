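# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `painlfp`, and what the synthetic-data tests do and do not establish
about real recordings.

## The synthetic bilateral-LFP model

Each trial is a 9-s epoch (4 s pre-, 5 s post-onset) of two hemisphere
signals at 1 kHz, built additively from four ingredients.

**Background.** Gaussian noise spectrally shaped to a 1/f^α density
(α = 1 by default) band-limited to 3–350 Hz and normalized so the expected
variance equals `noise_sd`².  The spectrum is partitioned into seven
contiguous segments — the five canonical analysis bands (theta 4–8, alpha
8–12, beta 12–30, low-gamma 30–80, high-gamma 80–120 Hz) plus the flanks
3–4 and 120–350 Hz — each synthesized independently in the frequency
domain.  Because the segments partition the spectrum, their sum reproduces
the 1/f background exactly, while giving the generator an exact handle on
per-band power: multiplying a segment by a gain g(t) scales that band's
power by g² up to the leakage of the slowly varying envelope.

**Band modulation.** After a stimulus each band's amplitude is multiplied
by `early_gain` on [0, 0.5] s, then by `late_gain` relaxing linearly to 1
at `recovery_time_s`.  Defaults for noxious (HN) trials: all low bands
×1.5 early then ×0.6 late, both gamma bands ×2.0 early then ×1.4 late,
recovery at 4 s — the transient broadband increase followed by low-band
suppression and sustained gamma elevation that characterizes noxious
mechano-nociceptive ACC responses.  Non-noxious (NN) trials use the same
shape at reduced amplitude (×1.2/×0.85 low bands, ×1.4/×1.15 gamma,
recovery 2.5 s); NS trials are unmodulated.  The gain magnitudes are free
parameters of the emulation; only their directions are empirically
anchored.

**Evoked potentials.** Templates are sums of Gaussian lobes
(polarity, latency, amplitude, FWHM).  Defaults: HN = P1 (+, 92 ms,
1.15 z, 25 ms), N1 (−, 157 ms, 1.17 z, 25 ms), P2 (+, 235 ms, 0.45 z,
40 ms); NN = P1 (+, 61 ms, 0.21 z, 25 ms), N1 (−, 157 ms, 0.18 z, 25 ms);
NS has no evoked response.  The rendered waveform is band-limited to the
3–350 Hz recording band, and lobe centers/amplitudes are corrected by a
fixed-point iteration so that each component's extremum lands exactly on
the configured latency sample with the configured amplitude *after*
band-limiting.  This makes preprocessing approximately idempotent on
generated data and makes the configured values the true recovery targets.
Templates whose lobes overlap so strongly that the iteration cannot place
the extrema raise a template-infeasibility error.

Amplitudes are interpreted as the *bilateral mean*: with ipsi:contra ratio
g (`ipsi_gain`, default 1.3 for HN), the ipsilateral copy is scaled by
2g/(1+g) and the contralateral by 2/(1+g), so the hemisphere-pooled EP
keeps the configured amplitudes while realizing the ratio.  A per-subject
multiplicative effect (sd 0.05) adds between-animal variability.

**Interhemispheric coupling.** Each spectral segment is mixed as
`c(t)·shared + (1−c(t))·independent`, variance-renormalized, with
`shared_fraction` c = 0.7 at baseline (sliding-window correlation ≈ 0.84).
After a stimulus, c drops by a relative `post_stim_dip_depth` (0.35) at
0.5 s and relaxes linearly over `dip_duration_s` (3.5 s), ending at 4 s —
the post-stimulus desynchronization window.  The dip is scaled per class
(HN 1.0, NN 0.25, NS 0) so that only noxious trials show a statistically
robust dip.  `baseline_plv_target` is carried as documentation; the
mechanism parameter is `shared_fraction`.

**Nuisance structure.** Per-session multiplicative gains (default 1.0,
1.15, 0.9, 1.05) emulate day-to-day drift and are removed by per-session
z-scoring.  Motion artifacts are injected into ⌊rate·n⌋ trials (default
rate 2%) as a contiguous oscillatory Gaussian burst of amplitude 20 sd
covering 18% of the epoch in one hemisphere.  The burst is oscillatory
rather than a flat offset deliberately: a flat excursion of that extent
*masks* the Grubbs statistic (the contaminated sd grows faster than the
maximum deviation), whereas the heavy-spread burst keeps G above its
critical value throughout the iterative removal, so the prescribed
detector can find what the generator plants.  Withdrawal latencies for HN
trials are N(225, 10²) ms, truncated at zero; the 10-ms figure is used as
the per-trial spread.

**Reproducibility.** One root `SeedSequence` per trial set; every trial
draws from a child stream keyed by its global index, so output is
byte-identical for a fixed config and early trials do not change when the
trial count grows.

What the generator does *not* emulate: non-Gaussian and non-stationary
background dynamics, spike-band structure, cross-frequency coupling,
latency jitter of single-trial EPs, electrode drift within a session, and
any real biophysics.  Passing recovery tests therefore demonstrates the
*estimators* are correct and calibrated on data satisfying their
assumptions — not that real ACC recordings satisfy those assumptions.

## Preprocessing

Filters are applied forward–backward (zero phase), so effective attenuation
is the squared single-pass Butterworth magnitude and EP latencies are not
biased; a causal filter would shift P1/N1 by tens of ms.  Defaults: 4th
order band-pass 3–350 Hz; notch at 50 Hz mains and harmonics up to 350 Hz
with quality factor 30.  Z-scoring uses the sample (n−1) sd and is applied
per channel per session (statistics pooled over all trials of the
session), before hemisphere averaging.  Grubbs outlier detection runs per
trial and hemisphere on the filtered signal, two-sided at α = 0.05,
iteratively removing one sample while G = max|x−x̄|/s exceeds the critical
value; trials with > 10% flagged samples in either hemisphere are
rejected.  Within `reject_trials` the iteration is capped at twice the
threshold fraction, since only the threshold crossing matters.  Sample
indexing is 0-based with half-open [start, stop) windows and time 0 at
stimulus onset.

Re-running the full chain on its own output changes signals only through
renewed band-edge attenuation (a few percent of RMS near 3–6 Hz and
350 Hz); z-scoring is exactly idempotent and EP extrema do not move.  An
exact fixed point is not attainable with Butterworth responses and is not
claimed.

## Evoked potentials

The EP is the stimulus-locked trial average (SEM across trials).  For
parametrization the average is first smoothed with a Savitzky–Golay filter
(25 ms window, order 3), which attenuates the default template peaks by
< 2% while suppressing residual averaging noise; P1 is then the largest
positive value in the [20, 130] ms window (earliest sample on ties), N1
the most negative value in [80, 260] ms after P1, and P2 the earliest
positive local maximum after N1 exceeding 3× the mean baseline SEM.  The
global-extremum rule is preferred over "earliest local maximum" because on
noisy averages the earliest-local-max rule locks onto noise wiggles; the
two coincide on clean single-peak windows.  The search windows bracket
both classes' latencies with margin and are configurable.

Single-trial parameters (for dispersion tables and paired tests) are
extracted with guidance from the class-average EP: each trial is smoothed
(20-ms moving average), the amplitude is read at the reference latency
(unbiased under additive noise), and the latency is the extremum within
±40 ms of the reference.  Across-trial SEM is reported; with unit
background variance, per-trial amplitude sd ≈ 1 z, matching the ±0.04 SEM
scale seen at n ≈ 600 trials in this kind of data.

Samplewise tests mirror the field's convention: paired Wilcoxon
signed-rank per post-onset sample against the trial's own baseline mean,
and unpaired rank-sum between classes, flagged at p < 0.05 with **no**
multiplicity correction by default (Benjamini–Hochberg available behind a
flag).  Zero-variance differences give p = 1 by convention.

### Estimator bias and experiment size

Picking the extremum of a noisy averaged trace is upward-biased by the
expected maximum of the residual noise in the search window.  At the
default SNR (background sd 1 z) the bias is ≈ +0.9× the post-smoothing
SEM — negligible for the HN amplitudes (≈ 1.15 z) at 200 trials but
material for the small NN amplitudes (≈ 0.2 z).  The recovery experiments
in `workflows.ep_recovery_*` and the acceptance script therefore run at
study-scale counts (657 HN / 533 NN trials), where the same estimator
recovers both classes' amplitudes, and the HN/NN amplitude ratios, within
10%.

## Spectral analysis

Complex Morlet wavelets with 6 cycles (pywt `cmorB-C` with C = 1 and
B = 2(n_c/2πC)²), 60 log-spaced frequencies 3–120 Hz by default.  Power is
the squared coefficient magnitude computed **per trial** and averaged
afterwards, so induced (non-phase-locked) modulation is visible.  Epochs
are reflection-padded by four wavelet supports at the lowest frequency;
samples within two supports of the edges are flagged as the cone of
influence.  Baseline normalization z-scores each frequency row against the
[−1, 0] s interval (per trial for trial stacks).  Note that at the lowest
frequencies the wavelet support (≈ 0.3 s std at 3 Hz) is comparable to the
1-s baseline, so the baseline sd is estimated from few effective samples
and normalized values are heavy-tailed there; calibration tests use
frequencies whose support fits the baseline.  Scaling a signal by a scales
raw power by a² exactly.  Group comparisons use rank-sum tests with the
conventional star encoding (0.05/0.01/0.001/0.0001); bilateral comparisons
use paired signed-rank tests.  In the generator, hemispheric asymmetry is
carried by the EP (not by lateralized band gains), so the detectable
ipsi > contra band-power excess concentrates in the EP's spectral band
(theta) during [0, 0.5] s.

## Decoding

Features: per hemisphere and band, zero-phase 4th-order Butterworth
band-pass then MAV over 30-ms non-overlapping windows of the [0, 3] s
stimulus interval — exactly 1000 features.  Features are z-scored per
column; mutual information is estimated by plug-in entropy on 8
equal-frequency bins (configurable); mRMR greedily maximizes relevance
minus mean redundancy, with the first pick the maximum-relevance feature.
The classifier is an RBF-kernel SVM (`gamma='scale'`), cost selected from
a small grid {1, 10} by 3-fold inner CV, inverse-frequency class weights
by default.  Both normalization and feature ranking are fitted inside each
training fold — the label-shuffle test keeping accuracy in the binomial
chance band is the guard against selection-before-split leakage.  The
candidate selected-feature count is scanned over `k_grid` and chosen by
validation accuracy.  AUC comes from decision-function scores; Cohen's
kappa is (p_o − p_e)/(1 − p_e) with marginal-product chance agreement
(defined as 0 when p_e = 1).  Folds are seeded and stratified;
leave-one-subject-out iterates subjects in sorted order.

Desk-scale defaults (tens of trials per class, single k, 5–10 folds) keep
a full decoding run in seconds-to-minutes on one CPU; at those sizes the
noxious-vs-baseline decoder consistently outperforms the
non-noxious-vs-baseline one, mirroring the intended effect-size ordering.

## Connectivity

PLV uses the same Morlet phases; the phase-difference phasor is averaged
over a centered sliding window (500 ms, 1-ms step by default) per trial,
and magnitudes are averaged across trials.  Reading Eq.-style "N over
time" this way (rather than across trials at fixed time) is the package's
primary estimator; an across-trials variant is provided
(`plv_across_trials`).  Raw PLV is clipped to [0, 1] and obeys the
√(π/4N) null bias for N independent phases.  The normalized map subtracts
the per-frequency baseline mean (z-scoring switchable).  Sliding Pearson
correlation uses the same windowing; zero-variance windows are excluded
from the mean and counted.  Cross-correlation implements the biased
estimator (division by T at every lag) normalized by population sds, so
r_xx(0) = 1 exactly; the interhemispheric lag is the argmax of the
trial-averaged cross-correlation, with earliest-lag tie-breaking (flagged)
and an optional trial-permutation test that marks sub-threshold peaks
unreliable.

The dip-persistence readout (`below_baseline_recovery`) thresholds a trace
at baseline mean − 2 baseline sd and reports the end of the last sustained
(≥ 0.2 s) below-threshold run; on generated HN trials both the correlation
trace and the PLV map return the configured 4-s recovery within ±0.5 s on
seed averages.

## Problem sizes used in the shipped tests

Chosen as desk-scale defaults: EP recovery at 657/533 trials × 12 seeds
(tests) or 20 seeds (acceptance script); decoding sanity at 60 trials per
class × 10 seeds; coupling recovery at 100 trials × 12 seeds; property
suites at hundreds of trials.  All randomness flows from explicit seeds;
reruns are bit-reproducible.

## Known limitations

- The generator's Gaussianity makes rank tests conservative-to-exact; real
  LFPs are heavier-tailed.
- Band gains, coupling depth, and SNR are emulation parameters, not fitted
  quantities; absolute effect sizes on real data will differ.
- Baseline z-normalization is poorly conditioned below ~8 Hz with a 1-s
  baseline (see above).
- Channel exclusion is an input flag; no automatic noisy-channel detection.
- No spike-band analysis, phase-amplitude coupling, directed connectivity,
  or single-trial latency (Woody) correction.
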