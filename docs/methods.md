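# Methods

This note documents the models, parameter choices and numerical
conventions behind `afpulse`, and what the synthetic validation does
and does not establish.

## The staged window classifier

Every 30-second window of PPG (with a time-aligned tri-axial
accelerometer slice) passes through three stages in a fixed order:
motion-noise screening, irregularity detection, ectopy salvage. The
order matters: rhythm statistics are only meaningful on windows whose
pulse train is trustworthy, and Poincaré periodicity is only consulted
for windows already deemed irregular, where the question "AF or benign
ectopy?" actually arises. Each window receives exactly one label from
{AF, PAC_PVC, NSR, NOISE}; windows with too few usable beats for the
statistics (flat line, massive dropout) are labelled NOISE as well,
since they are equally unanalyzable even if the cause is not motion.

## Motion-noise screening

A clean wrist PPG window is close to a stationary tone train. Its
short-time spectrum (Hann frames of 4 s, 50% overlap — long enough to
resolve 0.25 Hz, short enough to give ~14 frames per window) keeps a
stable dominant frequency in the cardiac band (0.5–3 Hz), low spectral
entropy, and most power in band. Three per-window features are computed
on frame-normalized spectra (hence invariant to PPG amplitude
rescaling):

* dominant-frequency instability — SD across frames of the in-band
  dominant frequency, mapped to [0, 1] by a 0.5 Hz scale;
* mean per-frame spectral entropy, normalized by log bin count;
* mean in-band power fraction (used as 1 − fraction).

Severity is their mean, escalated to 1.0 when the gravity-removed
accelerometer vector RMS exceeds the 0.1 g motion gate; a window is
clean iff severity ≤ 0.6.

Two calibration points, both measured on the synthetic corpora and then
frozen: the gate at 0.1 g sits well above sensor noise (~0.003 g) and
below every scripted movement scenario (0.15–0.5 g); the 0.6 severity
threshold admits ≥ 99% of clean windows of *every* rhythm class
(clean-NSR severity ≈ 0.14–0.31, clean-AF up to ≈ 0.54, clean
trigeminy/quadrigeminy up to ≈ 0.6 — ectopic rhythms produce pattern
subharmonics that legitimately destabilize the spectrum) while the
accelerometer gate rejects all scripted-movement windows.

A real limitation follows from the calibration: with the accelerometer
absent or quiet, the spectral path alone only rejects gross broadband
corruption. This mirrors the physics — a PPG spectrum cannot reliably
distinguish a genuinely irregular pulse from pulse-band-limited
artifact; the accelerometer is the disambiguating sensor, which is
precisely why it is part of the architecture.

## Pulse peaks and RR intervals

The PPG slice is band-passed 0.5–5 Hz (3rd-order Butterworth, applied
forward-backward for zero phase; the band covers 30–220 bpm
fundamentals plus low harmonics). Peaks are local maxima at least
300 ms apart (refractory, a 200 bpm ceiling) that exceed 0.4× a
centered rolling 90th-percentile amplitude envelope (3 s window); peak
positions are refined by parabolic interpolation of the three
surrounding samples, so RR resolution is not limited to the 10 ms
sampling grid. Successive peak-time differences become RR intervals in
ms; intervals outside [300, 2000] ms are removed (counted, not merged).
On 200 seeded clean windows spanning 45–150 bpm the detector recovers
≈ 99.8% of simulated beats within ±20 ms; the residual misses are final
beats clipped by the window edge.

## Irregularity statistics

Sample entropy SampEn(m, r) = −ln(A/B) uses template length m = 1 and
an *absolute* tolerance r = 0.1 × mean RR of the window. The
conventional r = 0.2 × SD was evaluated and rejected: on ~35-beat
windows it makes the statistic nearly scale-invariant, and measured
NSR (≈ 1.9) and AF (≈ 2.1) distributions overlap almost completely —
a 30-beat window simply does not contain enough *pattern* information.
An absolute tolerance keeps the beat-to-beat amplitude information
that separates AF from sinus rhythm; this is the same reasoning that
motivates fixed-tolerance entropies for very short RR series (the
COSEn lineage). With it, NSR windows score ≈ 0–0.1 and AF ≈ 0.6–1.5.
When no (m+1)-template pair matches (A = 0, common in genuine AF at
30 s) the entropy is unbounded and the window is treated as maximally
irregular rather than as an error.

RMSSD is normalized by mean RR (heart-rate robust, dimensionless). The
fusion Comb = SampEn · (1 + k · RMSSD/meanRR) is monotone
non-decreasing in both statistics and zero whenever SampEn is zero.
The gain k = 10 was calibrated once on the synthetic corpora so the
0.94 decision threshold separates them: measured NSR Comb ≤ ~0.14
(99th percentile) versus AF ≥ ~1.8 (1st percentile). The decision is
strict (Comb > 0.94); a tie is regular.

## Poincaré ectopy salvage

Bigeminy/trigeminy/quadrigeminy make the RR sequence periodic with
period p ∈ {2, 3, 4}; in the Poincaré plane the points collapse onto p
off-diagonal clusters. The periodicity score folds the RR sequence at
each candidate period and compares spread within phase groups to total
spread: score(p) = 1 − mean within-phase variance / total variance
(population variances; a zero-variance sequence scores 0 by
convention). Scores are invariant to RR rescaling. A pattern is
declared when a score strictly exceeds 0.7; among passing periods the
*smallest* period within 0.02 of the best score wins. The epsilon
resolves period nesting — an exact period-2 alternation is explained
equally well by period 4, and the parsimonious (physiological) period
is the right call. Scores require ≥ 10 intervals; irregular windows
with fewer stay AF.

On seeded corpora (100 windows per ectopy class, 15 ms phase jitter;
200 AF windows) the detector recovers the correct pattern in 100% of
ectopy windows and calls "none" on ≥ 95% of AF windows.

One behaviour worth naming: *perfectly regular* bigeminy and trigeminy
have low sample entropy (the alternation is predictable), so many such
windows never cross the Comb threshold and are labelled NSR without
consulting the ectopy stage. They are still non-AF, so diagnostic
metrics are unaffected; the salvage stage matters for the ectopy
variants (and occasional noisy windows) that do cross the threshold —
quadrigeminy in particular, whose longer cycle raises its entropy.

## The synthetic generator

The generator encodes the study conditions the pipeline is meant for:
older cardiology patients wearing a wrist device while performing
scripted activities of daily living.

* **NSR** — RR = 60000/HR plus AR(1) deviations (coefficient 0.9,
  stationary SD `hrv_sd` = 30 ms) plus sinusoidal respiratory timing
  modulation (10 ms at 0.25 Hz). Defaults give RMSSD ≈ 15–20 ms,
  typical of older adults.
* **AF** — serially independent RR from a standardized shifted
  log-normal (long right tail), SD `af_variability` = 150 ms. Lag-1
  autocorrelation is ~0 by construction.
* **Ectopy** — every p-th beat premature (coupling interval shortened
  by 35%) followed by a *full* compensatory pause (the next sinus beat
  arrives on schedule), with 15 ms Gaussian phase jitter. The full
  pause (factor 1.0) is what preserves the mean heart rate exactly; a
  longer pause would bias the simulated rate upward by several
  percent.
* **PPG rendering** — each beat is a stereotyped primary systolic wave
  plus a 30%-amplitude dicrotic wave delayed by 0.35 RR, widths scaled
  to the local RR; the waveform peak defines the beat time. PPG at
  100 Hz, accelerometer at 50 Hz (explicit config; the hardware rates
  are deployment metadata).
* **Motion scenarios** — additive band-limited artifact at gait/arm
  frequencies with a synchronized accelerometer record. Intensities
  (gravity-removed RMS: still 0.003 g, slow walk 0.15 g, fast walk
  0.25 g, arm movement 0.35 g, stairs 0.5 g) follow wrist-actigraphy
  magnitudes for the scripted protocol and preserve the ordering
  still < slow walk < fast walk ≤ arm movement ≤ stairs.

All draws derive from one integer seed; a fixed seed reproduces a
corpus byte-for-byte. The default validation corpus is 200 AF + 200
NSR + 20 windows each of bigeminy/trigeminy/quadrigeminy (still), plus
100 motion-corrupted windows (25 each of slow walk, fast walk, arm
movement on NSR and stairs on AF).

**What the generator does not model:** optical skin-tone/perfusion
effects, beat-morphology changes of ectopic beats (premature beats are
rendered at full amplitude), pulse-amplitude variation, non-stationary
drift, atrial flutter and other organized arrhythmias, and artifact
that lacks an accelerometer signature (e.g. band pressure changes).
Passing the synthetic acceptance therefore demonstrates internal
correctness and sensible behaviour under the modelled conditions — not
clinical performance. In particular the published in-clinic yields
(how many of 2538 windows are clean, the exact 54/6/248 split) depend
on real recordings and unpublished sub-algorithm constants and are not
reproducible at desk scale; the evaluation module instead reproduces
the published diagnostic metrics exactly from their confusion counts.

## Numerical conventions

* Windows are half-open [t, t+30), indexed from 0; trailing partials
  dropped. Segmentation is a partition: concatenated slices reproduce
  the record prefix bit-exactly.
* CSV: comma-separated, '.' decimal, UTF-8, header required; floats
  written at 17 significant digits and parsed in round-trip mode so
  write→read is lossless.
* Metric rounding: one decimal, half away from zero. Zero-denominator
  metrics are *not available* (None/NA), never 0.
* Evaluation excludes NOISE windows; with `intersect=True` the
  comparison is restricted to windows noise-free on both sides (the
  study convention), otherwise differing key sets are an error.
* Degenerate inputs are conventions, not errors, where a convention is
  defensible: constant PPG → all-zero spectral features; constant RR →
  SampEn 0, periodicity scores 0.

## Problem sizes

The test suite and the acceptance script use the corpus sizes above
(560 windows end-to-end, 200 windows for peak recovery, 1000 series
for the entropy oracle); the full suite runs in well under a minute on
one CPU, the acceptance script in a few seconds.
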