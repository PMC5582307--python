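# Methods

This note documents the models, estimators and numerical choices behind
`dopbeat`, and what the synthetic-data experiments do and do not show.

## Problem

Continuous Doppler ultrasound (DUS) of the fetal heart encodes the
*mechanical* cardiac cycle: each beat produces short reflection bursts
from moving valves and heart walls. Beat-to-beat intervals estimated
from DUS are the only non-invasive route to fetal heart-rate
variability in routine practice, but the classical
autocorrelation-based estimators average several beats per measurement
and therefore misstate short-term variability. `dopbeat` implements a
beat-resolved detector: empirical mode decomposition of the denoised
DUS signal, sliding-window kurtosis over the informative intrinsic mode
functions (IMFs), and refractory-constrained peak search on the summed
kurtosis trace.

## Pipeline

1. **Denoising.** 15-level Haar discrete wavelet transform; every
   detail band is hard-thresholded at the universal level
   `sigma * sqrt(2 ln N)`. `sigma` comes from the 20th percentile of
   the finest band's absolute coefficients (divided by the matching
   normal quantile): burst transients contaminate the upper half of
   that distribution and inflate the usual median/0.6745 estimate
   roughly twofold on clean records. Hard (keep-or-kill) thresholding
   is used instead of soft shrinkage because shrinkage biases every
   surviving burst coefficient toward zero; on synthetic records soft
   thresholding *lowered* the correlation with the known clean signal.
   Boundary handling is symmetric extension. Depth is reduced (with a
   logged warning) for signals shorter than `2^levels`.

2. **Decomposition.** Ensemble empirical mode decomposition (EEMD).
   Sifting subtracts the mean of natural cubic-spline envelopes through
   the local maxima/minima, with two boundary extrema mirrored about
   each end to suppress endpoint swings. A sift stops when the relative
   change `sum((h_prev - h_new)^2)/sum(h_prev^2)` falls below 0.05 *and*
   the iterate's extrema and zero-crossing counts balance within one
   (the defining IMF property; the SD criterion alone stops too early
   on noise-like signals), with a cap of 100 iterations. Decomposition
   stops at a monotone residue (< 4 extrema) or 10 modes. EEMD runs the
   decomposition on `ensemble_size` noisy replicates (white noise, SD =
   0.2 x signal SD by default), truncates every member to the minimum
   mode count, averages aligned modes, and defines the residue as the
   complement `x - sum(imfs)` so reconstruction is exact by
   construction. With an ensemble of one and zero noise EEMD reduces
   bitwise to plain EMD. The library default ensemble is 100; the
   simulation studies in the test-suite and acceptance script use 20,
   which the averaging error (~`noise_sd/sqrt(E)`) makes
   indistinguishable from 100 for these records while keeping the
   default runs fast.

3. **Kurtosis matrix.** The statistic is the non-centered ratio
   `k(x) = (N-1) sum(x^4) / (sum(x^2))^2` (a Gaussian window scores ~3,
   a constant window `(N-1)/N`, a single impulse `N-1`; all-zero
   windows are defined as 0 so silence cannot rank as a peak). It is
   computed for every IMF over sliding windows of 50–600 ms in 50 ms
   increments, shifted 1 ms at a time, via cumulative sums of `x^2` and
   `x^4` (linear cost; values are clipped at zero where cumulative-sum
   cancellation leaves tiny negatives). Each value is time-stamped at
   the window center so kurtosis peaks align with burst centers.

4. **IMF screening.** An IMF enters the matrix only if the *median* of
   its sliding kurtosis (at the 300 ms reference window) exceeds 3.5,
   i.e. its windows are impulsive on average, clearly above the
   Gaussian level of 3. This level test separates burst-carrying modes
   (median ≥ ~4 at 0–10 dB burst SNR) from noise-dominated modes
   (median ≤ ~3) far more reliably than shape-based tail tests: a
   wavelet-denoised pure-noise record consists of sparse spikes whose
   kurtosis *trace* looks more peak-concentrated than a true burst
   trace. The package also exposes `chebyshev_screen`, a tail-mass
   test that accepts a vector when its mass beyond `lambda` SDs stays
   below `selectivity / lambda^2` (concentrated rare peaks use little
   of the Chebyshev allowance; noise-like spread sits near it); it is
   useful for classifying trace shapes but is deliberately not the
   pipeline's IMF gate. If no IMF passes the screen the pipeline
   raises "signal too noisy" rather than fabricating beats from noise
   peaks.

5. **Vector selection.** Two modes.
   *Calibrated* (reference beats available): each (IMF, window) vector
   is run through the peak search alone and scored by the absolute
   beat-count mismatch and by `varB_loc`, the SD of absolute offsets
   between matched estimated/true beats; the two scores are
   rank-normalized, summed, and the lowest decile of cells is kept.
   The two score surfaces are returned for inspection;
   `optimal_window_ms` reports the window of the surface's argmin cell.
   *Default* (deployment): IMF levels 1–3 with windows 300–400 ms —
   slightly below the mean beat interval, so one window spans one
   cardiac cycle's worth of mechanical events.

6. **Detection.** Selected vectors are summed over their common
   center-aligned span; beats are local maxima under a 300 ms minimum
   peak distance (greedy suppression by descending height, via
   `scipy.signal.find_peaks(distance=...)`), guaranteeing all returned
   intervals ≥ 300 ms.

## Autocorrelation baseline (AF)

The comparator is an adaptive-window autocorrelation estimator of the
DUS envelope (analytic-signal magnitude, 30 Hz low-pass). Each step
measures the dominant periodicity as the lag of the highest *local*
peak of the unbiased, normalized autocorrelation within 250–800 ms
(boundary-pinned maxima are rejected; among peaks within 15% of the
tallest the smallest lag wins, so a period-doubled harmonic cannot win
narrowly; parabolic interpolation refines the lag below one sample).
Five sub-windows shifted 25 ms apart are aggregated by median, and a
step is marked unreliable when fewer than half the sub-measurements
exist or they scatter by more than 50 ms — a genuine cardiac
periodicity is stable under such shifts, noise peaks are not. The
window advances by the accepted period and its size tracks 3x the
running-mean period; more than 50% unreliable steps raises "signal too
noisy". This is a baseline faithful in spirit to the adaptive-AF
literature, not a reference implementation of any specific device.
Because one autocorrelation covers ~3 beats, its interval series is
intrinsically smoothed: accurate for slow trends, sluggish at steps,
and an under-reader of beat-to-beat variability.

## Evaluation metrics

* signed count mismatch `100 (true - est) / true` (negative =
  over-detection), aggregated across a cohort as RMS;
* mean successive beat error: index-paired
  `100 |true_rr(i) - est_bb(i)| / true_rr(i)` over the first `N_min`
  intervals — by definition a missed beat shifts all later pairs, so a
  time-aligned variant is logged for diagnostics but never replaces it;
* `varB_loc`: sample SD of absolute matched-beat offsets (greedy
  nearest matching, each true beat used once, 300 ms matching limit);
  a constant mechanical-electrical latency contributes nothing;
* HRV summaries: mean interval, SDNN (sample SD, n−1), RMSSD;
* Bland–Altman mean difference with mean ± 2 SD limits.

## Synthetic records

No public fetal DUS corpus with beat-level truth exists, so all tests
run on simulated 1-min records (1 kHz) built in two stages.

*Interval process.* Beat-to-beat intervals are AR(1) around the mean:
`phi = 1 - RMSSD^2 / (2 SDNN^2)` gives independent control of both
variability targets; `RMSSD > 2 SDNN` is rejected as unreachable by a
stationary process. Because the sample moments of a short, strongly
correlated record fluctuate by tens of percent, each draw is
conditioned on its realized moments: the spectrum is split at the
median of the difference-filter gain and the two bands rescaled to hit
sample SDNN exactly and RMSSD within a few percent, leaving phases (the
trajectory shape) untouched. Intervals are clipped to the fetal
physiological band 250–800 ms. Default targets follow the early-
gestation cohort profile: mean 400–406 ms, SDNN 13.5 ms, RMSSD 9.5 ms,
150 beats ≈ 1 min.

*Waveform.* Each beat places three Gaussian-windowed tone bursts: a
short high-frequency valve burst (80 Hz carrier, 30 ms window) at the
beat time, a longer low-frequency wall burst (25 Hz, 80 ms) at +60 ms,
and a second valve (end-systolic closure) burst at +200 ms — without
the second heart-sound event, mechanical activity would occupy only the
first third of the cycle, which is neither physiological nor compatible
with the observed behavior of window sizes near the mean interval.
Burst strengths vary beat to beat (lognormal, CV 0.25 per component)
and the wall/closure timings wobble (SD 10 ms), modelling the changing
probe-to-heart geometry; electromechanical jitter (Gaussian, SD 5 ms,
clamped to preserve ordering) perturbs all of a beat's bursts together,
and the jittered times are stored as truth. White Gaussian noise is
scaled so that the ratio of burst-support signal power to noise power
equals the requested SNR exactly as measured on the generated record
(silence between bursts is excluded so it cannot deflate the nominal
SNR); the clean and noise components are stored so the realized SNR is
recomputable from bookkeeping.

*What the generator does not emulate* — and hence what passing tests do
not establish about clinical data: maternal ECG leakage, fetal movement
episodes, probe re-orientation dropouts, nonstationary or impulsive
noise, and drifting burst morphology. The noise is stationary and
white; real early-gestation records are not. One visible consequence:
with stationary noise at 10 dB burst SNR, a 150 ms kurtosis window that
isolates the clean valve event is genuinely optimal on the calibration
surfaces, and the characteristic optimum slightly below the mean beat
interval (300–400 ms for ~400 ms cycles) emerges only at low SNR
(~0 dB), where single events become unreliable and only windows
spanning the full mechanical complex detect every cycle.

## Problem sizes

Simulation studies use 150-beat (≈1 min) records; stochastic checks use
8–20 seeded records per condition with EEMD ensembles of 20 (library
default 100, see above). Short pipeline fixtures use 40–80 beats.

## Known limitations

* The kurtosis statistic is scale-invariant, so a cleanly separated
  single-component IMF localizes equally well at any amplitude; only
  noise and within-IMF interference limit small-window localization.
* EEMD mode alignment by truncation to the member-minimum can fold a
  slow mode into the residue for some noise realizations.
* The AF baseline's beat times are integrated periods, not event
  locations; its `varB_loc` is therefore not comparable with the
  detector's.
* Estimated SDNN/RMSSD from both methods overshoot the true interval
  variability (detection-error variance adds to physiological
  variance); the overshoot is larger for the beat-resolved detector,
  whose errors are per-beat rather than averaged.
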