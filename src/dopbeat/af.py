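"""Adaptive autocorrelation (AF) baseline estimator.

The classical cardiotocography approach: the envelope of the Doppler
signal is quasi-periodic at the cardiac cycle, and the lag of the
dominant peak of its windowed autocorrelation estimates the current
beat-to-beat period.  The window is slid forward by one estimated period
per step and its size adapts to three times the running-mean period, so
a few neighbouring beats are always enclosed.  Because one periodicity
value summarises all beats in the window, the estimate is intrinsically
smoothed: it tracks slow trends well but responds sluggishly to rapid
interval changes and under-reads beat-to-beat variability.

This is a baseline faithful in spirit to the adaptive-window
autocorrelation estimators of the CTG literature, not a reference
implementation of any specific device algorithm; per-step periodicity
measurements from a handful of sub-window shifts are aggregated by
median.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, hilbert

from .core import BeatSeries, DopbeatError, SampledSignal, SignalTooNoisyError

logger = logging.getLogger(__name__)

#: Physiological fetal lag range, ms (75-240 bpm).
DEFAULT_LAG_RANGE_MS = (250.0, 800.0)

ENVELOPE_CUTOFF_HZ = 30.0
MIN_AC_PEAK = 0.1


def envelope(x: SampledSignal, cutoff_hz: float = ENVELOPE_CUTOFF_HZ) -> SampledSignal:
    """Low-pass-smoothed magnitude of the analytic signal (always >= 0)."""
    mag = np.abs(hilbert(x.samples))
    nyq = x.fs / 2.0
    if cutoff_hz < nyq:
        b, a = butter(4, cutoff_hz / nyq)
        mag = filtfilt(b, a, mag)
    # filtering can undershoot slightly; the envelope is non-negative
    return x.with_samples(np.maximum(mag, 0.0), label=(x.label + " [envelope]").strip())


def af_periodicity(
    env_window: np.ndarray,
    fs: float,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
) -> float | None:
    """Dominant periodicity (ms) of one envelope window, or None.

    The lag of the maximum of the normalized autocorrelation within
    ``lag_range_ms`` is returned.  The searched upper lag is capped at
    half the window length so the correlation estimate stays supported.
    Returns None ("unreliable") when no peak exceeds 0.1 — a flat or
    noise-dominated window.
    """
    env_window = np.asarray(env_window, dtype=float)
    lo = int(round(lag_range_ms[0] * fs / 1000.0))
    hi = int(round(lag_range_ms[1] * fs / 1000.0))
    hi = min(hi, env_window.size // 2)
    if hi <= lo:
        raise DopbeatError("window too short for the requested lag range")

    x = env_window - np.mean(env_window)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    # unbiased normalization: the raw sum tapers linearly with lag, which
    # biases peak lags low; divide by the overlap length per lag
    overlap = np.arange(x.size, 0, -1, dtype=float)
    ac = (ac / overlap) / (ac[0] / x.size)
    # genuine local peaks only: a maximum pinned at the range boundary is
    # a period outside the physiological band, not a measurement
    peaks, _ = find_peaks(ac[: hi + 1], height=MIN_AC_PEAK)
    peaks = peaks[(peaks >= lo) & (peaks <= hi)]
    if peaks.size == 0:
        return None
    heights = ac[peaks]
    # prefer the fundamental: smallest lag among peaks within a hair of
    # the tallest, so a period-doubled harmonic cannot win narrowly
    candidates = peaks[heights >= 0.85 * float(np.max(heights))]
    best = int(candidates[0])
    lag = float(best)
    # parabolic sub-sample refinement around the discrete peak
    if 0 < best < ac.size - 1:
        y0, y1, y2 = ac[best - 1], ac[best], ac[best + 1]
        denom_p = y0 - 2.0 * y1 + y2
        if denom_p < 0:
            lag += 0.5 * (y0 - y2) / denom_p
    return lag * 1000.0 / fs


def af_estimate(
    x: SampledSignal,
    init_window_ms: float = 1200.0,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
    n_subshifts: int = 5,
    subshift_ms: float = 25.0,
) -> BeatSeries:
    """Beat series from adaptive-window autocorrelation of the envelope.

    The analysis window advances by the last accepted period each step;
    its size adapts to 3x the running-mean period.  At each step the
    periodicity is measured on ``n_subshifts`` sub-windows offset by
    ``subshift_ms`` and aggregated by median.  Cumulative sums of the
    per-step periods form the returned beat times.

    Raises
    ------
    SignalTooNoisyError
        If more than half of all steps yield no reliable periodicity.
    """
    if x.duration_ms < 5000.0:
        raise DopbeatError("record shorter than 5 s")
    env = envelope(x).samples
    fs = x.fs
    n = env.size

    window_ms = float(init_window_ms)
    running_mean: float | None = None
    pos_ms = 0.0
    beat_times: list[float] = []
    n_steps = 0
    n_unreliable = 0

    while True:
        w = int(round(window_ms * fs / 1000.0))
        i0 = int(round(pos_ms * fs / 1000.0))
        if i0 + w > n:
            break
        n_steps += 1
        measurements = []
        for k in range(n_subshifts):
            s0 = i0 + int(round(k * subshift_ms * fs / 1000.0))
            if s0 + w > n:
                break
            p = af_periodicity(env[s0 : s0 + w], fs, lag_range_ms)
            if p is not None:
                measurements.append(p)
        # a true cardiac periodicity is stable under small window shifts;
        # scattered measurements mean the peaks were noise
        consistent = (
            len(measurements) >= max(2, n_subshifts // 2)
            and np.ptp(measurements) <= 50.0
        )
        if not consistent:
            n_unreliable += 1
            pos_ms += window_ms / 2.0
            continue
        period = float(np.median(measurements))
        t = (beat_times[-1] if beat_times else pos_ms) + period
        beat_times.append(t)
        pos_ms += period
        running_mean = period if running_mean is None else 0.8 * running_mean + 0.2 * period
        window_ms = float(np.clip(3.0 * running_mean, 2.0 * lag_range_ms[0] + 400.0, 3000.0))

    if n_steps == 0 or n_unreliable > 0.5 * n_steps:
        raise SignalTooNoisyError("signal too noisy for AF periodicity estimation")
    if len(beat_times) < 2:
        raise SignalTooNoisyError("AF produced fewer than 2 beats")
    logger.info("AF: %d beats from %d steps (%d unreliable)", len(beat_times), n_steps, n_unreliable)
    return BeatSeries(np.asarray(beat_times))
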