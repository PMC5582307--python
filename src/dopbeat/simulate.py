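"""Synthetic Doppler-ultrasound (DUS) record generator with known beat times.

Clinical fetal DUS recordings are rarely shareable, so every test and
benchmark in this package runs on synthetic records that emulate the
statistical structure of 1-min bedside recordings: a quasi-periodic train
of Doppler bursts (a short high-frequency "valve" burst and a longer
low-frequency "wall" burst per cardiac cycle), beat-to-beat variability
with controllable SDNN and RMSSD, a variable electromechanical delay
between the electrical beat time and the mechanical burst, and additive
broadband noise at a controlled SNR.

The beat-interval sequence is an AR(1) process around the mean interval.
With marginal SD ``s`` (the SDNN) and lag-1 coefficient ``phi``, the SD of
successive differences (the RMSSD) satisfies ``rmssd^2 = 2 s^2 (1 - phi)``,
so both variability targets are met simultaneously by solving
``phi = 1 - rmssd^2 / (2 s^2)``.  A stationary process cannot exceed
``rmssd = 2 * sdnn`` (anti-correlated alternation), which bounds the
feasible target region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import BeatSeries, DopbeatError, SampledSignal

#: Physiological bounds for fetal beat-to-beat intervals (75-240 bpm).
INTERVAL_BOUNDS_MS = (250.0, 800.0)

#: Default burst model: the "valve" component is short and high-frequency,
#: the "wall" component longer, lower-frequency and offset within the cycle.
DEFAULT_BURST_PARAMS: dict[str, float] = {
    "valve_freq_hz": 80.0,
    "valve_width_ms": 30.0,
    "valve_amp": 1.0,
    "valve_offset_ms": 0.0,
    "wall_freq_hz": 25.0,
    "wall_width_ms": 80.0,
    "wall_amp": 0.7,
    "wall_offset_ms": 60.0,
    # end-systolic valve closure: a second short high-frequency event
    # roughly 200 ms into the cycle, so mechanical activity spans much of
    # the cardiac cycle as in real Doppler records
    "valve2_amp": 0.8,
    "valve2_offset_ms": 200.0,
    # beat-to-beat variability of the mechanical reflection: Doppler burst
    # strength fluctuates with probe-to-heart geometry, and the wall
    # excursion drifts within the cycle relative to the valve snap
    "amp_cv": 0.25,
    "wall_offset_jitter_ms": 10.0,
}


@dataclass(frozen=True)
class RRSequence:
    """A sequence of true beat-to-beat intervals in milliseconds."""

    intervals: np.ndarray
    seed: int
    mean_rr: float
    sdnn_target: float
    rmssd_target: float

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        if intervals.size == 0 or np.any(intervals <= 0):
            raise DopbeatError("all intervals must be positive")
        object.__setattr__(self, "intervals", intervals)

    @property
    def n_beats(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class SyntheticRecord:
    """A synthetic DUS record together with its generating ground truth.

    ``clean`` and ``noise`` store the two additive components of ``dus``
    so that the realized SNR can be recomputed exactly from bookkeeping.
    """

    dus: SampledSignal
    true_beats: BeatSeries
    snr_db: float
    params: dict[str, Any]
    clean: np.ndarray = field(repr=False, default=None)
    noise: np.ndarray = field(repr=False, default=None)
    rr: RRSequence | None = None

    def measured_snr_db(self) -> float:
        """SNR recomputed from the stored clean/noise components.

        Signal power is measured on burst-support samples only; the
        silence between bursts would otherwise deflate the nominal SNR.
        """
        support = np.abs(self.clean) > 0
        p_sig = float(np.mean(self.clean[support] ** 2))
        p_noise = float(np.mean(self.noise**2))
        return 10.0 * np.log10(p_sig / p_noise)


def generate_rr_sequence(
    mean_rr: float,
    sdnn_target: float,
    rmssd_target: float,
    n_beats: int,
    seed: int,
) -> RRSequence:
    """Draw an interval sequence hitting mean/SDNN/RMSSD targets.

    Parameters
    ----------
    mean_rr : float
        Target mean interval, ms.  > 0.
    sdnn_target, rmssd_target : float
        Target marginal SD and successive-difference RMS, ms.  >= 0.
    n_beats : int
        Number of intervals, >= 2.  Sample statistics approach the
        targets as n grows (within ~25% for n >= 100).
    seed : int
        Seed for the interval-process RNG.

    Raises
    ------
    DopbeatError
        If ``rmssd_target > 2 * sdnn_target`` — unreachable by any
        stationary process.
    """
    if mean_rr <= 0:
        raise DopbeatError("mean_rr must be positive")
    if sdnn_target < 0 or rmssd_target < 0:
        raise DopbeatError("variability targets must be non-negative")
    if n_beats < 2:
        raise DopbeatError("need at least 2 beats")
    if rmssd_target > 2.0 * sdnn_target:
        raise DopbeatError(
            "infeasible targets: rmssd_target > 2*sdnn_target cannot be produced "
            "by a stationary interval process"
        )

    rng = np.random.default_rng(seed)
    sigma = float(sdnn_target)
    if sigma == 0.0:
        deviations = np.zeros(n_beats)
    elif rmssd_target == 0.0:
        # phi -> 1 limit: a frozen offset, constant within the record
        deviations = np.full(n_beats, rng.normal(0.0, sigma))
    else:
        phi = 1.0 - rmssd_target**2 / (2.0 * sigma**2)
        innov_sd = sigma * np.sqrt(max(0.0, 1.0 - phi**2))
        deviations = np.empty(n_beats)
        deviations[0] = rng.normal(0.0, sigma)
        eps = rng.normal(0.0, innov_sd, size=n_beats - 1)
        for k in range(1, n_beats):
            deviations[k] = phi * deviations[k - 1] + eps[k - 1]
        deviations = _condition_on_targets(deviations, sigma, rmssd_target)

    intervals = np.clip(mean_rr + deviations, *INTERVAL_BOUNDS_MS)
    return RRSequence(intervals, seed, mean_rr, sdnn_target, rmssd_target)


def _condition_on_targets(d: np.ndarray, sdnn: float, rmssd: float) -> np.ndarray:
    """Condition a deviation draw on its sample SDNN and RMSSD.

    With strong lag-1 correlation the sample statistics of a finite
    record fluctuate by tens of percent around the process values, so
    the draw's spectrum is adjusted: frequencies are split at the median
    of the difference-filter gain ``4 sin^2(pi f / n)`` and the two
    bands rescaled to solve for both quadratic targets at once (the
    circular/linear difference mismatch of order 1/n is then absorbed by
    a final exact SDNN rescale).  Phases — i.e. the shape of the
    trajectory — are untouched.
    """
    n = d.size
    d = d - d.mean()
    spec = np.fft.rfft(d)
    spec[0] = 0.0
    f = np.arange(spec.size)
    w = 4.0 * np.sin(np.pi * f / n) ** 2
    power = np.abs(spec) ** 2
    low = w <= np.median(w[1:])
    low[0] = False
    high = ~low
    high[0] = False
    a_pow, b_pow = power[low].sum(), power[high].sum()
    wa, wb = (power[low] * w[low]).sum(), (power[high] * w[high]).sum()
    # Parseval with rfft: sum x^2 = (|X0|^2 + 2 sum |Xf|^2 + ...) / n;
    # interior-bin doubling cancels in the 2x2 solve, up to Nyquist terms
    scale = n * (n - 1) / 2.0
    s_target = sdnn**2 * scale
    r_target = rmssd**2 * scale * (n - 1) / n
    det = a_pow * wb - b_pow * wa
    if det != 0.0 and a_pow > 0 and b_pow > 0:
        alpha = (s_target * wb - b_pow * r_target) / det
        beta = (a_pow * r_target - wa * s_target) / det
        if alpha > 0 and beta > 0:
            spec[low] *= np.sqrt(alpha)
            spec[high] *= np.sqrt(beta)
            d = np.fft.irfft(spec, n)
    realized = float(np.std(d, ddof=1))
    if realized > 0:
        d = d * (sdnn / realized)
    return d


def _add_burst(
    out: np.ndarray,
    fs: float,
    center_ms: float,
    freq_hz: float,
    width_ms: float,
    amp: float,
    phase: float,
) -> None:
    """Add one Gaussian-windowed tone burst in place (compact support)."""
    sigma_ms = width_ms / 4.0  # "width" spans +/- 2 sigma
    half_ms = 4.0 * sigma_ms
    i0 = max(0, int(np.ceil((center_ms - half_ms) * fs / 1000.0)))
    i1 = min(out.size, int(np.floor((center_ms + half_ms) * fs / 1000.0)) + 1)
    if i1 <= i0:
        return
    t_ms = np.arange(i0, i1) * (1000.0 / fs) - center_ms
    window = np.exp(-0.5 * (t_ms / sigma_ms) ** 2)
    out[i0:i1] += amp * window * np.cos(2.0 * np.pi * freq_hz * t_ms / 1000.0 + phase)


def synthesize_dus(
    rr: RRSequence,
    fs: float = 1000.0,
    snr_db: float = 10.0,
    jitter_sd: float = 5.0,
    seed: int = 0,
    burst_params: dict[str, float] | None = None,
) -> SyntheticRecord:
    """Render an RR sequence into a noisy DUS-like waveform.

    Each beat time (cumulative interval sum plus zero-mean Gaussian
    electromechanical jitter of SD ``jitter_sd`` ms, clamped to preserve
    ordering) receives two Gaussian-windowed tone bursts.  White Gaussian
    noise is scaled so that the burst-power-to-noise-power ratio equals
    ``snr_db`` exactly as measured on the generated record.
    """
    if fs < 500:
        raise DopbeatError("sampling rate must be >= 500 Hz")
    params = dict(DEFAULT_BURST_PARAMS)
    if burst_params:
        params.update(burst_params)

    intervals = rr.intervals
    duration_ms = float(np.sum(intervals))
    n_samples = int(round(duration_ms * fs / 1000.0))

    # nominal electrical beat times, centered so edge bursts stay in-record
    nominal = np.concatenate(([0.0], np.cumsum(intervals[:-1])))
    nominal = nominal + intervals[-1] / 2.0

    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_sd, size=nominal.size) if jitter_sd > 0 else np.zeros_like(nominal)
    max_shift = float(np.min(intervals)) / 4.0 - 1e-9
    jitter = np.clip(jitter, -max_shift, max_shift)
    beat_times = nominal + jitter

    # per-beat burst-strength factors (lognormal, unit median) and wall
    # timing wobble; both model the changing probe-to-heart geometry
    cv = float(params["amp_cv"])
    if cv > 0:
        valve_gain = rng.lognormal(0.0, cv, size=nominal.size)
        wall_gain = rng.lognormal(0.0, cv, size=nominal.size)
        valve2_gain = rng.lognormal(0.0, cv, size=nominal.size)
    else:
        valve_gain = wall_gain = valve2_gain = np.ones(nominal.size)
    woj = float(params["wall_offset_jitter_ms"])
    if woj > 0:
        wall_shift = rng.normal(0.0, woj, size=nominal.size)
        valve2_shift = rng.normal(0.0, woj, size=nominal.size)
    else:
        wall_shift = valve2_shift = np.zeros(nominal.size)

    clean = np.zeros(n_samples)
    for k, t in enumerate(beat_times):
        _add_burst(
            clean, fs, t + params["valve_offset_ms"], params["valve_freq_hz"],
            params["valve_width_ms"], params["valve_amp"] * valve_gain[k], 0.0,
        )
        _add_burst(
            clean, fs, t + params["wall_offset_ms"] + wall_shift[k], params["wall_freq_hz"],
            params["wall_width_ms"], params["wall_amp"] * wall_gain[k], 0.0,
        )
        _add_burst(
            clean, fs, t + params["valve2_offset_ms"] + valve2_shift[k],
            params["valve_freq_hz"], params["valve_width_ms"],
            params["valve2_amp"] * valve2_gain[k], 0.0,
        )

    support = np.abs(clean) > 0
    p_sig = float(np.mean(clean[support] ** 2))
    target_noise_power = p_sig / 10.0 ** (snr_db / 10.0)
    raw = rng.standard_normal(n_samples)
    raw_rms = np.sqrt(np.mean(raw**2))
    noise = raw * (np.sqrt(target_noise_power) / raw_rms)

    dus = SampledSignal(clean + noise, fs, label="synthetic DUS")
    record_params = dict(params)
    record_params.update(jitter_sd=jitter_sd, seed=seed, snr_db=snr_db)
    return SyntheticRecord(
        dus=dus,
        true_beats=BeatSeries(beat_times),
        snr_db=snr_db,
        params=record_params,
        clean=clean,
        noise=noise,
        rr=rr,
    )


def make_record(
    mean_rr: float = 400.0,
    sdnn: float = 13.5,
    rmssd: float = 9.5,
    n_beats: int = 150,
    snr_db: float = 10.0,
    jitter_sd: float = 5.0,
    fs: float = 1000.0,
    seed: int = 0,
    burst_params: dict[str, float] | None = None,
) -> SyntheticRecord:
    """One-call convenience wrapper: interval process + waveform synthesis.

    Defaults mimic a 1-min fetal recording: 150 beats of mean 400 ms at
    1 kHz with SDNN 13.5 ms, RMSSD 9.5 ms and 10 dB burst SNR.
    """
    rr = generate_rr_sequence(mean_rr, sdnn, rmssd, n_beats, seed)
    # decorrelate waveform noise from the interval process
    return synthesize_dus(
        rr, fs=fs, snr_db=snr_db, jitter_sd=jitter_sd,
        seed=seed + 1_000_003, burst_params=burst_params,
    )
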