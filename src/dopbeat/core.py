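"""Core data containers shared across the pipeline.

Two objects travel through every stage: a uniformly sampled waveform
(:class:`SampledSignal`) and a strictly increasing sequence of cardiac
event times (:class:`BeatSeries`).  Both ground-truth annotations and
detector output use the same :class:`BeatSeries` type so that the
evaluation code cannot accidentally treat them differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DopbeatError(Exception):
    """Base class for all errors raised by this package."""


class SignalTooNoisyError(DopbeatError):
    """Raised when a record cannot support a reliable estimate."""


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples : ndarray
        Finite sample values.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text description carried through processing stages.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise DopbeatError("signal must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise DopbeatError("signal contains non-finite values")
        if not (self.fs > 0):
            raise DopbeatError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds."""
        return np.arange(self.n) * (1000.0 / self.fs)

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SampledSignal":
        return SampledSignal(samples, self.fs, self.label if label is None else label)


@dataclass(frozen=True)
class BeatSeries:
    """Strictly increasing cardiac event times in milliseconds.

    ``intervals`` holds the successive differences (beat-to-beat
    intervals), the quantity every downstream metric is built from.
    """

    beat_times: np.ndarray
    intervals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise DopbeatError("beat series must contain at least one beat time")
        if not np.all(np.isfinite(times)):
            raise DopbeatError("beat times contain non-finite values")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0))
            raise DopbeatError(
                f"beat times must be strictly increasing (violation after beat {bad})"
            )
        object.__setattr__(self, "beat_times", times)
        object.__setattr__(self, "intervals", diffs)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    def __len__(self) -> int:
        return self.n_beats
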