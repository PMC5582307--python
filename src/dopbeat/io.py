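"""Readers and writers for signals, beat annotations and configs.

Signals travel as 16-bit PCM WAV (the bedside acquisition format,
amplitudes scaled to [-1, 1]) or as two-column CSV with header
``time_ms,amplitude``.  Beat annotations are single-column CSV with
header ``beat_time_ms``, strictly increasing, at 0.1 ms precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .config import RunConfig
from .core import BeatSeries, DopbeatError, SampledSignal

_PCM_FULL_SCALE = 32767


def write_signal(x: SampledSignal, path: str | Path) -> None:
    """Write a signal as 16-bit PCM WAV (.wav) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        peak = float(np.max(np.abs(x.samples)))
        scale = _PCM_FULL_SCALE / peak if peak > 0 else 1.0
        pcm = np.round(x.samples * scale).astype(np.int16)
        wavfile.write(path, int(round(x.fs)), pcm)
    else:
        pd.DataFrame({"time_ms": x.times_ms, "amplitude": x.samples}).to_csv(
            path, index=False
        )


def read_signal(path: str | Path, fs: float | None = None) -> SampledSignal:
    """Read a WAV or CSV signal.

    WAV: integer PCM is scaled to [-1, 1]; the rate comes from the
    header.  CSV: the ``time_ms`` column must be uniformly increasing
    and determines the rate (``fs`` overrides only a missing time
    column).
    """
    path = Path(path)
    if not path.exists():
        raise DopbeatError(f"no such file: {path}")
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        return SampledSignal(data.astype(float), float(rate), label=path.stem)

    frame = pd.read_csv(path)
    if "amplitude" not in frame.columns:
        raise DopbeatError(f"{path}: CSV needs an 'amplitude' column")
    samples = frame["amplitude"].to_numpy(dtype=float)
    if "time_ms" in frame.columns:
        t = frame["time_ms"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            # offending sample is the second of the pair; +1 header +1 one-based
            line = int(np.argmax(dt <= 0)) + 3
            raise DopbeatError(f"{path}: time_ms not increasing at line {line}")
        step = float(np.median(dt))
        if np.any(np.abs(dt - step) > 0.01 * step):
            raise DopbeatError(f"{path}: time_ms is not uniformly sampled")
        fs = 1000.0 / step
    elif fs is None:
        raise DopbeatError(f"{path}: no time_ms column and no fs given")
    return SampledSignal(samples, float(fs), label=path.stem)


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    """Write a beat-annotation CSV (header ``beat_time_ms``)."""
    pd.DataFrame({"beat_time_ms": np.round(beats.beat_times, 1)}).to_csv(
        Path(path), index=False
    )


def read_beats(path: str | Path) -> BeatSeries:
    """Read a beat-annotation CSV; rejects empty or non-increasing files."""
    path = Path(path)
    if not path.exists():
        raise DopbeatError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if "beat_time_ms" not in frame.columns:
        raise DopbeatError(f"{path}: missing 'beat_time_ms' header")
    times = frame["beat_time_ms"].to_numpy(dtype=float)
    if times.size == 0:
        raise DopbeatError(f"{path}: no beats in file")
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise DopbeatError(
            f"{path}: beat times not strictly increasing at row {int(bad[0]) + 3}"
        )
    return BeatSeries(times)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DopbeatError(f"{path}: config must be a YAML mapping")
    return RunConfig.from_dict(data)
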