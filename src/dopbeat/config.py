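"""Run configuration for the EMD-kurtosis pipeline.

The detector has roughly ten coupled parameters; bundling them in one
dataclass keeps end-to-end runs reproducible (a config plus a seed fully
determines the output) and lets the CLI serialize them to YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Any

from .core import DopbeatError

DEFAULT_WINDOWS_MS: tuple[float, ...] = tuple(float(w) for w in range(50, 601, 50))


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the full denoise → EEMD → kurtosis → detect pipeline.

    Defaults follow the published settings where stated (15 Haar levels,
    50–600 ms window grid in 50 ms steps with a 1 ms shift, 300 ms
    minimum peak distance) and standard practice elsewhere (EEMD ensemble
    of 100 at 0.2 relative noise SD).
    """

    wavelet_levels: int = 15
    ensemble_size: int = 100
    noise_sd_fraction: float = 0.2
    max_imfs: int = 10
    max_sift_iters: int = 10
    windows_ms: tuple[float, ...] = DEFAULT_WINDOWS_MS
    shift_ms: float = 1.0
    imf_levels: tuple[int, ...] = (1, 2, 3)
    default_window_range_ms: tuple[float, float] = (300.0, 400.0)
    min_distance_ms: float = 300.0
    screen_kurtosis_floor: float = 3.5
    screen_window_ms: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelet_levels < 1:
            raise DopbeatError("wavelet_levels must be >= 1")
        if self.ensemble_size < 1:
            raise DopbeatError("ensemble_size must be >= 1")
        if self.noise_sd_fraction < 0:
            raise DopbeatError("noise_sd_fraction must be >= 0")
        if not self.windows_ms or any(w <= 0 for w in self.windows_ms):
            raise DopbeatError("windows_ms must be a non-empty list of positive durations")
        if self.min_distance_ms <= 0:
            raise DopbeatError("min_distance_ms must be positive")
        if self.shift_ms <= 0:
            raise DopbeatError("shift_ms must be positive")
        object.__setattr__(self, "windows_ms", tuple(float(w) for w in self.windows_ms))
        object.__setattr__(self, "imf_levels", tuple(int(i) for i in self.imf_levels))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise DopbeatError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("windows_ms", "imf_levels", "default_window_range_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_overrides(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
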