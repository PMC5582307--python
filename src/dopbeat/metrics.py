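"""Evaluation of estimated beat series against reference annotations.

Per-record measures:

* signed beat-count mismatch (percent; negative = over-detection),
* mean successive beat error: the index-paired mean of
  ``100 * |true_rr(i) - est_bb(i)| / true_rr(i)`` over the first
  ``N_min`` intervals of the two series,
* spread of beat-location offsets (``var_b_loc``),
* heart-rate-variability summaries (mean interval, SDNN, RMSSD),
* Bland-Altman agreement statistics across a cohort.

Note the successive-beat error pairs intervals by index, not by time
alignment: a single missed beat shifts every subsequent pair.  This is
deliberate — it is the definition the error is known by — and a
time-aligned variant is logged separately for diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .core import BeatSeries, DopbeatError
from .kurtosis import mismatch_error, var_b_loc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HRVSummary:
    """Short-term heart-rate-variability summary of an interval series."""

    mean_bb: float
    sdnn: float
    rmssd: float
    n_intervals: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EvaluationReport:
    """All per-record comparison measures for one truth/estimate pair."""

    mismatch_pct: float
    mean_successive_beat_error_pct: float
    var_b_loc_ms: float
    hrv_true: HRVSummary
    hrv_est: HRVSummary
    n_min: int
    time_aligned_beat_error_pct: float | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def successive_beat_error(true_rr: np.ndarray, est_bb: np.ndarray) -> float:
    """Mean absolute index-paired interval error, percent.

    Averaged over ``N_min = min(len(true_rr), len(est_bb))`` interval
    pairs.
    """
    true_rr = np.asarray(true_rr, dtype=float)
    est_bb = np.asarray(est_bb, dtype=float)
    if true_rr.size == 0 or est_bb.size == 0:
        raise DopbeatError("interval vectors must be non-empty")
    n_min = min(true_rr.size, est_bb.size)
    t = true_rr[:n_min]
    if np.any(t <= 0):
        raise DopbeatError("true intervals must be positive")
    return float(np.mean(100.0 * np.abs(t - est_bb[:n_min]) / t))


def hrv_summary(intervals: np.ndarray) -> HRVSummary:
    """Mean, SDNN (sample SD) and RMSSD of an interval series (ms)."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise DopbeatError("need at least 2 intervals for an HRV summary")
    return HRVSummary(
        mean_bb=float(np.mean(intervals)),
        sdnn=float(np.std(intervals, ddof=1)),
        rmssd=float(np.sqrt(np.mean(np.diff(intervals) ** 2))),
        n_intervals=int(intervals.size),
    )


def bland_altman(
    true_vals: np.ndarray, est_vals: np.ndarray
) -> tuple[float, float, float]:
    """Mean difference and mean ± 2 SD limits of agreement.

    Differences are ``true - est``; the limits are symmetric about the
    mean difference by construction.
    """
    true_vals = np.asarray(true_vals, dtype=float)
    est_vals = np.asarray(est_vals, dtype=float)
    if true_vals.size != est_vals.size:
        raise DopbeatError("Bland-Altman requires equal-length vectors")
    if true_vals.size < 2:
        raise DopbeatError("Bland-Altman requires at least 2 pairs")
    d = true_vals - est_vals
    mean_d = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean_d, mean_d - 2.0 * sd, mean_d + 2.0 * sd


def _time_aligned_error(truth: BeatSeries, est: BeatSeries, max_ms: float = 300.0) -> float | None:
    """Diagnostic variant pairing intervals by nearest beat times."""
    t, e = truth.beat_times, est.beat_times
    idx = np.searchsorted(t, e)
    idx = np.clip(idx, 1, t.size - 1)
    nearest = np.where(
        np.abs(e - t[idx - 1]) <= np.abs(e - t[idx]), idx - 1, idx
    )
    ok = np.abs(e - t[nearest]) <= max_ms
    pairs = [
        (nearest[k], k)
        for k in range(1, e.size)
        if ok[k] and ok[k - 1] and nearest[k] == nearest[k - 1] + 1
    ]
    if not pairs:
        return None
    errs = [
        100.0 * abs((t[j] - t[j - 1]) - (e[k] - e[k - 1])) / (t[j] - t[j - 1])
        for j, k in pairs
    ]
    return float(np.mean(errs))


def evaluate_record(truth: BeatSeries, est: BeatSeries) -> EvaluationReport:
    """Full per-record evaluation of an estimated beat series."""
    if truth.n_beats == 0 or est.n_beats == 0:
        raise DopbeatError("both beat series must be non-empty")
    report = EvaluationReport(
        mismatch_pct=mismatch_error(truth.n_beats, est.n_beats),
        mean_successive_beat_error_pct=successive_beat_error(truth.intervals, est.intervals),
        var_b_loc_ms=var_b_loc(truth, est),
        hrv_true=hrv_summary(truth.intervals),
        hrv_est=hrv_summary(est.intervals),
        n_min=min(truth.intervals.size, est.intervals.size),
        time_aligned_beat_error_pct=_time_aligned_error(truth, est),
    )
    logger.info(
        "record evaluation: mismatch %.2f%%, successive beat error %.2f%%, varB_loc %.2f ms",
        report.mismatch_pct,
        report.mean_successive_beat_error_pct,
        report.var_b_loc_ms,
    )
    return report


def aggregate_cohort(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Cohort summary table.

    Beat-count mismatch is aggregated as the root-mean-square of the
    signed per-record values (the only aggregation that yields a single
    unsigned group number); the other measures as mean ± SD.
    """
    if not reports:
        raise DopbeatError("empty report list")
    mism = np.array([r.mismatch_pct for r in reports])
    sbe = np.array([r.mean_successive_beat_error_pct for r in reports])
    vb = np.array([r.var_b_loc_ms for r in reports])

    def mean_sd(values: np.ndarray) -> tuple[float, float]:
        return float(np.mean(values)), float(np.std(values, ddof=1)) if values.size > 1 else 0.0

    rows = {
        "mismatch_rms_pct": (float(np.sqrt(np.mean(mism**2))), np.nan),
        "successive_beat_error_pct": mean_sd(sbe),
        "var_b_loc_ms": mean_sd(vb),
    }
    for name, getter in (
        ("mean_bb_true_ms", lambda r: r.hrv_true.mean_bb),
        ("mean_bb_est_ms", lambda r: r.hrv_est.mean_bb),
        ("sdnn_true_ms", lambda r: r.hrv_true.sdnn),
        ("sdnn_est_ms", lambda r: r.hrv_est.sdnn),
        ("rmssd_true_ms", lambda r: r.hrv_true.rmssd),
        ("rmssd_est_ms", lambda r: r.hrv_est.rmssd),
    ):
        rows[name] = mean_sd(np.array([getter(r) for r in reports]))
    table = pd.DataFrame(rows, index=["mean", "sd"]).T
    table["n_records"] = len(reports)
    return table
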