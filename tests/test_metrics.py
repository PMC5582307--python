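"""Evaluation metrics: interval errors, HRV summaries, agreement stats."""

import numpy as np
import pytest

from dopbeat import (
    BeatSeries,
    DopbeatError,
    aggregate_cohort,
    bland_altman,
    evaluate_record,
    hrv_summary,
    successive_beat_error,
)


class TestSuccessiveBeatError:
    def test_identical_vectors_zero(self):
        assert successive_beat_error([400.0, 410.0], [400.0, 410.0]) == 0.0

    def test_hand_computed_case(self):
        assert successive_beat_error([400.0, 420.0], [410.0, 420.0]) == pytest.approx(1.25)

    def test_averages_over_n_min_terms_only(self):
        true_rr = [400.0, 400.0, 400.0, 999.0, 999.0]
        est = [410.0, 410.0, 410.0]
        assert successive_beat_error(true_rr, est) == pytest.approx(2.5)

    def test_truncation_beyond_n_min_is_irrelevant(self):
        base = successive_beat_error([400.0, 420.0, 440.0], [402.0, 418.0, 444.0])
        extended = successive_beat_error([400.0, 420.0, 440.0, 550.0], [402.0, 418.0, 444.0])
        assert base == extended

    def test_nonpositive_true_interval_rejected(self):
        with pytest.raises(DopbeatError):
            successive_beat_error([400.0, -1.0], [400.0, 400.0])


class TestHRVSummary:
    def test_constant_intervals(self):
        s = hrv_summary([400.0, 400.0, 400.0])
        assert (s.mean_bb, s.sdnn, s.rmssd) == (400.0, 0.0, 0.0)

    def test_definitional_hand_values(self):
        s = hrv_summary([390.0, 400.0, 410.0, 420.0])
        assert s.mean_bb == pytest.approx(405.0)
        assert s.sdnn == pytest.approx(12.9099, abs=1e-3)
        assert s.rmssd == pytest.approx(10.0)

    def test_two_intervals_rmssd_is_absolute_difference(self):
        s = hrv_summary([400.0, 412.0])
        assert s.rmssd == pytest.approx(12.0)

    def test_single_interval_rejected(self):
        with pytest.raises(DopbeatError):
            hrv_summary([400.0])

    def test_permutation_changes_rmssd_but_not_mean_or_sdnn(self):
        a = hrv_summary([390.0, 400.0, 410.0, 420.0])
        b = hrv_summary([390.0, 410.0, 400.0, 420.0])
        assert a.mean_bb == b.mean_bb
        assert a.sdnn == pytest.approx(b.sdnn)
        assert a.rmssd != b.rmssd


class TestBlandAltman:
    def test_perfect_agreement(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_hand_computed_limits(self):
        mean_d, lo, hi = bland_altman([1.0, 0.0], [0.0, 1.0])
        sd = np.std([1.0, -1.0], ddof=1)
        assert mean_d == pytest.approx(0.0)
        assert lo == pytest.approx(-2 * sd)
        assert hi == pytest.approx(2 * sd)
        assert hi == pytest.approx(2.8284, abs=1e-3)

    def test_limits_symmetric_about_mean(self):
        rng = np.random.default_rng(0)
        t, e = rng.normal(400, 10, 30), rng.normal(400, 10, 30)
        mean_d, lo, hi = bland_altman(t, e)
        assert hi - mean_d == pytest.approx(mean_d - lo)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DopbeatError):
            bland_altman([1.0, 2.0], [1.0])


class TestEvaluateRecord:
    def test_perfect_estimate_all_zero_errors(self):
        truth = BeatSeries(np.arange(20) * 400.0 + 100.0)
        rep = evaluate_record(truth, truth)
        assert rep.mismatch_pct == 0.0
        assert rep.mean_successive_beat_error_pct == 0.0
        assert rep.var_b_loc_ms == 0.0
        assert rep.hrv_true == rep.hrv_est

    def test_over_detection_gives_negative_mismatch(self):
        truth = BeatSeries(np.arange(10) * 400.0)
        est = BeatSeries(np.arange(11) * 365.0)
        rep = evaluate_record(truth, est)
        assert rep.mismatch_pct < 0.0

    def test_n_min_bookkeeping(self):
        truth = BeatSeries(np.arange(10) * 400.0)
        est = BeatSeries(np.arange(7) * 401.0)
        rep = evaluate_record(truth, est)
        assert rep.n_min == 6


class TestAggregateCohort:
    def _report(self, mismatch):
        truth = BeatSeries(np.arange(10) * 400.0)
        rep = evaluate_record(truth, truth)
        return type(rep)(
            mismatch_pct=mismatch,
            mean_successive_beat_error_pct=rep.mean_successive_beat_error_pct,
            var_b_loc_ms=rep.var_b_loc_ms,
            hrv_true=rep.hrv_true,
            hrv_est=rep.hrv_est,
            n_min=rep.n_min,
        )

    def test_single_report_rms_is_absolute_mismatch(self):
        table = aggregate_cohort([self._report(-3.0)])
        assert table.loc["mismatch_rms_pct", "mean"] == pytest.approx(3.0)

    def test_rms_of_mixed_signs(self):
        table = aggregate_cohort([self._report(3.0), self._report(-4.0)])
        assert table.loc["mismatch_rms_pct", "mean"] == pytest.approx(
            np.sqrt((9 + 16) / 2), abs=1e-3
        )

    def test_identical_reports_have_zero_sd(self):
        table = aggregate_cohort([self._report(2.0)] * 4)
        assert table.loc["successive_beat_error_pct", "sd"] == 0.0

    def test_rms_dominates_absolute_mean(self):
        rng = np.random.default_rng(1)
        reports = [self._report(m) for m in rng.normal(0, 3, 12)]
        table = aggregate_cohort(reports)
        rms = table.loc["mismatch_rms_pct", "mean"]
        assert rms >= abs(np.mean([r.mismatch_pct for r in reports])) - 1e-12

    def test_empty_cohort_rejected(self):
        with pytest.raises(DopbeatError):
            aggregate_cohort([])
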