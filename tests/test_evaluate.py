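"""Event matching and confusion-count metric arithmetic."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizefeat.evaluate import (
    ConfusionCounts,
    UndefinedMetricError,
    accuracy,
    aggregate,
    f_measure,
    fp_per_hour,
    g_mean,
    load_reference_counts,
    match_events,
    metrics_report,
    precision,
    sensitivity,
    specificity,
)
from seizefeat.io import Annotation, AnnotationSet


def toy_truth():
    return AnnotationSet(
        entries=[Annotation("a.edf", 2996, 3036), Annotation("b.edf", 100, 160)],
        roster=["a.edf", "b.edf", "c.edf", "d.edf"],
    )


class TestMatchEvents:
    def test_overlapping_detection_is_tp(self):
        counts = match_events([("a.edf", 3000.0, 3040.0)], toy_truth())
        assert (counts.tp, counts.fp) == (1, 0)
        assert counts.fn == 1  # b.edf seizure missed
        assert counts.tn == 2  # c.edf and d.edf untouched

    def test_no_detections_all_fn(self):
        counts = match_events([], toy_truth())
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (0, 0, 2, 2)

    def test_detection_in_clean_record_is_fp_not_tn(self):
        counts = match_events([("c.edf", 10.0, 20.0)], toy_truth())
        assert counts.fp == 1 and counts.tn == 1

    def test_unknown_record_rejected(self):
        with pytest.raises(ValueError, match="unknown record"):
            match_events([("zz.edf", 0.0, 1.0)], toy_truth())

    def test_onset_window_rejects_late_detection(self):
        counts = match_events(
            [("a.edf", 3030.0, 3100.0)], toy_truth(), onset_window_s=30.0
        )
        assert counts.tp == 0 and counts.fn == 2

    def test_hour_unit_policy(self):
        counts = match_events(
            [("a.edf", 3000.0, 3040.0)],
            toy_truth(),
            unit_policy="hour",
            record_hours={"a.edf": 1.0, "b.edf": 1.0, "c.edf": 2.0, "d.edf": 1.0},
        )
        # a busy (TP), b busy (missed ann), c and d clean: 2 + 1 = 3 clean hours
        assert counts.tn == 3

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partition_on_random_toy_rosters(self, seed):
        """TP+FN partitions annotations; every detection is TP-support or FP."""
        rng = np.random.default_rng(seed)
        files = [f"f{i}" for i in range(4)]
        entries = []
        for f in files:
            for _ in range(rng.integers(0, 3)):
                lo = float(rng.uniform(0, 500))
                entries.append(Annotation(f, lo, lo + float(rng.uniform(1, 60))))
        truth = AnnotationSet(entries=entries, roster=files)
        dets = []
        for f in files:
            for _ in range(rng.integers(0, 3)):
                lo = float(rng.uniform(0, 500))
                dets.append((f, lo, lo + float(rng.uniform(1, 60))))
        counts = match_events(dets, truth)
        # independent brute-force recount
        def overlap(a, b, c, d):
            return a < d and c < b

        exp_tp = sum(
            any(f == e.file_id and overlap(lo, hi, e.onset_s, e.end_s) for f, lo, hi in dets)
            for e in truth.entries
        )
        exp_fp = sum(
            not any(
                f == e.file_id and overlap(lo, hi, e.onset_s, e.end_s)
                for e in truth.entries
            )
            for f, lo, hi in dets
        )
        busy = {e.file_id for e in truth.entries} | {f for f, _, _ in dets}
        assert counts.tp == exp_tp
        assert counts.fn == len(truth.entries) - exp_tp
        assert counts.fp == exp_fp
        assert counts.tn == sum(f not in busy for f in files)


class TestMetricFormulas:
    def test_perfect_patient(self):
        c = ConfusionCounts(tp=7, fp=0, fn=0, tn=49)
        assert sensitivity(c) == 100.0 and specificity(c) == 100.0

    def test_partial_detection_row(self):
        c = ConfusionCounts(tp=8, fp=8, fn=4, tn=48)
        assert sensitivity(c) == pytest.approx(66.67, abs=0.005)
        assert specificity(c) == pytest.approx(85.71, abs=0.005)
        assert precision(c) == pytest.approx(50.00, abs=0.005)
        assert accuracy(c) == pytest.approx(82.35, abs=0.005)
        assert f_measure(c) == pytest.approx(57.14, abs=0.005)
        assert g_mean(c) == pytest.approx(75.59, abs=0.005)

    def test_zero_sensitivity(self):
        assert sensitivity(ConfusionCounts(tp=0, fn=5)) == 0.0
        assert specificity(ConfusionCounts(tn=0, fp=1)) == 0.0

    def test_undefined_metrics_signal_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(tn=10))
        report = metrics_report(ConfusionCounts(tn=10))
        assert math.isnan(report.sensitivity) and report.specificity == 100.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_metric_inequalities(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp, fp, fn, tn)
        try:
            assert g_mean(c) ** 2 == pytest.approx(sensitivity(c) * specificity(c))
            assert g_mean(c) <= max(sensitivity(c), specificity(c)) + 1e-9
            assert f_measure(c) <= max(precision(c), sensitivity(c)) + 1e-9
        except UndefinedMetricError:
            pass


class TestFpPerHour:
    def test_corpus_scale_rate(self):
        assert fp_per_hour(46, 980) == pytest.approx(0.047, abs=0.001)

    def test_zero_and_simple_rates(self):
        assert fp_per_hour(0, 10) == 0.0
        assert fp_per_hour(3, 1.5) == 2.0

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValueError):
            fp_per_hour(1, 0)


class TestAggregate:
    def test_single_patient_summary_equals_row(self):
        r = metrics_report(ConfusionCounts(tp=3, fp=1, fn=1, tn=20), label="p1")
        summary = aggregate([r])
        assert summary["mean_sensitivity"] == pytest.approx(r.sensitivity)
        assert summary["pooled_counts"] == r.counts

    def test_reference_corpus_footer_means(self):
        df = load_reference_counts("manual")
        reports = [
            metrics_report(
                ConfusionCounts(int(r.tp), int(r.fp), int(r.fn), int(r.tn)),
                label=str(r.patient),
            )
            for r in df.itertuples()
        ]
        summary = aggregate(reports)
        assert round(summary["mean_sensitivity"]) == 93
        assert round(summary["mean_specificity"]) == 96
        assert summary["pooled_counts"].tp == 174
        assert summary["pooled_counts"].fp == 46

    def test_pooled_and_mean_metrics_both_reported(self):
        rs = [
            metrics_report(ConfusionCounts(tp=1, fn=1, tn=10)),
            metrics_report(ConfusionCounts(tp=9, fn=0, tn=5, fp=5)),
        ]
        s = aggregate(rs)
        assert s["mean_sensitivity"] == pytest.approx((50 + 100) / 2)
        assert s["pooled_sensitivity"] == pytest.approx(100 * 10 / 11)
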