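"""Detection scoring: event matching, confusion counts, and derived metrics.

Events are matched by any-overlap between a detected interval and an
annotated one.  True negatives are counted per record (a file with neither
annotations nor detections), the convention used for whole-corpus EEG
benchmarks; an hour-segment unit is available as an alternative.  Derived
metrics are the six standard ones -- accuracy, specificity, sensitivity,
precision, F-measure, G-mean -- reported in percent, plus the false-positive
rate per hour of recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import EpochSet
from .io import AnnotationSet

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "match_events",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "f_measure",
    "g_mean",
    "fp_per_hour",
    "metrics_report",
    "aggregate",
    "load_reference_counts",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero: the value is undefined (not 0, not 100)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _overlaps(a_lo: float, a_hi: float, b_lo: float, b_hi: float) -> bool:
    return a_lo < b_hi and b_lo < a_hi


def match_events(
    detections: Mapping[str, EpochSet] | Iterable[tuple[str, float, float]],
    truth: AnnotationSet,
    roster: Sequence[str] | None = None,
    unit_policy: str = "record",
    record_hours: Mapping[str, float] | None = None,
    onset_window_s: float | None = None,
) -> ConfusionCounts:
    """Score detections against annotations.

    * TP: annotated seizures overlapped by at least one detection;
    * FN: annotated seizures with no overlapping detection;
    * FP: detections overlapping no annotation;
    * TN: roster records with neither annotations nor detections
      (``unit_policy="record"``), or empty hour segments
      (``unit_policy="hour"``, which needs ``record_hours``).

    ``detections`` is a mapping ``file_id -> EpochSet`` or an iterable of
    ``(file_id, onset_s, end_s)`` triples.  ``onset_window_s``, when given,
    additionally requires the detection onset to fall within that many
    seconds of the annotated onset for a TP.
    """
    if isinstance(detections, Mapping):
        det_list = [
            (fid, lo, hi) for fid, es in detections.items() for lo, hi in es.intervals_s()
        ]
    else:
        det_list = [(str(f), float(a), float(b)) for f, a, b in detections]
    roster = list(roster) if roster is not None else list(truth.roster)
    known = set(roster) | {e.file_id for e in truth.entries}
    for fid, _, _ in det_list:
        if fid not in known:
            raise ValueError(f"detection refers to unknown record {fid!r}")

    tp = fn = fp = 0
    matched_dets: set[int] = set()
    for ann in truth.entries:
        hit = False
        for i, (fid, lo, hi) in enumerate(det_list):
            if fid != ann.file_id or not _overlaps(lo, hi, ann.onset_s, ann.end_s):
                continue
            if onset_window_s is not None and abs(lo - ann.onset_s) > onset_window_s:
                continue
            hit = True
            matched_dets.add(i)
        tp += hit
        fn += not hit
    for i, (fid, lo, hi) in enumerate(det_list):
        overlaps_truth = any(
            fid == ann.file_id and _overlaps(lo, hi, ann.onset_s, ann.end_s)
            for ann in truth.entries
        )
        if not overlaps_truth:
            fp += 1

    files_with_ann = {e.file_id for e in truth.entries}
    files_with_det = {fid for fid, _, _ in det_list}
    if unit_policy == "record":
        tn = sum(1 for f in roster if f not in files_with_ann and f not in files_with_det)
    elif unit_policy == "hour":
        if record_hours is None:
            raise ValueError('unit_policy="hour" requires record_hours')
        tn = 0
        for f in roster:
            hours = int(math.ceil(record_hours.get(f, 0.0)))
            for h in range(hours):
                seg = (3600.0 * h, 3600.0 * (h + 1))
                busy = any(
                    _overlaps(*seg, e.onset_s, e.end_s)
                    for e in truth.entries
                    if e.file_id == f
                ) or any(
                    _overlaps(*seg, lo, hi) for fid, lo, hi in det_list if fid == f
                )
                tn += not busy
    else:
        raise ValueError(f"unknown unit_policy {unit_policy!r}")
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio_pct(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    return 100.0 * num / den


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN), percent: the fraction of seizures found."""
    return _ratio_pct(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP), percent: the fraction of non-seizure units kept clean."""
    return _ratio_pct(c.tn, c.tn + c.fp, "specificity")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP), percent."""
    return _ratio_pct(c.tp, c.tp + c.fp, "precision")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total, percent."""
    return _ratio_pct(c.tp + c.tn, c.total, "accuracy")


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and sensitivity, percent."""
    p, s = precision(c), sensitivity(c)
    if p + s == 0:
        raise UndefinedMetricError("f_measure undefined: precision + sensitivity = 0")
    return 2.0 * p * s / (p + s)


def g_mean(c: ConfusionCounts) -> float:
    """Geometric mean of sensitivity and specificity, percent."""
    return math.sqrt(sensitivity(c) * specificity(c))


def fp_per_hour(fp: int, hours: float) -> float:
    """False detections per hour of continuous recording."""
    if hours <= 0:
        raise ValueError(f"hours must be positive, got {hours}")
    return fp / hours


@dataclass
class MetricsReport:
    """The six derived metrics (percent; NaN where undefined) plus FP/h."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_measure: float
    g_mean: float
    fp_per_hour: float = float("nan")
    label: str | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        out = {
            "label": self.label,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
        }
        for k in ("sensitivity", "specificity", "precision", "accuracy", "f_measure", "g_mean", "fp_per_hour"):
            v = getattr(self, k)
            out[k] = round(v, ndigits) if not math.isnan(v) else None
        return out


def metrics_report(
    counts: ConfusionCounts, hours: float | None = None, label: str | None = None
) -> MetricsReport:
    """All metrics from one set of counts; undefined entries become NaN."""

    def safe(fn) -> float:
        try:
            return fn(counts)
        except UndefinedMetricError:
            return float("nan")

    return MetricsReport(
        counts=counts,
        sensitivity=safe(sensitivity),
        specificity=safe(specificity),
        precision=safe(precision),
        accuracy=safe(accuracy),
        f_measure=safe(f_measure),
        g_mean=safe(g_mean),
        fp_per_hour=fp_per_hour(counts.fp, hours) if hours else float("nan"),
        label=label,
    )


def aggregate(per_patient: Sequence[MetricsReport]) -> dict:
    """Dataset summary: unweighted means of per-patient metrics + pooled counts.

    The mean-of-patient-metrics (the usual benchmark-table footer) and the
    metrics of the pooled counts generally differ; both are returned, keyed
    ``mean_*`` and ``pooled_*``.
    """
    if not per_patient:
        raise ValueError("need at least one patient report")
    out: dict = {"n_patients": len(per_patient)}
    for k in ("sensitivity", "specificity", "precision", "accuracy", "f_measure", "g_mean"):
        vals = [getattr(r, k) for r in per_patient]
        defined = [v for v in vals if not math.isnan(v)]
        out[f"mean_{k}"] = float(np.mean(defined)) if defined else float("nan")
    pooled = ConfusionCounts()
    for r in per_patient:
        pooled = pooled + r.counts
    out["pooled_counts"] = pooled
    pooled_report = metrics_report(pooled)
    for k in ("sensitivity", "specificity", "precision", "accuracy", "f_measure", "g_mean"):
        out[f"pooled_{k}"] = getattr(pooled_report, k)
    return out


def load_reference_counts(mode: str = "manual") -> pd.DataFrame:
    """Published per-patient confusion counts for the CHB-MIT scalp-EEG corpus.

    ``mode`` selects the expert-assisted manual review counts (24 patients)
    or the fully automated counts (17 patients).  Columns: patient, trials,
    tp, fp, fn, tn.  These serve as reference inputs for the metric
    arithmetic; they are not produced by this package.
    """
    if mode not in {"manual", "automated"}:
        raise ValueError("mode must be 'manual' or 'automated'")
    with resources.files("seizefeat.data").joinpath("chbmit_reference_counts.csv").open() as f:
        df = pd.read_csv(f)
    return df[df["mode"] == mode].reset_index(drop=True)
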