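"""Optional external validation against a user-supplied CHB-MIT download.

Given the root of a local copy of the CHB-MIT scalp EEG corpus
(https://physionet.org/content/chbmit/ -- patient directories ``chb01/``,
``chb02/``, ... each holding ``*.edf`` files and a ``chbNN-summary.txt``),
this script runs the automated detector over every record and emits a
per-patient benchmark-style report (counts, the six derived metrics, and
FP/h) for side-by-side comparison with published numbers.

This is not part of the test suite: it needs the external download and
hours of CPU for the full corpus.  Restrict to a few patients first::

    python scripts/chbmit_report.py /data/chbmit --patients chb01 chb03 \
        --out chbmit_report.json
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

from seizefeat.config import RunConfig
from seizefeat.detect import detect
from seizefeat.evaluate import aggregate, fp_per_hour, match_events, metrics_report
from seizefeat.feature import build_feature_signal
from seizefeat.io import read_annotations, read_edf


def process_patient(patient_dir: Path, cfg: RunConfig) -> dict:
    summaries = sorted(patient_dir.glob("*-summary.txt"))
    if not summaries:
        raise FileNotFoundError(f"no *-summary.txt in {patient_dir}")
    truth = read_annotations(summaries[0], dialect="chbmit_summary")
    detections = []
    hours = 0.0
    for name in truth.roster:
        edf = patient_dir / name
        if not edf.exists():
            print(f"  missing {name}, skipped")
            continue
        t0 = time.perf_counter()
        rec = read_edf(edf, drop_non_eeg=True)
        hours += rec.duration_s / 3600.0
        fx = build_feature_signal(rec, cfg.preprocess, cfg.feature)
        epochs = detect(fx, cfg.detection)
        detections.extend((name, a, b) for a, b in epochs.intervals_s())
        print(
            f"  {name}: {len(epochs)} epoch(s) in {time.perf_counter() - t0:.1f}s"
        )
    counts = match_events(detections, truth, truth.roster)
    report = metrics_report(counts, hours=hours or None, label=patient_dir.name)
    return {"report": report, "hours": hours}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("corpus_root", type=Path)
    parser.add_argument("--patients", nargs="*", help="Patient ids (default: all chb* dirs).")
    parser.add_argument("--params", type=Path, help="Optional flat YAML parameter file.")
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    if args.params:
        from seizefeat.config import load_config

        cfg = load_config(args.params)
    else:
        cfg = RunConfig()
    cfg.validate()

    if args.patients:
        patient_dirs = [args.corpus_root / p for p in args.patients]
    else:
        patient_dirs = sorted(
            d for d in args.corpus_root.iterdir() if d.is_dir() and d.name.startswith("chb")
        )
    rows = []
    reports = []
    total_hours = 0.0
    for pdir in patient_dirs:
        print(pdir.name)
        result = process_patient(pdir, cfg)
        reports.append(result["report"])
        total_hours += result["hours"]
        rows.append(result["report"].rounded())
    summary = aggregate(reports)
    pooled = summary.pop("pooled_counts")
    payload = {
        "rows": rows,
        "footer": {k: round(v, 2) if isinstance(v, float) else v for k, v in summary.items()},
        "pooled": {
            "tp": pooled.tp, "fp": pooled.fp, "fn": pooled.fn, "tn": pooled.tn,
            "hours": round(total_hours, 1),
            "fp_per_hour": round(fp_per_hour(pooled.fp, total_hours), 4) if total_hours else None,
        },
        "parameters": cfg.to_flat_dict(),
    }
    args.out.write_text(json.dumps(payload, indent=1))
    print(json.dumps(payload["footer"], indent=1))


if __name__ == "__main__":
    main()
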