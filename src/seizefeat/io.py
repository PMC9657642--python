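"""EDF and annotation I/O for multichannel scalp EEG.

Reading goes through :func:`mne.io.read_raw_edf`; writing uses a small
built-in EDF encoder (16-bit, one-second data records).  Annotations are
(file, onset, end) triples in seconds, readable from plain CSV/JSON or from
the CHB-MIT ``*-summary.txt`` dialect.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Recording",
    "Annotation",
    "AnnotationSet",
    "EDFFormatError",
    "UnsupportedLayoutError",
    "AnnotationError",
    "DEFAULT_CHANNEL_BLACKLIST",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_detections",
]


class EDFFormatError(ValueError):
    """Raised when a file is not a readable EDF/EDF+ recording."""


class UnsupportedLayoutError(ValueError):
    """Raised for EDF layouts the pipeline cannot process (e.g. mixed rates)."""


class AnnotationError(ValueError):
    """Raised for malformed annotation files."""


#: Label substrings that mark non-EEG channels in CHB-MIT-style montages.
DEFAULT_CHANNEL_BLACKLIST = ("-", "ECG", "EKG", "VNS", "LOC-ROC", "DUMMY", ".")


def _dedup_labels(labels: Sequence[str]) -> list[str]:
    """Disambiguate duplicate labels deterministically ("T8-P8" -> "T8-P8-1")."""
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            out.append(f"{lab}-{seen[lab]}")
        else:
            seen[lab] = 0
            out.append(lab)
    return out


@dataclass
class Recording:
    """A multichannel EEG record.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz (shared by all channels).
    channel_labels
        Ordered channel names (10-20 bipolar names such as ``"FP1-F7"``).
        Duplicates are suffixed ``-1``, ``-2``, ... on construction.
    start_time
        Optional wall-clock start of the record.
    source
        Optional originating file name.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: _dt.datetime | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        self.channel_labels = _dedup_labels([str(c) for c in self.channel_labels])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        """Same metadata, new sample matrix (used by the filter stages)."""
        return Recording(
            data=data,
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            start_time=self.start_time,
            source=self.source,
        )

    def drop_non_eeg(
        self, blacklist: Sequence[str] = DEFAULT_CHANNEL_BLACKLIST
    ) -> "Recording":
        """Drop channels whose label matches the blacklist.

        A label is dropped when it equals a blacklist entry, or contains a
        blacklist entry of length > 1 as a substring (``"-"`` placeholders
        must match exactly -- every bipolar label contains a dash).
        """
        keep = []
        for i, lab in enumerate(self.channel_labels):
            up = lab.upper().strip()
            bad = any(
                up == b.upper() or (len(b) > 1 and b.upper() in up) for b in blacklist
            )
            if not bad:
                keep.append(i)
        if not keep:
            raise UnsupportedLayoutError("channel blacklist removed every channel")
        return Recording(
            data=self.data[keep],
            fs=self.fs,
            channel_labels=[self.channel_labels[i] for i in keep],
            start_time=self.start_time,
            source=self.source,
        )


@dataclass(frozen=True, order=True)
class Annotation:
    """One expert-marked seizure interval, in seconds from record start."""

    file_id: str
    onset_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise AnnotationError(f"negative onset for {self.file_id}")
        if self.end_s <= self.onset_s:
            raise AnnotationError(
                f"end {self.end_s} <= onset {self.onset_s} for {self.file_id}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


@dataclass
class AnnotationSet:
    """Ground-truth seizure intervals plus the roster of all scored files.

    ``roster`` keeps files with zero seizures so that true negatives can be
    counted at the record level.
    """

    entries: list[Annotation] = field(default_factory=list)
    roster: list[str] = field(default_factory=list)
    total_hours: float | None = None

    def __post_init__(self) -> None:
        self.entries = _normalize_entries(self.entries)
        roster = list(dict.fromkeys(self.roster))
        for e in self.entries:
            if e.file_id not in roster:
                roster.append(e.file_id)
        self.roster = sorted(roster)

    def for_file(self, file_id: str) -> list[Annotation]:
        return [e for e in self.entries if e.file_id == file_id]

    @property
    def seizure_files(self) -> list[str]:
        return sorted({e.file_id for e in self.entries})

    def __len__(self) -> int:
        return len(self.entries)


def _normalize_entries(entries: Iterable[Annotation]) -> list[Annotation]:
    """Sort by (file, onset) and merge overlapping intervals within a file."""
    out: list[Annotation] = []
    for e in sorted(entries):
        if out and out[-1].file_id == e.file_id and e.onset_s <= out[-1].end_s:
            prev = out.pop()
            e = Annotation(e.file_id, prev.onset_s, max(prev.end_s, e.end_s))
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def _parse_edf_header(path: Path) -> dict:
    """Read the fixed-layout EDF header (for validation MNE does not expose)."""
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise EDFFormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EDFFormatError(f"{path}: corrupt EDF header") from exc
        if ns <= 0:
            raise EDFFormatError(f"{path}: no signals in header")
        sig = f.read(256 * ns)
        if len(sig) < 256 * ns:
            raise EDFFormatError(f"{path}: truncated signal headers")
    labels = [sig[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip() for i in range(ns)]
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip()) for i in range(ns)]
    return {
        "n_records": n_records,
        "record_dur": record_dur,
        "n_signals": ns,
        "labels": labels,
        "samples_per_record": spr,
    }


def read_edf(path: str | Path, drop_non_eeg: bool = False) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (data in microvolts).

    Parameters
    ----------
    path
        EDF file path.
    drop_non_eeg
        When True, drop channels matching :data:`DEFAULT_CHANNEL_BLACKLIST`
        after load (the channel average must span EEG channels only).

    Raises
    ------
    EDFFormatError
        Unreadable or corrupt file.
    UnsupportedLayoutError
        EEG channels with differing sampling rates.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = _parse_edf_header(path)
    annot_chans = {"EDF ANNOTATIONS"}
    rates = {
        spr
        for lab, spr in zip(header["labels"], header["samples_per_record"])
        if lab.upper() not in annot_chans
    }
    if len(rates) > 1:
        raise UnsupportedLayoutError(
            f"{path}: mixed sampling rates across channels ({sorted(rates)})"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises plain ValueError/OSError on bad files
        raise EDFFormatError(f"{path}: not a readable EDF file ({exc})") from exc
    data_uv = raw.get_data() * 1e6  # MNE loads EEG in volts
    meas_date = raw.info.get("meas_date")
    if not np.all(np.isfinite(data_uv)):
        raise EDFFormatError(f"{path}: non-finite samples after load")
    rec = Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        start_time=meas_date,
        source=path.name,
    )
    return rec.drop_non_eeg() if drop_non_eeg else rec


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.encode("ascii").ljust(width)


def _fmt_float(x: float, width: int = 8) -> bytes:
    for fmt in (f"{x:.{width - 2}g}", f"{x:.2f}", f"{x:.0f}"):
        s = fmt[:width]
        try:
            float(s)
            return s.encode("ascii").ljust(width)
        except ValueError:
            continue
    raise ValueError(f"cannot format {x} into {width} ascii chars")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` as plain EDF (16-bit, 1-second records).

    Physical min/max per signal are taken from the data (symmetric about 0),
    so the round-trip error is bounded by half a quantization step,
    ``(phys_max - phys_min) / 2**16``.  If the record length is not a whole
    number of seconds the final data record is padded with edge values;
    reading it back then yields up to ``fs - 1`` extra trailing samples.
    """
    path = Path(path)
    if recording.n_samples == 0:
        raise ValueError("cannot write an empty recording (0 samples)")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedLayoutError(f"EDF writer requires an integer rate, got {fs}")
    fs = int(round(fs))
    n_ch, n_samp = recording.data.shape
    n_records = int(np.ceil(n_samp / fs))

    data = recording.data
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)  # symmetric range
    dig_min, dig_max = -32767, 32767  # symmetric so that digital 0 is exactly 0
    scale = phys_max / dig_max

    start = recording.start_time or _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate X X X X", 80),
            _ascii_field(start.strftime("%d.%m.%y"), 8),
            _ascii_field(start.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (1 + n_ch), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii_field(lab, 16) for lab in recording.channel_labels),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_ascii_field("uV", 8) for _ in range(n_ch)),
            b"".join(_fmt_float(-pm) for pm in phys_max),
            b"".join(_fmt_float(pm) for pm in phys_max),
            b"".join(_ascii_field(dig_min, 8) for _ in range(n_ch)),
            b"".join(_ascii_field(dig_max, 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_ascii_field(fs, 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 32) for _ in range(n_ch)),
        ]
    )

    pad = n_records * fs - n_samp
    if pad:
        data = np.concatenate([data, np.repeat(data[:, -1:], pad, axis=1)], axis=1)
    digital = np.clip(np.round(data / scale[:, None]), dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            f.write(block.tobytes())  # signal-major within each record
    return path


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_SUMMARY_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.IGNORECASE)
_SUMMARY_NSEIZ_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)", re.IGNORECASE)
_SUMMARY_START_RE = re.compile(
    r"^Seizure(?:\s+\d+)?\s+Start Time:\s*(\d+(?:\.\d+)?)\s*sec", re.IGNORECASE
)
_SUMMARY_END_RE = re.compile(
    r"^Seizure(?:\s+\d+)?\s+End Time:\s*(\d+(?:\.\d+)?)\s*sec", re.IGNORECASE
)


def _read_chbmit_summary(path: Path) -> AnnotationSet:
    entries: list[Annotation] = []
    roster: list[str] = []
    current: str | None = None
    pending_start: float | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if m := _SUMMARY_FILE_RE.match(line):
            current = m.group(1)
            roster.append(current)
            pending_start = None
        elif m := _SUMMARY_START_RE.match(line):
            if current is None:
                raise AnnotationError(f"{path}:{lineno}: seizure time before any file")
            pending_start = float(m.group(1))
        elif m := _SUMMARY_END_RE.match(line):
            if current is None or pending_start is None:
                raise AnnotationError(f"{path}:{lineno}: end time without a start time")
            end = float(m.group(1))
            if end <= pending_start:
                raise AnnotationError(
                    f"{path}:{lineno}: end {end} <= start {pending_start}"
                )
            entries.append(Annotation(current, pending_start, end))
            pending_start = None
    return AnnotationSet(entries=entries, roster=roster)


def _read_csv_annotations(path: Path) -> AnnotationSet:
    entries = []
    roster = []
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        if reader.fieldnames is None or "file_id" not in reader.fieldnames:
            raise AnnotationError(
                f"{path}: CSV annotations need a header with file_id,onset_s,end_s"
            )
        for lineno, row in enumerate(reader, start=2):
            fid = row["file_id"].strip()
            roster.append(fid)
            onset, end = row.get("onset_s", ""), row.get("end_s", "")
            if onset == "" and end == "":
                continue  # roster-only row (file with no seizures)
            try:
                onset_f, end_f = float(onset), float(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-numeric interval") from exc
            if end_f <= onset_f:
                raise AnnotationError(f"{path}:{lineno}: end <= onset")
            entries.append(Annotation(fid, onset_f, end_f))
    return AnnotationSet(entries=entries, roster=roster)


def _read_json_annotations(path: Path) -> AnnotationSet:
    payload = json.loads(path.read_text())
    if isinstance(payload, dict):
        records = payload.get("entries", [])
        roster = list(payload.get("roster", []))
        hours = payload.get("total_hours")
    else:
        records, roster, hours = payload, [], None
    entries = []
    for i, obj in enumerate(records):
        try:
            onset, end = float(obj["onset_s"]), float(obj["end_s"])
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"{path}: bad entry #{i}: {obj!r}") from exc
        if end <= onset:
            raise AnnotationError(f"{path}: entry #{i}: end <= onset")
        entries.append(Annotation(str(obj["file_id"]), onset, end))
    return AnnotationSet(entries=entries, roster=roster, total_hours=hours)


def read_annotations(path: str | Path, dialect: str | None = None) -> AnnotationSet:
    """Read seizure annotations.

    ``dialect`` is one of ``"csv"``, ``"json"``, ``"chbmit_summary"``; when
    None it is inferred from the file name (``*-summary.txt`` / extension).
    """
    path = Path(path)
    if dialect is None:
        if path.name.endswith("-summary.txt") or path.suffix == ".txt":
            dialect = "chbmit_summary"
        elif path.suffix == ".json":
            dialect = "json"
        else:
            dialect = "csv"
    if dialect == "chbmit_summary":
        return _read_chbmit_summary(path)
    if dialect == "csv":
        return _read_csv_annotations(path)
    if dialect == "json":
        return _read_json_annotations(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def write_detections(detections, path: str | Path, fs: float | None = None) -> Path:
    """Write detected epochs as CSV (or JSON by extension).

    ``detections`` is either a single ``EpochSet`` or a mapping of
    ``file_id -> EpochSet``.  Columns: file_id, onset_s, end_s, duration_s,
    peak_value, power; seconds rounded to 2 decimals, rows sorted by
    (file_id, onset).
    """
    path = Path(path)
    if isinstance(detections, Mapping):
        items = sorted(detections.items())
    else:
        items = [(detections.file_id or "", detections)]
    rows = []
    for fid, es in items:
        f = fs or es.fs
        for ep in es.epochs:
            rows.append(
                {
                    "file_id": fid,
                    "onset_s": round(ep.start / f, 2),
                    "end_s": round(ep.end / f, 2),
                    "duration_s": round((ep.end - ep.start) / f, 2),
                    "peak_value": round(float(ep.peak_value), 4),
                    "power": round(float(ep.power), 2),
                }
            )
    rows.sort(key=lambda r: (r["file_id"], r["onset_s"]))
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        with open(path, "w", newline="") as f:
            writer = csv.DictWriter(
                f,
                fieldnames=["file_id", "onset_s", "end_s", "duration_s", "peak_value", "power"],
            )
            writer.writeheader()
            writer.writerows(rows)
    return path
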