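"""Seeded generator of scalp-EEG-like records with known seizure truth.

Each record is a sum of caricatured but spectrally plausible components:

* per-channel pink-noise background (1/f spectral shaping of seeded white
  noise) with occasional 10 Hz alpha bursts;
* injected ictal segments: a 1-4 Hz rhythmic discharge with a second
  harmonic (spike-and-wave caricature) on a channel subset, opening with a
  brief high-amplitude onset discharge -- the event that produces the
  narrow onset peak and baseline discontinuity the detector keys on;
* artefacts the detection rules must reject: brief large jaw/EMG bursts
  (20-35 Hz), common-mode 60 Hz interference, slow drift, and per-channel
  DC offsets.

Every record draws from a single RNG stream keyed by (seed, record index),
so corpora are reproducible record-by-record.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Annotation, AnnotationSet, Recording, write_edf

__all__ = [
    "CHBMIT_BIPOLAR_LABELS",
    "SeizureSpec",
    "SimParams",
    "random_seizures",
    "simulate_recording",
    "make_test_suite",
]

#: The 23-channel longitudinal-bipolar montage used by CHB-MIT-style
#: recordings (note the duplicated "T8-P8" pair, present in the originals).
CHBMIT_BIPOLAR_LABELS = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9",
    "FT9-FT10", "FT10-T8", "T8-P8",
]


@dataclass(frozen=True)
class SeizureSpec:
    """One injected ictal segment.

    ``amplitude_mult`` scales the sustained discharge relative to the
    background noise amplitude (>= 3 for a detectable event); the first
    ``onset_burst_s`` seconds are further scaled by ``onset_factor`` to
    model the high-amplitude onset discharge.
    """

    onset_s: float
    duration_s: float
    channels: tuple[int, ...]
    ictal_freq_hz: float = 3.0
    amplitude_mult: float = 8.0
    onset_factor: float = 2.5
    onset_burst_s: float = 0.8

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("seizure channel subset must be non-empty")
        if self.duration_s <= 0 or self.onset_s < 0:
            raise ValueError("seizure interval must have positive extent")
        if not 1.0 <= self.ictal_freq_hz <= 4.0:
            raise ValueError("ictal frequency must lie in the 1-4 Hz band")
        if self.amplitude_mult < 3:
            raise ValueError("amplitude multiplier must be >= 3 for a visible event")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SimParams:
    """Generator settings (defaults emulate a CHB-MIT-style hour record)."""

    n_channels: int = 23
    fs: float = 256.0
    duration_s: float = 3600.0
    seed: int = 0
    background_amp_uv: float = 30.0    # pink-noise standard deviation
    alpha_amp_uv: float = 20.0         # 10 Hz burst amplitude
    alpha_bursts_per_min: float = 3.0
    seizures: tuple[SeizureSpec, ...] = ()
    jaw_bursts_per_hour: float = 12.0  # brief >20 Hz EMG bursts
    jaw_amp_uv: float = 100.0
    powerline_amp_uv: float = 8.0      # common-mode 60 Hz
    drift_amp_uv: float = 15.0         # < 0.05 Hz baseline wander
    dc_offset_uv: float = 50.0         # per-channel offset range (+-)
    file_id: str | None = None

    def validate(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("n_channels, fs and duration_s must be positive")
        events = sorted(self.seizures, key=lambda s: s.onset_s)
        for s in events:
            if s.end_s > self.duration_s:
                raise ValueError(f"seizure at {s.onset_s}s extends past the record")
            if max(s.channels) >= self.n_channels or min(s.channels) < 0:
                raise ValueError("seizure channel subset outside the montage")
        for a, b in zip(events, events[1:]):
            if b.onset_s < a.end_s:
                raise ValueError(
                    f"injected seizures overlap ({a.onset_s}-{a.end_s}s vs {b.onset_s}s)"
                )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    shape[0] = 0.0  # no DC from the noise itself
    pink = np.fft.irfft(spec * shape, n=n)
    return pink / pink.std()


def _cos_ramp(n: int, up: bool) -> np.ndarray:
    r = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n)))
    return r if up else r[::-1]


_ONSET_DISCHARGE_HZ = 3.0  # stereotyped onset rhythm, shared by all events


def _ictal_waveform(spec: SeizureSpec, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Sustained rhythmic discharge with onset burst; unit sustained amplitude.

    The opening discharge is a stereotyped 3 Hz polyspike burst at
    ``onset_factor`` times the sustained amplitude, identical in shape for
    every event: seizure onsets are far more uniform than the evolving
    rhythm that follows, and this keeps the per-record normalized onset
    peaks mutually consistent so that an onset threshold near 1 is
    meaningful when a record holds several seizures of one patient.
    """
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * spec.ictal_freq_hz * t + phase)
    wave += 0.3 * np.sin(2 * np.pi * 2 * spec.ictal_freq_hz * t + 2 * phase)  # spike
    env = np.ones(n)
    attack = max(2, int(0.1 * fs))
    decay = max(2, min(n // 4, int(2.0 * fs)))
    env[:attack] *= _cos_ramp(attack, up=True)
    env[-decay:] *= _cos_ramp(decay, up=False)
    out = wave * env

    nb = min(n, int(round(spec.onset_burst_s * fs)))
    taper = min(n - nb, int(0.3 * fs))
    onset = np.sin(2 * np.pi * _ONSET_DISCHARGE_HZ * t[: nb + taper])
    onset += 0.3 * np.sin(2 * np.pi * 2 * _ONSET_DISCHARGE_HZ * t[: nb + taper])
    blend = np.ones(nb + taper)
    if taper > 0:
        blend[nb:] = _cos_ramp(taper, up=False)
    out[: nb + taper] = (
        blend * spec.onset_factor * onset + (1 - blend) * out[: nb + taper]
    )
    return out


def simulate_recording(params: SimParams) -> tuple[Recording, AnnotationSet]:
    """Generate one record and the annotations of its injected seizures."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration_s * fs))
    n_ch = params.n_channels
    t = np.arange(n) / fs

    data = np.empty((n_ch, n))
    for c in range(n_ch):
        data[c] = params.background_amp_uv * _pink_noise(rng, n)

    # per-channel DC offsets and slow drift
    data += rng.uniform(-params.dc_offset_uv, params.dc_offset_uv, size=(n_ch, 1))
    for c in range(n_ch):
        f_drift = rng.uniform(0.01, 0.045)
        data[c] += params.drift_amp_uv * np.sin(
            2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi)
        )

    # common-mode mains interference
    data += params.powerline_amp_uv * np.sin(
        2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
    )[None, :]

    # alpha bursts on a posterior-ish random pair of channels
    n_alpha = rng.poisson(params.alpha_bursts_per_min * params.duration_s / 60.0)
    for _ in range(n_alpha):
        dur = rng.uniform(1.0, 2.0)
        start = rng.uniform(0, max(params.duration_s - dur, 0))
        i0, i1 = int(start * fs), int((start + dur) * fs)
        if i1 <= i0 + 4:
            continue
        seg_t = t[i0:i1]
        win = np.hanning(i1 - i0)
        chans = rng.choice(n_ch, size=min(2, n_ch), replace=False)
        for c in chans:
            data[c, i0:i1] += params.alpha_amp_uv * win * np.sin(
                2 * np.pi * 10.0 * seg_t + rng.uniform(0, 2 * np.pi)
            )

    # jaw / EMG bursts: brief, large, >20 Hz, on a spatially broad subset
    n_jaw = rng.poisson(params.jaw_bursts_per_hour * params.duration_s / 3600.0)
    for _ in range(n_jaw):
        dur = rng.uniform(0.1, 0.3)
        start = rng.uniform(0, max(params.duration_s - dur, 0))
        i0, i1 = int(start * fs), int((start + dur) * fs)
        if i1 <= i0 + 4:
            continue
        f_emg = rng.uniform(20.0, 35.0)
        win = np.hanning(i1 - i0)
        # EMG contaminates a roughly fixed fraction of the montage (the
        # temporal/frontal chains), so its weight in the channel average is
        # independent of montage size
        lo_n = max(2, n_ch // 5)
        hi_n = max(lo_n + 1, n_ch // 3 + 1)
        chans = rng.choice(n_ch, size=int(rng.integers(lo_n, hi_n)), replace=False)
        for c in chans:
            data[c, i0:i1] += params.jaw_amp_uv * win * np.sin(
                2 * np.pi * f_emg * t[i0:i1] + rng.uniform(0, 2 * np.pi)
            )

    # injected seizures
    entries = []
    file_id = params.file_id or f"sim-{params.seed}.edf"
    prev_end = 0
    for spec in sorted(params.seizures, key=lambda s: s.onset_s):
        i0 = int(round(spec.onset_s * fs))
        wave = _ictal_waveform(spec, fs, rng)
        amp = spec.amplitude_mult * params.background_amp_uv
        for c in spec.channels:
            data[c, i0 : i0 + len(wave)] += amp * wave
        entries.append(Annotation(file_id, spec.onset_s, spec.end_s))
        _assert_inband_contrast(data, spec, params, i0, len(wave), prev_end)
        prev_end = i0 + len(wave)

    labels = (
        CHBMIT_BIPOLAR_LABELS
        if n_ch == len(CHBMIT_BIPOLAR_LABELS)
        else [f"CH{i + 1}" for i in range(n_ch)]
    )
    rec = Recording(data=data, fs=fs, channel_labels=labels, source=file_id)
    ann = AnnotationSet(
        entries=entries, roster=[file_id], total_hours=params.duration_s / 3600.0
    )
    return rec, ann


def _inband_rms(x: np.ndarray, fs: float, lo: float = 0.1, hi: float = 4.1) -> float:
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    band = (freqs >= lo) & (freqs <= hi)
    return float(np.sqrt(np.sum(np.abs(spec[band]) ** 2) / len(x) ** 2 * 2))


def _assert_inband_contrast(
    data: np.ndarray,
    spec: SeizureSpec,
    params: SimParams,
    i0: int,
    n_ict: int,
    prev_end: int = 0,
) -> None:
    """Construction invariant: ictal in-band RMS >= 3x adjacent background.

    The comparison window is up to 30 s immediately before onset, clipped to
    exclude any earlier injected seizure.
    """
    c = spec.channels[0]
    pre = data[c, max(prev_end, i0 - int(30 * params.fs)) : i0]
    if len(pre) < int(params.fs):
        return  # seizure at record start: no adjacent background to compare
    r_ict = _inband_rms(data[c, i0 : i0 + n_ict], params.fs)
    r_bg = _inband_rms(pre, params.fs)
    if r_ict < 3 * r_bg:
        raise AssertionError(
            f"ictal in-band RMS {r_ict:.1f} < 3x background {r_bg:.1f}"
        )


def random_seizures(
    rng: np.random.Generator,
    n: int,
    duration_s: float,
    n_channels: int = 23,
    subset_size: int = 6,
    min_gap_s: float = 60.0,
) -> tuple[SeizureSpec, ...]:
    """Draw n non-overlapping seizures with defaults matching SeizureSpec.

    Durations are 30-120 s; the channel subset is a random draw of
    ``subset_size`` channels (all seizures of one record share amplitude
    settings so that every onset peak reaches the upper amplitude
    threshold after per-record normalization).
    """
    specs: list[SeizureSpec] = []
    margin = 30.0
    dur_hi = min(120.0, duration_s - 2 * margin)
    if n > 0 and dur_hi < 10.0:
        raise ValueError(f"record of {duration_s}s too short to hold a seizure")
    dur_lo = min(30.0, dur_hi)
    for _ in range(200):
        if len(specs) == n:
            break
        dur = float(rng.uniform(dur_lo, dur_hi))
        onset = float(rng.uniform(margin, max(duration_s - dur - margin, margin + 1)))
        if any(
            onset < s.end_s + min_gap_s and s.onset_s < onset + dur + min_gap_s
            for s in specs
        ):
            continue
        channels = tuple(
            int(c) for c in rng.choice(n_channels, size=min(subset_size, n_channels), replace=False)
        )
        specs.append(
            SeizureSpec(
                onset_s=onset,
                duration_s=dur,
                channels=channels,
                ictal_freq_hz=float(rng.uniform(1.0, 4.0)),
            )
        )
    if len(specs) < n:
        raise ValueError(f"could not place {n} seizures in {duration_s}s")
    return tuple(sorted(specs, key=lambda s: s.onset_s))


def corpus_params(
    seed: int,
    index: int,
    duration_s: float = 600.0,
    n_channels: int = 23,
    fs: float = 256.0,
) -> SimParams:
    """Parameters for record ``index`` of a corpus keyed by ``seed``.

    Roughly one record in three is seizure-free (artefacts only), so false
    positives per hour remain measurable; the rest carry 1-3 seizures.
    """
    rng = np.random.default_rng([seed, index])
    record_seed = int(rng.integers(0, 2**31 - 1))
    n_seiz = 0 if index % 3 == 2 else int(rng.integers(1, 4))
    max_fit = max(1, int(duration_s // 180))  # 30-120 s events + gaps
    n_seiz = min(n_seiz, max_fit)
    seizures = random_seizures(rng, n_seiz, duration_s, n_channels)
    return SimParams(
        n_channels=n_channels,
        fs=fs,
        duration_s=duration_s,
        seed=record_seed,
        seizures=seizures,
        file_id=f"sim{index:03d}.edf",
    )


def make_test_suite(
    n_records: int,
    seed: int,
    out_dir: str | Path,
    duration_s: float = 600.0,
    n_channels: int = 23,
) -> dict:
    """Write a corpus of EDFs + truth CSV + manifest; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "n_records": n_records, "records": []}
    all_entries: list[Annotation] = []
    roster: list[str] = []
    for i in range(n_records):
        params = corpus_params(seed, i, duration_s, n_channels)
        rec, ann = simulate_recording(params)
        write_edf(rec, out_dir / params.file_id)
        all_entries.extend(ann.entries)
        roster.append(params.file_id)
        manifest["records"].append(
            {
                "file_id": params.file_id,
                "n_seizures": len(ann.entries),
                "duration_s": duration_s,
            }
        )
    manifest["total_seizures"] = len(all_entries)
    with open(out_dir / "truth.csv", "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["file_id", "onset_s", "end_s"])
        for fid in roster:
            rows = [e for e in all_entries if e.file_id == fid]
            if not rows:
                writer.writerow([fid, "", ""])
            for e in rows:
                writer.writerow([e.file_id, f"{e.onset_s:.2f}", f"{e.end_s:.2f}"])
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
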