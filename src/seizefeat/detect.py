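"""Seizure-epoch detection on the normalized feature signal.

A seizure announces itself as a discontinuity in the envelope's baseline
band: a tall, narrow onset peak followed by a sustained supra-threshold
region.  Detection is a fixed rule cascade -- no classifier, no training:

1. find local maxima (onset candidates have height >= ``amp_upper``);
2. keep candidates whose half-prominence width lies in 0.4-1.8 s;
3. keep candidates whose in-band power clears ``seizAggressiveness``
   (rejects brief high-amplitude artefacts such as jaw clenches);
4. grow each survivor to the surrounding envelope region >= ``amp_lower``,
   merge regions separated by less than ``seizLinterval`` samples, and drop
   anything shorter than ``seizLinterval``.

An assisted-manual path (:func:`picks_to_epochs`) accepts externally picked
onset/offset times instead of step 1-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .feature import FeatureSignal

__all__ = [
    "DetectionParams",
    "PeakCandidate",
    "SeizureEpoch",
    "EpochSet",
    "find_onset_peaks",
    "width_filter",
    "epoch_power",
    "grow_and_merge",
    "detect",
    "make_mask",
    "mask_to_epochs",
    "picks_to_epochs",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds (all user-tunable within documented ranges).

    Attributes
    ----------
    seizLinterval : int
        Minimum epoch length and merge gap, in samples (default 256 = 1 s
        at 256 Hz).
    seizAggressiveness : float
        In-band power threshold in unnormalized feature-signal units
        (amplitude^2 * s); ideal range 180-220, default 200.  Smaller values
        start marking jaw artefacts as seizures.
    amp_lower : float
        Lower envelope limit as a fraction of 1 (default 0.075, usual range
        0.05-0.1); epoch extent is the contiguous region above it.
    amp_upper : float
        Onset-peak height threshold as a fraction of 1 (default 0.9, usual
        range 0.8-1).
    width_min_s, width_max_s : float
        Admissible onset-peak width (half-prominence) in seconds; outside
        0.4-1.8 s a peak is not considered a seizure onset.
    """

    seizLinterval: int = 256
    seizAggressiveness: float = 200.0
    amp_lower: float = 0.075
    amp_upper: float = 0.9
    width_min_s: float = 0.4
    width_max_s: float = 1.8

    def validate(self) -> None:
        if not 0 < self.amp_lower < self.amp_upper <= 1:
            raise ValueError(
                f"need 0 < amp_lower < amp_upper <= 1, got {self.amp_lower}, {self.amp_upper}"
            )
        if not 0 < self.width_min_s < self.width_max_s:
            raise ValueError("need 0 < width_min_s < width_max_s")
        if self.seizLinterval < 1:
            raise ValueError("seizLinterval must be >= 1 sample")
        if self.seizAggressiveness < 0:
            raise ValueError("seizAggressiveness must be non-negative")


@dataclass(frozen=True)
class PeakCandidate:
    """A local envelope maximum and its half-prominence geometry."""

    index: int
    height: float
    width_s: float
    prominence: float
    left_ips: float
    right_ips: float
    is_onset: bool  # height >= amp_upper


@dataclass(frozen=True)
class SeizureEpoch:
    """A detected seizure interval, half-open ``[start, end)`` in samples."""

    start: int
    end: int
    peak_value: float
    peak_width_s: float
    power: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty epoch [{self.start}, {self.end})")

    def duration_s(self, fs: float) -> float:
        return (self.end - self.start) / fs


@dataclass
class EpochSet:
    """Ordered, disjoint seizure epochs for one record."""

    epochs: list[SeizureEpoch] = field(default_factory=list)
    n_samples: int = 0
    fs: float = 256.0
    file_id: str | None = None

    def __post_init__(self) -> None:
        self.epochs = sorted(self.epochs, key=lambda e: e.start)
        prev_end = -1
        for ep in self.epochs:
            if ep.start <= prev_end:
                raise ValueError("epochs overlap or touch; merge them first")
            if ep.start < 0 or ep.end > self.n_samples:
                raise ValueError(f"epoch [{ep.start}, {ep.end}) outside record")
            prev_end = ep.end

    def __len__(self) -> int:
        return len(self.epochs)

    def intervals_s(self) -> list[tuple[float, float]]:
        return [(e.start / self.fs, e.end / self.fs) for e in self.epochs]

    @property
    def total_seizure_s(self) -> float:
        return sum(e.end - e.start for e in self.epochs) / self.fs


def find_onset_peaks(
    feature: FeatureSignal, params: DetectionParams = DetectionParams()
) -> list[PeakCandidate]:
    """Locate envelope maxima; flag onset candidates (height >= amp_upper).

    Peaks below ``amp_upper`` (but above ``amp_lower``) are returned too --
    they carry epoch-extent evidence -- while only onset candidates can seed
    an epoch.  Widths are measured at half prominence; a plateau's leftmost
    sample is its peak index (scipy's convention).  Peaks clipped by the
    record edge are measured on the available support.
    """
    params.validate()
    env = feature.envelope
    peaks, props = signal.find_peaks(
        env, height=params.amp_lower, prominence=params.amp_lower
    )
    if len(peaks) == 0:
        return []
    widths, _, left_ips, right_ips = signal.peak_widths(env, peaks, rel_height=0.5)
    out = []
    for i, p in enumerate(peaks):
        out.append(
            PeakCandidate(
                index=int(p),
                height=float(props["peak_heights"][i]),
                width_s=float(widths[i] / feature.fs),
                prominence=float(props["prominences"][i]),
                left_ips=float(left_ips[i]),
                right_ips=float(right_ips[i]),
                is_onset=bool(props["peak_heights"][i] >= params.amp_upper),
            )
        )
    return out


def width_filter(
    candidates: list[PeakCandidate], params: DetectionParams = DetectionParams()
) -> list[PeakCandidate]:
    """Keep onset candidates whose width lies in [width_min_s, width_max_s].

    Too-narrow peaks are amplitude spikes; too-wide ones are slow baseline
    swings -- neither is a seizure onset.
    """
    params.validate()
    return [
        c
        for c in candidates
        if c.is_onset and params.width_min_s <= c.width_s <= params.width_max_s
    ]


def epoch_power(filtered_avg: np.ndarray, start: int, end: int, fs: float) -> float:
    """Time-integrated squared in-band amplitude over ``[start, end)``.

    Units: amplitude^2 * s (microvolts squared-seconds for EEG input).  This
    is the quantity compared against ``seizAggressiveness``: genuine ictal
    discharges hold in-band amplitude for tens of seconds, while jaw/EMG
    bursts are both brief and largely out of band, so their integral stays
    small.
    """
    n = filtered_avg.shape[-1]
    if not 0 <= start < end <= n:
        raise ValueError(f"empty or out-of-range interval [{start}, {end}) for n={n}")
    seg = filtered_avg[start:end]
    return float(np.sum(seg * seg) / fs)


def _candidate_support(c: PeakCandidate, n: int) -> tuple[int, int]:
    lo = max(0, int(np.floor(c.left_ips)))
    hi = min(n, int(np.ceil(c.right_ips)) + 1)
    return lo, max(hi, lo + 1)


def power_filter(
    candidates: list[PeakCandidate],
    feature: FeatureSignal,
    params: DetectionParams = DetectionParams(),
) -> list[PeakCandidate]:
    """Keep candidates whose half-prominence support clears the power test."""
    params.validate()
    out = []
    for c in candidates:
        lo, hi = _candidate_support(c, feature.n_samples)
        if epoch_power(feature.filtered_avg, lo, hi, feature.fs) >= params.seizAggressiveness:
            out.append(c)
    return out


def _supra_regions(env: np.ndarray, thresh: float) -> list[tuple[int, int]]:
    """Half-open runs where env >= thresh."""
    above = env >= thresh
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(env))
    return list(zip(starts, ends))


def grow_and_merge(
    candidates: list[PeakCandidate],
    feature: FeatureSignal,
    params: DetectionParams = DetectionParams(),
) -> EpochSet:
    """Expand surviving candidates into epochs; merge near-contiguous ones.

    Each candidate grows to the contiguous envelope region >= ``amp_lower``
    that contains its peak; regions separated by fewer than
    ``seizLinterval`` samples are merged; merged epochs shorter than
    ``seizLinterval`` are discarded.
    """
    params.validate()
    env = feature.envelope
    n = feature.n_samples
    if not candidates:
        return EpochSet(epochs=[], n_samples=n, fs=feature.fs)
    regions = _supra_regions(env, params.amp_lower)
    grown: list[tuple[int, int, PeakCandidate]] = []
    for c in candidates:
        for lo, hi in regions:
            if lo <= c.index < hi:
                grown.append((lo, hi, c))
                break
    grown.sort(key=lambda t: t[0])
    merged: list[list] = []
    for lo, hi, c in grown:
        if merged and lo - merged[-1][1] < params.seizLinterval:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2].append(c)
        elif merged and lo <= merged[-1][1]:  # same region, different seeds
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2].append(c)
        else:
            merged.append([lo, hi, [c]])
    epochs = []
    for lo, hi, seeds in merged:
        if hi - lo < params.seizLinterval:
            continue
        best = max(seeds, key=lambda c: c.height)
        epochs.append(
            SeizureEpoch(
                start=lo,
                end=hi,
                peak_value=float(env[lo:hi].max()),
                peak_width_s=best.width_s,
                power=epoch_power(feature.filtered_avg, lo, hi, feature.fs),
            )
        )
    return EpochSet(epochs=epochs, n_samples=n, fs=feature.fs)


def detect(
    feature: FeatureSignal, params: DetectionParams = DetectionParams()
) -> EpochSet:
    """Full automated rule cascade on one feature signal (deterministic)."""
    params.validate()
    cands = find_onset_peaks(feature, params)
    cands = width_filter(cands, params)
    cands = power_filter(cands, feature, params)
    return grow_and_merge(cands, feature, params)


def make_mask(epochs: EpochSet) -> np.ndarray:
    """Binary mask over the record: 1 inside detected epochs, 0 elsewhere."""
    mask = np.zeros(epochs.n_samples, dtype=np.int8)
    for ep in epochs.epochs:
        mask[ep.start : ep.end] = 1
    return mask


def mask_to_epochs(mask: np.ndarray, fs: float, file_id: str | None = None) -> EpochSet:
    """Inverse of :func:`make_mask` (scores are recomputed as trivial)."""
    mask = np.asarray(mask)
    regions = _supra_regions(mask.astype(np.float64), 0.5)
    epochs = [
        SeizureEpoch(start=lo, end=hi, peak_value=1.0, peak_width_s=0.0, power=0.0)
        for lo, hi in regions
    ]
    return EpochSet(epochs=epochs, n_samples=len(mask), fs=fs, file_id=file_id)


def picks_to_epochs(
    picked_times_s: list[float],
    feature: FeatureSignal,
    params: DetectionParams = DetectionParams(),
) -> EpochSet:
    """Assisted-manual mode: onset/offset time pairs become epochs.

    Picks come from visual inspection of the feature signal (the "void"
    boundaries), in ascending order and in even count.  Pairs shorter than
    ``width_min_s`` are flagged as not-a-seizure and dropped; the merge and
    minimum-length rules of the automated path then apply.
    """
    params.validate()
    picks = list(picked_times_s)
    if len(picks) % 2:
        raise ValueError(f"picked times must pair up (got {len(picks)} values)")
    if any(b <= a for a, b in zip(picks, picks[1:])):
        raise ValueError("picked times must be strictly ascending")
    fs, n = feature.fs, feature.n_samples
    raw: list[tuple[int, int]] = []
    for onset_s, end_s in zip(picks[::2], picks[1::2]):
        if end_s - onset_s < params.width_min_s:
            continue  # duration rule: too brief to be a seizure
        lo = max(0, int(np.floor(onset_s * fs)))
        hi = min(n, int(np.ceil(end_s * fs)))
        if hi > lo:
            raw.append((lo, hi))
    merged: list[list[int]] = []
    for lo, hi in raw:
        if merged and lo - merged[-1][1] < params.seizLinterval:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    epochs = []
    for lo, hi in merged:
        if hi - lo < params.seizLinterval:
            continue
        epochs.append(
            SeizureEpoch(
                start=lo,
                end=hi,
                peak_value=float(feature.envelope[lo:hi].max()),
                peak_width_s=(hi - lo) / fs,
                power=epoch_power(feature.filtered_avg, lo, hi, fs),
            )
        )
    return EpochSet(epochs=epochs, n_samples=n, fs=fs)
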