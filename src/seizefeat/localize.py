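"""Trace detected epochs back to the channels (and lobe) that drive them.

The same amplitude analysis used for detection is re-applied per channel,
restricted to the masked (seizure) samples: each channel's rectified,
feature-filtered trace is reduced to its amplitude excursion (max - min)
inside the mask, the median excursion across channels becomes the
threshold, and channels above threshold are reported as the seizure origin.
Electrode-name prefixes of the 10-20 system then vote for a cortical lobe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .detect import EpochSet, SeizureEpoch, make_mask
from .feature import FeatureParams, feature_filter, rectify
from .io import Recording
from .preprocess import PreprocessParams, preprocess

__all__ = [
    "ChannelScore",
    "LocalizationResult",
    "channel_scores",
    "map_to_lobe",
    "localize_epochs",
    "patient_lobe",
]

LOBES = ("frontal", "central", "temporal", "parietal", "occipital")

_COMBINING = {
    "frontal": "fronto",
    "central": "centro",
    "temporal": "temporo",
    "parietal": "parieto",
    "occipital": "occipito",
}

#: 10-20 electrode-name prefixes -> lobes they vote for.  Two-letter sites
#: (FT, TP, CP, FC, PO) sit on a boundary and vote for both lobes.
_PREFIX_VOTES = {
    "FP": ("frontal",),
    "FT": ("frontal", "temporal"),
    "FC": ("frontal", "central"),
    "TP": ("temporal", "parietal"),
    "CP": ("central", "parietal"),
    "PO": ("parietal", "occipital"),
    "F": ("frontal",),
    "T": ("temporal",),
    "C": ("central",),
    "P": ("parietal",),
    "O": ("occipital",),
}

_ELECTRODE_RE = re.compile(r"^([A-Z]+)(?:[0-9]+|Z)?$")


@dataclass(frozen=True)
class ChannelScore:
    """Amplitude excursion of one channel within the seizure mask."""

    channel_index: int
    channel_label: str
    amp_diff: float  # max - min of the rectified feature-filtered trace, uV
    above_threshold: bool


@dataclass
class LocalizationResult:
    """Per-epoch channel attribution."""

    epoch: SeizureEpoch
    scores: list[ChannelScore]
    threshold: float  # median amp_diff across channels, uV
    selected_channels: list[str]
    lobe: str


def channel_traces(
    recording: Recording,
    pre_params: PreprocessParams = PreprocessParams(),
    feat_params: FeatureParams = FeatureParams(),
) -> np.ndarray:
    """Per-channel rectified, feature-filtered traces (mask-independent).

    This is the expensive part of localization; compute it once per record
    and score any number of epochs against it.
    """
    pre = preprocess(recording, pre_params)
    return feature_filter(rectify(pre.data), feat_params, recording.fs)


def channel_scores(
    recording: Recording,
    mask: np.ndarray,
    pre_params: PreprocessParams = PreprocessParams(),
    feat_params: FeatureParams = FeatureParams(),
    margin: float = 1.0,
    traces: np.ndarray | None = None,
) -> list[ChannelScore]:
    """Score every channel's contribution inside the masked samples.

    ``margin`` scales the median threshold; 1.0 is the literal
    above-the-median rule (which by construction can select up to half the
    channels), larger values (e.g. 1.5) isolate the few dominant channels.
    ``traces`` may carry a precomputed :func:`channel_traces` result.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape[0] != recording.n_samples:
        raise ValueError("mask length does not match the recording")
    if not mask.any():
        raise ValueError("mask selects no samples (no detected epochs)")
    per_channel = (
        traces if traces is not None else channel_traces(recording, pre_params, feat_params)
    )
    masked = per_channel[:, mask]
    amp_diff = masked.max(axis=1) - masked.min(axis=1)
    threshold = float(np.median(amp_diff))
    return [
        ChannelScore(
            channel_index=i,
            channel_label=recording.channel_labels[i],
            amp_diff=float(d),
            above_threshold=bool(d > threshold * margin),
        )
        for i, d in enumerate(amp_diff)
    ]


def _electrodes(label: str) -> list[str]:
    """Electrode names in a (possibly bipolar) channel label."""
    return [part.strip().upper() for part in label.split("-") if part.strip()]


def map_to_lobe(selected_channels: list[str], strict: bool = True) -> str:
    """Plurality vote of electrode-name prefixes over the selected channels.

    Bipolar labels contribute both electrodes; unknown labels are ignored.
    A two-way tie yields a compound label (e.g. ``temporo-occipital``),
    three or more tied lobes yield ``mixed``.
    """
    votes = {lobe: 0 for lobe in LOBES}
    any_known = False
    for chan in selected_channels:
        for elec in _electrodes(chan):
            m = _ELECTRODE_RE.match(elec)
            if not m:
                continue
            prefix = m.group(1)
            for pfx in sorted(_PREFIX_VOTES, key=len, reverse=True):
                if prefix == pfx:
                    for lobe in _PREFIX_VOTES[pfx]:
                        votes[lobe] += 1
                    any_known = True
                    break
    if not any_known:
        if strict:
            raise ValueError(f"no recognizable 10-20 labels in {selected_channels!r}")
        return "mixed"
    top = max(votes.values())
    winners = [lobe for lobe in LOBES if votes[lobe] == top]
    if len(winners) == 1:
        return winners[0]
    if len(winners) == 2:
        return f"{_COMBINING[winners[0]]}-{winners[1]}"
    return "mixed"


def localize_epochs(
    recording: Recording,
    epochs: EpochSet,
    pre_params: PreprocessParams = PreprocessParams(),
    feat_params: FeatureParams = FeatureParams(),
    margin: float = 1.0,
) -> list[LocalizationResult]:
    """Channel attribution for every detected epoch of a record."""
    results = []
    traces = channel_traces(recording, pre_params, feat_params) if epochs.epochs else None
    for ep in epochs.epochs:
        single = EpochSet(
            epochs=[ep], n_samples=epochs.n_samples, fs=epochs.fs, file_id=epochs.file_id
        )
        scores = channel_scores(
            recording, make_mask(single), pre_params, feat_params, margin, traces=traces
        )
        selected = [s.channel_label for s in scores if s.above_threshold]
        lobe = map_to_lobe(selected, strict=False) if selected else "mixed"
        results.append(
            LocalizationResult(
                epoch=ep,
                scores=scores,
                threshold=float(np.median([s.amp_diff for s in scores])),
                selected_channels=selected,
                lobe=lobe,
            )
        )
    return results


def patient_lobe(results: list[LocalizationResult]) -> str:
    """Plurality lobe over a patient's epochs (ties resolved alphabetically)."""
    if not results:
        raise ValueError("no localization results to summarize")
    counts: dict[str, int] = {}
    for r in results:
        counts[r.lobe] = counts.get(r.lobe, 0) + 1
    top = max(counts.values())
    return sorted(l for l, c in counts.items() if c == top)[0]
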