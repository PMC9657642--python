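"""Shared fixtures: small synthetic records generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from seizefeat.feature import build_feature_signal
from seizefeat.io import Recording
from seizefeat.simulate import SeizureSpec, SimParams, simulate_recording

FS = 256.0


@pytest.fixture(scope="session")
def seizure_record():
    """180 s, 23-channel record with one 40 s seizure on channels 0-3.

    The full CHB-MIT-style montage matters: the in-band power threshold is
    calibrated in unnormalized channel-average units, which scale with the
    montage size.
    """
    params = SimParams(
        n_channels=23,
        duration_s=180.0,
        seed=1234,
        seizures=(SeizureSpec(onset_s=60.0, duration_s=40.0, channels=(0, 1, 2, 3)),),
        file_id="fixture.edf",
    )
    return simulate_recording(params)


@pytest.fixture(scope="session")
def seizure_feature(seizure_record):
    rec, _ = seizure_record
    return build_feature_signal(rec)


@pytest.fixture(scope="session")
def quiet_record():
    """60 s seizure-free record dominated by jaw/EMG bursts.

    Exercises the artefact classes the power gate exists to reject; the
    statistical false-positive rate under the full artefact mix is bounded
    separately on the 50-record corpus.
    """
    params = SimParams(
        n_channels=23, duration_s=60.0, seed=99, jaw_bursts_per_hour=240.0,
        alpha_bursts_per_min=0.0, drift_amp_uv=0.0, powerline_amp_uv=0.0,
        file_id="quiet.edf",
    )
    return simulate_recording(params)


@pytest.fixture()
def small_recording():
    """Deterministic 4-channel, 10 s sinusoid-mix recording (no RNG)."""
    t = np.arange(int(10 * FS)) / FS
    data = np.vstack(
        [
            50 * np.sin(2 * np.pi * 3 * t),
            30 * np.sin(2 * np.pi * 7 * t + 1.0),
            20 * np.sin(2 * np.pi * 11 * t + 2.0) + 10.0,
            5 * np.sin(2 * np.pi * 1 * t + 0.5),
        ]
    )
    return Recording(
        data=data, fs=FS, channel_labels=["FP1-F7", "F7-T7", "T7-P7", "P7-O1"]
    )
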