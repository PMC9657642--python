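"""Per-channel denoising cascade applied before channel averaging.

Three zero-phase stages, in order: power-line notch (optional), 35 Hz FIR
low-pass, and a first-order recursive DC-removal notch
``H(z) = (1 - z^-1) / (1 - lambda z^-1)``.  Zero-phase application is
forward-backward filtering with odd-reflection edge padding; a causal mode
is available for real-time style processing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "PreprocessParams",
    "lowpass_fir",
    "powerline_notch",
    "dc_notch",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Denoising-cascade parameters.

    Attributes
    ----------
    lp_cutoff : float
        Low-pass cutoff in Hz (default 35).
    lp_order : int
        FIR order of the low-pass (default 50, i.e. 51 taps); must be even
        so the impulse response is symmetric about an integer delay.
    powerline_f0 : float
        Mains frequency in Hz (default 60; use 50 for European recordings).
    powerline_enabled : bool
        The notch can be switched off entirely.
    powerline_harmonics : int | None
        Number of harmonics to notch (f0, 2*f0, ...); None = all below
        Nyquist.
    powerline_q : float
        Quality factor of each second-order notch section (default 30).
    dc_lambda : float
        Pole radius of the DC notch, in (0, 1); default 0.9991.
    zero_phase : bool
        Forward-backward (non-causal) filtering when True; plain causal
        filtering otherwise.
    """

    lp_cutoff: float = 35.0
    lp_order: int = 50
    powerline_f0: float = 60.0
    powerline_enabled: bool = True
    powerline_harmonics: int | None = None
    powerline_q: float = 30.0
    dc_lambda: float = 0.9991
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.lp_cutoff < fs / 2:
            raise ValueError(f"lp_cutoff {self.lp_cutoff} outside (0, {fs / 2})")
        if self.lp_order < 2 or self.lp_order % 2:
            raise ValueError(f"lp_order must be even and >= 2, got {self.lp_order}")
        if not 0 < self.dc_lambda < 1:
            raise ValueError(f"dc_lambda must be in (0, 1), got {self.dc_lambda}")
        if self.powerline_enabled and not self.powerline_f0 < fs / 2:
            raise ValueError(
                f"powerline_f0 {self.powerline_f0} at or above Nyquist {fs / 2}"
            )


def _apply_fir(taps, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    """FIR along the last axis; zero-phase via odd-reflection filtfilt."""
    if zero_phase:
        padlen = min(3 * len(taps), x.shape[-1] - 1)
        return signal.filtfilt(taps, 1.0, x, axis=-1, padtype="odd", padlen=padlen)
    return signal.lfilter(taps, 1.0, x, axis=-1)


def _apply_iir(b, a, x: np.ndarray, zero_phase: bool, padlen: int) -> np.ndarray:
    """IIR along the last axis; zero-phase and time-reversal symmetric.

    Zero-phase mode averages forward-backward filtering of the signal with
    the time-reverse of forward-backward filtering of the reversed signal.
    Plain filtfilt leaves slightly asymmetric edge transients (worst for
    the near-unit-circle DC-notch pole), so processing would not commute
    with time reversal; the symmetrized form restores that property
    exactly -- reversing the input swaps the two terms of the average --
    while preserving the squared magnitude response and the exact DC null
    (a constant input still maps to zero).

    Edge padding is even (mirror) reflection: it preserves the local mean
    of the signal, where odd reflection gives the padding a spurious mean
    of ``2 x[0] - local mean`` that a mean-tracking pole drags into the
    record as a multi-second low-frequency transient.
    """
    if not zero_phase:
        return signal.lfilter(b, a, x, axis=-1)
    padlen = min(padlen, x.shape[-1] - 1)
    fwd = signal.filtfilt(b, a, x, axis=-1, padtype="even", padlen=padlen)
    bwd = signal.filtfilt(b, a, x[..., ::-1], axis=-1, padtype="even", padlen=padlen)
    return 0.5 * (fwd + bwd[..., ::-1])


def lowpass_design(params: PreprocessParams, fs: float) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase low-pass taps."""
    return signal.firwin(params.lp_order + 1, params.lp_cutoff, fs=fs)


def lowpass_fir(recording: Recording, params: PreprocessParams = PreprocessParams()) -> Recording:
    """Zero-phase FIR low-pass (35 Hz default) on every channel.

    Requires the record to be longer than 3x the filter length so that the
    reflection padding can suppress edge transients.
    """
    params.validate(recording.fs)
    taps = lowpass_design(params, recording.fs)
    if recording.n_samples <= 3 * len(taps):
        raise ValueError(
            f"record too short for zero-phase filtering: {recording.n_samples} samples"
            f" <= 3 x {len(taps)} taps"
        )
    out = _apply_fir(taps, recording.data, params.zero_phase)
    return recording.copy_with(out)


def powerline_sos(params: PreprocessParams, fs: float) -> np.ndarray:
    """Cascade of second-order notches at f0 and its harmonics below Nyquist."""
    n_harm = int(np.floor((fs / 2 - 1e-9) / params.powerline_f0))
    if params.powerline_harmonics is not None:
        n_harm = min(n_harm, params.powerline_harmonics)
    sections = []
    for k in range(1, n_harm + 1):
        b, a = signal.iirnotch(k * params.powerline_f0, params.powerline_q, fs=fs)
        sections.append(np.hstack([b, a]))
    return np.array(sections)


def powerline_notch(recording: Recording, params: PreprocessParams = PreprocessParams()) -> Recording:
    """Notch out the mains frequency and its harmonics (no-op when disabled)."""
    params.validate(recording.fs)
    if not params.powerline_enabled:
        return recording.copy_with(recording.data.copy())
    out = recording.data
    # sections applied sequentially: each is symmetric under time reversal,
    # hence so is the cascade
    for section in powerline_sos(params, recording.fs):
        b, a = section[:3], section[3:]
        out = _apply_iir(b, a, out, params.zero_phase, padlen=2000)
    return recording.copy_with(out)


def dc_notch(recording: Recording, params: PreprocessParams = PreprocessParams()) -> Recording:
    """First-order recursive DC notch ``(1 - z^-1)/(1 - lambda z^-1)``.

    The zero at z = 1 gives exactly zero DC gain; with lambda = 0.9991 at
    256 Hz the single-pass -3 dB point is ~0.037 Hz, so seizure-band content
    (>= 0.5 Hz) passes essentially unchanged while offsets and slow drift
    are removed before channel averaging.
    """
    params.validate(recording.fs)
    b, a = np.array([1.0, -1.0]), np.array([1.0, -params.dc_lambda])
    # pad long enough for the slow pole's transient to settle (~10 tau)
    padlen = int(10 / (1 - params.dc_lambda))
    out = _apply_iir(b, a, recording.data, params.zero_phase, padlen=padlen)
    return recording.copy_with(out)


def preprocess(recording: Recording, params: PreprocessParams = PreprocessParams()) -> Recording:
    """Full cascade: power-line notch, then low-pass, then DC notch."""
    params.validate(recording.fs)
    rec = powerline_notch(recording, params)
    rec = lowpass_fir(rec, params)
    rec = dc_notch(rec, params)
    return rec


def causal(params: PreprocessParams) -> PreprocessParams:
    """Convenience: same parameters with causal (real-time) filtering."""
    return replace(params, zero_phase=False)
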