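"""Filtering, re-referencing, resampling and epoching of EEG recordings.

The analysis-ready form is: 0.1-70 Hz zero-phase band-pass with a 50 Hz
notch, average reference, resampled to 140 Hz (so that a 5-level dyadic
wavelet decomposition lands on the delta/theta band edges used downstream),
and a 120 s epoch per recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .synthetic_cohort import EEGRecording


@dataclass
class PreprocessConfig:
    bandpass: tuple[float, float] = (0.1, 70.0)
    notch: float | None = 50.0
    reference: str = "average"          # "average" or "linked-ear-as-recorded"
    resample_to: float | None = 140.0
    epoch_length: float = 120.0
    epoch_offset: float = 0.0
    amplitude_reject_uv: float | None = None   # plumbing utility, off by default

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if self.notch is not None and not lo < self.notch < hi:
            raise ValueError("notch frequency must lie inside the bandpass")
        if self.reference not in ("average", "linked-ear-as-recorded"):
            raise ValueError(f"unknown reference {self.reference!r}")


def filter_recording(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Zero-phase band-pass then notch filter, per channel.

    4th-order Butterworth band-pass and 2nd-order IIR notch, both applied
    forward-backward (``filtfilt``) so the output is phase-free.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.bandpass
    if hi >= 0.99 * rec.fs / 2:
        raise ValueError(
            f"band edge {hi} Hz too close to Nyquist ({rec.fs / 2} Hz)")
    sos = sps.butter(4, [lo / (rec.fs / 2), hi / (rec.fs / 2)],
                     btype="band", output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    if cfg.notch is not None:
        b, a = sps.iirnotch(cfg.notch, Q=30.0, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return rec.copy_with(data=out)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean over channels (average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def extract_epoch(rec: EEGRecording, length: float, offset: float = 0.0) -> EEGRecording:
    """Contiguous segment [offset, offset+length) seconds, 0-based half-open."""
    start = int(round(offset * rec.fs))
    stop = start + int(round(length * rec.fs))
    if start < 0 or stop > rec.n_samples:
        raise ValueError(
            f"epoch [{offset}, {offset + length}) s out of range for a "
            f"{rec.duration:.1f} s recording")
    ev = None
    if rec.event_log is not None:
        ev = [(i - start, s) for i, s in rec.event_log if start <= i < stop]
    return rec.copy_with(data=rec.data[:, start:stop], event_log=ev)


def resample_recording(rec: EEGRecording, fs_target: float) -> EEGRecording:
    """Polyphase resampling to ``fs_target`` (downsampling only)."""
    if fs_target > rec.fs:
        raise ValueError("upsampling is not supported")
    if fs_target == rec.fs:
        return rec.copy_with()
    frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=out, fs=fs_target, event_log=None)


def reject_high_amplitude(rec: EEGRecording, threshold_uv: float,
                          window_s: float = 1.0) -> EEGRecording:
    """Drop windows whose peak absolute amplitude exceeds ``threshold_uv``.

    Simple amplitude-threshold artifact rejection; returns the concatenation
    of the retained windows (a shorter recording).
    """
    w = int(round(window_s * rec.fs))
    n_win = rec.n_samples // w
    keep = [k for k in range(n_win)
            if np.abs(rec.data[:, k * w:(k + 1) * w]).max() <= threshold_uv]
    if not keep:
        warnings.warn("all windows exceeded the amplitude threshold; returning input")
        return rec.copy_with()
    data = np.concatenate([rec.data[:, k * w:(k + 1) * w] for k in keep], axis=1)
    return rec.copy_with(data=data, event_log=None)


def preprocess_recording(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Run the standard chain: filter -> reference -> resample -> epoch."""
    cfg = cfg or PreprocessConfig()
    out = filter_recording(rec, cfg)
    if cfg.reference == "average":
        out = rereference_average(out)
    if cfg.amplitude_reject_uv is not None:
        out = reject_high_amplitude(out, cfg.amplitude_reject_uv)
    if cfg.resample_to is not None:
        out = resample_recording(out, cfg.resample_to)
    length = min(cfg.epoch_length, out.duration)
    out = extract_epoch(out, length, min(cfg.epoch_offset, out.duration - length))
    return out
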