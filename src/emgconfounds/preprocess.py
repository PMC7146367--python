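"""Signal conditioning and window segmentation.

The default chain mirrors common surface-EMG practice: power-line notch,
20–450 Hz band-pass (4th-order Butterworth), integer-ratio downsampling to a
common rate, then overlapping window segmentation (150 ms windows, 50 ms
increments).  All filters are applied forward–backward (zero phase): the
analysis is offline, so phase distortion is avoidable and avoided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synth import EmgRecording

__all__ = [
    "WindowSet",
    "notch_filter",
    "bandpass_filter",
    "downsample",
    "segment",
    "preprocess_chain",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSet:
    """Stack of fixed-length windows with aligned per-window metadata."""

    windows: np.ndarray  # n_windows x channels x window_samples, mV
    window_ms: float
    increment_ms: float
    fs: float
    motion_label: np.ndarray
    condition_value: np.ndarray
    trial_index: np.ndarray
    subject_id: np.ndarray

    def __post_init__(self):
        n = self.windows.shape[0]
        for name in ("motion_label", "condition_value", "trial_index", "subject_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"metadata vector {name} misaligned with windows")
        if not np.all(np.isfinite(self.windows)):
            raise ValueError("windows must be finite")
        expected = int(round(self.window_ms * self.fs / 1000.0))
        if self.windows.shape[2] != expected:
            raise ValueError("window_samples inconsistent with window_ms and fs")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


def notch_filter(recording: EmgRecording, freq: float = 50.0, quality: float = 30.0) -> EmgRecording:
    """Zero-phase IIR notch removing power-line interference at ``freq`` Hz."""
    if not (0.0 < freq < recording.fs / 2.0):
        raise ValueError("notch frequency must lie strictly below Nyquist")
    if quality <= 0:
        raise ValueError("quality factor must be positive")
    b, a = signal.iirnotch(freq, quality, fs=recording.fs)
    data = signal.filtfilt(b, a, recording.data, axis=1)
    return replace(recording, data=data)


def bandpass_filter(
    recording: EmgRecording, low: float = 20.0, high: float = 450.0, order: int = 4
) -> EmgRecording:
    """Zero-phase Butterworth band-pass; defaults cover the 20–450 Hz EMG band."""
    if not (0.0 < low < high < recording.fs / 2.0):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=data)


def downsample(recording: EmgRecording, target_fs: float = 1000.0) -> EmgRecording:
    """Anti-alias filter and decimate to ``target_fs``.

    Only integer decimation ratios are supported; fractional resampling has
    dialect-dependent behaviour and is out of scope.
    """
    if target_fs > recording.fs:
        raise ValueError("target_fs must not exceed the recording rate")
    ratio = recording.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fs must be an integer multiple of target_fs")
    q = int(round(ratio))
    if q == 1:
        return replace(recording, data=recording.data.copy())
    data = signal.decimate(recording.data, q, axis=1, zero_phase=True)
    n_out = int(np.floor(recording.n_samples * target_fs / recording.fs))
    data = data[:, :n_out]
    return replace(recording, data=data, fs=target_fs)


def segment(
    recordings: list[EmgRecording], window_ms: float = 150.0, increment_ms: float = 50.0
) -> WindowSet:
    """Cut every recording into fixed-length windows.

    Per recording, ``floor((samples - L) / I) + 1`` windows are produced, where
    L and I are the window and increment lengths in samples; windows never span
    a trial boundary.  ``increment_ms == window_ms`` gives adjacent
    (non-overlapping) segmentation.  Recordings shorter than one window are
    skipped with a warning; an empty result is an error.
    """
    if not (0 < increment_ms <= window_ms):
        raise ValueError("need window_ms >= increment_ms > 0")
    if not recordings:
        raise ValueError("no recordings to segment")
    fs = recordings[0].fs
    if any(r.fs != fs for r in recordings):
        raise ValueError("recordings must share one sampling rate")
    length = int(round(window_ms * fs / 1000.0))
    inc = int(round(increment_ms * fs / 1000.0))
    if length < 1 or inc < 1:
        raise ValueError("window and increment must be at least one sample")

    chunks, motions, conds, trials, subjects = [], [], [], [], []
    for rec in recordings:
        if rec.n_samples < length:
            log.warning(
                "skipping recording (subject %s, %s, trial %s): %d samples < window %d",
                rec.subject_id, rec.motion_label, rec.trial_index, rec.n_samples, length,
            )
            continue
        n_win = (rec.n_samples - length) // inc + 1
        view = np.lib.stride_tricks.sliding_window_view(rec.data, length, axis=1)
        starts = np.arange(n_win) * inc
        chunks.append(view[:, starts, :].transpose(1, 0, 2))
        motions.extend([rec.motion_label] * n_win)
        conds.extend([rec.condition_value] * n_win)
        trials.extend([rec.trial_index] * n_win)
        subjects.extend([rec.subject_id] * n_win)
    if not chunks:
        raise ValueError("every recording was shorter than one window")
    return WindowSet(
        windows=np.ascontiguousarray(np.concatenate(chunks, axis=0)),
        window_ms=window_ms,
        increment_ms=increment_ms,
        fs=fs,
        motion_label=np.asarray(motions),
        condition_value=np.asarray(conds, dtype=object),
        trial_index=np.asarray(trials, dtype=int),
        subject_id=np.asarray(subjects, dtype=int),
    )


def preprocess_chain(
    recordings: list[EmgRecording],
    *,
    notch_freq: float | None = 50.0,
    notch_q: float = 30.0,
    band: tuple[float, float] | None = (20.0, 450.0),
    band_order: int = 4,
    target_fs: float | None = 1000.0,
    window_ms: float = 150.0,
    increment_ms: float = 50.0,
) -> WindowSet:
    """Default conditioning order: notch -> band-pass -> downsample -> segment.
    Any filtering stage can be disabled by passing ``None``."""
    out = []
    for rec in recordings:
        if notch_freq is not None:
            rec = notch_filter(rec, notch_freq, notch_q)
        if band is not None:
            rec = bandpass_filter(rec, band[0], band[1], band_order)
        if target_fs is not None and target_fs != rec.fs:
            rec = downsample(rec, target_fs)
        out.append(rec)
    return segment(out, window_ms, increment_ms)
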