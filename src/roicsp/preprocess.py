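"""Signal conditioning: average reference, 7-15 Hz zero-phase FIR band-pass,
polyphase downsampling to 100 Hz, and cue-locked epoching.

The band covers the sensorimotor mu rhythm plus low beta, where the
event-related desynchronization / synchronization (ERD/ERS) that the
spatial filters exploit lives.  The canonical order of operations is
average reference -> band-pass -> downsample -> epoch; see
:func:`preprocess_continuous`.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ContinuousEEG, SensorEpochs

__all__ = [
    "apply_average_reference",
    "bandpass_fir",
    "downsample",
    "extract_epochs",
    "preprocess_continuous",
]

logger = logging.getLogger(__name__)


def apply_average_reference(epochs):
    """Re-reference to the instantaneous channel mean.

    Works on :class:`SensorEpochs` (per trial) or :class:`ContinuousEEG`.
    Idempotent: once the channel mean is zero at every sample the data is
    unchanged.
    """
    if isinstance(epochs, ContinuousEEG):
        if epochs.n_channels < 2:
            raise ValueError("average reference undefined for a single channel")
        data = epochs.data - epochs.data.mean(axis=0, keepdims=True)
        return epochs.copy_with(data=data)
    if isinstance(epochs, SensorEpochs):
        if epochs.n_channels < 2:
            raise ValueError("average reference undefined for a single channel")
        data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
        return epochs.copy_with(data=data)
    raise TypeError(f"unsupported input type {type(epochs).__name__}")


def _design_bandpass(low_hz: float, high_hz: float, fs: float,
                     n_samples: int) -> np.ndarray:
    """Hamming windowed-sinc band-pass taps.

    The transition width is the smaller of 3.5 Hz and half the distance to
    the nearest band edge; tap count follows the Hamming rule of thumb
    (~3.3 / normalized transition width), capped so that forward-backward
    filtering remains feasible on short recordings.
    """
    transition = min(3.5, low_hz / 2.0, (fs / 2.0 - high_hz) / 2.0)
    transition = max(transition, 0.5)
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps |= 1  # odd for a type-I linear-phase filter
    max_taps = max(31, (n_samples - 1) // 3)
    if numtaps > max_taps:
        logger.warning(
            "reducing FIR order %d -> %d for a %d-sample recording",
            numtaps, max_taps | 1, n_samples)
        numtaps = max_taps | 1
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                         window="hamming", fs=fs)


def bandpass_fir(x: ContinuousEEG, low_hz: float = 7.0,
                 high_hz: float = 15.0) -> ContinuousEEG:
    """Zero-phase FIR band-pass via forward-backward filtering."""
    if not 0 < low_hz < high_hz < x.fs / 2:
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) must satisfy "
            f"0 < low < high < fs/2 = {x.fs / 2}")
    taps = _design_bandpass(low_hz, high_hz, x.fs, x.n_samples)
    data = signal.filtfilt(taps, [1.0], x.data, axis=1)
    return x.copy_with(data=data)


def downsample(x: ContinuousEEG, fs_out: float = 100.0) -> ContinuousEEG:
    """Polyphase resampling to ``fs_out``; event indices are rescaled.

    Output length is ``floor(n_samples * fs_out / fs)``.  No extra
    anti-alias filtering is applied: the caller is expected to have
    band-limited the signal (the 7-15 Hz band-pass guarantees this for
    any ``fs_out`` >= 30 Hz).
    """
    if fs_out >= x.fs:
        raise ValueError(f"fs_out={fs_out} must be below fs={x.fs}")
    ratio = Fraction(fs_out / x.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    data = signal.resample_poly(x.data, up, down, axis=1, padtype="line")
    n_out = int(np.floor(x.n_samples * fs_out / x.fs))
    data = data[:, :n_out]
    scale = fs_out / x.fs
    events = [(int(round(idx * scale)), label) for idx, label in x.events]
    events = [(min(i, n_out - 1), lbl) for i, lbl in events]
    return ContinuousEEG(data=data, fs=fs_out,
                         channel_names=list(x.channel_names), events=events)


def extract_epochs(x: ContinuousEEG, offset_s: float = 0.5,
                   duration_s: float = 3.0) -> SensorEpochs:
    """Cut cue-locked trials: window [cue + offset, cue + offset + duration).

    Indices are 0-based and windows half-open.  Any event whose window
    falls outside the recording raises, naming the offending event.
    """
    if not x.events:
        raise ValueError("no events to epoch")
    n_per = int(round(duration_s * x.fs))
    start_off = int(round(offset_s * x.fs))
    trials, labels = [], []
    for k, (cue, label) in enumerate(x.events):
        start = cue + start_off
        stop = start + n_per
        if start < 0 or stop > x.n_samples:
            raise ValueError(
                f"event {k} (cue sample {cue}, class {label}): window "
                f"[{start}, {stop}) outside recording of {x.n_samples} samples")
        trials.append(x.data[:, start:stop])
        labels.append(label)
    return SensorEpochs(data=np.stack(trials), fs=x.fs,
                        labels=np.asarray(labels), t0=offset_s,
                        channel_names=list(x.channel_names))


def preprocess_continuous(x: ContinuousEEG, low_hz: float = 7.0,
                          high_hz: float = 15.0, fs_out: float = 100.0,
                          offset_s: float = 0.5,
                          duration_s: float = 3.0) -> SensorEpochs:
    """Full chain: average reference -> band-pass -> downsample -> epoch."""
    y = apply_average_reference(x)
    y = bandpass_fir(y, low_hz, high_hz)
    if fs_out < y.fs:
        y = downsample(y, fs_out)
    return extract_epochs(y, offset_s=offset_s, duration_s=duration_s)
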