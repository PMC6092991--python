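"""In-memory containers for continuous, epoched and source-space EEG.

All arrays are plain ``numpy`` arrays; channel and trial metadata travel
with the data so that every stage of the decoding pipeline can validate
its input.  Class labels are small positive integers (1..4 for the
four motor-imagery tasks: left arm, right arm, feet, tongue).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ContinuousEEG", "SensorEpochs", "SourceEpochs"]

VALID_CLASSES = frozenset({1, 2, 3, 4})


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    events : list of (int, int)
        ``(sample_index, class_label)`` cue markers.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"EEG{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")
        n = self.data.shape[1]
        for idx, label in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample {idx} outside recording [0, {n})")
            if label not in VALID_CLASSES:
                raise ValueError(f"event label {label} not in {sorted(VALID_CLASSES)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "ContinuousEEG":
        return replace(self, **kw)


@dataclass
class SensorEpochs:
    """Epoched sensor-space trials.

    ``data`` has shape (n_trials, n_channels, n_samples); ``t0`` is the
    epoch start relative to the visual cue, in seconds.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    t0: float = 0.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per trial")
        if self.labels.size == 0:
            raise ValueError("epochs must contain at least one trial")
        bad = set(np.unique(self.labels)) - VALID_CLASSES
        if bad:
            raise ValueError(f"labels {sorted(bad)} not in {sorted(VALID_CLASSES)}")
        if not self.channel_names:
            self.channel_names = [f"EEG{i:03d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kw) -> "SensorEpochs":
        return replace(self, **kw)


@dataclass
class SourceEpochs:
    """Epoched dipole current-density time series.

    ``data`` has shape (n_trials, n_dipoles, n_samples).  Produced by
    applying an inverse operator to :class:`SensorEpochs`; ``labels``,
    ``fs`` and ``t0`` are carried through unchanged.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("source data must be 3-D (trials x dipoles x samples)")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kw) -> "SourceEpochs":
        return replace(self, **kw)
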