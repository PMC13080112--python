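"""In-memory containers for multichannel EEG.

Signals are stored as plain ``(n_channels, n_samples)`` float arrays in
microvolts, together with the sampling rate and the subject/group/paradigm
metadata that the augmentation and cross-validation stages rely on to keep
segments of one subject together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecording", "EpochSet"]


@dataclass
class EEGRecording:
    """A continuous multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel; must match ``data.shape[0]``.
    subject_id, group, paradigm : str
        Provenance metadata. ``group`` is typically ``"HC"`` or ``"MCI"``;
        ``paradigm`` is ``"rest"`` or ``"task"``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    group: str = ""
    paradigm: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        """Return a copy with selected fields replaced."""
        return replace(self, **changes)


@dataclass
class EpochSet:
    """A stack of equal-length epochs from one recording.

    ``data`` has shape ``(n_epochs, n_channels, n_samples)``. ``tmin`` is the
    time of the first sample relative to the epoch-defining event (0.0 for
    resting-state segments).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    group: str = ""
    paradigm: str = ""
    tmin: float = 0.0
    epoch_info: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel names do not match channel axis")
        if not self.epoch_info:
            self.epoch_info = [{"epoch": i} for i in range(self.data.shape[0])]
        if len(self.epoch_info) != self.data.shape[0]:
            raise ValueError("epoch_info length does not match epoch axis")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, indices) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[indices],
            fs=self.fs,
            channel_names=list(self.channel_names),
            subject_id=self.subject_id,
            group=self.group,
            paradigm=self.paradigm,
            tmin=self.tmin,
            epoch_info=[self.epoch_info[i] for i in indices],
        )
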