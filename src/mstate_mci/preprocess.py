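"""Deterministic signal conditioning and per-paradigm augmentation.

The conditioning chain is: zero-phase 2-20 Hz band-pass, downsampling to
250 Hz, common average reference, epoching, and +/-100 uV amplitude
rejection.  Augmentation produces 10 analysis segments per subject for both
paradigms: non-overlapping 20-s epochs of the resting recording, and random
balanced blocks of task trials averaged within block.  Every produced
segment keeps its source subject id; the grouped cross-validation downstream
relies on that to prevent leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EEGRecording, EpochSet

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "resample",
    "common_average_reference",
    "reject_by_amplitude",
    "segment_resting",
    "extract_task_epochs",
    "block_average",
    "preprocess_rest",
    "preprocess_task",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning and augmentation parameters (amplitudes in uV, times in
    the units given by each field name)."""

    band_low_hz: float = 2.0
    band_high_hz: float = 20.0
    target_fs_hz: float = 250.0
    reject_uv: float = 100.0
    rest_epoch_s: float = 20.0
    rest_n_epochs: int = 10
    task_window_ms: tuple[float, float] = (0.0, 1000.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    task_n_blocks: int = 10
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz < self.target_fs_hz / 2):
            raise ValueError("need 0 < band_low < band_high < target_fs/2")
        if self.reject_uv <= 0:
            raise ValueError("reject_uv must be positive")


def bandpass(rec: EEGRecording, cfg: PreprocessConfig = PreprocessConfig()) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    if rec.fs <= 2 * cfg.band_high_hz:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {cfg.band_high_hz} Hz band edge"
        )
    sos = sps.butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out)


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase downsampling to ``target_fs`` (upsampling is refused)."""
    if target_fs > rec.fs:
        raise ValueError(f"cannot upsample from {rec.fs} to {target_fs} Hz")
    if target_fs == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=out, fs=float(target_fs))


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels at every sample."""
    if rec.n_channels < 2:
        raise ValueError("CAR needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=out)


def reject_by_amplitude(epochs: EpochSet, reject_uv: float = 100.0) -> EpochSet:
    """Drop epochs whose absolute maximum exceeds ``reject_uv`` (strict).

    An epoch peaking at exactly the threshold is retained.  Surviving epochs
    are untouched and keep their order.  If every epoch is rejected, an
    empty set is returned and a warning is emitted.
    """
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    keep = np.flatnonzero(~(peaks > reject_uv))
    if keep.size == 0:
        warnings.warn("all epochs rejected by the amplitude criterion", stacklevel=2)
    return epochs.subset(keep)


def segment_resting(
    rec: EEGRecording, epoch_s: float = 20.0, n_epochs: int = 10
) -> EpochSet:
    """Cut ``n_epochs`` contiguous non-overlapping epochs from the start."""
    n_per = int(round(epoch_s * rec.fs))
    needed = n_per * n_epochs
    if rec.n_samples < needed:
        raise ValueError(
            f"recording has {rec.n_samples} samples; "
            f"{n_epochs} x {epoch_s}-s epochs need {needed}"
        )
    data = rec.data[:, :needed].reshape(rec.n_channels, n_epochs, n_per)
    data = np.transpose(data, (1, 0, 2))
    return EpochSet(
        data=data,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        subject_id=rec.subject_id,
        group=rec.group,
        paradigm=rec.paradigm,
        epoch_info=[{"epoch": i, "start_s": i * epoch_s} for i in range(n_epochs)],
    )


def extract_task_epochs(
    rec: EEGRecording,
    events: pd.DataFrame,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> EpochSet:
    """Epoch correct incongruent trials, baseline-corrected.

    ``events`` must carry columns ``onset_s``, ``condition`` and ``correct``.
    For each qualifying trial the channelwise mean over the baseline window
    is subtracted, and the returned epoch spans the analysis window
    (0-1000 ms post-onset by default).  If no trial qualifies, an empty set
    is returned with a warning.
    """
    required = {"onset_s", "condition", "correct"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    sel = events[(events["condition"] == "incongruent") & (events["correct"] == 1)]
    fs = rec.fs
    w0 = int(round(cfg.task_window_ms[0] / 1000.0 * fs))
    w1 = int(round(cfg.task_window_ms[1] / 1000.0 * fs))
    b0 = int(round(cfg.baseline_ms[0] / 1000.0 * fs))
    b1 = int(round(cfg.baseline_ms[1] / 1000.0 * fs))
    epochs, info = [], []
    for _, ev in sel.iterrows():
        onset = int(round(ev["onset_s"] * fs))
        if onset + b0 < 0 or onset + w1 > rec.n_samples:
            continue  # trial extends beyond the recording
        baseline = rec.data[:, onset + b0 : onset + b1].mean(axis=1, keepdims=True)
        window = rec.data[:, onset + w0 : onset + w1] - baseline
        epochs.append(window)
        info.append({"onset_s": float(ev["onset_s"])})
    if not epochs:
        warnings.warn("no correct incongruent trials to epoch", stacklevel=2)
        data = np.empty((0, rec.n_channels, w1 - w0))
    else:
        data = np.asarray(epochs)
    return EpochSet(
        data=data,
        fs=fs,
        channel_names=list(rec.channel_names),
        subject_id=rec.subject_id,
        group=rec.group,
        paradigm=rec.paradigm,
        tmin=cfg.task_window_ms[0] / 1000.0,
        epoch_info=info or [],
    )


def block_average(
    epochs: EpochSet, n_blocks: int = 10, seed: int | np.random.Generator = 0
) -> EpochSet:
    """Randomly partition trials into balanced blocks and average each.

    Block sizes differ by at most one trial.  Exactly ``n_blocks`` averaged
    epochs are returned.
    """
    if epochs.n_epochs < n_blocks:
        raise ValueError(
            f"{epochs.n_epochs} trials cannot fill {n_blocks} blocks"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(epochs.n_epochs)
    blocks = np.array_split(order, n_blocks)
    data = np.asarray([epochs.data[b].mean(axis=0) for b in blocks])
    return EpochSet(
        data=data,
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        subject_id=epochs.subject_id,
        group=epochs.group,
        paradigm=epochs.paradigm,
        tmin=epochs.tmin,
        epoch_info=[
            {"block": i, "n_trials": len(b)} for i, b in enumerate(blocks)
        ],
    )


# --------------------------------------------------------------------------
# per-paradigm convenience chains (filter -> resample -> CAR -> epoch -> reject)


def preprocess_rest(
    rec: EEGRecording, cfg: PreprocessConfig = PreprocessConfig()
) -> EpochSet:
    """Full resting chain: band-pass, resample, CAR, 20-s segmentation,
    amplitude rejection."""
    rec = bandpass(rec, cfg)
    rec = resample(rec, cfg.target_fs_hz)
    rec = common_average_reference(rec)
    epochs = segment_resting(rec, cfg.rest_epoch_s, cfg.rest_n_epochs)
    return reject_by_amplitude(epochs, cfg.reject_uv)


def preprocess_task(
    rec: EEGRecording,
    events: pd.DataFrame,
    cfg: PreprocessConfig = PreprocessConfig(),
    seed: int | np.random.Generator = 0,
) -> EpochSet:
    """Full task chain: band-pass, resample, CAR, epoching of correct
    incongruent trials, amplitude rejection, block averaging."""
    rec = bandpass(rec, cfg)
    rec = resample(rec, cfg.target_fs_hz)
    rec = common_average_reference(rec)
    epochs = extract_task_epochs(rec, events, cfg)
    epochs = reject_by_amplitude(epochs, cfg.reject_uv)
    return block_average(epochs, cfg.task_n_blocks, seed)
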