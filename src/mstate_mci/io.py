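"""On-disk formats: recordings, epochs, events, models, labels, features.

Recordings and epoch stacks are stored as a ``.npy`` numeric matrix plus a
JSON sidecar with the sampling rate and metadata; the pair round-trips
bit-exactly.  Event tables and feature tables are plain CSV.  Microstate
models are JSON.  Label sequences are run-length-encoded CSV
(state, start_sample, length).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, EpochSet
from .features import ascii_feature_name
from .microstate import MicrostateModel

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "save_events",
    "load_events",
    "model_to_json",
    "model_from_json",
    "save_labels_rle",
    "load_labels_rle",
    "save_feature_table",
    "load_feature_table",
]


def save_recording(rec: EEGRecording, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, rec.data)
    meta.write_text(
        json.dumps(
            {
                "fs": rec.fs,
                "channel_names": list(rec.channel_names),
                "subject_id": rec.subject_id,
                "group": rec.group,
                "paradigm": rec.paradigm,
            },
            indent=1,
        )
    )
    return npy, meta


def load_recording(stem: str | Path) -> EEGRecording:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EEGRecording(data=data, **meta)


def save_epochs(epochs: EpochSet, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, epochs.data)
    meta.write_text(
        json.dumps(
            {
                "fs": epochs.fs,
                "channel_names": list(epochs.channel_names),
                "subject_id": epochs.subject_id,
                "group": epochs.group,
                "paradigm": epochs.paradigm,
                "tmin": epochs.tmin,
                "epoch_info": epochs.epoch_info,
            },
            indent=1,
        )
    )
    return npy, meta


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EpochSet(data=data, **meta)


def save_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, index=False)
    return path


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def model_to_json(model: MicrostateModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "class_labels": list(model.class_labels),
                "templates": model.templates.tolist(),
                "gev": model.gev,
                "n_restarts": model.n_restarts,
                "seed": model.seed,
                "channel_names": model.channel_names,
                "diagnostics": model.diagnostics,
            },
            indent=1,
        )
    )
    return path


def model_from_json(path: str | Path) -> MicrostateModel:
    d = json.loads(Path(path).read_text())
    return MicrostateModel(
        templates=np.asarray(d["templates"], dtype=float),
        class_labels=tuple(d["class_labels"]),
        gev=d["gev"],
        n_restarts=d["n_restarts"],
        seed=d.get("seed"),
        channel_names=d.get("channel_names"),
        diagnostics=d.get("diagnostics", {}),
    )


def save_labels_rle(labels: np.ndarray, path: str | Path) -> Path:
    """Run-length-encoded label CSV: state, start_sample, length."""
    from .features import merge_runs

    symbols, lengths = merge_runs(np.asarray(labels))
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    pd.DataFrame(
        {"state": symbols, "start_sample": starts, "length": lengths}
    ).to_csv(Path(path), index=False)
    return Path(path)


def load_labels_rle(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return np.repeat(df["state"].to_numpy(np.int8), df["length"].to_numpy(np.int64))


def save_feature_table(
    table: pd.DataFrame, path: str | Path, ascii_headers: bool = False
) -> Path:
    """Write a tidy feature CSV (UTF-8 arrows, or the ASCII ``A.B`` dialect)."""
    path = Path(path)
    out = table
    if ascii_headers:
        out = table.rename(columns={c: ascii_feature_name(c) for c in table.columns})
    out.to_csv(path, index=False, encoding="utf-8")
    return path


def load_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    # accept the ASCII dialect transparently: rX.Y -> rX→Y
    renames = {}
    for c in df.columns:
        if len(c) == 4 and c[2] == "." and c[0] in "rt":
            renames[c] = f"{c[0]}{c[1]}→{c[3]}"
    return df.rename(columns=renames)
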