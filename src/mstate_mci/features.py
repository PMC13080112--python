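"""The 26 microstate features of one analysis segment.

Per segment and paradigm the feature set is: mean duration (MD, ms),
coverage (COV, fraction of time) and occurrence (OC, appearances per second)
for each of the four classes; the 12 ordered distinct-pair transition
probabilities (TP); the model's global explained variance (GEV); and the
Lempel-Ziv complexity (LZC) of the merged label sequence.  Names follow the
``{paradigm prefix}{state}-{metric}`` and ``{prefix}{i}→{j}`` convention
(prefix ``r`` for resting, ``t`` for task), e.g. ``rA-MD`` or ``tC→D``.

All temporal features are computed on the *merged* sequence, in which
maximal runs of identical labels are collapsed to single occurrences
("AAAAABBBAAB" becomes "ABAB") while run lengths are retained for the
duration features.  States that never occur yield missing values (NaN) for
MD; transition rows with no outgoing transition are missing as well.
Coverage and occurrence of an absent state are genuinely zero.
"""

from __future__ import annotations

import numpy as np

from .montage import CLASS_NAMES

__all__ = [
    "merge_runs",
    "mean_duration",
    "coverage",
    "occurrence",
    "transition_probabilities",
    "lzc",
    "extract_all",
    "feature_names",
    "ascii_feature_name",
]

N_STATES = len(CLASS_NAMES)


def merge_runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse maximal runs; return ``(symbols, run_lengths)``.

    ``symbols`` is the distinct-run sequence (no two adjacent equal) and
    ``run_lengths`` the number of samples in each run; the lengths sum to
    the original sequence length.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot merge an empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts].astype(np.int8), (ends - starts).astype(np.int64)


def mean_duration(
    symbols: np.ndarray, run_lengths: np.ndarray, fs: float
) -> np.ndarray:
    """Per-state mean run duration in ms (NaN for states that never occur)."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    counts = np.bincount(symbols, minlength=N_STATES).astype(float)
    sums = np.bincount(symbols, weights=run_lengths, minlength=N_STATES)
    with np.errstate(invalid="ignore", divide="ignore"):
        md = sums / counts / fs * 1000.0
    md[counts == 0] = np.nan
    return md


def coverage(symbols: np.ndarray, run_lengths: np.ndarray) -> np.ndarray:
    """Fraction of total samples spent in each state (sums to 1)."""
    sums = np.bincount(symbols, weights=run_lengths, minlength=N_STATES)
    return sums / run_lengths.sum()


def occurrence(symbols: np.ndarray, total_time_s: float) -> np.ndarray:
    """Appearances of each state per second of recording."""
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    counts = np.bincount(symbols, minlength=N_STATES).astype(float)
    return counts / total_time_s


def transition_probabilities(symbols: np.ndarray) -> np.ndarray:
    """Distinct-state transition matrix ``TP[i, j] = N_(i->j) / N_i->``.

    The denominator counts outgoing transitions from state ``i`` (runs of
    ``i`` followed by another run), so each observed row sums to one.  Rows
    of states with no outgoing transition are NaN; the diagonal is
    structurally zero on a merged sequence.
    """
    symbols = np.asarray(symbols)
    if symbols.size < 2:
        raise ValueError("need at least 2 runs for transition probabilities")
    pairs = symbols[:-1].astype(int) * N_STATES + symbols[1:].astype(int)
    counts = np.bincount(pairs, minlength=N_STATES * N_STATES).astype(float)
    counts = counts.reshape(N_STATES, N_STATES)
    out = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = counts / out[:, None]
    tp[out == 0] = np.nan
    return tp


def lzc(symbols) -> int:
    """Lempel-Ziv complexity of a symbol sequence (exhaustive parsing).

    Scans left to right, growing the current word while it is still
    reproducible from the already-seen text (allowing overlap); the counter
    increments whenever the extension becomes a novel pattern, and the final
    incomplete word counts as one.  Returns the raw, unnormalised count.
    """
    s = bytes(np.asarray(symbols, dtype=np.uint8))
    n = len(s)
    if n == 0:
        raise ValueError("LZC of an empty sequence is undefined")
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def feature_names(prefix: str) -> list[str]:
    """The canonical 26 feature names for one paradigm prefix."""
    names = [f"{prefix}{s}-MD" for s in CLASS_NAMES]
    names += [f"{prefix}{s}-COV" for s in CLASS_NAMES]
    names += [f"{prefix}{s}-OC" for s in CLASS_NAMES]
    names += [
        f"{prefix}{a}→{b}" for a in CLASS_NAMES for b in CLASS_NAMES if a != b
    ]
    names += [f"{prefix}-GEV", f"{prefix}-LZC"]
    return names


def ascii_feature_name(name: str) -> str:
    """ASCII dialect of a feature name (``rA→B`` becomes ``rA.B``)."""
    return name.replace("→", ".")


def extract_all(
    labels: np.ndarray, fs: float, gev: float, prefix: str = "r"
) -> dict[str, float]:
    """Compute the full 26-feature vector of one segment.

    ``gev`` is the segment-level global explained variance computed against
    the fitted model (see :func:`mstate_mci.microstate.model_gev`); it is
    passed in because it needs the scalp maps, not just the labels.
    """
    if prefix not in ("r", "t"):
        raise ValueError("paradigm prefix must be 'r' or 't'")
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    symbols, run_lengths = merge_runs(labels)
    total_s = labels.size / fs
    md = mean_duration(symbols, run_lengths, fs)
    cov = coverage(symbols, run_lengths)
    oc = occurrence(symbols, total_s)
    if symbols.size >= 2:
        tp = transition_probabilities(symbols)
    else:
        tp = np.full((N_STATES, N_STATES), np.nan)
    out: dict[str, float] = {}
    for i, s in enumerate(CLASS_NAMES):
        out[f"{prefix}{s}-MD"] = float(md[i])
    for i, s in enumerate(CLASS_NAMES):
        out[f"{prefix}{s}-COV"] = float(cov[i])
    for i, s in enumerate(CLASS_NAMES):
        out[f"{prefix}{s}-OC"] = float(oc[i])
    for i, a in enumerate(CLASS_NAMES):
        for j, b in enumerate(CLASS_NAMES):
            if i != j:
                out[f"{prefix}{a}→{b}"] = float(tp[i, j])
    out[f"{prefix}-GEV"] = float(gev)
    out[f"{prefix}-LZC"] = float(lzc(symbols))
    return out
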