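"""Microstate segmentation: GFP, peak picking, polarity-invariant modified
k-means, canonical A-D labelling, and backfitting.

The pipeline follows the standard three-step microstate procedure: global
field power (GFP) is the per-sample standard deviation of potentials across
electrodes; topographies at strict local GFP maxima are clustered with a
modified k-means in which maps are assigned to the template of highest
*absolute* spatial correlation (polarity is ignored) and each template is
re-estimated as the dominant eigenvector of its cluster's outer-product sum.
The fitted templates are then backfitted to every sample of the continuous
data without temporal smoothing, so short, potentially pathological states
are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import EEGRecording, EpochSet
from .montage import CLASS_NAMES, canonical_maps

__all__ = [
    "GfpSeries",
    "MicrostateModel",
    "gfp",
    "find_gfp_peaks",
    "peak_maps",
    "modified_kmeans",
    "label_templates",
    "fit_microstates",
    "backfit",
    "model_gev",
]


@dataclass
class GfpSeries:
    """Per-sample global field power plus detected peak indices."""

    values: np.ndarray
    fs: float
    peak_indices: np.ndarray | None = None


@dataclass
class MicrostateModel:
    """Fitted microstate templates with canonical class labels.

    ``templates`` rows are unit-norm, average-referenced maps ordered to
    match ``class_labels`` (canonically ``("A", "B", "C", "D")``).
    """

    templates: np.ndarray
    class_labels: tuple[str, ...]
    gev: float
    n_restarts: int
    seed: int | None = None
    channel_names: list[str] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


def _as_array(rec) -> tuple[np.ndarray, float]:
    if isinstance(rec, EEGRecording):
        return rec.data, rec.fs
    raise TypeError("expected an EEGRecording")


def gfp(rec: EEGRecording) -> GfpSeries:
    """Global field power: the spatial standard deviation at each sample.

    ``GFP(t) = sqrt(mean_j (u_j(t) - mean_j u_j(t))^2)`` -- the population
    standard deviation of the scalp potentials across the ``n`` electrodes.
    """
    data, fs = _as_array(rec)
    if data.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return GfpSeries(values=data.std(axis=0, ddof=0), fs=fs)


def find_gfp_peaks(series: GfpSeries) -> GfpSeries:
    """Strict local maxima of the GFP curve.

    A sample is a peak iff both neighbours are strictly lower; endpoints and
    plateaus therefore never qualify.  A constant series yields an empty
    peak set with a warning.
    """
    v = series.values
    if v.size < 3:
        raise ValueError("need at least 3 samples to find peaks")
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0 and np.ptp(v) == 0:
        warnings.warn("constant GFP series: no peaks", stacklevel=2)
    series.peak_indices = peaks
    return series


def _center_normalize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre maps across channels and normalise rows; returns (unit, norms)."""
    X = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return X / safe[:, None], norms


def peak_maps(
    epochs: EpochSet | EEGRecording,
    max_per_epoch: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Collect topographies at GFP peaks, optionally subsampled per epoch.

    Returns ``(maps, gfp_values)`` with ``maps`` of shape ``(N_p, n)``.
    Subsampling (when ``max_per_epoch`` is set) keeps a random subset of
    each epoch's peaks, which bounds the clustering cost on long recordings.
    """
    rng = np.random.default_rng(seed)
    if isinstance(epochs, EEGRecording):
        stack = epochs.data[None]
        fs = epochs.fs
        names = epochs.channel_names
    else:
        stack = epochs.data
        fs = epochs.fs
        names = epochs.channel_names
    all_maps, all_gfp = [], []
    for ep in stack:
        rec = EEGRecording(data=ep, fs=fs, channel_names=list(names))
        series = find_gfp_peaks(gfp(rec))
        idx = series.peak_indices
        if max_per_epoch is not None and idx.size > max_per_epoch:
            idx = np.sort(rng.choice(idx, size=max_per_epoch, replace=False))
        all_maps.append(ep[:, idx].T)
        all_gfp.append(series.values[idx])
    return np.concatenate(all_maps, axis=0), np.concatenate(all_gfp)


def _dominant_map(X: np.ndarray) -> np.ndarray:
    """Unit dominant eigenvector of ``X.T @ X`` with a fixed sign convention."""
    G = X.T @ X
    vals, vecs = np.linalg.eigh(G)
    v = vecs[:, -1]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v / np.linalg.norm(v)


def _gev_from_assignment(
    corr: np.ndarray, assign: np.ndarray, gfp_vals: np.ndarray
) -> float:
    r = np.abs(corr[np.arange(corr.shape[0]), assign])
    w = gfp_vals**2
    denom = w.sum()
    if denom == 0:
        return 0.0
    return float((w * r**2).sum() / denom)


def modified_kmeans(
    maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Polarity-invariant modified k-means on GFP-peak topographies.

    Iterates (a) assignment of each map to the template of highest absolute
    spatial correlation and (b) template update as the dominant eigenvector
    of the assigned maps' outer-product sum, until assignments are stable or
    the GEV improvement drops below ``tol``.  The best of ``n_restarts``
    random initialisations by GEV is returned (ties keep the earliest
    restart).  Empty clusters are re-seeded from the currently worst-fit
    map.

    Returns ``(templates, assignments, gev)`` with unit-norm templates of
    shape ``(k, n)``.
    """
    maps = np.asarray(maps, dtype=float)
    n_maps = maps.shape[0]
    if n_maps < k:
        raise ValueError(f"{n_maps} maps cannot support k={k}")
    rng = np.random.default_rng(seed)
    Xn, norms = _center_normalize(maps)
    gfp_vals = norms / np.sqrt(maps.shape[1])

    best = None
    for _ in range(n_restarts):
        init = rng.choice(n_maps, size=k, replace=False)
        C = Xn[init].copy()
        C /= np.linalg.norm(C, axis=1, keepdims=True)
        prev_assign = None
        prev_gev = -np.inf
        for _ in range(max_iter):
            corr = Xn @ C.T
            assign = np.argmax(np.abs(corr), axis=1)
            fit = np.abs(corr).max(axis=1)
            for j in range(k):
                members = assign == j
                if not members.any():
                    worst = int(np.argmin(fit))
                    assign[worst] = j
                    members = assign == j
                C[j] = _dominant_map(Xn[members])
            corr = Xn @ C.T
            assign_new = np.argmax(np.abs(corr), axis=1)
            gev = _gev_from_assignment(corr, assign_new, gfp_vals)
            if prev_assign is not None and (
                np.array_equal(assign_new, prev_assign)
                or abs(gev - prev_gev) < tol
            ):
                prev_assign, prev_gev = assign_new, gev
                break
            prev_assign, prev_gev = assign_new, gev
        if best is None or prev_gev > best[2]:
            best = (C.copy(), prev_assign.copy(), prev_gev)
    return best


def label_templates(
    templates: np.ndarray, positions: np.ndarray
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Reorder templates to canonical A-D order.

    Templates are matched to the built-in canonical prototype maps by a
    globally optimal bijective assignment on absolute spatial correlation.
    Requires ``k <= 4``; any surplus canonical classes are simply unused.
    """
    protos = canonical_maps(positions)
    k = templates.shape[0]
    if k > protos.shape[0]:
        raise ValueError("canonical labelling supports at most 4 templates")
    Tn, _ = _center_normalize(templates)
    cost = -np.abs(Tn @ protos.T)  # (k, 4)
    rows, cols = linear_sum_assignment(cost)
    template_of_class = {int(c): int(r) for r, c in zip(rows, cols)}
    ordered_classes = sorted(template_of_class)
    reordered = np.asarray([Tn[template_of_class[c]] for c in ordered_classes])
    labels = tuple(CLASS_NAMES[c] for c in ordered_classes)
    return reordered, labels


def fit_microstates(
    maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
    positions: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> MicrostateModel:
    """Cluster peak maps and wrap the result in a labelled model.

    When ``positions`` is given the templates are re-ordered to canonical
    A-D; otherwise they keep the fitted order with generic numeric labels.
    """
    templates, assign, gev = modified_kmeans(
        maps, k=k, n_restarts=n_restarts, seed=seed
    )
    if positions is not None and k <= len(CLASS_NAMES):
        templates, labels = label_templates(templates, positions)
    else:
        labels = tuple(str(i + 1) for i in range(k))
    counts = np.bincount(assign, minlength=k)
    return MicrostateModel(
        templates=templates,
        class_labels=labels,
        gev=gev,
        n_restarts=n_restarts,
        seed=None,
        channel_names=channel_names,
        diagnostics={"n_maps": int(maps.shape[0]), "cluster_sizes": counts.tolist()},
    )


def backfit(
    rec: EEGRecording | np.ndarray, model: MicrostateModel
) -> tuple[np.ndarray, np.ndarray]:
    """Label every sample with the template of highest absolute correlation.

    No temporal constraint or minimum-duration rule is applied.  Ties break
    to the lowest class index.  Zero-variance samples inherit the previous
    sample's label (class 0 at the start) and are flagged.

    Returns ``(labels, flags)`` where ``labels`` are integer class codes
    indexing ``model.class_labels`` and ``flags`` marks zero-variance
    samples.
    """
    data = rec.data if isinstance(rec, EEGRecording) else np.asarray(rec, dtype=float)
    if data.shape[0] != model.n_channels:
        raise ValueError(
            f"recording has {data.shape[0]} channels, model {model.n_channels}"
        )
    Xn, norms = _center_normalize(data.T)
    corr = np.abs(Xn @ model.templates.T)
    labels = np.argmax(corr, axis=1).astype(np.int8)
    flags = norms == 0
    if flags.any():
        for i in np.flatnonzero(flags):
            labels[i] = labels[i - 1] if i > 0 else 0
    return labels, flags


def model_gev(
    maps: np.ndarray, gfp_vals: np.ndarray, model: MicrostateModel
) -> float:
    """GFP-squared-weighted explained variance of peak maps under a model.

    ``GEV = sum_p GFP_p^2 r_p^2 / sum_p GFP_p^2`` with ``r_p`` the spatial
    correlation between peak map ``p`` and its assigned (best-correlating)
    template.  Invariant to global amplitude scaling.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] == 0:
        raise ValueError("GEV is undefined without peaks")
    Xn, _ = _center_normalize(maps)
    corr = Xn @ model.templates.T
    assign = np.argmax(np.abs(corr), axis=1)
    return _gev_from_assignment(corr, assign, np.asarray(gfp_vals, dtype=float))
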