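"""mRMR ranking, wrapper subset construction, fusion, and grouped nested SVM
cross-validation.

The evaluation protocol is leakage-safe throughout: folds partition
*subjects* (every augmented segment of a subject shares a fold), class
proportions are balanced across folds, and screening, mRMR ranking, subset
choice, imputation and standardisation are all refitted inside each training
fold.  Hyperparameters (kernel, C, gamma) are chosen by an inner grouped
5-fold grid search on the training fold only.

Feature ranking uses the difference form of minimum-redundancy
maximum-relevance: the first feature maximises the mutual information
I(x; C) with the class label, and each subsequent feature maximises
``I(x; C) - mean_{s in S} I(x; s)`` over the already-selected set ``S``.
Mutual information is the plug-in estimate (in bits) on features
discretised into three bins at +/-0.5 SD of the training fold.

The wrapper evaluates the top-F mRMR prefix for F = 1..10 under the full
repeated grouped CV and retains the best prefix with at most five features
as the optimal feature subset (OFS).  Sensitivity is the recall of the MCI
class, specificity the recall of HC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .group_stats import screen_features

__all__ = [
    "SVMGrid",
    "CVConfig",
    "MrmrRanking",
    "CVReport",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "fuse",
    "sgkf_split",
    "inner_grid_search",
    "nested_fit_predict",
    "wrapper_ofs",
]

META_COLUMNS = ("subject_id", "segment_id", "group", "paradigm")
POSITIVE_CLASS = "MCI"  # sensitivity = recall of this class


@dataclass(frozen=True)
class SVMGrid:
    """Hyperparameter grid: decade grids over C and gamma, RBF vs linear."""

    kernels: tuple[str, ...] = ("rbf", "linear")
    C: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    gamma: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)

    def candidates(self) -> list[dict]:
        out = []
        for kernel in self.kernels:
            for C in self.C:
                if kernel == "rbf":
                    out.extend(
                        {"kernel": "rbf", "C": C, "gamma": g} for g in self.gamma
                    )
                else:
                    out.append({"kernel": "linear", "C": C})
        return out


@dataclass(frozen=True)
class CVConfig:
    """Evaluation protocol parameters."""

    n_folds: int = 5
    n_repeats: int = 5
    inner_folds: int = 5
    f_max: int = 5
    f_curve_max: int = 10
    alpha: float = 0.05
    in_fold_screening: bool = True  # False reproduces full-data screening
    grid: SVMGrid = field(default_factory=SVMGrid)
    seed: int = 0


@dataclass
class MrmrRanking:
    """Greedy mRMR order with per-step relevance, redundancy and score."""

    order: list[str]
    relevance: list[float]
    redundancy: list[float]
    score: list[float]


@dataclass
class CVReport:
    """Cross-validated performance of one run configuration."""

    config_name: str
    curve: pd.DataFrame  # per-F metrics, mean +/- SD over folds x repeats
    ofs: list[str]
    ofs_f: int
    ofs_metrics: dict[str, float]
    fold_hyperparams: list[dict]
    seed: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_name": self.config_name,
            "curve": self.curve.to_dict(orient="list"),
            "ofs": self.ofs,
            "ofs_f": self.ofs_f,
            "ofs_metrics": self.ofs_metrics,
            "fold_hyperparams": self.fold_hyperparams,
            "seed": self.seed,
            "notes": self.notes,
        }


# --------------------------------------------------------------------------
# discretisation and mutual information


def discretize(
    values: np.ndarray, mean: float | None = None, sd: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Three-bin discretisation at +/-0.5 SD after z-scoring.

    ``mean``/``sd`` are learned from the data when omitted (pass training
    statistics to transform held-out data).  A zero-variance column yields a
    single bin.  Returns ``(codes, mean, sd)``.
    """
    values = np.asarray(values, dtype=float)
    if mean is None:
        mean = float(np.nanmean(values))
    if sd is None:
        sd = float(np.nanstd(values))
    if sd == 0 or not np.isfinite(sd):
        return np.zeros(values.shape, dtype=np.int64), mean, 0.0
    z = (values - mean) / sd
    return np.digitize(z, [-0.5, 0.5]).astype(np.int64), mean, sd


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    n = x.size
    joint = np.bincount(xi * (yi.max() + 1) + yi).astype(float)
    joint = joint[joint > 0] / n
    px = np.bincount(xi).astype(float) / n
    py = np.bincount(yi).astype(float) / n
    px = px[px > 0]
    py = py[py > 0]
    h_x = -np.sum(px * np.log2(px))
    h_y = -np.sum(py * np.log2(py))
    h_xy = -np.sum(joint * np.log2(joint))
    return max(0.0, float(h_x + h_y - h_xy))


def mrmr_rank(
    features: pd.DataFrame, labels: np.ndarray, top_m: int | None = None
) -> MrmrRanking:
    """Greedy difference-form mRMR ranking of discretised feature columns.

    The first feature maximises relevance I(x; C); each next feature
    maximises relevance minus the mean mutual information with the features
    already selected.  Ties break by feature-name order.
    """
    cols = list(features.columns)
    if not cols:
        raise ValueError("no features to rank")
    if top_m is None:
        top_m = len(cols)
    y = np.asarray(labels)
    data = {c: features[c].to_numpy() for c in cols}
    relevance = {c: mutual_information(data[c], y) for c in cols}
    # cache of pairwise MI with selected features, built incrementally
    redundancy_sum = {c: 0.0 for c in cols}
    selected: list[str] = []
    rel_out, red_out, score_out = [], [], []
    remaining = sorted(cols)  # name order gives deterministic tie-breaks
    while remaining and len(selected) < top_m:
        best_name, best_score, best_red = None, -np.inf, 0.0
        for c in remaining:
            red = redundancy_sum[c] / len(selected) if selected else 0.0
            s = relevance[c] - red
            if s > best_score:
                best_name, best_score, best_red = c, s, red
        selected.append(best_name)
        rel_out.append(relevance[best_name])
        red_out.append(best_red)
        score_out.append(best_score)
        remaining.remove(best_name)
        for c in remaining:
            redundancy_sum[c] += mutual_information(data[c], data[best_name])
    return MrmrRanking(selected, rel_out, red_out, score_out)


# --------------------------------------------------------------------------
# fusion


def fuse(
    tables: list[pd.DataFrame], moca: pd.Series | pd.DataFrame | None = None
) -> pd.DataFrame:
    """Concatenate per-paradigm feature tables by (subject, segment).

    All tables must cover the same subjects and segment indices; their
    feature columns must be disjoint (guaranteed by the r/t prefixes).  When
    ``moca`` is given (a Series indexed by subject id, or a DataFrame with
    ``subject_id``/``moca`` columns) it is added as one candidate column,
    replicated across each subject's segments.
    """
    if not tables:
        raise ValueError("nothing to fuse")
    tables = [t for t in tables if t is not None and not t.empty]
    base = tables[0]
    keys = ["subject_id", "segment_id", "group"]
    fused = base.copy()
    for other in tables[1:]:
        a = set(base["subject_id"].unique())
        b = set(other["subject_id"].unique())
        if a != b:
            offenders = sorted(a.symmetric_difference(b))
            raise ValueError(f"subject mismatch between paradigms: {offenders}")
        drop = [c for c in other.columns if c in fused.columns and c not in keys]
        overlap = [c for c in drop if c not in ("paradigm", "moca")]
        if overlap:
            raise ValueError(f"duplicate feature columns: {overlap}")
        right = other.drop(columns=[c for c in ("paradigm", "moca") if c in other.columns])
        fused = fused.merge(right, on=keys, how="inner", validate="one_to_one")
    if moca is not None:
        if isinstance(moca, pd.DataFrame):
            moca = moca.set_index("subject_id")["moca"]
        fused = fused.drop(columns=[c for c in ("moca",) if c in fused.columns])
        fused["moca"] = fused["subject_id"].map(moca).astype(float)
    return fused


# --------------------------------------------------------------------------
# grouped, stratified, repeated cross-validation


def sgkf_split(
    subjects: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Subject-grouped stratified K-fold, repeated with fresh partitions.

    ``subjects`` and ``labels`` are per-segment; the label must be constant
    within a subject.  Folds partition subjects, stratified by class, so
    per-fold class counts are balanced within one subject.  Returns a list
    of ``(repeat, fold, train_idx, test_idx)`` segment-index tuples.
    """
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    subj_ids, first = np.unique(subjects, return_index=True)
    subj_labels = labels[first]
    for sid, lab in zip(subj_ids, subj_labels):
        if not np.all(labels[subjects == sid] == lab):
            raise ValueError(f"subject {sid} has inconsistent labels")
    counts = pd.Series(subj_labels).value_counts()
    if (counts < n_folds).any():
        raise ValueError(
            f"every class needs >= {n_folds} subjects; got {counts.to_dict()}"
        )
    root = np.random.SeedSequence(seed)
    out = []
    for rep, ss in enumerate(root.spawn(n_repeats)):
        state = int(ss.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=state)
        for fold, (tr_subj, te_subj) in enumerate(skf.split(subj_ids, subj_labels)):
            tr_set = set(subj_ids[tr_subj])
            te_set = set(subj_ids[te_subj])
            tr_idx = np.flatnonzero(pd.Series(subjects).isin(tr_set).to_numpy())
            te_idx = np.flatnonzero(pd.Series(subjects).isin(te_set).to_numpy())
            out.append((rep, fold, tr_idx, te_idx))
    return out


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


def inner_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    grid: SVMGrid,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Grouped inner grid search; returns the best parameter dict.

    Inner folds partition the training subjects (stratified); the candidate
    with the highest mean segment accuracy wins, ties going to the first
    candidate in grid order.  The search fits use a relaxed optimiser
    tolerance and an iteration cap -- they only rank candidates; the final
    model is always refitted at full precision.
    """
    from sklearn.exceptions import ConvergenceWarning

    splits = sgkf_split(subjects, y, n_folds=n_folds, n_repeats=1, seed=seed)
    candidates = grid.candidates()
    scores = np.zeros(len(candidates))
    with warnings.catch_warnings():
        # the iteration cap is deliberate for ranking-only fits
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _, _, tr, te in splits:
            Xtr, Xte = X[tr], X[te]
            ytr, yte = y[tr], y[te]
            for ci, params in enumerate(candidates):
                clf = SVC(**params, tol=1e-2, max_iter=2000)
                clf.fit(Xtr, ytr)
                scores[ci] += float(np.mean(clf.predict(Xte) == yte))
    return candidates[int(np.argmax(scores))]


def nested_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    subjects_train: np.ndarray,
    X_test: np.ndarray,
    grid: SVMGrid = SVMGrid(),
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Fit an SVM with nested hyperparameter search; predict the test fold.

    Standardisation uses training statistics only.  Raises if the training
    fold contains a single class.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    Ztr, Zte = _standardize(X_train, X_test)
    params = inner_grid_search(Ztr, y_train, subjects_train, grid, inner_folds, seed)
    clf = SVC(**params)
    clf.fit(Ztr, y_train)
    return clf.predict(Zte), params


# --------------------------------------------------------------------------
# wrapper feature-subset construction


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent; MCI is positive."""
    acc = 100.0 * float(np.mean(y_true == y_pred))
    pos = y_true == 1
    neg = ~pos
    sens = 100.0 * float(np.mean(y_pred[pos] == 1)) if pos.any() else np.nan
    spec = 100.0 * float(np.mean(y_pred[neg] == 0)) if neg.any() else np.nan
    return acc, sens, spec


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS and c != "moca"]


def _screen_candidates(
    table: pd.DataFrame, rows: np.ndarray, feature_cols: list[str], alpha: float
) -> list[str]:
    """Per-paradigm-family screening on the given (training) rows."""
    sub = table.iloc[rows]
    retained: list[str] = []
    prefixes = sorted({c[0] for c in feature_cols})
    for p in prefixes:
        fam = [c for c in feature_cols if c.startswith(p)]
        res = screen_features(sub, alpha=alpha, feature_cols=fam)
        retained.extend(res.retained)
    return [c for c in feature_cols if c in set(retained)]


def wrapper_ofs(
    table: pd.DataFrame,
    cv: CVConfig = CVConfig(),
    config_name: str = "run",
    include_moca: bool = False,
) -> CVReport:
    """Evaluate mRMR prefixes F = 1..10 under repeated grouped CV.

    ``table`` holds one row per (subject, segment) with ``group`` as the
    class label, the candidate feature columns, and optionally ``moca``.
    Screening (unless ``cv.in_fold_screening`` is off), ranking, imputation
    and standardisation happen inside each training fold.  SVM
    hyperparameters are tuned once per training fold -- the protocol's unit
    of optimisation -- by the inner grouped grid search on the OFS-sized
    mRMR prefix, and shared across the F curve of that fold.  The reported
    OFS is the best-accuracy prefix with at most ``cv.f_max`` features,
    recomputed on the full data for presentation (the metrics remain the
    honest cross-validated ones).
    """
    table = table.reset_index(drop=True)
    feature_cols = _feature_columns(table)
    if include_moca and "moca" not in table.columns:
        raise ValueError("include_moca requested but table has no moca column")
    y = (table["group"] == POSITIVE_CLASS).to_numpy().astype(int)
    subjects = table["subject_id"].to_numpy()
    splits = sgkf_split(subjects, y, cv.n_folds, cv.n_repeats, cv.seed)

    if not cv.in_fold_screening:
        fixed_retained = _screen_candidates(
            table, np.arange(len(table)), feature_cols, cv.alpha
        )

    notes: list[str] = []
    fold_hyperparams: list[dict] = []
    records = []  # (repeat, fold, F, acc, sens, spec)
    subj_votes: dict[tuple[int, int], list] = {}
    rng_root = np.random.SeedSequence(cv.seed + 101)
    inner_seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng_root.spawn(len(splits))]

    for split_i, (rep, fold, tr, te) in enumerate(splits):
        retained = (
            _screen_candidates(table, tr, feature_cols, cv.alpha)
            if cv.in_fold_screening
            else list(fixed_retained)
        )
        candidates = retained + (["moca"] if include_moca else [])
        if not candidates:
            notes.append(f"repeat {rep} fold {fold}: no candidate features retained")
            continue
        raw = table[candidates].to_numpy(dtype=float)
        med = np.nanmedian(raw[tr], axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        X = np.where(np.isnan(raw), med[None, :], raw)
        # discretised copy (training statistics) for the MI-based ranking
        disc = {}
        for ci, c in enumerate(candidates):
            codes, mu, sd = discretize(X[tr, ci])
            disc[c] = np.digitize((X[:, ci] - mu) / sd if sd else X[:, ci] * 0.0, [-0.5, 0.5])
        ranking = mrmr_rank(pd.DataFrame(disc, index=table.index)[candidates].iloc[tr], y[tr])
        f_top = min(cv.f_curve_max, len(ranking.order))
        if f_top < cv.f_curve_max:
            notes.append(
                f"repeat {rep} fold {fold}: curve truncated at F={f_top} "
                f"({len(ranking.order)} candidates)"
            )
        col_index = {c: candidates.index(c) for c in candidates}
        # hyperparameters are tuned once per training fold (the protocol's
        # unit of optimisation), on the OFS-sized prefix, and shared across
        # the F curve
        f_tune = min(cv.f_max, f_top)
        tune_cols = [col_index[c] for c in ranking.order[:f_tune]]
        Ztr_tune, _ = _standardize(X[np.ix_(tr, tune_cols)], X[np.ix_(te, tune_cols)])
        params = inner_grid_search(
            Ztr_tune, y[tr], subjects[tr], cv.grid, cv.inner_folds,
            inner_seeds[split_i],
        )
        fold_hyperparams.append(
            {"repeat": rep, "fold": fold, "tuned_on_F": f_tune, **params,
             "features": ranking.order[:f_tune]}
        )
        for F in range(1, f_top + 1):
            cols = [col_index[c] for c in ranking.order[:F]]
            Ztr, Zte = _standardize(X[np.ix_(tr, cols)], X[np.ix_(te, cols)])
            clf = SVC(**params)
            clf.fit(Ztr, y[tr])
            pred = clf.predict(Zte)
            acc, sens, spec = _metrics(y[te], pred)
            records.append((rep, fold, F, acc, sens, spec))
            for sid, yt, yp in zip(subjects[te], y[te], pred):
                subj_votes.setdefault((F, rep), []).append((sid, yt, yp))

    rec = pd.DataFrame(
        records, columns=["repeat", "fold", "F", "acc", "sens", "spec"]
    )
    if rec.empty:
        raise RuntimeError("no folds produced candidate features; nothing to report")
    curve = (
        rec.groupby("F")
        .agg(
            acc_mean=("acc", "mean"),
            acc_sd=("acc", "std"),
            sens_mean=("sens", "mean"),
            sens_sd=("sens", "std"),
            spec_mean=("spec", "mean"),
            spec_sd=("spec", "std"),
            n_folds=("acc", "size"),
        )
        .reset_index()
    )
    # subject-level majority vote accuracy, averaged over repeats
    subj_acc = {}
    for (F, rep), votes in subj_votes.items():
        df = pd.DataFrame(votes, columns=["sid", "y", "pred"])
        per_subj = df.groupby("sid").agg(y=("y", "first"), p=("pred", "mean"))
        subj_acc.setdefault(F, []).append(
            100.0 * float(np.mean((per_subj["p"] >= 0.5).astype(int) == per_subj["y"]))
        )
    curve["subj_acc_mean"] = [float(np.mean(subj_acc[F])) for F in curve["F"]]

    # OFS: best accuracy among F <= f_max, ties to the smaller F
    eligible = curve[curve["F"] <= cv.f_max]
    best_row = None
    for _, row in eligible.iterrows():
        if best_row is None or row["acc_mean"] > best_row["acc_mean"]:
            best_row = row
    ofs_f = int(best_row["F"])

    # presentation OFS from a full-data selection pass
    full_retained = _screen_candidates(
        table, np.arange(len(table)), feature_cols, cv.alpha
    )
    full_candidates = full_retained + (["moca"] if include_moca else [])
    if full_candidates:
        raw = table[full_candidates].to_numpy(dtype=float)
        med = np.nanmedian(raw, axis=0)
        raw = np.where(np.isnan(raw), np.where(np.isfinite(med), med, 0.0)[None, :], raw)
        disc = {
            c: discretize(raw[:, i])[0] for i, c in enumerate(full_candidates)
        }
        full_rank = mrmr_rank(pd.DataFrame(disc)[full_candidates], y)
        ofs = full_rank.order[: min(ofs_f, len(full_rank.order))]
    else:
        ofs = []
        notes.append("full-data screening retained no features")
    ofs_metrics = {
        "accuracy": float(best_row["acc_mean"]),
        "accuracy_sd": float(best_row["acc_sd"]),
        "sensitivity": float(best_row["sens_mean"]),
        "sensitivity_sd": float(best_row["sens_sd"]),
        "specificity": float(best_row["spec_mean"]),
        "specificity_sd": float(best_row["spec_sd"]),
        "subject_accuracy": float(best_row["subj_acc_mean"]),
    }
    return CVReport(
        config_name=config_name,
        curve=curve,
        ofs=ofs,
        ofs_f=ofs_f,
        ofs_metrics=ofs_metrics,
        fold_hyperparams=fold_hyperparams,
        seed=cv.seed,
        notes=notes,
    )
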