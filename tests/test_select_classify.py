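"""Selection/classification tests: discretisation, mutual information, mRMR
(against a brute-force sequential oracle), fusion arithmetic, grouped
stratified folds, nested SVM fitting and the wrapper protocol."""

import numpy as np
import pandas as pd
import pytest

from mstate_mci.select_classify import (
    CVConfig,
    SVMGrid,
    discretize,
    fuse,
    mrmr_rank,
    mutual_information,
    nested_fit_predict,
    sgkf_split,
    wrapper_ofs,
)
from mstate_mci.synth import simulate_feature_table
from tests.conftest import make_spec

SMALL_GRID = SVMGrid(kernels=("rbf", "linear"), C=(0.1, 1.0, 10.0), gamma=(0.01, 0.1, 1.0))


def toy_table(n_subjects=20, n_segments=5, informative=2, n_noise=4, seed=0):
    """Segment table with per-subject informative features plus noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        group = "MCI" if i < n_subjects // 2 else "HC"
        shift = 6.0 if group == "MCI" else 0.0
        base = shift + rng.normal(0.0, 0.5, size=informative)
        for seg in range(n_segments):
            row = {"subject_id": f"S{i:02d}", "segment_id": seg, "group": group}
            for j in range(informative):
                row[f"rI{j}-MD"] = base[j] + rng.normal(0, 0.3)
            for j in range(n_noise):
                row[f"rN{j}-MD"] = rng.normal(0, 1.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestDiscretize:
    def test_standard_normal_bin_masses(self, rng):
        x = rng.standard_normal(200_000)
        codes, _, _ = discretize(x)
        masses = np.bincount(codes, minlength=3) / x.size
        assert np.allclose(masses, [0.3085, 0.3829, 0.3085], atol=0.01)

    def test_constant_column_single_bin(self):
        codes, _, sd = discretize(np.full(50, 3.0))
        assert sd == 0.0 and np.all(codes == 0)

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(500)
        a, _, _ = discretize(x)
        b, _, _ = discretize(x + 42.0)
        assert np.array_equal(a, b)

    def test_train_statistics_transfer(self, rng):
        x = rng.standard_normal(100)
        _, mu, sd = discretize(x)
        codes, _, _ = discretize(np.array([mu - sd, mu, mu + sd]), mean=mu, sd=sd)
        assert codes.tolist() == [0, 1, 2]


class TestMutualInformation:
    def test_identity_balanced_binary_is_one_bit(self):
        x = np.array([0, 1] * 50)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x = rng.integers(0, 3, 500)
        y = rng.integers(0, 2, 500)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_independent_shuffle_near_zero(self, rng):
        x = rng.integers(0, 3, 5000)
        y = rng.permutation(x)
        assert mutual_information(x, y) < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))


def mrmr_oracle(features: pd.DataFrame, labels, top_m):
    """Exhaustive sequential maximisation with name-order tie-breaks."""
    remaining = sorted(features.columns)
    selected = []
    y = np.asarray(labels)
    while remaining and len(selected) < top_m:
        best, best_score = None, -np.inf
        for c in remaining:
            rel = mutual_information(features[c].to_numpy(), y)
            red = (
                np.mean(
                    [
                        mutual_information(features[c].to_numpy(), features[s].to_numpy())
                        for s in selected
                    ]
                )
                if selected
                else 0.0
            )
            if rel - red > best_score:
                best, best_score = c, rel - red
        selected.append(best)
        remaining.remove(best)
    return selected


class TestMrmr:
    def test_single_feature(self, rng):
        f = pd.DataFrame({"only": rng.integers(0, 3, 50)})
        ranking = mrmr_rank(f, rng.integers(0, 2, 50))
        assert ranking.order == ["only"]

    def test_duplicate_penalised_below_weaker_independent_feature(self, rng):
        y = rng.integers(0, 2, 2000)
        strong = np.where(rng.uniform(size=2000) < 0.9, y, 1 - y)
        duplicate = strong.copy()
        weaker = np.where(rng.uniform(size=2000) < 0.75, y, 1 - y)
        f = pd.DataFrame({"a_strong": strong, "b_dup": duplicate, "c_weak": weaker})
        ranking = mrmr_rank(f, y)
        assert ranking.order[0] == "a_strong"
        assert ranking.order[1] == "c_weak"  # redundancy penalty beats relevance

    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(5):
            f = pd.DataFrame(
                {f"f{j}": rng.integers(0, 3, 80) for j in range(6)}
            )
            y = rng.integers(0, 2, 80)
            ranking = mrmr_rank(f, y)
            assert ranking.order == mrmr_oracle(f, y, 6)

    def test_first_feature_maximises_relevance(self, rng):
        f = pd.DataFrame({f"f{j}": rng.integers(0, 3, 100) for j in range(5)})
        y = rng.integers(0, 2, 100)
        ranking = mrmr_rank(f, y)
        rels = {c: mutual_information(f[c].to_numpy(), y) for c in f.columns}
        assert rels[ranking.order[0]] == pytest.approx(max(rels.values()))


class TestFuse:
    def make_tables(self, n_rest=10, n_task=13):
        rows_r, rows_t = [], []
        for i in range(4):
            for seg in range(3):
                base = {"subject_id": f"S{i}", "segment_id": seg,
                        "group": "MCI" if i % 2 else "HC"}
                rows_r.append({**base, **{f"rF{j}-MD": float(j) for j in range(n_rest)}})
                rows_t.append({**base, **{f"tF{j}-MD": float(j) for j in range(n_task)}})
        return pd.DataFrame(rows_r), pd.DataFrame(rows_t)

    def test_ten_plus_thirteen_gives_23_candidates(self):
        rest, task = self.make_tables()
        fused = fuse([rest, task])
        feats = [c for c in fused.columns if c not in ("subject_id", "segment_id", "group")]
        assert len(feats) == 23
        assert len(fused) == 12

    def test_fuse_single_table_identity(self):
        rest, _ = self.make_tables()
        assert fuse([rest]).equals(rest)

    def test_subject_mismatch_listed(self):
        rest, task = self.make_tables()
        task = task[task["subject_id"] != "S2"]
        with pytest.raises(ValueError, match="S2"):
            fuse([rest, task])

    def test_moca_constant_within_subject(self):
        rest, task = self.make_tables()
        moca = pd.Series({f"S{i}": 20.0 + i for i in range(4)})
        fused = fuse([rest, task], moca=moca)
        assert "moca" in fused.columns
        per_subject = fused.groupby("subject_id")["moca"].nunique()
        assert (per_subject == 1).all()


class TestSgkf:
    def test_subject_disjoint_and_stratified(self):
        table = toy_table(n_subjects=21, n_segments=4)
        y = (table["group"] == "MCI").to_numpy().astype(int)
        splits = sgkf_split(table["subject_id"].to_numpy(), y, 5, 2, seed=0)
        assert len(splits) == 10
        for _, _, tr, te in splits:
            tr_subj = set(table["subject_id"].iloc[tr])
            te_subj = set(table["subject_id"].iloc[te])
            assert not tr_subj & te_subj
            te_labels = [y[table["subject_id"] == s][0] for s in te_subj]
            # 10 MCI / 11 HC subjects over 5 folds: 2 +/- 1 per class per fold
            assert 1 <= sum(te_labels) <= 3

    def test_deterministic_given_seed(self):
        table = toy_table()
        y = (table["group"] == "MCI").to_numpy().astype(int)
        a = sgkf_split(table["subject_id"].to_numpy(), y, 5, 2, seed=3)
        b = sgkf_split(table["subject_id"].to_numpy(), y, 5, 2, seed=3)
        for (r1, f1, tr1, te1), (r2, f2, tr2, te2) in zip(a, b):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_too_few_subjects_per_class_rejected(self):
        table = toy_table(n_subjects=6)
        y = (table["group"] == "MCI").to_numpy().astype(int)
        with pytest.raises(ValueError):
            sgkf_split(table["subject_id"].to_numpy(), y, 5, 1, seed=0)

    def test_inconsistent_subject_labels_rejected(self):
        subjects = np.array(["a", "a", "b", "b"])
        labels = np.array([0, 1, 0, 0])
        with pytest.raises(ValueError):
            sgkf_split(subjects, labels, 2, 1, seed=0)


class TestNestedFit:
    def test_linearly_separable_is_perfect(self, rng):
        n = 120
        X = np.vstack([rng.normal(-2, 0.3, (n // 2, 2)), rng.normal(2, 0.3, (n // 2, 2))])
        y = np.repeat([0, 1], n // 2)
        subjects = np.repeat(np.arange(n // 4), 4).astype(str)
        order = rng.permutation(n)
        X, y, subjects = X[order], y[order], subjects[order]
        preds, params = nested_fit_predict(
            X[:80], y[:80], subjects[:80], X[80:], SMALL_GRID, inner_folds=3, seed=0
        )
        assert np.mean(preds == y[80:]) == 1.0
        assert params["kernel"] in ("rbf", "linear")

    def test_single_class_training_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(ValueError):
            nested_fit_predict(
                X, np.zeros(20, dtype=int), np.arange(20).astype(str), X, SMALL_GRID
            )


@pytest.fixture(scope="module")
def informative_table():
    hc = make_spec("HC", n_subjects=16)
    mci = make_spec(
        "MCI", n_subjects=16, durations=(76.0, 64.0, 68.0, 60.0),
        into=[1, 1, 1, 0.5], moca_mean=19.2,
    )
    return simulate_feature_table(hc, mci, n_segments=5, segment_s=20.0, seed=7)


FAST_CV = CVConfig(
    n_folds=4, n_repeats=2, inner_folds=3, f_max=3, f_curve_max=4,
    grid=SMALL_GRID, seed=0,
)


class TestWrapper:
    def test_ofs_capped_and_metrics_bounded(self, informative_table):
        report = wrapper_ofs(informative_table, FAST_CV, config_name="rest")
        assert len(report.ofs) <= FAST_CV.f_max
        assert 0 <= report.ofs_metrics["accuracy"] <= 100
        assert report.curve["F"].max() <= FAST_CV.f_curve_max
        assert (report.curve["n_folds"] > 0).all()

    def test_separable_toy_problem_is_perfect(self):
        table = toy_table(n_subjects=24, n_segments=4, seed=3)
        cv = CVConfig(n_folds=4, n_repeats=1, inner_folds=3, f_max=3,
                      f_curve_max=3, grid=SMALL_GRID, seed=1, in_fold_screening=True)
        report = wrapper_ofs(table, cv, config_name="toy")
        assert report.ofs_metrics["accuracy"] == pytest.approx(100.0)

    def test_deterministic_given_seed(self, informative_table):
        a = wrapper_ofs(informative_table, FAST_CV)
        b = wrapper_ofs(informative_table, FAST_CV)
        assert a.curve.equals(b.curve) and a.ofs == b.ofs

    def test_test_fold_labels_never_influence_training(self, informative_table):
        """At a fixed partition, corrupting held-out labels changes neither
        the screened/ranked features nor the test predictions."""
        from mstate_mci.select_classify import _screen_candidates, discretize

        table = informative_table.reset_index(drop=True)
        y = (table["group"] == "MCI").to_numpy().astype(int)
        subjects = table["subject_id"].to_numpy()
        _, _, tr, te = sgkf_split(subjects, y, 4, 1, seed=5)[0]
        feature_cols = [c for c in table.columns
                        if c not in ("subject_id", "segment_id", "group")]

        def training_path(tbl):
            retained = _screen_candidates(tbl, tr, feature_cols, 0.05)
            X = tbl[retained].to_numpy(dtype=float)
            med = np.nanmedian(X[tr], axis=0)
            X = np.where(np.isnan(X), med[None, :], X)
            disc = {}
            for i, c in enumerate(retained):
                _, mu, sd = discretize(X[tr, i])
                disc[c] = discretize(X[:, i], mean=mu, sd=sd)[0]
            ranking = mrmr_rank(pd.DataFrame(disc)[retained].iloc[tr], y[tr])
            cols = [retained.index(c) for c in ranking.order[:3]]
            preds, params = nested_fit_predict(
                X[np.ix_(tr, cols)], y[tr], subjects[tr], X[np.ix_(te, cols)],
                SMALL_GRID, inner_folds=3, seed=1,
            )
            return retained, ranking.order, preds, params

        corrupted = table.copy()
        grp = corrupted["group"].to_numpy().copy()
        grp[te] = np.where(grp[te] == "MCI", "HC", "MCI")
        corrupted["group"] = grp

        ret_a, order_a, preds_a, params_a = training_path(table)
        ret_b, order_b, preds_b, params_b = training_path(corrupted)
        assert ret_a == ret_b and order_a == order_b and params_a == params_b
        assert np.array_equal(preds_a, preds_b)
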