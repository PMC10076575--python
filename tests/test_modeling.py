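"""RF training/prediction, cross-validation, diversity split, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hergml.evaluation import BINDER, NON_BINDER
from hergml.lb_features import FeatureMatrix
from hergml.modeling import (
    ModelBundle,
    ModelSpec,
    consensus_predict,
    consensus_predict_table,
    diversity_split,
    predict,
    ten_fold_cv,
    train,
)

B, N = BINDER, NON_BINDER


def separable_toy(n=40, seed=0):
    r = np.random.default_rng(seed)
    x = np.concatenate([r.uniform(0, 1, n // 2), r.uniform(2, 3, n // 2)])
    y = [N] * (n // 2) + [B] * (n // 2)
    df = pd.DataFrame({"x": x, "z": r.normal(size=n)})
    return FeatureMatrix(df), y


class TestTrainPredict:
    def test_deterministic_given_seed(self, small_lb_matrix, small_labels):
        fm = small_lb_matrix.subset(["logP", "TPSA", "mol_weight"])
        labels = small_labels.loc[fm.compound_ids]
        p1 = predict(train(fm, labels, ModelSpec(seed=5)), fm)
        p2 = predict(train(fm, labels, ModelSpec(seed=5)), fm)
        pd.testing.assert_frame_equal(p1, p2)

    def test_separable_toy_training_accuracy_one(self):
        fm, y = separable_toy()
        bundle = train(fm, y, ModelSpec(seed=1))
        preds = predict(bundle, fm)
        assert (preds["label"].to_numpy() == np.array(y)).all()

    def test_single_class_labels_raise(self):
        fm, _ = separable_toy()
        with pytest.raises(ValueError, match="single class"):
            train(fm, [B] * len(fm.values), ModelSpec())

    def test_missing_values_raise(self):
        fm, y = separable_toy()
        fm.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train(fm, y, ModelSpec())

    def test_schema_mismatch_lists_columns(self):
        fm, y = separable_toy()
        bundle = train(fm, y, ModelSpec())
        other = FeatureMatrix(fm.values.rename(columns={"z": "w"}))
        with pytest.raises(ValueError) as err:
            predict(bundle, other)
        assert "z" in str(err.value) and "w" in str(err.value)

    def test_probability_tie_maps_to_binder(self):
        fm, y = separable_toy()
        bundle = train(fm, y, ModelSpec(seed=0))

        class HalfProba:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        bundle.classifier = HalfProba()
        preds = predict(bundle, fm)
        assert (preds["label"] == B).all()

    def test_identical_rows_get_identical_outputs(self):
        fm, y = separable_toy()
        bundle = train(fm, y, ModelSpec(seed=2))
        probe = FeatureMatrix(
            pd.DataFrame({"x": [1.5, 1.5], "z": [0.0, 0.0]}, index=["p", "q"])
        )
        preds = predict(bundle, probe)
        assert preds.loc["p", "probability"] == preds.loc["q", "probability"]

    def test_feature_importances_exposed(self):
        fm, y = separable_toy()
        bundle = train(fm, y, ModelSpec(seed=3))
        imp = bundle.feature_importances
        assert set(imp.index) == {"x", "z"}
        assert imp["x"] > imp["z"]  # the separating feature dominates

    def test_bundle_roundtrip(self, tmp_path):
        fm, y = separable_toy()
        bundle = train(fm, y, ModelSpec(seed=4))
        path = tmp_path / "model.joblib"
        bundle.save(path)
        back = ModelBundle.load(path)
        pd.testing.assert_frame_equal(predict(back, fm), predict(bundle, fm))
        assert (tmp_path / "model.joblib.schema.json").exists()


class TestTenFoldCV:
    def test_out_of_fold_predictions_cover_each_row_once(self):
        fm, y = separable_toy(n=50)
        report, preds = ten_fold_cv(
            fm, y, ModelSpec(seed=0), seed=0, return_predictions=True
        )
        assert len(preds) == 50
        assert preds["probability"].notna().all()
        assert report.n == 50

    def test_separable_toy_cv_mcc_one(self):
        fm, y = separable_toy(n=60)
        report = ten_fold_cv(fm, y, ModelSpec(seed=0), seed=0)
        assert report.MCC == pytest.approx(1.0)
        assert report.AUC == pytest.approx(1.0)

    def test_too_few_rows_raise(self):
        fm, y = separable_toy(n=8)
        with pytest.raises(ValueError, match="10"):
            ten_fold_cv(fm, y, ModelSpec(), seed=0)

    def test_fold_sizes_differ_by_at_most_one(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 23 + [1] * 31)
        sizes = [
            len(test)
            for _, test in StratifiedKFold(10, shuffle=True, random_state=1).split(
                np.zeros((54, 1)), y
            )
        ]
        assert max(sizes) - min(sizes) <= 1

    def test_metrics_invariant_to_row_permutation(self):
        fm, y = separable_toy(n=50, seed=9)
        perm = np.random.default_rng(0).permutation(50)
        fm2 = FeatureMatrix(fm.values.iloc[perm])
        y2 = [y[i] for i in perm]
        r1 = ten_fold_cv(fm, y, ModelSpec(seed=0), seed=0)
        r2 = ten_fold_cv(fm2, y2, ModelSpec(seed=0), seed=0)
        # separable either way: identical perfect reports
        assert r1.MCC == r2.MCC == 1.0


class TestDiversitySplit:
    def _fps(self):
        twin = [1, 1, 1, 1, 0, 0, 0, 0]
        distinct = [0, 0, 0, 0, 1, 1, 1, 1]
        return np.array([twin, twin, distinct])

    def test_distinct_compound_always_picked_at_size_two(self):
        # whatever the random anchor, the MaxMin criterion must pull in the
        # structurally distinct compound by the second pick
        for seed in range(10):
            _, test = diversity_split(
                ["t1", "t2", "d"], self._fps(), test_fraction=0.67, seed=seed
            )
            assert "d" in test and len(test) == 2

    def test_same_seed_same_split(self, small_cohort):
        fps = np.random.default_rng(3).integers(0, 2, size=(40, 64))
        ids = [f"c{i}" for i in range(40)]
        assert diversity_split(ids, fps, seed=7) == diversity_split(ids, fps, seed=7)

    def test_small_fraction_gives_single_test_compound(self):
        fps = np.random.default_rng(1).integers(0, 2, size=(20, 16))
        train_ids, test_ids = diversity_split(
            [str(i) for i in range(20)], fps, test_fraction=0.01, seed=0
        )
        assert len(test_ids) == 1 and len(train_ids) == 19

    def test_partition_is_complete_and_disjoint(self):
        fps = np.random.default_rng(2).integers(0, 2, size=(30, 16))
        ids = [str(i) for i in range(30)]
        train_ids, test_ids = diversity_split(ids, fps, test_fraction=0.3, seed=5)
        assert sorted(train_ids + test_ids) == sorted(ids)
        assert not set(train_ids) & set(test_ids)
        assert len(test_ids) == 9

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            diversity_split(["a"], np.array([[1]]), test_fraction=1.5)


class TestConsensus:
    @pytest.mark.parametrize(
        "votes,min_votes,expected",
        [
            ([B, B, B, N, N], 3, B),
            ([B, B, N, N, N], 3, N),
            ([N, N, N, N, N], 3, N),
            ([B], 1, B),
        ],
    )
    def test_minimum_vote_rule(self, votes, min_votes, expected):
        assert consensus_predict(votes, min_votes) == expected

    def test_empty_votes_raise(self):
        with pytest.raises(ValueError):
            consensus_predict([])

    def test_min_votes_one_is_or_and_n_is_and(self):
        for combo in itertools.product([B, N], repeat=4):
            any_b = B in combo
            all_b = all(v == B for v in combo)
            assert (consensus_predict(combo, 1) == B) == any_b
            assert (consensus_predict(combo, 4) == B) == all_b

    def test_table_interface(self):
        table = pd.DataFrame(
            {"m1": [B, N], "m2": [B, N], "m3": [B, B], "m4": [N, B], "m5": [N, N]},
            index=["c1", "c2"],
        )
        out = consensus_predict_table(table, min_votes=3)
        assert out.tolist() == [B, N]
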