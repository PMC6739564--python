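import numpy as np
import pytest

from nlsp import (
    BaseLearnerSpec,
    fit_nlsp,
    label_powerset_encode,
    label_scores,
    load_model,
    make_base_learner,
    predict_nlsp,
    save_model,
    svm_gamma,
)
from nlsp.community import CommunityPartition
from nlsp.ensemble import LabelPowersetModel, NLSPModel, _ConstantClassifier

from conftest import make_dataset, random_dataset

# odd tree count: pure-leaf vote fractions can never tie at exactly 1/2
FAST_RF = BaseLearnerSpec("RF", {"n_trees": 31}, seed=0, allow_outside_grid=True)


class TestLabelPowersetEncode:
    def test_toy_rows(self):
        classes, table = label_powerset_encode([[1, 0], [1, 0], [1, 1]])
        assert classes.tolist() == [0, 0, 1]
        assert table == {(1, 0): 0, (1, 1): 1}

    def test_identical_rows_single_class(self):
        classes, table = label_powerset_encode([[0, 1, 1]] * 4)
        assert classes.tolist() == [0, 0, 0, 0] and len(table) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_decode_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.integers(0, 2, size=(30, 4))
        classes, table = label_powerset_encode(Y)
        inverse = {v: k for k, v in table.items()}
        decoded = np.array([inverse[c] for c in classes])
        assert np.array_equal(decoded, Y)

    def test_empty_width_rejected(self):
        with pytest.raises(ValueError):
            label_powerset_encode(np.zeros((3, 0)))


class TestMakeBaseLearner:
    def test_xgb_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((60, 5)), rng.integers(0, 3, size=60)
        spec = BaseLearnerSpec("XGB", {"n_trees": 20}, seed=7)
        preds = []
        for _ in range(2):
            est = make_base_learner(spec, 5)()
            est.fit(X, y)
            preds.append(est.predict_proba(X))
        assert np.array_equal(preds[0], preds[1])

    def test_svm_gamma_rule(self):
        assert svm_gamma(42) == pytest.approx(1 / 42)
        est = make_base_learner(BaseLearnerSpec("SVM", {"C": 1}), 42)()
        assert est.gamma == pytest.approx(1 / 42)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="GBM2"):
            BaseLearnerSpec("GBM2")

    def test_outside_grid_warns(self):
        with pytest.warns(UserWarning, match="outside the tuning grid"):
            BaseLearnerSpec("XGB", {"n_trees": 7})

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            BaseLearnerSpec("RF", {"max_depth": 3})


def fake_member(labels, table, proba, classes=None):
    """A LabelPowersetModel around a stub estimator with fixed outputs."""
    proba = np.asarray(proba, dtype=float)

    class Stub:
        classes_ = np.asarray(
            classes if classes is not None else range(proba.shape[1])
        )

        def predict(self, X):
            return self.classes_[np.argmax(proba, axis=1)][: len(X)]

        def predict_proba(self, X):
            return proba[: len(X)]

    return LabelPowersetModel(labels, table, Stub())


def model_from_members(members, label_names):
    return NLSPModel(
        partition=CommunityPartition([m.community_labels for m in members]),
        members=members,
        base_spec=FAST_RF,
        label_names=tuple(label_names),
        n_features=2,
    )


class TestPredictionSemantics:
    def test_union_of_disjoint_communities(self):
        m1 = fake_member(("A", "B"), {(1, 0): 0, (0, 1): 1}, [[0.9, 0.1]])
        m2 = fake_member(("C",), {(1,): 0, (0,): 1}, [[0.8, 0.2]])
        model = model_from_members([m1, m2], ["A", "B", "C"])
        assert predict_nlsp(model, np.zeros((1, 2))) == [frozenset({"A", "C"})]

    def test_union_keeps_any_positive_for_overlap(self):
        # both communities contain B; one predicts it present, one absent
        m1 = fake_member(("A", "B"), {(1, 1): 0, (1, 0): 1}, [[0.9, 0.1]])
        m2 = fake_member(("B", "C"), {(0, 0): 0, (1, 0): 1}, [[0.9, 0.1]])
        model = model_from_members([m1, m2], ["A", "B", "C"])
        assert predict_nlsp(model, np.zeros((1, 2))) == [
            frozenset({"A", "B"})
        ]

    def test_prediction_invariant_to_community_order(self):
        ds = random_dataset(np.random.default_rng(3), 60, 4)
        model = fit_nlsp(ds, clusterer="lpa", base_spec=FAST_RF, seed=1)
        flipped = NLSPModel(
            partition=CommunityPartition(model.partition.communities[::-1]),
            members=model.members[::-1],
            base_spec=model.base_spec,
            label_names=model.label_names,
            n_features=model.n_features,
        )
        X = ds.features[:10]
        assert predict_nlsp(model, X) == predict_nlsp(flipped, X)

    def test_width_mismatch_rejected(self):
        ds = random_dataset(np.random.default_rng(0), 30, 3)
        model = fit_nlsp(ds, clusterer="none", base_spec=FAST_RF, seed=0)
        with pytest.raises(ValueError, match="width"):
            predict_nlsp(model, np.zeros((2, 99)))

    def test_predicted_combinations_were_observed_in_training(self):
        ds = random_dataset(np.random.default_rng(8), 80, 5)
        model = fit_nlsp(ds, clusterer="louvain", base_spec=FAST_RF, seed=2)
        X = random_dataset(np.random.default_rng(9), 40, 5).features
        for member in model.members:
            observed = set(member.combination_table)
            for s in member.predict_sets(X):
                bits = tuple(
                    int(l in s) for l in member.community_labels
                )
                assert bits in observed


class TestLabelScores:
    def test_hand_summation(self):
        # classes: {A} with p=0.7, {A,B} with p=0.3
        m = fake_member(("A", "B"), {(1, 0): 0, (1, 1): 1}, [[0.7, 0.3]])
        model = model_from_members([m], ["A", "B"])
        s = label_scores(model, np.zeros((1, 2)))
        assert s[0].tolist() == pytest.approx([1.0, 0.3])

    def test_degenerate_single_class_model(self):
        member = LabelPowersetModel(
            ("A", "B"), {(1, 0): 0}, _ConstantClassifier(0)
        )
        model = model_from_members([member], ["A", "B"])
        s = label_scores(model, np.zeros((3, 2)))
        assert np.array_equal(s, np.tile([1.0, 0.0], (3, 1)))

    def test_overlapping_communities_take_max(self):
        m1 = fake_member(("A",), {(1,): 0, (0,): 1}, [[0.6, 0.4]])
        m2 = fake_member(("A",), {(1,): 0, (0,): 1}, [[0.2, 0.8]])
        model = model_from_members([m1, m2], ["A"])
        assert label_scores(model, np.zeros((1, 2)))[0, 0] == pytest.approx(0.6)

    def test_scores_bounded_and_independent_of_argmax_rule(self):
        ds = random_dataset(np.random.default_rng(4), 80, 4)
        model = fit_nlsp(ds, clusterer="lpa", base_spec=FAST_RF, seed=1)
        s = label_scores(model, ds.features)
        assert (s >= 0).all() and (s <= 1).all()
        # thresholding scores at 0.5 need not reproduce predict_nlsp
        assert s.shape == (80, 4)


def direct_label_powerset(ds, spec, X_test):
    """Independent plain-LP oracle: one multiclass model on all labels."""
    classes, table = label_powerset_encode(ds.labels)
    est = make_base_learner(spec, ds.n_features)()
    est.fit(ds.features, classes)
    inverse = {v: k for k, v in table.items()}
    names = np.asarray(ds.label_names, dtype=object)
    out = []
    for c in est.predict(X_test):
        bits = np.asarray(inverse[int(c)], dtype=bool)
        out.append(frozenset(names[bits]))
    return out


def direct_binary_relevance(ds, spec, X_test):
    """Independent BR oracle: one binary classifier per label."""
    preds = np.zeros((len(X_test), ds.n_labels), dtype=int)
    for j in range(ds.n_labels):
        y = ds.labels[:, j]
        if y.sum() == 0:
            continue
        if y.sum() == len(y):
            preds[:, j] = 1
            continue
        est = make_base_learner(spec, ds.n_features)()
        est.fit(ds.features, y)
        preds[:, j] = est.predict(X_test)
    names = np.asarray(ds.label_names, dtype=object)
    return [frozenset(names[row.astype(bool)]) for row in preds]


class TestDegenerateEquivalences:
    def test_none_clusterer_equals_label_powerset(self):
        ds = random_dataset(np.random.default_rng(1), 100, 5)
        X = random_dataset(np.random.default_rng(2), 30, 5).features
        model = fit_nlsp(ds, clusterer="none", base_spec=FAST_RF, seed=0)
        assert model.k == 1
        assert predict_nlsp(model, X) == direct_label_powerset(ds, FAST_RF, X)

    def test_singletons_clusterer_equals_binary_relevance(self):
        ds = random_dataset(np.random.default_rng(5), 100, 5)
        X = random_dataset(np.random.default_rng(6), 30, 5).features
        model = fit_nlsp(ds, clusterer="singletons", base_spec=FAST_RF, seed=0)
        assert model.k == ds.n_labels
        assert predict_nlsp(model, X) == direct_binary_relevance(ds, FAST_RF, X)


class TestFit:
    def test_planted_communities_recovered(self, strong_signal_dataset,
                                           planted_blocks):
        model = fit_nlsp(
            strong_signal_dataset, clusterer="lpa", base_spec=FAST_RF, seed=0
        )
        assert sorted(map(set, model.partition.communities), key=min) == sorted(
            planted_blocks, key=min
        )

    def test_zero_positive_label_forced_constant_absent(self):
        Y = np.array([[1, 0, 0], [1, 0, 1], [0, 0, 1]], dtype=np.int8)
        ds = make_dataset(Y)
        with pytest.warns(UserWarning, match="no positive"):
            model = fit_nlsp(ds, clusterer="lpa", base_spec=FAST_RF, seed=0)
        preds = predict_nlsp(model, ds.features)
        assert all("B" not in p for p in preds)
        assert ("B",) in model.partition.communities

    def test_unknown_clusterer_rejected(self):
        ds = make_dataset([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="clusterer"):
            fit_nlsp(ds, clusterer="kmeans", base_spec=FAST_RF)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        ds = random_dataset(np.random.default_rng(7), 60, 4)
        model = fit_nlsp(ds, clusterer="lpa", base_spec=FAST_RF, seed=3)
        path = tmp_path / "model.nlsp.zip"
        save_model(model, path)
        back = load_model(path)
        assert back.partition.communities == model.partition.communities
        assert back.label_names == model.label_names
        X = ds.features[:15]
        assert predict_nlsp(back, X) == predict_nlsp(model, X)
        assert np.allclose(label_scores(back, X), label_scores(model, X))

    def test_wrong_version_rejected(self, tmp_path):
        ds = random_dataset(np.random.default_rng(7), 30, 3)
        model = fit_nlsp(ds, clusterer="none", base_spec=FAST_RF, seed=3)
        model.format_version = 99
        path = tmp_path / "m.zip"
        save_model(model, path)
        with pytest.raises(ValueError, match="version"):
            load_model(path)
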