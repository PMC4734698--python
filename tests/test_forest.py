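import numpy as np
import pytest

from vesselseg.forest import (
    best_interval_split,
    information_gain,
    model_from_json,
    model_to_json,
    predict,
    predict_batch,
    train_forest,
)

from .oracles import exhaustive_interval_gain, information_gain_direct


class TestInformationGain:
    def test_pure_parent_zero_gain(self):
        assert information_gain(["M"] * 4, ["M", "M"], ["M", "M"]) == 0.0

    def test_perfect_split_one_bit(self):
        assert information_gain(
            ["M", "M", "N", "N"], ["M", "M"], ["N", "N"]
        ) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            labels = ["M" if b else "N" for b in rng.integers(0, 2, n)]
            cut = int(rng.integers(0, n + 1))
            left, right = labels[:cut], labels[cut:]
            want = max(0.0, information_gain_direct(labels, left, right))
            assert information_gain(labels, left, right) == pytest.approx(want)

    def test_rejects_non_partition(self):
        with pytest.raises(ValueError):
            information_gain(["M", "N"], ["M"], ["M"])
        with pytest.raises(ValueError):
            information_gain([], [], [])


class TestIntervalSplit:
    def test_isolates_middle_class(self):
        # the single M at value 2 needs BOTH thresholds; one cannot do it
        res = best_interval_split([1, 2, 3, 10, 11], ["N", "M", "N", "N", "N"])
        assert res.tau2 < 2 < res.tau1
        assert res.tau1 <= 2.5 and res.tau2 >= 1.5
        parent_h = information_gain_direct(
            ["N", "M", "N", "N", "N"], ["M"], ["N"] * 4
        )
        assert res.gain == pytest.approx(parent_h)

    def test_uniform_labels_zero_gain(self):
        res = best_interval_split([1.0, 2.0, 3.0], ["M", "M", "M"])
        assert res.gain == 0.0

    def test_identical_values_degenerate(self):
        res = best_interval_split([5.0, 5.0, 5.0], ["M", "N", "M"])
        assert res.degenerate and res.gain == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(50):
            values = rng.normal(size=12).round(2)
            labels = ["M" if b else "N" for b in rng.integers(0, 2, 12)]
            if len(set(labels)) < 2:
                labels[0] = "M" if labels[0] == "N" else "N"
            res = best_interval_split(values, labels, candidate_grid=64)
            distinct = np.unique(values)
            cand = (distinct[:-1] + distinct[1:]) / 2
            want = exhaustive_interval_gain(values, labels, cand)
            assert res.gain == pytest.approx(want, abs=1e-12)

    def test_tie_break_deterministic(self):
        values = [0.0, 1.0, 2.0, 3.0]
        labels = ["N", "N", "N", "N"]
        a = best_interval_split(values, labels)
        b = best_interval_split(values, labels)
        assert (a.tau1, a.tau2) == (b.tau1, b.tau2)


def interval_band_data(rng, n=200):
    """Class M occupies the middle band of both features."""
    X = rng.uniform(0, 1, size=(n, 2))
    y = [
        "M" if (0.4 < a < 0.6 and 0.4 < b < 0.6) else "N"
        for a, b in X
    ]
    if "M" not in y:
        X[0] = [0.5, 0.5]
        y[0] = "M"
    return X, y


class TestTraining:
    def test_single_class_refused(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            train_forest(rng.normal(size=(10, 6)), ["M"] * 10)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 6))
        y = ["M" if v > 0 else "N" for v in X[:, 2]]
        m1 = train_forest(X, y, n_trees=8, seed=5)
        m2 = train_forest(X, y, n_trees=8, seed=5)
        assert model_to_json(m1) == model_to_json(m2)

    def test_record_order_invariance(self, rng):
        X = rng.normal(size=(60, 6))
        y = np.array(["M" if v > 0 else "N" for v in X[:, 2]])
        perm = rng.permutation(60)
        m1 = train_forest(X, y, n_trees=8, seed=5)
        m2 = train_forest(X[perm], y[perm], n_trees=8, seed=5)
        assert model_to_json(m1) == model_to_json(m2)

    def test_single_tree_zero_training_error_on_three_bands(self):
        """A middle band is interval-separable in ONE split; a single
        threshold test cannot isolate it."""
        values = np.linspace(0, 1, 60)
        y = ["M" if 0.35 < v < 0.65 else "N" for v in values]
        X = np.column_stack([values] * 1)
        model = train_forest(
            X, y, n_trees=1, subset_size=1, bootstrap=False, max_depth=16
        )
        assert predict_batch(model, X) == y

    def test_interval_region_learnable(self, rng):
        """2-D band-intersection region: out-of-bag accuracy is high."""
        accs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            X, y = interval_band_data(r)
            model = train_forest(X, y, n_trees=64, subset_size=2, seed=seed)
            accs.append(model.metadata["oob_accuracy"])
        assert np.mean(accs) >= 0.9


class TestPrediction:
    def test_unanimous_vote(self, rng):
        X = rng.normal(size=(30, 6))
        y = ["M" if v > 0 else "N" for v in X[:, 0]]
        model = train_forest(X, y, n_trees=5, seed=1)
        x = np.zeros(6)
        x[0] = 10.0
        votes = [t.predict_one(x) for t in model.trees]
        assert predict(model, x) == max(set(votes), key=votes.count)

    def test_vote_tie_resolves_to_n(self):
        from vesselseg.forest import DecisionTree, ForestModel, Leaf

        model = ForestModel(
            trees=[DecisionTree(Leaf("M")), DecisionTree(Leaf("N"))]
        )
        assert predict(model, np.zeros(6)) == "N"

    def test_forest_vote_equals_mode_of_tree_votes(self, rng):
        X = rng.normal(size=(80, 6))
        y = ["M" if a + b > 0 else "N" for a, b in zip(X[:, 0], X[:, 1])]
        model = train_forest(X, y, n_trees=9, seed=2)
        for _ in range(100):
            x = rng.normal(size=6)
            votes = [t.predict_one(x) for t in model.trees]
            n_m = votes.count("M")
            want = "M" if n_m > len(votes) - n_m else "N"
            assert predict(model, x) == want

    def test_dimensionality_checked(self, rng):
        X = rng.normal(size=(20, 6))
        y = ["M" if v > 0 else "N" for v in X[:, 0]]
        model = train_forest(X, y, n_trees=2, seed=0)
        with pytest.raises(ValueError):
            predict(model, np.zeros(4))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng):
        X = rng.normal(size=(60, 6))
        y = ["M" if v > 0.2 else "N" for v in X[:, 3]]
        model = train_forest(X, y, n_trees=6, seed=9)
        back = model_from_json(model_to_json(model))
        probes = rng.normal(size=(50, 6))
        assert predict_batch(model, probes) == predict_batch(back, probes)
        assert model_to_json(back) == model_to_json(model)

    def test_version_checked(self):
        with pytest.raises(ValueError, match="version"):
            model_from_json('{"format_version": 99, "trees": [], "feature_names": []}')


class TestCrossCheck:
    def test_comparable_to_sklearn_on_separable_data(self, rng):
        """Independent reference: sklearn's forest on the same band data
        reaches similar accuracy — the interval-split forest is not worse
        by a wide margin."""
        from sklearn.ensemble import RandomForestClassifier

        r = np.random.default_rng(0)
        X, y = interval_band_data(r, n=300)
        Xtr, ytr, Xte, yte = X[:200], y[:200], X[200:], y[200:]
        mine = train_forest(Xtr, ytr, n_trees=32, subset_size=2, seed=0)
        acc_mine = np.mean([predict(mine, x) == t for x, t in zip(Xte, yte)])
        ref = RandomForestClassifier(n_estimators=32, random_state=0).fit(Xtr, ytr)
        acc_ref = ref.score(Xte, yte)
        assert acc_mine >= acc_ref - 0.1
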