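import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbond.classifiers import (
    ClassifierConfig,
    DegenerateModelWarning,
    FeatureScaler,
    knn_predict_proba,
    normalized_distance,
    pair_training_data,
    predict_pair_matrix,
    train_pair_classifier,
)
from ssbond.features import FeatureFunctionSet


def _scaler(sigma, groups):
    return FeatureScaler(np.asarray(sigma, dtype=float), list(groups))


class TestNormalizedDistance:
    def test_identity(self):
        scaler = _scaler([1.0, 2.0], [2])
        x = np.array([0.3, 0.7])
        assert normalized_distance(x, x, scaler) == 0.0

    def test_single_component_closed_form(self):
        scaler = _scaler([2.0], [1])
        assert normalized_distance([0.0], [4.0], scaler) == pytest.approx(2.0)

    def test_group_weighted_sum(self):
        # groups of size 1 and 4, standardized difference 1 everywhere:
        # sqrt(1 + 4 * (1/4)) = sqrt(2)
        scaler = _scaler([1.0] * 5, [1, 4])
        x = np.zeros(5)
        y = np.ones(5)
        assert normalized_distance(x, y, scaler) == pytest.approx(np.sqrt(2))

    def test_zero_sigma_components_excluded(self):
        scaler = _scaler([0.0, 1.0], [2])
        assert normalized_distance([0, 0], [5, 0], scaler) == 0.0
        assert len(scaler.degenerate_components) == 1

    def test_dimension_mismatch_raises(self):
        scaler = _scaler([1.0, 1.0], [2])
        with pytest.raises(ValueError):
            normalized_distance([0.0], [1.0], scaler)

    def test_duplicating_a_groups_columns_leaves_distance_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 3))
        x, y = rng.random(3), rng.random(3)
        scaler = FeatureScaler.fit(X, [1, 2])
        base = normalized_distance(x, y, scaler)
        # duplicate the 2-column group -> group size 4, same distance
        X_dup = np.hstack([X[:, :1], X[:, 1:], X[:, 1:]])
        x_dup = np.concatenate([x[:1], x[1:], x[1:]])
        y_dup = np.concatenate([y[:1], y[1:], y[1:]])
        scaler_dup = FeatureScaler.fit(X_dup, [1, 4])
        assert normalized_distance(x_dup, y_dup, scaler_dup) == pytest.approx(base)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_pseudometric_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((20, 5))
        scaler = FeatureScaler.fit(X, [2, 3])
        x, y, z = rng.random(5), rng.random(5), rng.random(5)
        dxy = normalized_distance(x, y, scaler)
        assert dxy == pytest.approx(normalized_distance(y, x, scaler))
        assert dxy <= (
            normalized_distance(x, z, scaler)
            + normalized_distance(z, y, scaler)
            + 1e-9
        )


class TestKnn:
    def test_all_positive_neighbors(self):
        train = np.arange(5.0).reshape(-1, 1)
        scaler = FeatureScaler.fit(train, [1])
        p = knn_predict_proba([0.0], train, np.ones(5), k=3, scaler=scaler)
        assert p == 1.0

    def test_frequency_of_positives(self):
        train = np.arange(10.0).reshape(-1, 1)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        scaler = FeatureScaler.fit(train, [1])
        p = knn_predict_proba([0.0], train, labels, k=10, scaler=scaler)
        assert p == pytest.approx(0.3)

    def test_probability_levels_limited_to_k_plus_one(self):
        rng = np.random.default_rng(4)
        train = rng.random((40, 2))
        labels = rng.integers(0, 2, size=40)
        scaler = FeatureScaler.fit(train, [2])
        k = 5
        for _ in range(20):
            p = knn_predict_proba(rng.random(2), train, labels, k, scaler=scaler)
            assert round(p * k) == pytest.approx(p * k)

    def test_tie_at_rank_k_resolved_by_training_order(self):
        # four training points, two equidistant at the deciding rank: the
        # earlier one must win, so the label at index 1 decides
        train = np.array([[0.0], [1.0], [-1.0], [5.0]])
        labels = np.array([1, 1, 0, 0])
        scaler = _scaler([1.0], [1])
        p = knn_predict_proba([0.0], train, labels, k=2, scaler=scaler)
        assert p == 1.0  # neighbors: index 0 (d=0) then index 1 (tie with 2)

    def test_too_few_samples_raises(self):
        train = np.zeros((3, 1))
        scaler = _scaler([1.0], [1])
        with pytest.raises(ValueError):
            knn_predict_proba([0.0], train, np.ones(3), k=5, scaler=scaler)


@pytest.fixture
def separable_toy():
    rng = np.random.default_rng(7)
    X0 = rng.normal(0.0, 0.3, size=(10, 4))
    X1 = rng.normal(3.0, 0.3, size=(10, 4))
    X = np.vstack([X0, X1])
    y = np.array([0] * 10 + [1] * 10)
    return X, y


FEATURES = FeatureFunctionSet.from_spec("RelPos,PosDiff,IdxDiff")


class TestTraining:
    def test_et_separates_linearly_separable_toy(self, separable_toy):
        X, y = separable_toy
        model = train_pair_classifier(
            X, y, FEATURES, ClassifierConfig.et(n_trees=100), seed=0,
            group_sizes=[4],
        )
        p = model.predict_proba(X)
        assert np.all(p[y == 1] >= 0.5)
        assert np.all(p[y == 0] < 0.5)

    def test_constant_label_training_yields_constant_predictor(self, separable_toy):
        X, _ = separable_toy
        with pytest.warns(DegenerateModelWarning):
            model = train_pair_classifier(
                X, np.ones(20, dtype=int), FEATURES,
                ClassifierConfig.et(n_trees=10), seed=0, group_sizes=[4],
            )
        assert np.all(model.predict_proba(X) == 1.0)

    def test_ensemble_size_stabilizes_probabilities(self, separable_toy):
        X, y = separable_toy
        query = np.full((1, 4), 1.5)  # between the two clusters

        def spread(n_trees):
            values = []
            for seed in range(20):
                model = train_pair_classifier(
                    X, y, FEATURES, ClassifierConfig.et(n_trees=n_trees),
                    seed=seed, group_sizes=[4],
                )
                values.append(model.predict_proba(query)[0])
            return np.var(values)

        assert spread(100) <= spread(1)

    def test_fixed_seed_reproducible(self, separable_toy):
        X, y = separable_toy
        runs = [
            train_pair_classifier(
                X, y, FEATURES, ClassifierConfig.et(n_trees=50), seed=3,
                group_sizes=[4],
            ).predict_proba(X)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_et_output_within_leaf_proportion_range(self, separable_toy):
        X, y = separable_toy
        model = train_pair_classifier(
            X, y, FEATURES, ClassifierConfig.et(n_trees=30), seed=0,
            group_sizes=[4],
        )
        p = model.predict_proba(X)
        assert np.all(p >= 0.0) and np.all(p <= 1.0)

    def test_svm_and_knn_paths(self, separable_toy):
        X, y = separable_toy
        for config in (ClassifierConfig.svm(), ClassifierConfig.knn(k=3)):
            model = train_pair_classifier(
                X, y, FEATURES, config, seed=0, group_sizes=[4]
            )
            p = model.predict_proba(X)
            assert np.mean((p >= 0.5) == y.astype(bool)) >= 0.9

    def test_wrong_dimensionality_rejected(self, separable_toy):
        X, y = separable_toy
        model = train_pair_classifier(
            X, y, FEATURES, ClassifierConfig.et(n_trees=10), seed=0,
            group_sizes=[4],
        )
        with pytest.raises(ValueError, match="features"):
            model.predict_proba(np.zeros((1, 7)))


class TestPairMatrix:
    def test_pair_counts_and_symmetry(self, small_dataset):
        feature_set = FeatureFunctionSet.from_spec("CSP:3,PosDiff")
        X, y = pair_training_data(
            small_dataset.proteins[:20], small_dataset.patterns, feature_set
        )
        assert X.shape[0] == 20 * 6  # C(4,2) pairs per protein
        model = train_pair_classifier(
            X, y, feature_set, ClassifierConfig.et(n_trees=20), seed=0
        )
        protein = small_dataset.proteins[25]
        matrix = predict_pair_matrix(model, protein)
        assert matrix.n == 4
        np.testing.assert_array_equal(matrix.probs, matrix.probs.T)
        upper = matrix.probs[np.triu_indices(4, k=1)]
        assert upper.shape == (6,)

    def test_protein_without_pairs_gives_empty_matrix(self):
        from ssbond.core import Protein

        feature_set = FeatureFunctionSet.from_spec("CSP:3")
        rng = np.random.default_rng(0)
        X = rng.random((12, 6))
        y = rng.integers(0, 2, 12)
        model = train_pair_classifier(
            X, y, feature_set, ClassifierConfig.et(n_trees=5), seed=0
        )
        assert predict_pair_matrix(model, Protein(id="x", sequence="ACA")).n == 1
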