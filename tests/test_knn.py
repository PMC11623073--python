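"""From-scratch K-NN: distances, neighbour search, voting, prediction.

The independent oracle is a plain-loop brute-force search: all pairwise
distances computed elementwise, sorted by (distance, index), with a counting
vote — no shared code with the implementation under test.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locustlens import knn
from locustlens.containers import GLAD_COLUMNS, GladDataset
from locustlens.errors import ContractError
from locustlens.knn import (
    FittedKnn,
    KnnConfig,
    encode_features,
    manhattan_distance,
    nearest_neighbours,
    predict,
    vote,
)


# ---------------------------------------------------------------- oracle
def oracle_distance(x, z, metric, p=None):
    total, order = 0.0, {"manhattan": 1.0, "euclidean": 2.0}.get(metric, p)
    for xi, zi in zip(x, z):
        total += abs(xi - zi) ** order
    return total ** (1.0 / order)


def oracle_neighbours(X, x, k, metric):
    dists = [(oracle_distance(x, z, metric), i) for i, z in enumerate(X)]
    dists.sort()
    return [(i, d) for d, i in dists[:k]]


def oracle_predict(X, y, x, k, metric, weights):
    nn = oracle_neighbours(X, x, k, metric)
    if weights == "uniform":
        w = [1.0] * len(nn)
    else:
        zeros = [d == 0.0 for _, d in nn]
        w = (
            [1.0 if z else 0.0 for z in zeros]
            if any(zeros)
            else [1.0 / d for _, d in nn]
        )
    score = {}
    for (i, _), wi in zip(nn, w):
        score[y[i]] = score.get(y[i], 0.0) + wi
    best = max(score.values())
    winners = [c for c, s in score.items() if s == best]
    return y[nn[0][0]] if len(winners) > 1 else winners[0]


# ---------------------------------------------------------------- encoding
def glad_frame(labels, months=None):
    n = len(labels)
    months = months or [1 + i % 12 for i in range(n)]
    return pd.DataFrame(
        {
            "start_month": months,
            "start_year": [2000 + i for i in range(n)],
            "country": ["C01"] * n,
            "region": ["C01-R01"] * n,
            "soil_moisture": np.linspace(0, 10, n),
            "precipitation": np.linspace(5, 50, n),
            "max_temperature": np.linspace(20, 40, n),
            "locust_present": labels,
        }
    )[GLAD_COLUMNS]


class TestEncodeFeatures:
    def test_feature_vector_order(self):
        X, y, names = encode_features(glad_frame(["yes"]))
        assert names == ["start_year", "start_month", "precipitation",
                         "max_temperature", "soil_moisture"]
        row = glad_frame(["yes"]).iloc[0]
        assert X[0].tolist() == [
            row.start_year, row.start_month, row.precipitation,
            row.max_temperature, row.soil_moisture,
        ]

    def test_label_mapping(self):
        _, y, _ = encode_features(glad_frame(["yes", "no", "yes"]))
        assert y.tolist() == [1, 0, 1]

    def test_month_thirteen_rejected(self):
        with pytest.raises(ContractError):
            encode_features(glad_frame(["yes"], months=[13]))

    def test_one_hot_region_appends_columns(self):
        df = glad_frame(["yes", "no"])
        df.loc[1, "region"] = "C01-R02"
        X, _, names = encode_features(df, one_hot_region=True)
        assert X.shape[1] == 7
        assert names[5].startswith("region_")


class TestManhattanDistance:
    def test_identity(self):
        assert manhattan_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_example(self):
        assert manhattan_distance([1, 2], [4, 6]) == 7.0

    def test_weighted_hand_example(self):
        assert manhattan_distance([1, 2], [4, 6], w=[2, 1]) == 10.0

    def test_dimension_mismatch(self):
        with pytest.raises(ContractError):
            manhattan_distance([1, 2], [1, 2, 3])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)
            ),
            min_size=3, max_size=3,
        )
    )
    def test_metric_axioms_on_sampled_triples(self, pts):
        x, y, z = (np.array(p) for p in pts)
        dxy = manhattan_distance(x, y)
        assert dxy >= 0
        assert dxy == manhattan_distance(y, x)
        assert manhattan_distance(x, z) <= dxy + manhattan_distance(y, z) + 1e-9


class TestFitPredict:
    def test_k1_recovers_training_label(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.integers(0, 2, 10)
        model = knn.fit(X, y, KnnConfig(k=1))
        for xi, yi in zip(X, y):
            assert predict(model, xi)[0] == yi

    def test_constant_feature_unit_spread(self, rng):
        X = np.hstack([np.full((8, 1), 3.0), rng.normal(size=(8, 2))])
        model = knn.fit(X, rng.integers(0, 2, 8), KnnConfig(k=3))
        assert model.spread[0] == 1.0

    def test_refit_is_identical(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.integers(0, 2, 15)
        m1 = knn.fit(X, y)
        m2 = knn.fit(X, y)
        assert np.array_equal(m1.X, m2.X)
        assert np.array_equal(m1.center, m2.center)

    def test_separable_blobs_training_accuracy(self, rng):
        # two blobs 20 sigma apart: every training point classified correctly
        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(20, 1, (30, 5))])
        y = np.array([0] * 30 + [1] * 30)
        model = knn.fit(X, y, KnnConfig(k=7))
        preds = [predict(model, xi)[0] for xi in X]
        assert preds == y.tolist()

    def test_affine_rescaling_invariance(self, rng):
        # z-scoring absorbs any common affine map of the raw features
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, 40)
        queries = rng.normal(size=(10, 5))
        base = [predict(knn.fit(X, y), q)[0] for q in queries]
        for _ in range(20):
            a = rng.uniform(0.1, 10.0, 5)
            b = rng.uniform(-5.0, 5.0, 5)
            model = knn.fit(X * a + b, y)
            assert [predict(model, q * a + b)[0] for q in queries] == base

    def test_single_class_training(self, rng):
        X = rng.normal(size=(5, 3))
        model = knn.fit(X, np.ones(5, dtype=int), KnnConfig(k=3))
        label, score = predict(model, rng.normal(size=3))
        assert (label, score) == (1, 1.0)

    def test_empty_training_rejected(self):
        with pytest.raises(ContractError):
            knn.fit(np.empty((0, 3)), np.empty(0))


class TestNearestNeighbours:
    def test_nearest_on_a_line(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = FittedKnn(X=X, y=np.zeros(4, dtype=int),
                          center=np.zeros(1), spread=np.ones(1),
                          config=KnnConfig(k=2))
        nn = nearest_neighbours(model, np.array([1.6]), 2)
        assert [i for i, _ in nn] == [2, 1]

    def test_exact_tie_goes_to_earlier_index(self):
        X = np.array([[1.0], [2.0]])
        model = FittedKnn(X=X, y=np.zeros(2, dtype=int),
                          center=np.zeros(1), spread=np.ones(1),
                          config=KnnConfig(k=1))
        assert nearest_neighbours(model, np.array([1.5]), 1)[0][0] == 0

    def test_k_exceeding_n_rejected(self, rng):
        model = knn.fit(rng.normal(size=(3, 2)), np.zeros(3, dtype=int))
        with pytest.raises(ContractError):
            nearest_neighbours(model, np.zeros(2), 4)

    def test_agreement_with_exhaustive_sort(self, rng):
        X = rng.normal(size=(50, 5))
        model = FittedKnn(X=X, y=np.zeros(50, dtype=int),
                          center=np.zeros(5), spread=np.ones(5),
                          config=KnnConfig(k=5))
        for _ in range(200):
            q = rng.normal(size=5)
            got = nearest_neighbours(model, q, 5)
            want = oracle_neighbours(X, q, 5, "manhattan")
            assert [i for i, _ in got] == [i for i, _ in want]
            assert np.allclose([d for _, d in got], [d for _, d in want])


class TestVote:
    def test_uniform_majority(self):
        assert vote([1, 1, 0], [0.1, 0.2, 0.3], "uniform") == (1, 2 / 3)

    def test_zero_distance_dominates(self):
        label, _ = vote([1, 0, 0, 0], [0.0, 5.0, 5.0, 5.0], "distance")
        assert label == 1

    def test_class_tie_breaks_to_nearest(self):
        label, _ = vote([0, 1], [0.1, 0.2], "uniform")
        assert label == 0

    def test_uniform_vote_is_mode_when_unique(self, rng):
        for _ in range(50):
            labels = rng.integers(0, 2, 7)
            counts = np.bincount(labels, minlength=2)
            if counts[0] == counts[1]:
                continue
            label, _ = vote(labels, rng.uniform(0.1, 1.0, 7), "uniform")
            assert label == int(np.argmax(counts))


class TestSerialization:
    def test_json_round_trip(self, rng):
        X = rng.normal(size=(6, 5))
        y = rng.integers(0, 2, 6)
        model = knn.fit(X, y, KnnConfig(k=3, weights="distance"))
        back = FittedKnn.from_json(model.to_json())
        assert np.allclose(back.X, model.X)
        assert back.config == model.config
        q = rng.normal(size=5)
        assert predict(back, q) == predict(model, q)


@pytest.mark.parametrize("k", [1, 3, 7])
@pytest.mark.parametrize("weights", ["uniform", "distance"])
@pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
def test_predict_matches_brute_force_oracle(k, weights, metric, rng):
    """Full-surface equivalence with the plain-loop oracle on standardized
    data (identity scaler keeps both sides in the same space)."""
    X = rng.normal(size=(60, 5))
    y = rng.integers(0, 2, 60)
    model = FittedKnn(
        X=X, y=y, center=np.zeros(5), spread=np.ones(5),
        config=KnnConfig(k=k, weights=weights, metric=metric),
    )
    for _ in range(30):
        q = rng.normal(size=5)
        assert predict(model, q)[0] == oracle_predict(
            X, y.tolist(), q, k, metric, weights
        )
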