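"""Neural interaction detection: weight formulas, ranking, training."""

from itertools import combinations

import numpy as np
import pytest

from cdr3bench._exceptions import ValidationError
from cdr3bench.nid import (
    MLPWeights,
    predict_logits,
    rank_interactions,
    train_mlp,
    unit_influence,
    unit_influences,
    unit_strength,
)


def make_weights(W1, W2=None, W3=None, wy=None):
    """Small hand-built network; defaults give a single hidden layer."""
    W1 = np.asarray(W1, dtype=float)
    Ws = [W1]
    bs = [np.zeros(W1.shape[0])]
    if W2 is not None:
        Ws.append(np.asarray(W2, dtype=float))
        bs.append(np.zeros(len(W2)))
    if W3 is not None:
        Ws.append(np.asarray(W3, dtype=float))
        bs.append(np.zeros(len(W3)))
    if wy is None:
        wy = np.ones(Ws[-1].shape[0])
    return MLPWeights(Ws, bs, np.asarray(wy, dtype=float), 0.0)


class TestUnitFormulas:
    def test_unit_strength_is_min_over_set(self):
        row = np.array([0.5, 0.2, 0.9])
        assert unit_strength(row, [0, 1]) == pytest.approx(0.2)
        assert unit_strength(row, [2]) == pytest.approx(0.9)

    def test_unit_strength_bounded_by_every_weight(self):
        row = np.array([0.7, -0.4, 0.1, 0.3])
        for I in ([0, 1], [1, 2, 3], [0, 3]):
            assert unit_strength(row, I) <= min(abs(row[j]) for j in I) + 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            unit_strength(np.ones(3), [])

    def test_single_hidden_layer_influence_is_output_weight(self):
        w = make_weights(np.ones((2, 3)), wy=[1.5, -2.0])
        assert unit_influence(w, 0) == pytest.approx(1.5)
        assert unit_influence(w, 1) == pytest.approx(2.0)

    def test_two_layer_influence_hand_product(self):
        # z = |w_y|^T |W2[:, i]| with w_y = (1, -2), column (0.5, 1) -> 2.5
        W2 = np.array([[0.5, 0.0], [1.0, 0.0]])
        w = make_weights(np.ones((2, 3)), W2=W2, wy=[1.0, -2.0])
        assert unit_influence(w, 0) == pytest.approx(1 * 0.5 + 2 * 1.0)

    def test_influence_linear_in_layer_scale(self):
        rng = np.random.default_rng(0)
        W2 = rng.normal(size=(4, 3))
        w1 = make_weights(rng.normal(size=(3, 5)), W2=W2, wy=rng.normal(size=4))
        w2 = make_weights(w1.W[0], W2=3.0 * W2, wy=w1.w_y)
        assert np.allclose(unit_influences(w2), 3.0 * unit_influences(w1))


class TestRanking:
    def test_isolated_pair_is_sole_strong_candidate(self):
        # only features 3 and 4 feed unit 0; everything else is zero
        W1 = np.zeros((2, 6))
        W1[0, 3], W1[0, 4] = 0.8, 0.6
        w = make_weights(W1, wy=[2.0, 0.0])
        pairwise, any_order = rank_interactions(w, K=3)
        assert pairwise.entries[0][0] == frozenset({3, 4})
        assert pairwise.entries[0][1] == pytest.approx(0.6 * 2.0)
        assert any_order.entries[0][0] == frozenset({3, 4})

    def test_any_order_candidate_matches_exhaustive_enumeration(self):
        # single unit: the order-k candidate must equal the argmax of
        # min(|W1[I]|) * z over all order-k subsets
        rng = np.random.default_rng(3)
        W1 = rng.normal(size=(1, 6))
        w = make_weights(W1, wy=[1.3])
        _, any_order = rank_interactions(w, K=50, max_order=None)
        by_order = {}
        for s, score in any_order.entries:
            by_order.setdefault(len(s), (s, score))
        absw = np.abs(W1[0])
        for k in range(2, 7):
            best = max(
                combinations(range(6), k), key=lambda I: (min(absw[list(I)]), tuple(I))
            )
            s, score = by_order[k]
            assert s == frozenset(best)
            assert score == pytest.approx(min(absw[list(best)]) * 1.3)

    def test_all_equal_weights_tie_breaks_lexicographically(self):
        w = make_weights(np.full((3, 5), 0.4), wy=[1.0, 1.0, 1.0])
        _, any_order = rank_interactions(w, K=1, max_order=2)
        assert any_order.entries[0][0] == frozenset({0, 1})

    def test_pairwise_monotone_in_first_layer_weight(self):
        W1 = np.zeros((1, 4))
        W1[0, 0], W1[0, 1] = 0.5, 0.4
        base = make_weights(W1, wy=[1.0])
        bumped = make_weights(W1 * np.array([1.0, 2.0, 1.0, 1.0]), wy=[1.0])
        score = lambda w: dict(rank_interactions(w, K=10)[0].entries)[frozenset({0, 1})]
        assert score(bumped) >= score(base)

    def test_invalid_k(self):
        w = make_weights(np.ones((1, 3)))
        with pytest.raises(ValidationError):
            rank_interactions(w, K=0)


class TestTraining:
    def test_identical_seed_identical_weights(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(120, 8)).astype(float)
        y = (X[:, 0] * X[:, 1]).astype(float)
        a = train_mlp(X, y, architecture=(16, 8), seed=9, max_epochs=30)
        b = train_mlp(X, y, architecture=(16, 8), seed=9, max_epochs=30)
        assert all(np.array_equal(u, v) for u, v in zip(a.W, b.W))

    def test_fits_separable_single_feature(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(600, 5)).astype(float)
        y = X[:, 2]
        w = train_mlp(X, y, architecture=(16, 8), seed=4)
        idx_te = w.meta["split"][2]
        assert roc_auc_score(y[idx_te], predict_logits(w, X[idx_te])) > 0.95

    def test_huge_l1_shrinks_first_layer(self):
        # penalty-dominated limit: the optimisation endpoint has all
        # first-layer weights at the subgradient-oscillation floor (~lr)
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(120, 6)).astype(float)
        y = rng.integers(0, 2, size=120).astype(float)
        w = train_mlp(
            X, y, architecture=(8,), l1_const=10.0, seed=5, max_epochs=600,
            patience=600, restore_best=False,
        )
        assert np.abs(w.W[0]).max() < 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            train_mlp(np.zeros((10, 3)), np.zeros(10))
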