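"""Logic regression: tree evaluation, moves, annealing, MCLR scores."""

import itertools
import math

import numpy as np
import pytest

from cdr3bench.logicreg import (
    DEFAULT_MOVE_PROBS,
    LogicModel,
    MCLRConfig,
    _fit_glm,
    acceptance_probability,
    anneal,
    evaluate_tree,
    extract_interactions,
    leaves,
    mclr_aggregate,
    null_deviance,
    propose_tree_move,
    tree_expression,
)

AND, OR = "and", "or"
leaf = lambda i, neg=False: ("leaf", i, neg)


class TestEvaluation:
    def test_worked_example(self):
        tree = (AND, leaf(0), (OR, leaf(1), leaf(2)))
        X = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.uint8)
        assert evaluate_tree(tree, X).tolist() == [True, False]

    def test_negated_leaf(self):
        X = np.array([[0], [1]], dtype=np.uint8)
        assert evaluate_tree(leaf(0, True), X).tolist() == [True, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_truth_table_enumeration(self, seed):
        # random trees on p = 4 covariates vs direct Boolean evaluation
        rng = np.random.default_rng(seed)

        def random_tree(depth):
            if depth == 0 or rng.random() < 0.3:
                return leaf(int(rng.integers(4)), bool(rng.random() < 0.5))
            return (AND if rng.random() < 0.5 else OR, random_tree(depth - 1), random_tree(depth - 1))

        def python_eval(tree, row):
            if tree[0] == "leaf":
                v = bool(row[tree[1]])
                return (not v) if tree[2] else v
            l, r = python_eval(tree[1], row), python_eval(tree[2], row)
            return (l and r) if tree[0] == AND else (l or r)

        tree = random_tree(3)
        X = np.array(list(itertools.product([0, 1], repeat=4)), dtype=np.uint8)
        expected = [python_eval(tree, row) for row in X]
        assert evaluate_tree(tree, X).tolist() == expected

    def test_expression_rendering(self):
        tree = (AND, leaf(0), (OR, leaf(1), leaf(2, True)))
        assert tree_expression(tree, ["5T", "6T", "7A"]) == "(5T & (6T | !7A))"


class TestExtractInteractions:
    def test_published_convention_example(self):
        tree = (AND, leaf(0), (OR, leaf(1), leaf(2)))
        assert extract_interactions([tree]) == {frozenset({0, 1}), frozenset({0, 2})}

    def test_single_leaf_has_no_interactions(self):
        assert extract_interactions([leaf(3)]) == set()

    def test_pure_conjunction_reports_all_subsets(self):
        tree = (AND, (AND, leaf(0), leaf(1)), leaf(2))
        assert extract_interactions([tree]) == {
            frozenset(s)
            for s in [{0, 1}, {0, 2}, {1, 2}, {0, 1, 2}]
        }

    def test_contradictory_conjunct_dropped(self):
        tree = (AND, leaf(0), leaf(0, True))  # X and not-X is identically false
        assert extract_interactions([tree]) == set()

    def test_negated_leaves_map_to_their_covariate(self):
        tree = (AND, leaf(0, True), leaf(1))
        assert extract_interactions([tree]) == {frozenset({0, 1})}


class TestMoves:
    def test_permute_operator(self):
        rng = np.random.default_rng(0)
        trees = [(AND, leaf(0), leaf(1))]
        probs = {"permute": 1.0}
        _, new, move = propose_tree_move(trees, 4, 8, probs, rng)
        assert move == "permute" and new[0] == OR

    def test_illegal_prune_on_single_leaf_redrawn(self):
        rng = np.random.default_rng(1)
        trees = [leaf(0)]
        probs = {"prune": 0.95, "alternate": 0.05}
        for _ in range(20):
            _, _, move = propose_tree_move(trees, 4, 8, probs, rng)
            assert move == "alternate"  # prune is never legal here

    def test_alternate_changes_exactly_one_leaf(self):
        rng = np.random.default_rng(2)
        trees = [(AND, leaf(0), (OR, leaf(1), leaf(2)))]
        probs = {"alternate": 1.0}
        for _ in range(200):
            _, new, _ = propose_tree_move(trees, 6, 8, probs, rng)
            diff = set(leaves(new)) ^ set(leaves(trees[0]))
            assert len(diff) in (1, 2)  # one leaf replaced (or negation toggled)

    def test_max_leaves_respected(self):
        rng = np.random.default_rng(3)
        trees = [(AND, leaf(0), leaf(1))]
        probs = dict(DEFAULT_MOVE_PROBS)
        for _ in range(300):
            t_idx, new, _ = propose_tree_move(trees, 6, 3, probs, rng)
            assert len(leaves(new)) <= 3
            trees = [new]


class TestAnnealing:
    def test_acceptance_arithmetic(self):
        assert acceptance_probability(10.0, 8.0, 5.0) == 1.0  # improvement
        assert acceptance_probability(8.0, 10.0, 1.0) == pytest.approx(math.exp(-2))
        assert acceptance_probability(8.0, 8.0, 1.0) == 1.0

    def test_glm_deviance_never_worse_than_null(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(300, 3)).astype(np.uint8)
        y = (X[:, 0] | X[:, 1]).astype(float)
        _, dev = _fit_glm(X[:, :2], y)
        assert dev <= null_deviance(y) + 1e-6

    def test_anneal_recovers_planted_conjunction(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(500, 10)).astype(np.uint8)
        y = (X[:, 3] & X[:, 7]).astype(np.int8)
        best = anneal(X, y, n_trees=2, iterations=3000, seed=6)
        assert frozenset({3, 7}) in extract_interactions(best.trees)
        assert best.deviance < 0.2 * null_deviance(y.astype(float))

    def test_best_model_no_worse_than_visited(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, size=(200, 6)).astype(np.uint8)
        y = rng.integers(0, 2, size=200).astype(np.int8)
        visited = []
        best = anneal(
            X, y, n_trees=2, iterations=500, seed=7, _recorder=lambda it, t, s: visited.append(s)
        )
        assert best.deviance <= min(visited) + 1e-9

    def test_determinism(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, size=(200, 6)).astype(np.uint8)
        y = (X[:, 0] & X[:, 1]).astype(np.int8)
        a = anneal(X, y, iterations=400, seed=8)
        b = anneal(X, y, iterations=400, seed=8)
        assert a.trees == b.trees and a.deviance == pytest.approx(b.deviance)


class TestMCLR:
    def test_score_is_fraction_of_recorded_models(self):
        # noisy planted conjunction: label noise keeps additive leaf models
        # strictly worse than the true conjunction, which then dominates
        # the recorded models
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(600, 8)).astype(np.uint8)
        flip = rng.random(600) < 0.05
        y = ((X[:, 2] & X[:, 5]).astype(bool) ^ flip).astype(np.int8)
        cfg = MCLRConfig(anneal_iterations=4000, chain_iterations=2000, record_every=100)
        ranking, best = mclr_aggregate(X, y, cfg, seed=9)
        assert len(ranking) >= 1
        top_set, top_score = ranking.entries[0]
        assert 0 < top_score <= 1.0
        assert top_set == frozenset({2, 5})

    def test_null_data_has_no_stable_interaction(self):
        # with Y independent of X, any conjunction a single run overfits is
        # run-specific, so pooling many runs dilutes every set's frequency
        rng = np.random.default_rng(9)
        X = rng.integers(0, 2, size=(300, 10)).astype(np.uint8)
        y = rng.integers(0, 2, size=300).astype(np.int8)  # independent of X
        cfg = MCLRConfig(
            n_runs=10, anneal_iterations=1500, chain_iterations=1000, record_every=100
        )
        ranking, _ = mclr_aggregate(X, y, cfg, seed=10)
        if len(ranking):
            assert ranking.entries[0][1] < 0.5
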