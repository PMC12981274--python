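"""Iterative random forests (iRF) with random-intersection-tree candidates.

The detector proceeds in three stages:

1. *Iterative reweighting*: K feature-weighted random forests are grown; at
   each split, candidate features are sampled with probability proportional
   to the current weights, which start uniform and are replaced by the mean
   decrease in Gini impurity of the previous forest.
2. *Candidate extraction*: on each of B bootstrap samples a forest with the
   final weights is fitted, and a generalised random intersection tree (RIT)
   intersects feature sets read off root-to-leaf paths of class-1 leaves
   (paths sampled with probability proportional to leaf size); surviving
   sets of size >= 2 are that bootstrap's candidates S(b).
3. *Stability scores*: stability(S) = (1/B) sum_b 1{S in S(b)}.

Trees split binary covariates only (split = indicator value), which keeps
the growing kernel simple enough to jit with numba.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from ._exceptions import ConfigurationError, ValidationError
from .ranking import InteractionRanking, build_ranking
from .seqsim import EncodedMatrix

logger = logging.getLogger(__name__)


@dataclass
class RITConfig:
    depth: int = 5
    branching: int = 2
    n_paths: int = 100  # path draws consumed per bootstrap forest


@dataclass
class IRFConfig:
    n_iterations: int = 5  # K: reweighting rounds; interactions read at the last
    n_trees: int = 500
    n_bootstrap: int = 30  # B
    min_leaf: int = 5
    mtry: int | None = None  # default round(sqrt(p))
    selection: str = "first"  # "first": the weighted draw picks the split
    # feature directly (first legal candidate in draw order); "best": best
    # Gini gain among the mtry candidates
    rit: RITConfig = None  # type: ignore[assignment]
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.rit is None:
            self.rit = RITConfig()


# ---------------------------------------------------------------------------
# numba tree kernel


@njit(cache=True)
def _grow_tree(X, y, idx, cumw, active, mtry, min_leaf, seed, importance, first_valid):
    """Grow one CART tree on binary features with weighted feature sampling.

    ``idx`` is the (bootstrap) row index array, partitioned in place.
    ``cumw`` is the cumulative feature-weight vector over ``active`` features.
    Returns parallel node arrays: feature (-1 for leaves), parent, and for
    leaves the sample count and positive count.  ``importance`` accumulates
    the weighted mean decrease in Gini impurity per feature.
    """
    np.random.seed(seed)
    n_total = len(idx)
    max_nodes = 4 * n_total + 1
    feat = np.full(max_nodes, -1, dtype=np.int64)
    parent = np.full(max_nodes, -1, dtype=np.int64)
    leaf_n = np.zeros(max_nodes, dtype=np.int64)
    leaf_pos = np.zeros(max_nodes, dtype=np.int64)

    stack_start = np.empty(max_nodes, dtype=np.int64)
    stack_end = np.empty(max_nodes, dtype=np.int64)
    stack_node = np.empty(max_nodes, dtype=np.int64)
    cand = np.empty(mtry, dtype=np.int64)
    taken = {np.int64(-1)}  # typed-set seed value, cleared per node

    n_nodes = 1
    top = 0
    stack_start[0] = 0
    stack_end[0] = n_total
    stack_node[0] = 0
    while top >= 0:
        start = stack_start[top]
        end = stack_end[top]
        node = stack_node[top]
        top -= 1
        m = end - start
        pos = 0
        for i in range(start, end):
            pos += y[idx[i]]
        if pos == 0 or pos == m or m < 2 * min_leaf:
            leaf_n[node] = m
            leaf_pos[node] = pos
            continue
        # sample mtry distinct split-candidate features with probability
        # proportional to weight (mtry = 1: the split feature itself is the
        # weighted draw, so no gain competition between candidates)
        taken.clear()
        n_cand = 0
        tries = 0
        n_active = len(active)
        k_want = mtry if mtry < n_active else n_active
        while n_cand < k_want and tries < 40 * k_want:
            tries += 1
            u = np.random.random() * cumw[-1]
            j = np.searchsorted(cumw, u)
            if j >= n_active:
                j = n_active - 1
            f = active[j]
            if f not in taken:
                taken.add(np.int64(f))
                cand[n_cand] = f
                n_cand += 1
        # split feature: either the best Gini gain among the candidates, or
        # the first candidate (in weighted draw order) with a legal,
        # impurity-reducing split — the latter makes the weighted draw
        # itself pick the split feature
        inv_m = 1.0 / m
        g_parent = 1.0 - (pos * inv_m) ** 2 - ((m - pos) * inv_m) ** 2
        best_f = -1
        best_gain = 1e-12
        for c in range(n_cand):
            f = cand[c]
            n1 = 0
            p1 = 0
            for i in range(start, end):
                if X[idx[i], f] == 1:
                    n1 += 1
                    p1 += y[idx[i]]
            n0 = m - n1
            if n1 < min_leaf or n0 < min_leaf:
                continue
            p0 = pos - p1
            g1 = 1.0 - (p1 / n1) ** 2 - ((n1 - p1) / n1) ** 2
            g0 = 1.0 - (p0 / n0) ** 2 - ((n0 - p0) / n0) ** 2
            gain = g_parent - (n1 * g1 + n0 * g0) * inv_m
            if gain > best_gain:
                best_gain = gain
                best_f = f
                if first_valid:
                    break
        if best_f < 0:
            leaf_n[node] = m
            leaf_pos[node] = pos
            continue
        importance[best_f] += (m / n_total) * best_gain
        # partition rows: zeros first
        left = start
        right = end - 1
        while left <= right:
            if X[idx[left], best_f] == 0:
                left += 1
            else:
                tmp = idx[left]
                idx[left] = idx[right]
                idx[right] = tmp
                right -= 1
        split = left
        feat[node] = best_f
        child0 = n_nodes
        child1 = n_nodes + 1
        n_nodes += 2
        parent[child0] = node
        parent[child1] = node
        top += 1
        stack_start[top] = start
        stack_end[top] = split
        stack_node[top] = child0
        top += 1
        stack_start[top] = split
        stack_end[top] = end
        stack_node[top] = child1
    return feat[:n_nodes], parent[:n_nodes], leaf_n[:n_nodes], leaf_pos[:n_nodes]


# ---------------------------------------------------------------------------
# forest


@dataclass
class WeightedForest:
    """Fitted feature-weighted forest: per-tree node arrays + importances."""

    trees: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    importances: np.ndarray  # mean decrease in Gini impurity per feature
    weights: np.ndarray

    def class1_paths(self) -> tuple[list[frozenset[int]], np.ndarray]:
        """Feature sets of root-to-leaf paths ending in class-1 leaves.

        A leaf predicts class 1 when its positive fraction exceeds 1/2.
        Path weights are the leaf sample counts.
        """
        paths: list[frozenset[int]] = []
        weights: list[int] = []
        for feat, parent, leaf_n, leaf_pos in self.trees:
            for node in range(len(feat)):
                if feat[node] >= 0 or leaf_n[node] == 0:
                    continue
                if 2 * leaf_pos[node] <= leaf_n[node]:
                    continue
                used = set()
                q = parent[node]
                while q >= 0:
                    used.add(int(feat[q]))
                    q = parent[q]
                if used:
                    paths.append(frozenset(used))
                    weights.append(int(leaf_n[node]))
        return paths, np.asarray(weights, dtype=float)


def fit_weighted_forest(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    min_leaf: int = 5,
    mtry: int | None = None,
    bootstrap: bool = True,
    selection: str = "first",
) -> WeightedForest:
    """Grow a forest sampling split candidates with probability ∝ weights."""
    X = np.ascontiguousarray(X, dtype=np.uint8)
    y = np.ascontiguousarray(y, dtype=np.int64)
    n, p = X.shape
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (p,):
        raise ConfigurationError(f"weights must have length p={p}")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ConfigurationError("feature weights must be nonnegative and not all zero")
    active = np.flatnonzero(weights > 0).astype(np.int64)
    cumw = np.cumsum(weights[active])
    if mtry is None:
        mtry = max(1, int(round(np.sqrt(p))))
    rng = np.random.default_rng(seed)
    importances = np.zeros(p)
    trees = []
    for _ in range(n_trees):
        idx = (
            rng.integers(0, n, size=n).astype(np.int64)
            if bootstrap
            else np.arange(n, dtype=np.int64)
        )
        tree = _grow_tree(
            X, y, idx, cumw, active, mtry, min_leaf, int(rng.integers(2**31)), importances,
            1 if selection == "first" else 0,
        )
        trees.append(tree)
    return WeightedForest(trees, importances / n_trees, weights)


def iterate_weights(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 5,
    n_trees: int = 500,
    seed: int = 0,
    min_leaf: int = 5,
    mtry: int | None = None,
    selection: str = "first",
) -> np.ndarray:
    """K rounds of importance reweighting; K=1 returns uniform weights."""
    if K < 1:
        raise ValidationError("K must be >= 1")
    p = X.shape[1]
    w = np.full(p, 1.0 / p)
    rng = np.random.default_rng(seed)
    for _ in range(K - 1):
        forest = fit_weighted_forest(
            X, y, w, n_trees=n_trees, seed=int(rng.integers(2**31)), min_leaf=min_leaf,
            mtry=mtry, selection=selection,
        )
        imp = forest.importances
        if imp.sum() <= 0:  # degenerate response: nothing to learn from
            return w
        w = imp / imp.sum()
    return w


# ---------------------------------------------------------------------------
# random intersection trees


def rit_candidates(
    forest: WeightedForest,
    config: RITConfig | None = None,
    seed: int = 0,
) -> set[frozenset[int]]:
    """Candidate interactions: intersections of sampled class-1 path sets.

    Random intersection trees of the configured depth and branching factor
    are built until ``n_paths`` path draws are consumed; each node
    intersects its parent's set with a freshly drawn path set, and leaf
    sets of size >= 2 survive.
    """
    config = config or RITConfig()
    paths, weights = forest.class1_paths()
    if not paths:
        logger.info("no class-1 leaves in forest; RIT returns no candidates")
        return set()
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    nodes_per_tree = sum(config.branching**d for d in range(config.depth + 1))
    survivors: set[frozenset[int]] = set()
    consumed = 0
    while consumed < config.n_paths:
        draws = rng.choice(len(paths), size=nodes_per_tree, p=probs)
        consumed += nodes_per_tree
        di = iter(draws)
        level = [paths[next(di)]]
        for _ in range(config.depth):
            nxt = []
            for s in level:
                for _ in range(config.branching):
                    child = s & paths[next(di)]
                    if child:
                        nxt.append(child)
            level = nxt
            if not level:
                break
        for s in level:
            if len(s) >= 2:
                survivors.add(s)
    return survivors


def stability_scores(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 30,
    config: IRFConfig | None = None,
    seed: int = 0,
) -> tuple[InteractionRanking, np.ndarray]:
    """Full iRF run: iterate weights, bootstrap forests, RIT, stabilities."""
    config = config or IRFConfig()
    if B < 1:
        raise ValidationError("B must be >= 1")
    X = np.ascontiguousarray(X, dtype=np.uint8)
    y = np.asarray(y).astype(np.int64)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * B + 1) % (2**31)
    w = iterate_weights(
        X,
        y,
        K=config.n_iterations,
        n_trees=config.n_trees,
        seed=int(seeds[0]),
        min_leaf=config.min_leaf,
        mtry=config.mtry,
        selection=config.selection,
    )
    counts: dict[frozenset[int], int] = {}
    n = len(y)
    rng = np.random.default_rng(int(seeds[0]) + 1)
    for b in range(B):
        rows = np.random.default_rng(int(seeds[1 + b])).integers(0, n, size=n)
        forest = fit_weighted_forest(
            X[rows],
            y[rows],
            w,
            n_trees=config.n_trees,
            seed=int(seeds[1 + B + b]),
            min_leaf=config.min_leaf,
            mtry=config.mtry,
            selection=config.selection,
        )
        for s in rit_candidates(forest, config.rit, seed=int(seeds[1 + B + b]) + 1):
            counts[s] = counts.get(s, 0) + 1
    scores = {tuple(sorted(s)): c / B for s, c in counts.items()}
    ranking = build_ranking(scores, flavor="any", detector="irf", k=config.top_k)
    return ranking, w


def irf_detect(
    enc: EncodedMatrix, y: np.ndarray, config: IRFConfig | None = None, seed: int = 0
) -> InteractionRanking:
    """Detector API: iRF stability ranking with covariate identities."""
    config = config or IRFConfig()
    ranking, w = stability_scores(enc.X, y, B=config.n_bootstrap, config=config, seed=seed)
    mapped = [
        (frozenset(enc.columns[i] for i in s), score) for s, score in ranking.entries
    ]
    out = InteractionRanking(mapped, flavor="any", detector="irf")
    out.meta["final_weights_top"] = {
        enc.labels()[i]: float(w[i]) for i in np.argsort(w)[::-1][:10]
    }
    return out
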