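"""Logic regression: Boolean-tree GLM fitted by simulated annealing, with
Monte-Carlo aggregation over the visited models (MCLR).

The model is a logistic GLM whose predictors are logic trees — Boolean
combinations (AND/OR over possibly negated leaves) of the binary covariates:

    logit P(Y=1|x) = b0 + sum_i b_i L_i(x).

A simulated-annealing search mutates one randomly chosen tree at a time
(alternate a leaf, permute an operator, grow/prune a branch, split/delete a
leaf), refits the GLM coefficients after every move, and accepts a proposal
with probability min{1, exp((eps_old - eps_new)/T)} where the score eps is
the binomial deviance and the temperature T decreases geometrically.

Interactions are the covariate sets that co-occur within a conjunction of a
tree: expanding each tree to disjunctive normal form, every subset (size >=
2) of a conjunct's covariates counts as an interaction, so X1 AND (X2 OR X3)
yields {X1,X2} and {X1,X3} but not {X2,X3}.  MCLR scores a set by the
fraction of recorded models in which it occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from numba import njit

from ._exceptions import ConfigurationError, ValidationError
from .ranking import InteractionRanking, build_ranking
from .seqsim import EncodedMatrix

# Trees are immutable nested tuples:
#   ("leaf", covariate_index, negated)
#   ("and"|"or", left, right)
Tree = tuple

DEFAULT_MOVE_PROBS = {
    "alternate": 0.40,
    "permute": 0.20,
    "grow": 0.15,
    "prune": 0.15,
    "split": 0.05,
    "delete": 0.05,
}


@dataclass
class MCLRConfig:
    n_trees: int = 5
    max_leaves: int = 8
    n_runs: int = 3  # independent annealing+sampling runs pooled together
    anneal_iterations: int = 50_000
    chain_iterations: int = 100_000
    record_every: int = 100
    temp_log10: tuple[float, float] = (5.0, 0.0)
    move_probs: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_PROBS))
    size_penalty: float = math.log(2.0)  # per leaf, during the sampling chain
    acceptance_reference: str = "current"  # textbook annealing; "best" uses the best-so-far reference
    top_k: int = 10


# ---------------------------------------------------------------------------
# tree utilities


def leaves(tree: Tree) -> list[tuple[int, bool]]:
    if tree[0] == "leaf":
        return [(tree[1], tree[2])]
    return leaves(tree[1]) + leaves(tree[2])


def n_leaves(tree: Tree) -> int:
    return len(leaves(tree))


def _paths(tree: Tree, kind: str, prefix=()) -> list[tuple]:
    """Paths (tuples of 1/2 child steps) to nodes of a kind: leaf/internal/any."""
    here = []
    if tree[0] == "leaf":
        if kind in ("leaf", "any"):
            here.append(prefix)
        return here
    if kind in ("internal", "any"):
        here.append(prefix)
    return here + _paths(tree[1], kind, prefix + (1,)) + _paths(tree[2], kind, prefix + (2,))


def _get(tree: Tree, path: tuple) -> Tree:
    for step in path:
        tree = tree[step]
    return tree


def _replace(tree: Tree, path: tuple, new: Tree) -> Tree:
    if not path:
        return new
    step, rest = path[0], path[1:]
    if step == 1:
        return (tree[0], _replace(tree[1], rest, new), tree[2])
    return (tree[0], tree[1], _replace(tree[2], rest, new))


def evaluate_tree(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Row-wise Boolean evaluation of a tree on a binary matrix."""
    if tree[0] == "leaf":
        idx = tree[1]
        if idx >= X.shape[1]:
            raise ConfigurationError(f"tree references covariate {idx} outside the matrix")
        col = X[:, idx].astype(bool)
        return ~col if tree[2] else col
    left = evaluate_tree(tree[1], X)
    right = evaluate_tree(tree[2], X)
    return left & right if tree[0] == "and" else left | right


def tree_expression(tree: Tree, labels: list[str] | None = None) -> str:
    """Parenthesised Boolean expression, e.g. ``(5T & (6T | !7A))``."""
    if tree[0] == "leaf":
        name = labels[tree[1]] if labels else f"X{tree[1]}"
        return f"!{name}" if tree[2] else name
    op = "&" if tree[0] == "and" else "|"
    return f"({tree_expression(tree[1], labels)} {op} {tree_expression(tree[2], labels)})"


def _conjuncts(tree: Tree) -> list[dict[int, bool]]:
    """DNF expansion: each conjunct maps covariate index -> negation flag."""
    if tree[0] == "leaf":
        return [{tree[1]: tree[2]}]
    left, right = _conjuncts(tree[1]), _conjuncts(tree[2])
    if tree[0] == "or":
        return left + right
    out = []
    for a in left:
        for b in right:
            merged = dict(a)
            ok = True
            for idx, neg in b.items():
                if idx in merged and merged[idx] != neg:
                    ok = False  # X and not-X: contradiction, conjunct is false
                    break
                merged[idx] = neg
            if ok:
                out.append(merged)
    return out


def extract_interactions(trees) -> set[frozenset[int]]:
    """Covariate-index sets co-occurring inside a conjunction of some tree.

    A subset of size >= 2 of the covariates of any DNF conjunct is reported;
    negated leaves contribute their underlying covariate.
    """
    if hasattr(trees, "trees"):
        trees = trees.trees
    found: set[frozenset[int]] = set()
    for tree in trees:
        for conj in _conjuncts(tree):
            idxs = sorted(conj)
            for size in range(2, len(idxs) + 1):
                for sub in combinations(idxs, size):
                    found.add(frozenset(sub))
    return found


# ---------------------------------------------------------------------------
# GLM refit on tree columns


def _fit_glm(cols: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None):
    """Logistic GLM of y on the tree indicator columns (plus intercept).

    Rows are aggregated over the <= 2^T distinct indicator patterns, so each
    IRLS step works on a tiny weighted design.  A small ridge keeps the fit
    defined under separation.  Returns (beta, deviance).
    """
    n, T = cols.shape
    pow2 = 1 << np.arange(T)
    ids = cols @ pow2 if T else np.zeros(n, dtype=int)
    counts = np.bincount(ids, minlength=1 << T).astype(float)
    pos = np.bincount(ids, weights=y, minlength=1 << T)
    mask = counts > 0
    counts, pos = counts[mask], pos[mask]
    patt = ((np.flatnonzero(mask)[:, None] >> np.arange(T)) & 1).astype(float)
    Z = np.hstack([np.ones((len(counts), 1)), patt])

    beta, dev = _irls(Z, counts, pos)
    return beta, dev


@njit(cache=True)
def _deviance_of(Z, counts, pos, b):
    eta = Z @ b
    dev = 0.0
    for i in range(len(counts)):
        e = min(max(eta[i], -25.0), 25.0)
        mu = 1.0 / (1.0 + math.exp(-e))
        mu = min(max(mu, 1e-12), 1.0 - 1e-12)
        # binomial deviance = -2 log-likelihood (saturated binary loglik is 0)
        dev += pos[i] * math.log(mu) + (counts[i] - pos[i]) * math.log1p(-mu)
    return -2.0 * dev


@njit(cache=True)
def _irls(Z, counts, pos):
    """Ridge-stabilised Newton fit of the aggregated logistic GLM.

    Cold start from zero: Newton from the origin is reliable here, while a
    warm start from another model's coefficients can overshoot badly after a
    column swap; a mild ridge keeps the optimum finite under separation, and
    step halving guards the remaining overshoots.
    """
    m, q = Z.shape
    beta = np.zeros(q)
    dev = _deviance_of(Z, counts, pos, beta)
    for _ in range(25):
        eta = np.clip(Z @ beta, -25.0, 25.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = counts * mu * (1.0 - mu) + 1e-8
        z = eta + (pos - counts * mu) / w
        Zw = Z * w.reshape(-1, 1)
        A = Zw.T @ Z
        for j in range(q):
            A[j, j] += 1e-4
        step = np.linalg.solve(A, Zw.T @ z) - beta
        new_dev = _deviance_of(Z, counts, pos, beta + step)
        for _ in range(5):  # step halving if Newton overshoots
            if new_dev <= dev + 1e-9:
                break
            step *= 0.5
            new_dev = _deviance_of(Z, counts, pos, beta + step)
        if new_dev > dev:
            break
        beta = beta + step
        if dev - new_dev < 1e-6:
            dev = new_dev
            break
        dev = new_dev
    return beta, dev


def null_deviance(y: np.ndarray) -> float:
    beta, dev = _fit_glm(np.zeros((len(y), 0), dtype=np.uint8), np.asarray(y, dtype=float))
    return dev


# ---------------------------------------------------------------------------
# moves


def _random_leaf(p: int, rng: np.random.Generator) -> Tree:
    return ("leaf", int(rng.integers(p)), False)


def _apply_move(
    tree: Tree, move: str, p: int, max_leaves: int, rng: np.random.Generator
) -> Tree | None:
    """One structural move; None when the move is illegal on this tree."""
    if move == "alternate":
        path = _paths(tree, "leaf")[rng.integers(len(_paths(tree, "leaf")))]
        idx, negated = _get(tree, path)[1:]
        if rng.random() < 0.5:
            return _replace(tree, path, ("leaf", idx, not negated))
        new_idx = int(rng.integers(p - 1))
        if new_idx >= idx:
            new_idx += 1
        return _replace(tree, path, ("leaf", new_idx, negated))
    if move == "permute":
        internal = _paths(tree, "internal")
        if not internal:
            return None
        path = internal[rng.integers(len(internal))]
        node = _get(tree, path)
        return _replace(tree, path, ("or" if node[0] == "and" else "and", node[1], node[2]))
    if move in ("grow", "split"):
        if n_leaves(tree) >= max_leaves:
            return None
        kind = "any" if move == "grow" else "leaf"
        nodes = _paths(tree, kind)
        path = nodes[rng.integers(len(nodes))]
        op = "and" if rng.random() < 0.5 else "or"
        return _replace(tree, path, (op, _get(tree, path), _random_leaf(p, rng)))
    if move == "prune":
        internal = _paths(tree, "internal")
        if not internal:
            return None
        path = internal[rng.integers(len(internal))]
        node = _get(tree, path)
        return _replace(tree, path, node[1 + int(rng.random() < 0.5)])
    if move == "delete":
        if tree[0] == "leaf":
            return None
        leaf_paths = _paths(tree, "leaf")
        path = leaf_paths[rng.integers(len(leaf_paths))]
        parent = _get(tree, path[:-1])
        sibling = parent[2] if path[-1] == 1 else parent[1]
        return _replace(tree, path[:-1], sibling)
    raise ConfigurationError(f"unknown move {move!r}")


def propose_tree_move(
    trees: list[Tree],
    p: int,
    max_leaves: int,
    move_probs: dict,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> tuple[int, Tree, str]:
    """Pick a tree and a legal move; illegal draws are re-drawn."""
    names = list(move_probs)
    probs = np.array([move_probs[m] for m in names], dtype=float)
    probs /= probs.sum()
    for _ in range(max_tries):
        t = int(rng.integers(len(trees)))
        move = names[rng.choice(len(names), p=probs)]
        new = _apply_move(trees[t], move, p, max_leaves, rng)
        if new is not None:
            return t, new, move
    raise ConfigurationError("no legal move found (degenerate move distribution?)")


@dataclass
class LogicModel:
    """Fitted logic-regression model: trees, GLM coefficients, deviance."""

    trees: list[Tree]
    coefs: np.ndarray
    deviance: float

    def interactions(self) -> set[frozenset[int]]:
        return extract_interactions(self.trees)

    def expression(self, labels: list[str] | None = None) -> list[str]:
        return [tree_expression(t, labels) for t in self.trees]

    def to_json(self, labels: list[str] | None = None) -> dict:
        return {
            "trees": self.expression(labels),
            "coefficients": self.coefs.tolist(),
            "deviance": self.deviance,
        }


def propose_move(
    model: LogicModel,
    move_probs: dict,
    rng: np.random.Generator,
    n_covariates: int | None = None,
    max_leaves: int = 8,
) -> LogicModel:
    """One legal move applied to a copy of the model.

    The returned candidate has stale coefficients/deviance; callers refit.
    ``n_covariates`` bounds the covariate pool for new/alternated leaves
    (defaults to the largest index already referenced, plus one).
    """
    p = n_covariates or max(l[0] for t in model.trees for l in leaves(t)) + 1
    t, new, _ = propose_tree_move(model.trees, p, max_leaves, move_probs, rng)
    trees = list(model.trees)
    trees[t] = new
    return LogicModel(trees, model.coefs.copy(), math.inf)


def acceptance_probability(eps_old: float, eps_new: float, T: float) -> float:
    """min{1, exp((eps_old - eps_new)/T)}; smaller scores are better."""
    if eps_new <= eps_old:
        return 1.0
    return math.exp((eps_old - eps_new) / T)


def anneal(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 5,
    max_leaves: int = 8,
    iterations: int = 50_000,
    temp_log10: tuple[float, float] = (5.0, 0.0),
    move_probs: dict | None = None,
    seed: int = 0,
    acceptance_reference: str = "current",
    _recorder=None,
) -> LogicModel:
    """Simulated-annealing fit; returns the best-scoring model visited.

    The temperature decreases geometrically from 10^hi to 10^lo over the
    iteration budget; coefficients are refitted (warm-started) after every
    proposal; acceptance uses the best score so far as reference by default
    (``acceptance_reference='current'`` gives textbook Metropolis annealing).
    """
    X = np.ascontiguousarray(X, dtype=np.uint8)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    move_probs = move_probs or DEFAULT_MOVE_PROBS
    rng = np.random.default_rng(seed)

    trees = [_random_leaf(p, rng) for _ in range(n_trees)]
    cols = np.stack([evaluate_tree(t, X) for t in trees], axis=1).astype(np.uint8)
    beta, score = _fit_glm(cols, y)
    best = LogicModel(list(trees), beta.copy(), score)

    hi, lo = temp_log10
    temps = np.power(10.0, np.linspace(hi, lo, max(iterations, 2)))
    for it in range(iterations):
        t_idx, new_tree, _ = propose_tree_move(trees, p, max_leaves, move_probs, rng)
        new_col = evaluate_tree(new_tree, X).astype(np.uint8)
        old_col = cols[:, t_idx].copy()
        cols[:, t_idx] = new_col
        new_beta, new_score = _fit_glm(cols, y, beta0=beta)
        ref = best.deviance if acceptance_reference == "best" else score
        if rng.random() < acceptance_probability(ref, new_score, temps[it]):
            trees[t_idx] = new_tree
            beta, score = new_beta, new_score
            if new_score < best.deviance:
                best = LogicModel(list(trees), new_beta.copy(), new_score)
        else:
            cols[:, t_idx] = old_col
        if _recorder is not None:
            _recorder(it, trees, score)
    return best


def mclr_aggregate(
    X: np.ndarray,
    y: np.ndarray,
    config: MCLRConfig | None = None,
    seed: int = 0,
) -> tuple[InteractionRanking, LogicModel]:
    """MCLR: several annealing runs, each followed by a sampling chain.

    Following the Monte-Carlo logic regression recipe, several independent
    runs of the fit are generated to obtain a large collection of models:
    each run anneals from a fresh start and then continues at T = 1 as a
    Metropolis chain whose score carries a size penalty (log 2 per leaf),
    recording every ``record_every``-th state.  A covariate set's score is
    the fraction of all recorded models containing it (via the DNF
    convention of :func:`extract_interactions`).  Returns the ranking and
    the best-scoring model across runs.
    """
    config = config or MCLRConfig()
    X = np.ascontiguousarray(X, dtype=np.uint8)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)

    recorded: list[set[frozenset[int]]] = []
    best: LogicModel | None = None
    for _ in range(max(1, config.n_runs)):
        run_best = anneal(
            X,
            y,
            n_trees=config.n_trees,
            max_leaves=config.max_leaves,
            iterations=config.anneal_iterations,
            temp_log10=config.temp_log10,
            move_probs=config.move_probs,
            seed=int(rng.integers(2**31)),
            acceptance_reference=config.acceptance_reference,
        )
        if best is None or run_best.deviance < best.deviance:
            best = run_best

        # sampling chain from the annealed state
        trees = list(run_best.trees)
        cols = np.stack([evaluate_tree(t, X) for t in trees], axis=1).astype(np.uint8)
        beta, dev = _fit_glm(cols, y)

        def penalized(d: float, ts) -> float:
            return d + config.size_penalty * sum(n_leaves(t) for t in ts)

        score = penalized(dev, trees)
        for it in range(config.chain_iterations):
            t_idx, new_tree, _ = propose_tree_move(
                trees, p, config.max_leaves, config.move_probs, rng
            )
            new_col = evaluate_tree(new_tree, X).astype(np.uint8)
            old_col = cols[:, t_idx].copy()
            cols[:, t_idx] = new_col
            new_beta, new_dev = _fit_glm(cols, y, beta0=beta)
            cand_trees = list(trees)
            cand_trees[t_idx] = new_tree
            new_score = penalized(new_dev, cand_trees)
            if rng.random() < acceptance_probability(score, new_score, 1.0):
                trees, beta, score = cand_trees, new_beta, new_score
            else:
                cols[:, t_idx] = old_col
            if (it + 1) % config.record_every == 0:
                recorded.append(extract_interactions(trees))

    if len(recorded) < 2:
        raise ValidationError("need at least 2 recorded models for MCLR aggregation")
    counts: dict[frozenset[int], int] = {}
    for sets in recorded:
        for s in sets:
            counts[s] = counts.get(s, 0) + 1
    scores = {tuple(sorted(s)): c / len(recorded) for s, c in counts.items()}
    ranking = build_ranking(scores, flavor="any", detector="mclr", k=config.top_k)
    return ranking, best


def mclr_detect(
    enc: EncodedMatrix, y: np.ndarray, config: MCLRConfig | None = None, seed: int = 0
) -> InteractionRanking:
    """Detector API: MCLR ranking with covariate identities."""
    ranking, best = mclr_aggregate(enc.X, y, config, seed)
    mapped = [
        (frozenset(enc.columns[i] for i in s), score) for s, score in ranking.entries
    ]
    out = InteractionRanking(mapped, flavor="any", detector="mclr")
    out.meta["best_model"] = best.to_json(enc.labels())
    return out
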