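"""Neural interaction detection (NID).

A fully connected feed-forward network is fitted to the binary covariates
with binary cross-entropy on the logits and an L1 penalty on all weights,
and interactions are then read off the trained weights: the strength of a
candidate set I at first-layer unit i is

    w_i(I) = mu(|W1[i, I]|) * z_i,        mu = min,

where z_i aggregates the absolute weights connecting unit i to the output,

    z_i = |w_y|^T |W^(L)| ... |W^(2)[:, i]|.

Each first-layer unit proposes one candidate per order (its top-k features
by absolute first-layer weight); strengths are summed across units per
distinct set, and the top-K sets form the ranking — a pairwise-only list
(order-2 candidates) and an any-order list.

The network is a compact numpy implementation: full-batch Adam, ReLU hidden
layers, data split into equal train/validation/test thirds, and the epoch
with the best validation loss kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import NumericError, ValidationError
from .ranking import InteractionRanking, build_ranking
from .seqsim import EncodedMatrix

DEFAULT_ARCHITECTURE = (100, 60, 20)


@dataclass
class NIDConfig:
    architecture: tuple[int, ...] = DEFAULT_ARCHITECTURE
    learning_rate: float = 1e-2
    l1_const: float = 5e-4
    max_epochs: int = 600
    patience: int = 60
    standardize: bool = True  # z-score the binary inputs before training
    top_k: int = 10
    flavor: str = "pairwise"  # which list the detector API returns
    max_order: int | None = 4  # cap on any-order candidate size


@dataclass
class MLPWeights:
    """Weights of the trained network (hidden matrices, output vector)."""

    W: list[np.ndarray]  # W[l] has shape (p_{l+1}, p_l); W[0] is the first layer
    b: list[np.ndarray]
    w_y: np.ndarray
    b_y: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, bmat in zip(self.W[:-1], self.W[1:]):
            if bmat.shape[1] != a.shape[0]:
                raise ValidationError("weight matrix shapes do not chain")
        if len(self.w_y) != self.W[-1].shape[0]:
            raise ValidationError("output vector does not match last hidden layer")

    @property
    def n_features(self) -> int:
        return self.W[0].shape[1]

    @property
    def n_units(self) -> int:
        return self.W[0].shape[0]

    def save(self, path) -> None:
        arrays = {f"W{i}": w for i, w in enumerate(self.W)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.b)}
        np.savez(path, w_y=self.w_y, b_y=self.b_y, **arrays)


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # log(1 + e^z) computed stably
    return float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    architecture: tuple[int, ...] = DEFAULT_ARCHITECTURE,
    learning_rate: float = 1e-2,
    l1_const: float = 5e-4,
    seed: int = 0,
    max_epochs: int = 200,
    patience: int = 20,
    restore_best: bool = True,
) -> MLPWeights:
    """Train the feed-forward network; returns the best-validation weights.

    The data is split into three equal parts (train / validation / test);
    training is full-batch Adam on BCE-with-logits plus an L1 penalty on all
    weight matrices.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if n < 30:
        raise ValidationError("need at least 30 samples to split into thirds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    third = n // 3
    idx_tr, idx_va, idx_te = perm[:third], perm[third : 2 * third], perm[2 * third :]
    Xtr, ytr = X[idx_tr], y[idx_tr]
    Xva, yva = X[idx_va], y[idx_va]

    sizes = [p, *architecture]
    Ws = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[l]), size=(sizes[l + 1], sizes[l]))
        for l in range(len(architecture))
    ]
    bs = [np.zeros(s) for s in architecture]
    wy = rng.normal(0.0, np.sqrt(2.0 / architecture[-1]), size=architecture[-1])
    by = 0.0

    params = [*Ws, *bs, wy, np.array([by])]
    m = [np.zeros_like(q) for q in params]
    v = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def forward(Xb):
        acts = [Xb]
        h = Xb
        for W, b in zip(Ws, bs):
            h = np.maximum(h @ W.T + b, 0.0)
            acts.append(h)
        logits = h @ wy + params[-1][0]
        return acts, logits

    best_val = np.inf
    best = None
    stale = 0
    for epoch in range(max_epochs):
        acts, logits = forward(Xtr)
        if not np.isfinite(logits).all():
            raise NumericError(f"training diverged at epoch {epoch}")
        # gradients
        delta = (1.0 / (1.0 + np.exp(-logits)) - ytr) / len(ytr)  # d loss / d logits
        g_wy = acts[-1].T @ delta + l1_const * np.sign(wy)
        g_by = delta.sum()
        gW = [None] * len(Ws)
        gb = [None] * len(bs)
        back = np.outer(delta, wy)
        for l in range(len(Ws) - 1, -1, -1):
            back = back * (acts[l + 1] > 0)
            gW[l] = back.T @ acts[l] + l1_const * np.sign(Ws[l])
            gb[l] = back.sum(axis=0)
            if l > 0:
                back = back @ Ws[l]
        grads = [*gW, *gb, g_wy, np.array([g_by])]
        t = epoch + 1
        for q, g, mq, vq in zip(params, grads, m, v):
            mq += (1 - beta1) * (g - mq)
            vq += (1 - beta2) * (g * g - vq)
            mhat = mq / (1 - beta1**t)
            vhat = vq / (1 - beta2**t)
            q -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        by = params[-1][0]

        _, val_logits = forward(Xva)
        val_loss = _bce_with_logits(val_logits, yva)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best = ([W.copy() for W in Ws], [b.copy() for b in bs], wy.copy(), float(by))
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break

    if best is None:
        raise NumericError(f"no finite validation loss reached (last {val_loss:.4g})")
    if not restore_best:  # keep the optimisation endpoint instead
        best = (Ws, bs, wy, float(params[-1][0]))
    Wb, bb, wyb, byb = best
    return MLPWeights(
        Wb,
        bb,
        wyb,
        byb,
        meta={
            "val_loss": best_val,
            "epochs_run": epoch + 1,
            "split": (idx_tr, idx_va, idx_te),
        },
    )


def predict_logits(weights: MLPWeights, X: np.ndarray) -> np.ndarray:
    h = np.asarray(X, dtype=np.float64)
    for W, b in zip(weights.W, weights.b):
        h = np.maximum(h @ W.T + b, 0.0)
    return h @ weights.w_y + weights.b_y


def unit_strength(W1_row: np.ndarray, I, mu=np.min) -> float:
    """mu(|W1[i, I]|): within-unit strength of the candidate set I (mu = min)."""
    I = list(I)
    if not I:
        raise ValidationError("candidate set must be non-empty")
    return float(mu(np.abs(np.asarray(W1_row))[I]))


def unit_influences(weights: MLPWeights) -> np.ndarray:
    """z_i for all first-layer units: |w_y|^T |W^(L)| ... |W^(2)| (columnwise)."""
    z = np.abs(weights.w_y)
    for W in weights.W[:0:-1]:
        z = z @ np.abs(W)
    return z


def unit_influence(weights: MLPWeights, i: int) -> float:
    """z_i of one first-layer unit (empty product with a single hidden layer)."""
    return float(unit_influences(weights)[i])


def rank_interactions(
    weights: MLPWeights, K: int = 10, max_order: int | None = None
) -> tuple[InteractionRanking, InteractionRanking]:
    """Build the two NID rankings: a pairwise list and an any-order list.

    Pairwise: every pair (a, b) is scored by summing min(|W1[i,a]|,
    |W1[i,b]|) * z_i over all first-layer units i, i.e. the w_i formula
    evaluated densely for every pair.

    Any order: each first-layer unit sorts its input features by absolute
    weight (ties broken by feature index); the unit's candidate of order k
    is the set of its top-k features, with strength min(|W1[i, top-k]|)
    * z_i (for a single unit this candidate is exactly the argmax of the
    w_i formula over all order-k sets); strengths are summed across units
    per distinct set.  Both lists are truncated to K.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    z = unit_influences(weights)
    p = weights.n_features
    hi = p if max_order is None else min(max_order, p)
    absW = np.abs(weights.W[0])
    pair_mat = np.zeros((p, p))
    for i in range(weights.n_units):
        pair_mat += z[i] * np.minimum.outer(absW[i], absW[i])
    iu = np.triu_indices(p, 1)
    pair_scores = {
        (int(a), int(b)): float(s) for a, b, s in zip(iu[0], iu[1], pair_mat[iu])
    }
    any_scores: dict[tuple[int, ...], float] = {}
    for i in range(weights.n_units):
        absw = absW[i]
        order = np.lexsort((np.arange(p), -absw))  # descending |w|, index tie-break
        sorted_w = absw[order]
        prefix: list[int] = [int(order[0])]
        for k in range(2, hi + 1):
            prefix.append(int(order[k - 1]))
            strength = sorted_w[k - 1] * z[i]  # min over the top-k = k-th largest
            key = tuple(sorted(prefix))
            any_scores[key] = any_scores.get(key, 0.0) + strength
    return (
        build_ranking(pair_scores, flavor="pairwise", detector="nid", k=K),
        build_ranking(any_scores, flavor="any", detector="nid", k=K),
    )


def nid_detect(
    enc: EncodedMatrix, y: np.ndarray, config: NIDConfig | None = None, seed: int = 0
) -> InteractionRanking:
    """Detector API: train the network and return the configured ranking.

    Inputs are standardized by default (zero mean, unit variance per
    column): without it, common columns — the conserved-flank indicators
    in particular — soak up large first-layer weights as intercept proxies
    and crowd the rare informative covariates out of the pairwise scores.
    """
    config = config or NIDConfig()
    X = enc.X.astype(np.float64)
    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    weights = train_mlp(
        X,
        y,
        architecture=config.architecture,
        learning_rate=config.learning_rate,
        l1_const=config.l1_const,
        seed=seed,
        max_epochs=config.max_epochs,
        patience=config.patience,
    )
    pairwise, any_order = rank_interactions(weights, K=config.top_k, max_order=config.max_order)
    chosen = pairwise if config.flavor == "pairwise" else any_order
    mapped = [
        (frozenset(enc.columns[i] for i in s), score) for s, score in chosen.entries
    ]
    return InteractionRanking(mapped, flavor=chosen.flavor, detector="nid")
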