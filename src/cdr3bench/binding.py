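"""Binding-label models: effect assignment, motif implantation, calibration.

The discriminative model draws the binary binding status Y of each sequence
from a logistic regression on the one-hot covariates

    F(x) = b0 + sum_{j in Sm} bj xj + sum_{I in SI} bI prod_{l in I} xl
              + sum_{n in Sn} bn xn + eps,     Y ~ Bernoulli(logistic(F)),

with five strong main effects (coefficients +-L), interaction coefficients
s*L for a strength multiplier s in {1,2,4,8}, many weak effects with
coefficients ~ N(0, 0.01*L) and Gaussian noise eps with sd 0.1.  The motif
corresponding to each interaction (its residues at its positions) is
implanted into a chosen fraction of sequences so that the product term is
actually active in the data.

The intercept b0 is calibrated so that the class balance is 50% when the
motif is implanted in half of the sequences, and the overall coefficient
scale L is calibrated so that the Bayes error,
E_x[min(P(Y=1|x), 1-P(Y=1|x))], is about 2.5%.

The generative model instead samples the two classes directly: binders carry
the motif (by implantation or rejection sampling), non-binders do not, with a
small contamination fraction in each class playing the role of the Bayes
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._exceptions import ConfigurationError, NumericError, ResourceError, ValidationError
from .seqsim import (
    AMINO_ACIDS,
    Cov,
    EncodedMatrix,
    PositionWeightModel,
    SequenceSet,
    cov_label,
    one_hot_encode,
    parse_cov,
    sample_sequences,
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: positions eligible for main and interaction effects (the variable core)
CORE_POSITIONS = tuple(range(4, 13))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class EffectSpec:
    """Effect sets and coefficients of the discriminative model.

    Coefficients are stored as scale-free draws (main-effect signs, the
    interaction strength multiplier, standard-normal weak draws) together
    with the scale ``L``, so that recalibrating ``L`` does not redraw
    anything: bj = sign_j * L, bI = s * L, bn = z_n * sqrt(0.01 * L).
    """

    mains: list[Cov]
    interactions: list[tuple[Cov, ...]]
    weak: list[Cov]
    main_signs: np.ndarray
    weak_z: np.ndarray
    strength: float
    scale: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.1
    hierarchy: str = "strong"

    def __post_init__(self) -> None:
        self.main_signs = np.asarray(self.main_signs, dtype=float)
        self.weak_z = np.asarray(self.weak_z, dtype=float)
        if len(self.main_signs) != len(self.mains):
            raise ValidationError("one sign per main effect required")
        if len(self.weak_z) != len(self.weak):
            raise ValidationError("one draw per weak effect required")
        mains = set(self.mains)
        main_pos = [p for p, _ in self.mains]
        if len(set(main_pos)) != len(main_pos):
            raise ValidationError("main-effect positions must be pairwise distinct")
        for inter in self.interactions:
            pos = [p for p, _ in inter]
            if len(set(pos)) != len(pos):
                raise ValidationError("interaction positions must be pairwise distinct")
            inside = sum(c in mains for c in inter)
            if self.hierarchy == "strong" and inside != len(inter):
                raise ValidationError("strong hierarchy: all interaction covariates must be mains")
            if self.hierarchy == "weak" and inside < 1:
                raise ValidationError("weak hierarchy: at least one interaction covariate in mains")
            if self.hierarchy == "none" and inside > 0:
                raise ValidationError("no hierarchy: interaction covariates must be weak effects")

    # -- coefficient views ------------------------------------------------
    @property
    def main_coefs(self) -> np.ndarray:
        return self.main_signs * self.scale

    @property
    def inter_coef(self) -> float:
        return self.strength * self.scale

    @property
    def weak_coefs(self) -> np.ndarray:
        return self.weak_z * np.sqrt(0.01 * self.scale)

    def with_calibration(self, scale: float | None = None, intercept: float | None = None):
        kwargs = {}
        if scale is not None:
            kwargs["scale"] = scale
        if intercept is not None:
            kwargs["intercept"] = intercept
        return replace(self, **kwargs)

    def motifs(self) -> list[tuple[tuple[int, ...], str]]:
        """One (positions, residues) motif per interaction set."""
        out = []
        for inter in self.interactions:
            ordered = sorted(inter)
            out.append((tuple(p for p, _ in ordered), "".join(r for _, r in ordered)))
        return out

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> dict:
        return {
            "mains": [cov_label(c) for c in self.mains],
            "interactions": [[cov_label(c) for c in i] for i in self.interactions],
            "weak": [cov_label(c) for c in self.weak],
            "main_signs": self.main_signs.tolist(),
            "weak_z": self.weak_z.tolist(),
            "strength": self.strength,
            "scale": self.scale,
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "hierarchy": self.hierarchy,
        }

    @classmethod
    def from_json(cls, d: dict) -> "EffectSpec":
        return cls(
            mains=[parse_cov(s) for s in d["mains"]],
            interactions=[tuple(parse_cov(s) for s in i) for i in d["interactions"]],
            weak=[parse_cov(s) for s in d["weak"]],
            main_signs=np.array(d["main_signs"]),
            weak_z=np.array(d["weak_z"]),
            strength=d["strength"],
            scale=d["scale"],
            intercept=d["intercept"],
            noise_sd=d["noise_sd"],
            hierarchy=d["hierarchy"],
        )


def assign_effects(
    columns: Sequence[Cov],
    n_main: int = 5,
    orders: Sequence[int] = (2,),
    hierarchy: str = "strong",
    strength: float = 8.0,
    scale: float = 1.0,
    seed: int = 0,
) -> EffectSpec:
    """Draw main effects, interaction sets and weak-effect coefficients.

    Main effects are ``n_main`` covariates at distinct positions within the
    variable core (positions 4-12).  Interaction covariates are taken from
    the mains (strong hierarchy), from one main plus fresh positions (weak),
    or entirely from fresh positions (no hierarchy); positions are distinct
    within each interaction and across interactions, so implanting one motif
    never overwrites another.
    """
    if hierarchy not in ("strong", "weak", "none"):
        raise ConfigurationError(f"unknown hierarchy {hierarchy!r}")
    orders = list(orders)
    if any(o not in (2, 3, 4) for o in orders):
        raise ConfigurationError("interaction orders must be in {2, 3, 4}")
    if hierarchy == "strong" and any(o > n_main for o in orders):
        raise ConfigurationError("strong hierarchy needs order <= n_main")
    rng = np.random.default_rng(seed)
    core = {}
    for cov in columns:
        if cov[0] in CORE_POSITIONS:
            core.setdefault(cov[0], []).append(cov)
    if len(core) < n_main:
        raise ConfigurationError("not enough variable-core positions for the main effects")

    main_pos = rng.choice(sorted(core), size=n_main, replace=False)
    mains = [core[p][rng.integers(len(core[p]))] for p in main_pos]

    free_pos = [p for p in sorted(core) if p not in set(main_pos)]
    rng.shuffle(free_pos)
    free_iter = iter(free_pos)

    def fresh_cov() -> Cov:
        try:
            p = next(free_iter)
        except StopIteration:
            raise ConfigurationError("not enough free core positions for the interactions")
        return core[p][rng.integers(len(core[p]))]

    interactions: list[tuple[Cov, ...]] = []
    used_mains: set[Cov] = set()
    for order in orders:
        if hierarchy == "strong":
            pool = [m for m in mains if m not in used_mains]
            if len(pool) < order:
                raise ConfigurationError("not enough unused mains for a strong-hierarchy set")
            idx = rng.choice(len(pool), size=order, replace=False)
            inter = tuple(pool[i] for i in idx)
        elif hierarchy == "weak":
            pool = [m for m in mains if m not in used_mains]
            if not pool:
                raise ConfigurationError("no unused main left for a weak-hierarchy set")
            anchor = pool[rng.integers(len(pool))]
            inter = (anchor,) + tuple(fresh_cov() for _ in range(order - 1))
        else:
            inter = tuple(fresh_cov() for _ in range(order))
        used_mains.update(c for c in inter if c in set(mains))
        interactions.append(tuple(sorted(inter)))

    main_set = set(mains)
    weak = [c for c in columns if c not in main_set]
    return EffectSpec(
        mains=mains,
        interactions=interactions,
        weak=weak,
        main_signs=rng.choice([-1.0, 1.0], size=n_main),
        weak_z=rng.standard_normal(len(weak)),
        strength=float(strength),
        scale=float(scale),
        hierarchy=hierarchy,
    )


# ---------------------------------------------------------------------------
# implantation


@dataclass
class ImplantPlan:
    positions: tuple[int, ...]
    residues: str
    rate: float
    selected_rows: np.ndarray = field(repr=False)


def implant_motif(
    seqs: SequenceSet,
    motif: tuple[Sequence[int], str],
    rate: float,
    seed: int,
) -> tuple[SequenceSet, ImplantPlan]:
    """Overwrite the motif positions of a uniformly chosen fraction of rows."""
    positions, residues = motif
    positions = tuple(int(p) for p in positions)
    if not 0 < rate <= 1:
        raise ValidationError("implantation rate must lie in (0, 1]")
    if len(positions) != len(residues):
        raise ValidationError("motif positions and residues must have equal length")
    if len(set(positions)) != len(positions):
        raise ValidationError("motif positions must be distinct")
    if max(positions) > seqs.seq_len or min(positions) < 1:
        raise ValidationError("motif positions outside the sequence")
    rng = np.random.default_rng(seed)
    n_implant = int(round(rate * len(seqs)))
    rows = rng.choice(len(seqs), size=n_implant, replace=False)
    out = seqs.copy()
    for p, r in zip(positions, residues):
        out.codes[rows, p - 1] = _AA_INDEX[r]
    implanted = np.zeros(len(seqs), dtype=bool)
    implanted[rows] = True
    out.implanted = implanted
    return out, ImplantPlan(positions, residues, rate, np.sort(rows))


def implant_interactions(
    seqs: SequenceSet, spec: EffectSpec, rate: float, seed: int
) -> SequenceSet:
    """Implant every interaction's motif at ``rate`` into disjoint row blocks.

    With one interaction this is plain implantation; with two at rate 0.25
    one quarter of the rows receives each motif (blocks drawn disjointly as
    long as the rates sum to at most 1).
    """
    rng = np.random.default_rng(seed)
    n = len(seqs)
    order = rng.permutation(n)
    out = seqs.copy()
    implanted = np.zeros(n, dtype=bool)
    start = 0
    for positions, residues in spec.motifs():
        k = int(round(rate * n))
        if start + k > n:  # rates exceed 1: fall back to independent draws
            rows = rng.choice(n, size=k, replace=False)
        else:
            rows = order[start : start + k]
            start += k
        for p, r in zip(positions, residues):
            out.codes[rows, p - 1] = _AA_INDEX[r]
        implanted[rows] = True
    out.implanted = implanted
    return out


def motif_match(seqs: SequenceSet, motif: tuple[Sequence[int], str]) -> np.ndarray:
    """Boolean vector: which sequences carry the motif residues at its positions."""
    positions, residues = motif
    hit = np.ones(len(seqs), dtype=bool)
    for p, r in zip(positions, residues):
        hit &= seqs.codes[:, int(p) - 1] == _AA_INDEX[r]
    return hit


# ---------------------------------------------------------------------------
# discriminative response

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(9)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _predictor_parts(X: EncodedMatrix, spec: EffectSpec):
    """Scale-free pieces of F: a = sum sign_j x_j + s * prod terms, c = sum z_n x_n.

    F = b0 + L * a + 0.1 * sqrt(L) * c (+ eps).  Weak covariates filtered out
    of X are skipped; they carry negligible coefficients by construction.
    """
    main_idx = [X.col(c) for c in spec.mains]
    a = X.X[:, main_idx].astype(float) @ spec.main_signs
    for inter in spec.interactions:
        idx = [X.col(c) for c in inter]
        a += spec.strength * X.X[:, idx].all(axis=1)
    weak_idx, weak_z = [], []
    for c, z in zip(spec.weak, spec.weak_z):
        if c in X:
            weak_idx.append(X.col(c))
            weak_z.append(z)
    c_part = X.X[:, weak_idx].astype(float) @ np.asarray(weak_z)
    return a, c_part


def _noise_free_predictor(X: EncodedMatrix, spec: EffectSpec) -> np.ndarray:
    a, c = _predictor_parts(X, spec)
    return spec.intercept + spec.scale * a + 0.1 * np.sqrt(spec.scale) * c


def response_probability(X: EncodedMatrix, spec: EffectSpec) -> np.ndarray:
    """P(Y=1|x) with the noise term marginalised (Gauss-Hermite over eps)."""
    f = _noise_free_predictor(X, spec)
    return _sigmoid(f[:, None] + spec.noise_sd * _GH_NODES[None, :]) @ _GH_WEIGHTS


def discriminative_response(
    X: EncodedMatrix, spec: EffectSpec, seed: int, noise: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labels Y ~ Bernoulli(logistic(F)); returns (labels, probabilities)."""
    rng = np.random.default_rng(seed)
    f = _noise_free_predictor(X, spec)
    if noise:
        f = f + rng.normal(0.0, spec.noise_sd, size=len(f))
    p = _sigmoid(f)
    y = (rng.random(len(p)) < p).astype(np.int8)
    return y, p


def bayes_error(X: EncodedMatrix, spec: EffectSpec) -> float:
    """E_x[min(P(Y=1|x), 1-P(Y=1|x))] over the rows of X."""
    p = response_probability(X, spec)
    return float(np.minimum(p, 1.0 - p).mean())


# ---------------------------------------------------------------------------
# calibration


def _mc_design(
    spec: EffectSpec, pwm: PositionWeightModel, rate: float, mc_n: int, seed: int
) -> EncodedMatrix:
    seqs = sample_sequences(pwm, mc_n, seed)
    seqs = implant_interactions(seqs, spec, rate, seed + 1)
    return one_hot_encode(seqs)


def _bisect(fn, lo: float, hi: float, tol: float, max_iter: int = 100) -> float:
    flo, fhi = fn(lo), fn(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise NumericError(
            f"bisection bracket failure: f({lo})={flo:.4g}, f({hi})={fhi:.4g}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fmid = fn(mid)
        if abs(fmid) < tol or (hi - lo) < 1e-12:
            return mid
        if np.sign(fmid) == np.sign(flo):
            lo, flo = mid, fmid
        else:
            hi, fhi = mid, fmid
    return 0.5 * (lo + hi)


def calibrate_intercept(
    spec: EffectSpec,
    pwm: PositionWeightModel,
    rate: float = 0.5,
    target_balance: float = 0.5,
    mc_n: int = 100_000,
    tol: float = 1e-3,
    seed: int = 0,
    _design: EncodedMatrix | None = None,
) -> float:
    """Intercept b0 giving the target mean of P(Y=1|x) at the given rate."""
    X = _design if _design is not None else _mc_design(spec, pwm, rate, mc_n, seed)

    def gap(b0: float) -> float:
        return float(response_probability(X, spec.with_calibration(intercept=b0)).mean()) - target_balance

    # the predictor's reach grows with the scale; keep the bracket ahead of it
    span = spec.scale * (abs(spec.strength) * len(spec.interactions) + len(spec.mains)) + 10.0 * (
        1.0 + np.sqrt(spec.scale)
    )
    return _bisect(gap, -span, span, tol)


def calibrate_scale(
    spec: EffectSpec,
    pwm: PositionWeightModel,
    target_bayes_error: float = 0.025,
    rate: float = 0.5,
    target_balance: float = 0.5,
    mc_n: int = 100_000,
    tol: float = 1e-3,
    seed: int = 0,
) -> EffectSpec:
    """Joint scale/intercept calibration.

    For each candidate scale L the intercept is re-calibrated to the target
    class balance, and L is then bisected so that the Bayes error of the
    balanced model hits the target.  Evaluations share one Monte-Carlo
    design, so the procedure is deterministic given the seed.
    """
    if not 0 < target_bayes_error < 0.5:
        raise ValidationError("target Bayes error must lie in (0, 0.5)")
    X = _mc_design(spec, pwm, rate, mc_n, seed)

    def balanced(L: float) -> EffectSpec:
        trial = spec.with_calibration(scale=L)
        b0 = calibrate_intercept(
            trial, pwm, rate, target_balance, mc_n, tol, seed, _design=X
        )
        return trial.with_calibration(intercept=b0)

    def gap(L: float) -> float:
        return bayes_error(X, balanced(L)) - target_bayes_error

    lo, hi = 1e-3, 30.0
    if gap(hi) > 0:
        # weak-signal regime (e.g. strength 1): the discrete covariate
        # lattice leaves a probability shell near 1/2, so the target Bayes
        # error is unattainable; Bayes error is non-increasing in L, so the
        # upper end of the bracket is the best achievable scale
        warnings.warn(
            f"target Bayes error {target_bayes_error} unattainable; "
            f"using scale L={hi} (closest achievable)",
            stacklevel=2,
        )
        return balanced(hi)
    L = _bisect(gap, lo, hi, tol)
    return balanced(L)


# ---------------------------------------------------------------------------
# generative model


def _draw_without_motif(
    pwm: PositionWeightModel,
    motif: tuple[Sequence[int], str],
    n: int,
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> np.ndarray:
    """Sample n sequences from the PWM, re-drawing any that carry the motif."""
    out = np.empty((0, pwm.seq_len), dtype=np.int8)
    need = n
    for _ in range(max_rounds):
        if need == 0:
            break
        batch = sample_sequences(pwm, max(need, 16), int(rng.integers(2**31)))
        keep = batch.codes[~motif_match(batch, motif)]
        out = np.vstack([out, keep[:need]])
        need = n - len(out)
    if need:
        raise ResourceError("could not draw motif-free sequences (motif nearly certain?)")
    return out


def _draw_with_motif_reject(
    pwm: PositionWeightModel,
    motif: tuple[Sequence[int], str],
    n: int,
    rng: np.random.Generator,
    max_draws: int,
) -> np.ndarray:
    out = np.empty((0, pwm.seq_len), dtype=np.int8)
    drawn = 0
    while len(out) < n:
        batch_size = min(max(4096, 4 * n), max_draws - drawn)
        if batch_size <= 0:
            rate = len(out) / max(drawn, 1)
            raise ResourceError(
                f"rejection budget of {max_draws} draws exhausted "
                f"(acceptance rate {rate:.2e}, {len(out)}/{n} kept)"
            )
        batch = sample_sequences(pwm, batch_size, int(rng.integers(2**31)))
        drawn += batch_size
        keep = batch.codes[motif_match(batch, motif)]
        out = np.vstack([out, keep[: n - len(out)]])
    return out


def generative_sample(
    pwm: PositionWeightModel,
    motif: tuple[Sequence[int], str],
    n_pos: int,
    n_neg: int,
    contamination: float = 0.025,
    mode: str = "implant",
    seed: int = 0,
    max_draws: int = 2_000_000,
) -> SequenceSet:
    """Sample binder/non-binder classes directly (class-conditional model).

    Binders carry the motif (implanted, or naturally present under rejection
    sampling); non-binders do not; each class contains a ``contamination``
    fraction of sequences that belong to the other class's distribution.
    """
    if mode not in ("implant", "reject"):
        raise ConfigurationError(f"unknown generative mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_pos_motif = int(round((1.0 - contamination) * n_pos))
    n_neg_motif = int(round(contamination * n_neg))

    if mode == "implant":
        with_motif = sample_sequences(
            pwm, n_pos_motif + n_neg_motif, int(rng.integers(2**31))
        ).codes.copy()
        positions, residues = motif
        for p, r in zip(positions, residues):
            with_motif[:, int(p) - 1] = _AA_INDEX[r]
    else:
        with_motif = _draw_with_motif_reject(
            pwm, motif, n_pos_motif + n_neg_motif, rng, max_draws
        )
    without = _draw_without_motif(pwm, motif, (n_pos - n_pos_motif) + (n_neg - n_neg_motif), rng)

    codes = np.vstack(
        [
            with_motif[:n_pos_motif],  # clean positives
            without[: n_pos - n_pos_motif],  # contaminated positives
            without[n_pos - n_pos_motif :],  # clean negatives
            with_motif[n_pos_motif:],  # contaminated negatives
        ]
    )
    labels = np.concatenate([np.ones(n_pos, dtype=np.int8), np.zeros(n_neg, dtype=np.int8)])
    carries = np.concatenate(
        [
            np.ones(n_pos_motif, dtype=bool),
            np.zeros(n_pos - n_pos_motif, dtype=bool),
            np.zeros(n_neg - n_neg_motif, dtype=bool),
            np.ones(n_neg_motif, dtype=bool),
        ]
    )
    perm = rng.permutation(len(labels))
    return SequenceSet(codes[perm], labels=labels[perm], implanted=carries[perm])
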