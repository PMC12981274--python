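# Methods

`cdr3bench` is a controlled simulation bench for statistical interaction
detection in immune-receptor sequence data.  It has three layers: a
sequence/label simulator whose ground truth is known exactly, a set of
interaction detectors implemented from their published descriptions, and a
replication driver that scores detection.  This note records the models,
the numerical choices, and what the defaults mean.

## Sequence model

Sequences are fixed-length 15-mers over the 20 standard amino acids,
mimicking CDR3 junctions of heavy-chain antibody repertoires.  Each
position is drawn independently from a position weight matrix (PWM).  The
default PWM is a deterministic stand-in for a V(D)J rearrangement
simulator:

* positions 1–3 and 13–15 are conserved flanks — one dominant residue at
  85% (C/A/R … D/Y/W, echoing the canonical `C…W` junction) plus six minor
  residues at 2.4% each;
* positions 4–12 (the variable core, from which all effects are drawn) are
  diverse but right-skewed: residue probabilities follow a geometric
  profile with ratio 0.8 over a position-specific ordering, so each core
  position has a few common residues and a tail of rare ones.  A randomly
  chosen surviving covariate has a frequency of a few percent, and
  frequency-weighted pairs of core residues co-occur at the percent level,
  as in rearranged repertoires.

What the PWM does **not** model: positional dependence (real junctions
correlate neighbouring residues through gene segments), length variation,
and nucleotide-level biases.  Detection results therefore show what the
*methods* can do when the independence assumptions of the encoding hold;
they do not certify performance on real repertoires.

One-hot encoding produces an indicator column per (position, residue) pair
observed; residue M is the per-position reference and is dropped everywhere
(15 × 19 = 285 potential columns), which removes the within-position
collinearity of a full dummy encoding.  Columns whose minor category falls
below 0.5% are removed — except the true effect columns of a simulation,
which are protected (and a warning raised); the low threshold exists to
stabilise model fits, not to screen covariates.  At n = 10⁴ the default
PWM yields ≈190 surviving covariates.

## Binding-label models

**Discriminative model.**  Labels are Bernoulli draws from a logistic
model on the one-hot covariates,

    F(x) = b0 + Σ_{j∈Sm} bj xj + Σ_{I∈SI} bI Π_{l∈I} xl + Σ_{n∈Sn} bn xn + ε,

with 5 main effects at distinct core positions (bj = ±L with random sign),
interaction coefficients bI = s·L for a strength multiplier s ∈ {1,2,4,8},
weak effects bn ~ N(0, 0.01·L) on every remaining covariate (read as
*variance* 0.01·L), and ε ~ N(0, 0.1²).  Interaction covariates come from
the mains (strong hierarchy), one main plus fresh positions (weak), or
entirely fresh positions (none); positions are distinct within and across
interactions, so implanting one motif never overwrites another.

The motif of an interaction (its residues at its positions) is implanted
into exactly round(rate·n) uniformly chosen rows.  Because the motif also
occurs naturally, the class proportion at rate r < 0.5 slightly exceeds r.

**Calibration.**  Two scalar knobs are calibrated by Monte Carlo against a
shared simulated design (default 10⁵ rows, Gauss–Hermite marginalisation
of ε with 9 nodes):

* the intercept b0, bisected so the mean of P(Y=1|x) is 50% when the motif
  is implanted in half the rows;
* the scale L, bisected so the Bayes error E_x[min(p, 1−p)] is 2.5%, with
  b0 re-calibrated inside every trial evaluation (a nested bisection —
  equivalent to alternating the two until joint convergence, but
  monotone and deterministic).

b0 and L are calibrated once at rate 0.5 and reused at lower rates; the
Bayes error is empirically flat (±0.1 pp) across rates 0.5–0.05.
Bisection tolerance 10⁻³; brackets scale with s·L so large trial scales
cannot escape them.

**Generative model.**  Alternatively the two classes are sampled directly:
binders carry the motif (implanted, or naturally present under rejection
sampling with an explicit draw budget), non-binders do not (motif hits are
re-drawn), and each class contains 2.5% contaminants from the other
class's distribution, playing the role of the Bayes error.

## Detectors

All detectors consume the filtered design matrix and labels and emit a
ranking of covariate sets (top 10 recorded, ties broken lexicographically
by covariate label).

**NID (neural interaction detection).**  A fully connected network
(hidden layers 100/60/20, ReLU) is trained on z-scored inputs with
full-batch Adam (lr 10⁻²), binary cross-entropy on logits plus an L1
penalty (5·10⁻⁴) on all weight matrices; the data is split into equal
train/validation/test thirds and the epoch with the best validation loss
is kept (cap 600 epochs, patience 60).  Standardising the binary inputs
matters: without it the common conserved-flank columns absorb large
first-layer weights as intercept proxies and crowd the rare informative
covariates out of the rankings.  Interactions are read off the weights:
unit influence z_i = |w_y|ᵀ|W⁽³⁾||W⁽²⁾|_{·,i}, and strength of a set I at
unit i is min(|W⁽¹⁾_{i,I}|)·z_i.  The pairwise list scores *every* pair by
summing this quantity over all units; the any-order list aggregates each
unit's top-k prefix candidate per order k (for one unit, that prefix is
exactly the argmax of the strength formula over order-k sets).  The MLP is
a compact numpy implementation (the full forward/backward pass is ~40
lines); it is deterministic given the seed.

**MCLR (Monte-Carlo logic regression).**  The model is a logistic GLM on
up to 5 Boolean trees (AND/OR over possibly negated leaves, ≤8 leaves
each).  Simulated annealing proposes one structural move per iteration
(alternate leaf 0.40, permute operator 0.20, grow 0.15, prune 0.15, split
0.05, delete 0.05 — re-drawn when illegal), refits the GLM, and accepts
with min{1, exp((ε_old − ε_new)/T)}, T decreasing geometrically from 10⁵
to 10⁰.  ε_old is the current state's score (textbook Metropolis
annealing); a switch selects a best-so-far reference instead, which in our
experiments freezes the chain far from the optimum once T drops and
roughly halves recovery.  The GLM refit aggregates rows over the ≤2⁵
indicator patterns and runs a ridge-stabilised Newton solve (ridge 10⁻⁴,
step halving, cold start — a warm start from the previous model can
overshoot catastrophically after a column swap); the score is the binomial
deviance.  Several independent runs are generated: each anneals and then
continues as a Metropolis chain at T = 1 with a log 2 per-leaf size
penalty, recording every 100th model; a covariate set's score is the
fraction of all recorded models (pooled over runs) in which it co-occurs
inside one tree.  Pooling runs matters — a junk conjunction a single run
overfits is run-specific and dilutes, while the true motif recurs.
Co-occurrence follows the disjunctive-normal-form convention: every subset
(≥2) of a conjunct's covariates counts, so X1∧(X2∨X3) yields {X1,X2} and
{X1,X3} but not {X2,X3}; negated leaves count as their covariate;
contradictory conjuncts are dropped.  Defaults: 3 runs, 50 000 annealing
and 100 000 chain iterations per run (the benchmark driver uses
25 000 + 10 000 to keep a 30-replicate run in minutes).  The inner Newton
solve is numba-compiled.

**iRF (iterative random forests).**  Feature-weighted forests are grown
for K = 5 rounds, the split feature of every node selected with
probability proportional to the weights (uniform at round 1, then the
previous forest's mean decrease in Gini impurity).  Concretely, weighted
draws are tried in order and the first candidate admitting a legal,
impurity-reducing split is used; a config switch instead takes the best
Gini gain among mtry = √p weighted candidates.  The direct-draw mode is
the default because the best-of-candidates variant exhibits a
winner-take-all pathology on implanted motifs: with rare background
co-occurrence, one motif covariate absorbs nearly all weight (its partner
is conditionally redundant inside its branch), after which junk pairs
{winner, next-weighted feature} acquire spuriously high stability.
Splits are on single binary covariates; minimum leaf size 5, unbounded
depth; the tree grower is a numba kernel, deterministic per seed.  On
each of B bootstrap samples a forest with the final weights is fitted and
a random intersection tree (depth 5, branching 2, 100 path draws)
intersects feature sets read off root-to-leaf paths of class-1 leaves,
sampled with probability proportional to leaf size; surviving sets of
size ≥2 are candidates, and stability(S) is the fraction of bootstraps
producing S.  Defaults B = 30 and 500 trees; the benchmark driver uses
B = 20 and 100 trees, which leaves recovery unchanged on pilot runs.

**All-pairs lasso baseline.**  L1-penalised logistic regression
(liblinear) on all main columns plus every pairwise product column whose
minor fraction clears the same 0.5% rarity rule; pairs ranked by |coef|.
The penalty C = 0.1 was fixed once by cross-validation at the reference
setting (one pair, rate 0.5, n = 10⁴) and reused everywhere.  This is a
generic baseline standing in for hierarchy-constrained lasso solvers,
used only for qualitative strength/rate monotonicity checks.

## Evaluation

A replicate = simulate sequences → draw effects → calibrate → implant →
encode → label → run detectors → record top-10.  Metrics: S_top1 (true
set ranked first), S_top10 (in the top 10), S_top1sub (a strict
sub-interaction ranked first; defined for order > 2).  With two truths
each is scored separately and summed.  Detector exceptions are logged,
counted as failures, and excluded from the counts.

The oracle AUC experiment fits logistic regression on the five true main
columns, with and without the true product column, by plain maximum
likelihood (IRLS capped at 25 iterations, the convention of standard GLM
implementations — under quasi-separation this reproduces the behaviour of
unpenalised reference fits, which matters at small n); only a numerically
failed fit falls back to a mild ridge.  AUC is computed on a held-out half
of equal size, or by stratified 10-fold cross-validation.

## Problem sizes and determinism

The bundled analyses and the acceptance script run at desk scale chosen to
keep each stage in minutes on one CPU: 30 replicates for detection
benchmarks (rescaled per 100 when reported), calibration Monte Carlo 10⁵
for headline numbers and 10⁴–2·10⁴ inside replicate loops, MCLR at
50 000 + 30 000 iterations, iRF at 100 trees / B = 20.  Every stage
derives its randomness from one base seed through `numpy.random.
SeedSequence` substreams; identical seeds give identical outputs bit for
bit.

## Known limitations

* The PWM stand-in reproduces the covariate-frequency regime of length-15
  CDR3 repertoires, not their dependence structure; absolute detection
  rates on real data will differ.
* In the oracle AUC experiment, the finite-sample behaviour of the
  rare-motif cell (rate 0.05, n_train = 500) is sensitive to the exact
  covariate distribution: under this simulator the mean held-out AUC sits
  near 0.85 at n_train = 500 and near 0.87 asymptotically, i.e. the
  small-sample penalty is mild.  Covariate distributions with stronger
  quasi-separation (and hence a larger small-sample penalty) exist in
  real repertoires but are not produced by the independent-position
  model.
* Logic-regression deviance cannot distinguish a conjunction from an
  additive fit on *noiseless* separable data; all bundled benchmarks
  include label noise (Bayes error 2.5%), where the distinction is real.
* Only one- and two-interaction designs of order 2–4 are exercised;
  hierarchy-constrained lasso solvers and Bayesian logic regression are
  outside the package's scope.
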