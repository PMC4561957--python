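# Methods

## Model

`mirbm` treats the multi-type miRNA–disease network as q exchangeable
training cases — one per miRNA — for a single shared conditional restricted
Boltzmann machine.  The visible layer of a case is the miRNA's n×t binary
slice (n diseases × t evidence types); m hidden binary units model latent
structure; a per-disease observed indicator r (r_i = 1 iff the miRNA has any
known association with disease i) conditions the hidden layer through the
coupling matrix D.  Parameters W (n×t×m), a (n×t), b (m) and D (n×m) are
shared across miRNAs, so the construction is the collaborative-filtering RBM
adapted to typed bipartite links: per-miRNA machines differ only in their
clamped data.

The energy is pairwise and bilinear,

    E(v, h | r) = − v·W·h − a·v − b·h − r·D·h ,

and because neither layer has intra-layer connections the conditionals
factorise into logistic units: P(h_j=1 | v, r) = σ(b_j + Σ v W + Σ D r) and
P(v_ik=1 | h) = σ(a_ik + Σ h W).  The covariate enters only through the
hidden biases, so P(v | h) is independent of r.  This is the unique pairwise
energy consistent with both conditionals; we adopt it as the model
definition.

Two indexing conventions deserve a note.  First, r is indexed by disease
(length n) and D is n×m: r is *defined* per disease, and any other shape
would make the conditional ill-typed.  Second, a (pair, type) cell absent
from the data is treated as an observed 0, not as missing: the prediction
task ranks exactly those zero cells, so zeros are the background class.
Consequently r can legitimately be 1 for a disease whose entire visible
slice is 0 in a given view (e.g. after a fold removal when the pair is known
under another type); the `VisibleConfig` container enforces "v implies r" by
default and relaxes it (`strict=False`) where r acts as a clamped covariate.

## Training

Training is mean-field contrastive divergence (CD-T):

* data phase: ĥ = P(h | v, r) with v clamped;
* model phase: T alternating mean-field sweeps v' = P(v | ĥ),
  h' = P(h | v', r), started from the data, r clamped throughout;
* update: Δθ = ε (⟨s⟩_data − ⟨s⟩_T) for each sufficient statistic s,
  averaged over the batch.

Both phases use expected activations, never Bernoulli samples.  This makes
training fully deterministic given the seed (the only random element is the
Gaussian initialisation, and the mini-batch order when mini-batches are
enabled), which in turn makes every downstream artifact byte-reproducible.
Since all statistics are probabilities, each update is bounded by ε
elementwise.

Defaults: m = 100 hidden units, ε = 0.01, 100 epochs, T = 1, Gaussian
initialisation with sd 0.1, full-batch updates ("epoch" here means one full
pass; the CD chain length is T, kept separate).  Momentum and weight decay
exist in `TrainConfig` but default to zero: plain gradient steps are the
only update the protocol specifies, and the tests characterise that
baseline.  On enumerable models (n·t + m ≤ 20) the trainer can track the
exact per-case log-likelihood Σ_u log P(v_u | r_u), computed by summing the
hidden layer analytically (softplus product) and enumerating visible states
for the normaliser, with the partition function cached per distinct r
pattern.

CD is a biased gradient estimator; the test suite therefore asserts a
directional property (positive inner product between the CD W-update and the
finite-difference exact gradient in ≥ 90% of seeded tiny trials) and a
monotone outcome (exact log-likelihood strictly increases over 100 epochs on
every tiny seeded instance), not exact gradient equality.

## Prediction and evaluation

Prediction is one mean-field iteration: ĥ = P(h | v, r), then P(v | ĥ)
evaluated with the real-valued ĥ is the score matrix.  Scores are strictly
inside (0, 1), so every candidate is rankable.

The evaluation protocol is global: a held-out (miRNA, disease, type) triple
is ranked against all candidate triples, i.e. every cell with no known
evidence, read per-type.  Rank ties receive the average of the tied
positions (a min-rank option exists).  Leave-one-out cross-validation zeroes
one triple per fold, recomputes the affected miRNA's r from the remaining
slice, and by default retrains from scratch with a fold-derived seed stream;
a fast mode trains once on the full network and zeroes the fold only in the
clamped input at scoring time.  Fast mode is an approximation — the held-out
triple still influenced the shared weights — and is labelled as such in run
manifests; it exists because full retraining scales as one training run per
known association.  The held-out fraction variant (`holdout_split` +
`evaluate_holdout`) removes a batch of triples, trains once on the rest, and
ranks each removed triple against the candidates excluded from both sets;
it is the default large-scale evaluation.

The ROC curve sweeps the rank threshold: a fold counts as a true positive at
threshold θ when its normalised rank p = (rank−1)/candidates is *strictly*
below θ (strict comparison, stated here because either convention is
defensible).  The curve is the empirical step CDF of p from (0,0) to (1,1)
and its trapezoidal area equals 1 − mean(p) exactly — the Mann–Whitney
rank-sum identity, which the tests assert to 1e−10.  AUC 1 is perfect
ranking; 0.5 is random.

## Synthetic data generator

The generator emulates the shape of the curated multi-type network used to
motivate the model: 174 diseases × 322 miRNAs × 4 types with per-type totals
(682, 443, 199, 356) — about 0.2% density.  Mechanism: disease factors
U (n×d) and miRNA factors M (q×d) are standard Gaussian with d = 8; each
type k has an affinity transform A_k (d×d); the logits U A_k Mᵀ are
standardised, scaled by `signal_sd` (default 2.0), shifted by a per-type
intercept found by bisection so the expected 1-count matches the target, and
Bernoulli-sampled.  The low-rank mechanism is chosen deliberately: the RBM's
hidden units are themselves a learned low-dimensional representation, so the
planted structure is in principle recoverable, making "AUC > 0.5" a
meaningful claim.  With `signal_sd` = 2.0 the sampled 1s concentrate in the
upper tail of the planted affinity; the pre-noise probability tensor
separates 1-cells from 0-cells with AUC ≈ 0.94, which bounds what any model
could recover from one draw.

Noise is density-preserving corruption: each 1-cell flips to 0 with
probability ρ (default 0.01) and each 0-cell flips to 1 with probability
ρ·(target/zeros), so the expected per-type counts are conserved.  A
symmetric per-cell flip at any useful ρ would swamp the sparse signal with
spurious positives (ρ = 0.01 would add ~560 false 1s per type against
targets as small as 199), so the preserved-density form is the one under
which realized counts remain near their targets — a property the tests
check at 3·√target tolerance.

What the generator does *not* emulate: disease–disease semantic similarity,
miRNA functional similarity, the heavy-tailed degree distribution of curated
databases, literature-driven ascertainment bias, and correlated evidence
types for the same pair.  Passing tests on planted data therefore show that
the implementation recovers the kind of structure the model class is built
for; they do not certify performance on real curated networks.

## Numerical choices

* Logistic units use `scipy.special.expit`; saturation is exact, not
  clipped.
* Exact oracles are hard-bounded at n·t + m ≤ 20 units (≈10^6 joint states)
  and raise a labelled error above it.
* Intercept calibration uses Brent root-finding on the mean sigmoid in
  [−60, 60] with xtol 1e−10; targets 0 and n·q short-circuit to constant
  0/1 tensors.
* Candidate ranking resolves score ties by average rank; top-k prediction
  tables break probability ties by (mirna, disease, type) lexical order via
  a stable sort, so outputs are deterministic.
* Per-fold LOOCV seeds derive from `SeedSequence(seed, spawn_key=(fold,))`,
  keeping folds independent and reproducible.
* Edge lists written by the package carry `#`-comment vocabulary metadata so
  that write/load round trips preserve zero-degree entities and axis order;
  plain files without metadata load with first-appearance order, defaulting
  to the canonical four type labels whenever the observed types are a subset
  of them.
* Degenerate inputs are rejected with labelled errors: empty edge lists,
  unknown type labels (with the offending row), all-zero networks (no
  training signal), empty batches, test triples still present in the seed
  network (leakage), hold-out fractions that would delete all signal.

## Problem sizes used in the checks

The acceptance script and the heavier tests run the default-scale network
(174 × 322 × 4, ≈1650 associations) with 20% hold-out, five seeds, full
default training (m = 100, 100 epochs) — about 4–5 s per fit on one CPU.
Exactness checks run on tiny instances (n, t, m ≤ 2) where full enumeration
is feasible.  Full per-fold-retrain LOOCV is exercised on small networks
only; at database scale the fast and hold-out modes are the intended tools.

## Known limitations

* Zeros are trained as observed negatives; truly missing-at-random data
  would call for a different likelihood.
* Fast LOOCV mildly leaks the held-out triple through the shared weights;
  its AUC is optimistic relative to full retraining.
* The model shares one parameter set across all miRNAs and has no side
  information (sequence, similarity networks); cold-start miRNAs with empty
  slices receive near-uniform scores driven by the visible biases.
* Softmax (one-of-t) visible groups, persistent CD and stacked/deep variants
  are out of scope.
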