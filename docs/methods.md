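# Methods

## Sequence recurrence networks

A protein sequence of length L over the 21-letter alphabet (20 standard
residues + X; the input layer folds ambiguity codes B, Z, J, U, O and `*`
into X) is turned into an undirected graph with binary adjacency α:

- **chain edges** between consecutive residues i and i+1;
- **recurrence edges** from each position j to the nearest *earlier*
  position holding the same residue type. Connecting only to the nearest
  previous occurrence realises the minimal-topological-distance rule
  without double-counting symmetric pairs;
- a **dummy bias node** (id 0) attached as a pendant to the first residue.
  It is the centre of the star-graph view of the same construction; since
  no further star detail is specified anywhere we rely on, only this
  pendant form is built. It can be disabled (`include_dummy=False`).

Adjacency is binary, so a recurrence edge that coincides with a chain edge
(adjacent identical residues, "AA") is stored once. Consequences worth
knowing: a single-letter sequence ("AAAA…") yields a pure path plus the
dummy pendant — a bipartite graph whose odd-power traces are exactly zero —
and, more generally, the recurrence-edge density is a *hump-shaped*
function of residue-composition concentration: it vanishes both for
maximally diverse sequences (few repeats) and for single-letter sequences
(repeats collapse onto the chain), peaking at intermediate concentration
(nearest repeats at gap ≈ 2 create triangles). This non-monotonicity
matters when designing classes that should be distinguishable by trace
descriptors; see the generator section.

## Markov descriptors

The stochastic matrix Π row-normalises α: p_ab = α_ab / Σ_b α_ab. Every
node of a valid SRN has degree ≥ 1, so the rows are well defined; an
isolated node is treated as a corrupted input and rejected.

- **Trace descriptors** Tr_k = tr(Π^k): the total k-step return
  probability summed over nodes — a closed-walk census weighted by walk
  probabilities. Default orders are k = 3 and 5. The default matrix is Π;
  an adjacency-matrix option (`matrix_kind="adjacency"`, closed-walk
  counts) is provided because "connectivity matrix" is ambiguous in parts
  of the literature, but Π is the only matrix the method defines
  explicitly. Powers are computed by `numpy.linalg.matrix_power`
  (repeated multiplication; k ≤ ~10 in practice, no eigendecomposition and
  no complex-arithmetic edge cases). Tr_0 would be tr(I) = n; it is
  accepted but flagged degenerate.
- **Markov–Shannon entropies** θ_k = −Σ_a π_k(a) ln π_k(a), where
  π_k = π_0 Π^k and π_0 is uniform over all n nodes *including* the dummy
  (it is a declared graph node). Zero-probability terms contribute 0.
  Natural logarithm, i.e. units of nats (the defining formula leaves the
  base open); a `base` argument converts. θ_0 = ln n exactly, and for any
  regular graph the uniform distribution is stationary so θ_k = ln n for
  all k.

Invariants enforced by tests: rows of Π sum to 1 (±1e−12), Σ_a π_k(a) = 1
(±1e−9 through k = 20), 0 ≤ θ_k ≤ ln n, |Tr_k| ≤ n on the stochastic
matrix, and exact agreement of both the edge set and tr(Π^k) with
independent brute-force enumeration (O(L²) rule application and explicit
closed-walk sums) on random short sequences.

## Multi-task feature table

Per-class profiles are arithmetic means of each descriptor over the class
members; they are computed on the full annotated set before any
train/validation split (the split applies to pair records, not to the
profile estimation — recorded in run metadata; training-only means are a
config switch away by passing a filtered annotation list). A (sequence,
candidate class) pair is featurised as (⟨Tr3⟩, ⟨Tr5⟩, DTr3, DTr5), with
D = sequence value − class mean, and labelled ε = +1 for an enzyme paired
with its own class, −1 otherwise.

Three negative-pair policies:

- `random-class` (default): each non-enzyme is paired with one uniformly
  random enzyme subclass (seeded). Total records = number of sequences,
  matching the published row accounting in which each non-enzyme
  contributes exactly one row;
- `all-classes`: each non-enzyme is paired with every subclass;
- `cross-class`: full ε_q(c) labelling over every (sequence, subclass)
  combination — enzymes additionally appear as negatives against every
  *other* subclass. This is the policy a per-class *ranking* scorer must be
  trained under (below).

## Classifiers and the class-ranking limitation

The published discriminant is the affine score
−0.95·⟨Tr3⟩ − 0.80·⟨Tr5⟩ − 0.80·DTr5 + 1.01·DTr3 − 2.05 (the printed
equation is typographically garbled; this reading assigns −0.80 to both
⟨Tr5⟩ and DTr5, consistent with the four documented variables). It ships
as the packaged default model; thresholding at 0 (exact ties → −1) gives
the pair label. Whether the original cut was 0 or fitted is not stated;
0 is the default and the threshold is exposed everywhere.

**Structural fact.** For any affine pair-scorer, the score difference
between two candidate classes for the same sequence depends only on the
class means: score_c(x) = A(x) + B(c) with A(x) = w_D·x + b and B(c) a
function of the class profile alone. The argmax over classes is therefore
the *same for every sequence*, and a linear model cannot perform
per-sequence subclass ranking — its real discriminating power is
enzyme-pair vs non-enzyme-pair. Subclass assignment through
`predict_subclass` (score against every profile, return the argmax class
if it clears the threshold, ties to the lexicographically smallest EC
string) is therefore meaningful only with a nonlinear scorer.

The retrainable models are:

- **Fisher discriminant** (`fit_lda`): direction w = S_w⁻¹(μ₊ − μ₋) with
  pooled within-class covariance, intercept at the pooled-mean midpoint so
  positive scores side with the enzyme-pair class. A singular S_w raises
  with a pointer to the `ridge` regulariser. A fit whose Mahalanobis
  separation is within 5× its null expectation p(1/n₊ + 1/n₋) is flagged
  as statistically indistinguishable classes. The published coefficients
  remain the default scoring path, so refits never silently change
  predictions. (The original fit used a proprietary "General Discriminant"
  tool; Fisher's rule is the standard open equivalent.)
- **One-hidden-layer perceptron** (`fit_mlp`): 4-h-2 topology (h = 9 by
  default, i.e. 65 trainable parameters), tanh hidden layer, softmax
  outputs, cross-entropy loss, full-batch Adam (a gradient-descent
  variant; plain momentum descent stalls short of separability on these
  features), inputs standardised by training-set mean/SD stored on the
  model. Deterministic for a given seed; trains on a seeded 70/30 split
  and records train/validation accuracy. Non-convergence within
  `max_epochs` (no loss plateau at 1e−6 and loss above 1e−4) warns and
  returns the best weights seen. The decision value is the logit
  difference (+1 minus −1), so 0 is the natural threshold.

**Sensitivity analysis** ranks predictors by error inflation: the model's
misclassification rate with one feature column replaced by its mean
(mean-substitution, the convention of the original analysis software) or
permuted (seeded `permutation` flag), divided by the baseline rate.
Misclassification — not a score residual — is the loss, because an
uncalibrated affine score can *shrink* its squared residual when an
informative feature is neutralised. A zero baseline is floored at 1e−12
with a warning; ratios remain usable for ranking.

## Synthetic data generator

The generator emulates a labelled corpus of enzyme subclasses plus
non-enzymes at desk scale. Class signal is carried by residue
*composition*, because recurrence-edge density — hence Tr_k — is driven
directly by composition. Defaults: 5 subclasses × 30 sequences + 60
non-enzymes, lengths uniform in 200–350 (the typical span of single
protein chains), each class holding a distinct dominant residue at a
class-specific dominant fraction, linspace(0.55, 0.9) across classes;
non-enzymes draw from the uniform composition over the 20 standard
residues. Sequences never contain X (it marks ambiguity in real inputs,
not a composition signal). Output is byte-identical under a fixed seed.

Two generator design points follow from the hump-shaped
composition-to-trace map described above:

- two classes dominated by *different letters at the same fraction* are
  indistinguishable to Tr_k (trace descriptors are blind to residue
  identity); class separation requires different dominance *strengths*;
- because the map is non-monotone with a peak near dominant fraction
  ≈ 0.65, very wide dominance ranges can make extreme classes collide.
  The default range (0.55, 0.9) spans the descending branch plus the peak
  shoulder, which keeps adjacent classes separated; fixtures that need
  extreme gaps (subclass-recovery tests) instead use compositions uniform
  over m letters (m = 2 vs 5 vs 20), whose Tr3 means sit ≥ 6 pooled SDs
  apart at fixed length 300.

What the generator does *not* emulate: real residue-usage profiles,
homology/redundancy structure, length–class correlations, multi-domain
architecture, or the heavy class-size skew of curated corpora (the largest
real subclasses are thousands of sequences, the smallest a handful).
Passing tests on generated data therefore demonstrate that the pipeline's
machinery — descriptor computation, profile/deviation arithmetic, model
fitting and evaluation — is correct and that composition-borne class
signal is recoverable; they do not certify classification accuracy on
real sequence corpora.

## Numerical and evaluation choices

- Percentages are carried at full precision and rounded to 2 dp only for
  display.
- MCC returns 0 with a warning when a confusion marginal is zero.
- Per-class correct rates are reported under neutral names
  (`rate_class_pos`, `rate_class_neg`): naming conventions for
  sensitivity/specificity differ between sources, including within the
  published tables this package's statistics are checked against.
- Wilks' Λ = 1/(1+λ) and canonical R = √(λ/(1+λ)) are single-discriminant
  identities; they are not valid for multi-discriminant fits. Bartlett's
  chi-square is deliberately not implemented: its sample-size correction
  cannot be reconciled exactly with the published N, and an approximate
  reproduction would be misleading.
- The pair-record train/validation split is a seeded permutation with
  round(0.70·n) training rows, not stratified; class profiles are not
  re-estimated per split.
- Problem sizes in the test and acceptance suites (hundreds of sequences,
  lengths ≤ 350, brute-force oracles at L ≤ 12) were chosen as the
  smallest sizes at which every claim under test is informative.

## Known limitations

- Only the first two EC digits are modelled; multi-label enzymes and the
  third/fourth digits are out of scope.
- The q-sequence/r-sequence entropy variants mentioned alongside θ_k in
  the source literature are undefined there and are not implemented.
- The linear scorer's subclass ranking is sequence-independent (see
  above); subclass assignment requires the perceptron scorer trained with
  `cross-class` pairs.
- Trace descriptors are composition statistics at heart; classes that
  differ only in residue *identity* or in sequence *order* beyond
  recurrence spacing are invisible to them.
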