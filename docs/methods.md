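# Methods

## Problem and model

A disulfide connectivity pattern of a protein with n cysteines is a set of
unordered cysteine-index pairs in which each cysteine appears at most once.
With exactly B bridges the pattern space has C(n, 2B)·(2B−1)!! elements —
choose the 2B bonded cysteines, then count perfect pairings; summing over B
(including the bridge-free term) gives the full space. `ssbond` predicts a
pattern in three steps:

1. every pair (a, b), a < b, of cysteines is encoded by a set of *feature
   functions* into a fixed-length vector;
2. a binary classifier turns each vector into a bonding probability,
   giving a symmetric n×n matrix;
3. the valid pattern maximizing the sum of its bond probabilities is
   extracted by maximum-weight perfect matching; for odd n the matching is
   run on all n subsets of n−1 cysteines and the best solution kept.

The modelling assumption is therefore that bonding is decided by pairwise
evidence (shared evolutionary profile, sequence separation) combined under
the one-partner-per-cysteine constraint; there is no explicit cooperative
term between bridges beyond what the matching enforces.

## Feature functions

Twelve families are implemented (see `ssbond.features`): seven
parameterless primary-structure functions (residue count, cysteine count
and parity, relative positions/indices and their differences), the cysteine
separation profile window CSP(w), and per annotation track the global
histogram, interval histogram, local histogram Hloc(A, w) and local window
LW(A, w). Conventions that the formulas leave open:

- feature order is member order, then cysteine a before b, then window
  offset ascending, then labels in track order (tree ensembles need stable
  columns);
- local histograms use offsets −⌊w/2⌋ .. ⌈w/2⌉−1 (a contiguous block of
  exactly w residues containing the cysteine — the Hloc grid contains even
  sizes, so a symmetric-inclusive window is impossible), average over the
  in-bounds positions only, and carry the boundary information in one
  out-of-bounds-fraction feature per cysteine;
- interval histogram endpoints are inclusive;
- the CSP center slot (distance of a cysteine to itself) is kept, so
  d(CSP) = w exactly; the constant-zero column is harmless to trees;
- PSSMs are consumed as weighted observed percentages divided by 100
  (values in [0, 1], rows not forced to sum to 1), keeping all feature
  formulas uniform over [0, 1] tracks; a logistic transform of the
  log-odds columns is selectable for workflows that prefer score space.

Window grids for selection: CSP {1, 3, …, 19}, Hloc {10, 20, …, 90},
LW {1, 5, 9, 11, 15, 19, 21, 25}. The production default feature set is
`LW:PSSM:15,CSP:17` (634 features per pair).

## Classifiers

- **Extremely randomized trees** (default): N = 1000 fully developed trees
  (min_samples_split = 2, no bootstrap), K = ⌈√D⌉ random split candidates
  per node. Each leaf carries the empirical bonded proportion of its
  training pairs; the ensemble probability is the mean over trees.
- **kNN** with the group-normalized l2 distance
  √(Σ_g (1/d_g) Σ_k ((x_gk−y_gk)/σ_gk)²): dividing by the per-component
  training standard deviation removes scale dependence, and the 1/d_g term
  keeps a 600-column window family from dominating a 1-column scalar
  family (duplicating a family's columns provably leaves the distance
  unchanged). Zero-variance components are excluded rather than divided
  by. Default k = 10, giving 11 probability levels; ties at the k-th
  distance keep earlier training samples for determinism.
- **RBF-SVM** operating in the same normalized space, with Platt-style
  probability calibration. Because the best (C, γ) depend strongly on the
  feature set, grids C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} are exposed for
  cross-validated tuning; defaults are C = 1, γ = 2⁻³.

## Matching

Exact maximum-weight perfect matching. For n ≤ 14 cysteines a bitmask
dynamic program is used: it matches the lowest unmatched cysteine first and
prefers the smallest partner among co-optimal choices, which yields the
lexicographically smallest optimal bond set deterministically. Above that,
networkx's blossom implementation provides the optimum and the same
tie-break is recovered by greedy refinement (fixing, for the lowest
unmatched cysteine, the smallest partner that preserves the optimal
total). Full cardinality is guaranteed even with zero-probability edges.
An exhaustive enumerator over all full patterns (guarded to n ≤ 10) serves
as an independent oracle in the tests and never backs the production path.

## Evaluation

Qp is the fraction of proteins whose predicted bond set equals the truth
exactly; Q2 the fraction of pairs (a < b, micro-pooled across proteins)
correctly labeled bonded/non-bonded; a macro (per-protein mean) variant is
available by flag. Proteins with fewer than two cysteines count in Qp
(correct iff predicted empty) and contribute no pairs. Binary accuracy and
the Matthews correlation coefficient (0 when its denominator vanishes)
cover the chain and bonding-state tasks.

## Forward feature-function selection

Candidates are grouped into parameterized families (one alternative per
window size). Greedy forward selection starts empty; each iteration scores
every alternative of every remaining family appended to the current set by
10-fold cross-validating the *whole pipeline's* Qp — not raw classifier
accuracy, since the two are imperfectly correlated — inserts the best and
drops its family. Ties go to the first candidate in enumeration order, and
all candidates within a run share one seeded fold assignment so greedy
comparisons are fair. The stopping rule is a fixed iteration budget
(default 5), with an optional no-improvement stop. The greedy score can
regress when every remaining addition hurts; this is logged as a warning
rather than forbidden.

The nested protocol re-runs the whole selection once per 90/10 train/test
split: selection only ever sees the train part, the held-out part provides
a per-iteration verification score, and overlapping splits are rejected —
evaluating on data used for selection is a classic source of
over-estimated scores.

The random sampling harness (for classifier comparisons) draws LW sizes
from Normal(15, 6) and Hloc sizes from Normal(40, 20), snapped to their
grids, and CSP sizes uniformly — declared defaults, exposed for override.

## Filter scenarios

The matcher always builds a maximal pattern, which is wrong for proteins
with free cysteines. Four filters address this: known/predicted chain
class (empty pattern for bridge-free chains) and known/predicted cysteine
bonding states (drop non-bonded cysteines and match the induced subgraph —
equivalent to zeroing their pair probabilities, and cleaner when the
admissible count is odd, in which case one bonded cysteine stays unpaired
and a warning is raised). The bonding-state threshold is 0.5 by default
and exposed in the configuration. The chain-predicted scenario derives its
chain call from the bonding-state predictor (any cysteine predicted
bonded); a standalone chain classifier over protein-arity features
(global histograms, Nr, Nc, parity) is also provided. A diagnostic counts
proteins where a truly bonded cysteine was predicted free, since the exact
pattern is then unrecoverable. All models are evaluated out-of-fold: no
test protein ever appears in the training folds of any model that scores
it.

## Synthetic data generator

`generate_dataset` emulates the statistical structure the pipeline
assumes, with signal strength s ∈ [0, 1]:

- **pair signal**: the two partners of each bridge share a prototype (one
  of six fixed two-column PSSM prototypes, drawn per bridge without
  replacement). The prototype is written *antisymmetrically* around each
  cysteine — prototype columns raised by s·0.2 on the upstream rows and
  lowered by s·0.2 on the downstream rows (half-width 2) over a
  U(0.2, 0.4) background — so the window mean stays at background level
  and only a position-resolved local window can read the signal, not a
  histogram. This is what makes the PSSM local window the planted-
  informative family for selection experiments;
- **state signal**: bonded cysteines carry a raised value on two dedicated
  columns of their own row, making bonding-state prediction learnable;
- **spacing signal**: cysteines bonded to their sequence neighbour sit
  closer (gap ≈ N(8, 2)) than unbonded neighbours (gap ≈ N(12, 4)),
  making the CSP informative;
- **composition signal**: bridge-free proteins over-represent the residues
  AGPST, making chain classification learnable from global histograms.

At s = 0 all four effects vanish exactly (the motif writes are additive
with amplitude s, gaps fall back to the base distribution), so the dataset
carries no information beyond chance. Gaussian observation noise
(sd 0.05) is added to all PSSM cells and values are clipped to [0, 1].
Strata fractions (all-bonded / bridge-free / mixed) mirror heterogeneous
benchmark collections. Generation is byte-deterministic given the config
seed.

What the generator does *not* emulate: real PSI-BLAST score distributions,
protein families and homology structure, inter-chain bonds, or annotation
errors correlated with structure. Passing tests therefore demonstrate that
the pipeline recovers the kinds of signal it assumes, at the planted
signal-to-noise level — not field performance on real proteins.

## Problem sizes and numerical choices

The test suite and examples run the pipeline at 60–500 proteins with
3-fold cross-validation and ensembles of 40–1000 trees, sizes chosen so
the full suite completes on one CPU in minutes while leaving the headline
checks (pattern recovery at 500 proteins with the production feature set
and N = 1000) at full strength. Matching ties are broken
lexicographically; probabilities are clipped to [0, 1] before matrix
assembly; weight comparisons in the matcher use exact float equality for
tie detection, with pattern weights always recomputed by one shared
summation routine so the DP, blossom and exhaustive paths agree bit-wise.

## Limitations

- Intra-chain bridges only; selenocysteine is not treated as bondable.
- The SVM path calibrates probabilities per LibSVM's Platt procedure,
  which is noisy for small training sets.
- Forward selection is greedy and can settle in local optima; families,
  not individual columns, are its selection unit by design.
- The exhaustive matcher guard (n ≤ 10) and enumeration guard (n ≤ 12)
  protect against factorial blow-up; the production matcher has no such
  limit.
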