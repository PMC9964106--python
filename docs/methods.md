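# Methods

## Problem and model

`mirlnc` classifies (miRNA, lncRNA) pairs as interacting or not from
sequence alone.  The classifier is a hybrid convolutional–recurrent
network: the pair is integer-encoded as one token row
`[miRNA | separator | lncRNA | padding]` (A=1, T=2, C=3, G=4, pad 0,
separator 5), embedded, passed through two convolution + ReLU +
max-pooling blocks that detect local sequence motifs, then through two
IndRNN layers that integrate motif evidence along the transcript, and
finally through dropout and a dense sigmoid head that emits an
interaction probability.  The IndRNN cell is

    h_t = ReLU(W x_t + u ⊙ h_{t−1} + b),

with a *vector* recurrent weight `u`: neurons recur independently, so
per-neuron gradient magnitudes across T steps scale as `u^T` and are
kept bounded by clipping `|u| ≤ c` after every optimizer step (default
`c = 2^(1/T)` for post-convolution length T, which allows mild
amplification over a full pass but no blow-up).  Training minimizes
binary cross-entropy by mini-batch gradient descent (plain SGD by
default; momentum and Adam are available) on a compact NumPy engine
with analytic backward passes for every layer; a numeric
central-difference check over all parameter groups is part of the test
suite.

Alongside the network, each sequence has a fixed 407-dimensional
descriptor used by the shallow-model path and by feature selection:
k-mer frequencies for k = 1, 2, 3 (4 + 16 + 64 values), gapped
compositions (64 + 256 values), and three structural descriptors

    DM = MFE / L,    E1 = n_pairs / (L/2),    E2 = (n_G + n_C) / L,

where `n_pairs` is the maximum number of nested base pairs and MFE the
energy assigned to that structure.  A pair vector is the miRNA block
concatenated with the lncRNA block (814 values).

### Gapped compositions

A gapped feature counts windows of `n_specified + n_gaps` positions,
aggregated over every placement of the gap (wildcard) positions within
the window.  The defaults (3 specified, 1 gap) and (4 specified,
2 gaps) produce the canonical 64- and 256-dimensional blocks; the
2-specified-letter variant is available through the same function.
With zero gaps the operation reduces exactly to k-mer counting, which
is asserted as a vector identity in the tests.  Counts are normalized
to frequencies by default so that 21-nt miRNAs and 4000-nt lncRNAs are
comparable; raw counts are one flag away.

### Folding

The built-in folder is the exact Nussinov dynamic program (O(L³)) over
Watson–Crick plus G:U wobble pairs with a minimum hairpin loop of 3 nt,
with a deterministic traceback (pairing the left end with the smallest
admissible partner is preferred over leaving it unpaired).  `n_pairs`
is therefore exact for the quantity E1 needs.  The energy is a per-pair
sum (GC −3, AU −2, GU −1, arbitrary units): it preserves the sign and
monotone structure DM needs without a nearest-neighbor thermodynamic
engine.  An external folding backend (any callable returning
dot-bracket + MFE, e.g. an RNAfold adapter) can be plugged in where
kcal/mol fidelity matters; its output is validated against the same
structural invariants.  Sequences longer than the 4000-nt dataset
filter never reach the folder.

### Dataset construction

Candidate non-interacting lncRNAs are aligned globally
(Needleman–Wunsch; match +1, mismatch −1, linear gap −2 — the standard
didactic scheme, configurable) against the interacting group, and
candidates whose best identity (matched columns over alignment length)
exceeds 0.80 are eliminated — strictly greater, so a candidate at
exactly 80% survives.  Negatives are uniform random (miRNA, retained
lncRNA) pairs without replacement.  SMOTE tops up a minority class in
feature space: `x + u (x_nn − x)` with `u ~ U[0,1]` and `x_nn` one of
the k = 5 nearest same-class neighbours (k = 1, the strict
nearest-neighbour reading, is a parameter away).  Sequences longer
than 4000 nt are dropped (boundary inclusive).

## Gorilla Troops Optimizer

Minimization convention throughout.  Per iteration, an exploration
phase moves each gorilla by one of three mechanisms — re-draw uniformly
in bounds with probability `p_migration` (default 0.03), a move
referenced to a random peer, or a local differential move — followed by
greedy per-index replacement; then an exploitation phase follows the
silverback (the incumbent best) when the decayed step size
`D = (cos(2 r4) + 1)(1 − t/T)` is at least `W = 0.8`, and otherwise
applies the competition update
`X ← X_sb − (X_sb − X)(2 rand − 1) A` (constant `A = 2`), again with
greedy replacement.  All candidates are clipped to bounds; the
evaluation budget is exactly `pop (2 iter + 1)`.  Best-so-far is
non-increasing by construction and bit-reproducible under a seed.

Binary mode thresholds `sigmoid(x) > 0.5` per coordinate (a stochastic
threshold variant is available) and scores subsets with
`OF = α error + (1 − α)|S|/d`, `α = 0.99`; the empty subset gets the
worst value 1.0 since the wrapped classifier is undefined on zero
columns.  The feature-selection driver wraps an L2 logistic regression
on standardized selected columns with a 30% hold-out, and caches OF per
bitmask.  The search warm-starts with the all-features subset in the
initial population — refining the complete set is both standard
feature-selection practice and a guarantee that the result is never
worse than using every feature; the remaining gorillas start uniform
random.  The hyperparameter tuner optimizes on the unit cube with
user-supplied decoders (log-uniform for rates, binning for categorical
sizes); failing training runs score worst rather than aborting the
search.

## Synthetic data: what it emulates and what it does not

The generator emulates the *shape* of a plant interaction dataset:
short miRNAs (uniform 20–24 nt), long lncRNAs (uniform within a
configurable range up to 4000 nt), i.i.d. background nucleotides with a
configurable G+C probability, and — in each positive pair — one
contiguous target site in which the lncRNA carries the reverse
complement of its miRNA with each position independently mutated at
rate 0.1 by default (a mutation always substitutes a different letter).
Negative pairs draw from lncRNAs that carry no planted site.  The
planted site is an explicit stand-in for a target predictor's
complementarity call, not a reconstruction of one; real transcripts
additionally have compositional structure, repeats, homologous families
and thermodynamically constrained accessibility that uniform
backgrounds lack.  Passing tests therefore demonstrate that the
pipeline can extract a bounded, known complementarity signal from
realistic sequence geometry — not that it attains any particular
accuracy on real wheat data.

## Study scale and numerical choices

The reproduction script and the end-to-end tests run one fixed desk
scale: 1,000 positive + 1,000 negative pairs, site mutation 0.1,
lncRNAs 200–800 nt, with 20 miRNAs against 1,230 lncRNAs — the
miRNA:lncRNA ratio (≈1:62) of the real resource scaled down ~15×, and
the lncRNA range restricted so that the O(L³) folds and the network's
input width stay tractable on a single CPU.  The network config for
this scale is embedding 8, conv blocks (48 filters, kernel 20,
pool 10) and (64, 8, 4), IndRNN 32+32, dropout 0.2, Adam at 0.01
decayed 10× at epoch 9, batch 64, 13 epochs: the first convolution
kernel spans a whole ~21-nt target site so filters can act as
site-template matchers, which generalizes to unseen lncRNA contexts
far better than short-kernel stacks; dropout is reduced from the 0.5
default because at this model and data size 0.5 under-fits within the
epoch budget.  Each cross-validation fold trains a small ensemble of
two differently-initialized models and averages their probabilities —
single training runs vary by a few accuracy points fold-to-fold and
the ensemble damps that variance.  Each fold also holds out 10% of its
*training* rows as an inner validation split, restores the parameters
of the best inner-validation epoch, and calibrates the decision
threshold on that split (test probabilities are shifted so the chosen
threshold maps onto the 0.5 rule); test rows are never touched before
scoring.  Batch-norm inference statistics are re-estimated each epoch
by an explicit calibration pass over (a 512-row sample of) the
training set, because momentum-averaged running statistics lag the
fast-moving weights early in training badly enough to corrupt
eval-mode predictions.  Inside the engine, max-pooling runs before the
ReLU (identical function — the max commutes with a monotone map — but
the nonlinearity then runs on the pooled tensor), and stride-1
convolutions use a single im2col GEMM.

Library defaults follow the published setup where one exists: dropout
0.5, batch size 128, learning rate 0.01 (an alternative printed value
of 0.1 is reachable via config), 50 epochs, two conv blocks, two IndRNN
layers.  Where the source was silent or ambiguous the choice is
documented at the definition site: embedding dimension, filter counts
and kernel/pool widths (all searchable through the tuner), BN placed on
the input projection before the activation, mean-over-time readout
(robust to padding-heavy tails; last-step readout available),
separator-token pair encoding (a two-tower alternative would be a
straightforward extension).

Five metrics are reported from confusion counts — specificity,
accuracy, precision, recall, F1 — with probability > 0.5 as the
positive call (a probability of exactly 0.5 is a negative call).
Ratios with zero denominators are reported as 0 with a degenerate flag
rather than raised, so sparse folds survive.  Cross-validation is
stratified (the data are balanced by construction; stratification
preserves it per fold) and summarized by the per-metric *median* across
folds, with the mean alongside.  Length-binned evaluation groups pairs
by maximum lncRNA length cumulatively (nested groups); disjoint ranges
are a flag away.

## Known limitations

- The built-in energy model is not thermodynamic; DM values are on an
  arbitrary (negative) scale unless an external backend is used.
- Uniform backgrounds make the planted signal close to the only signal;
  feature selection on such data favours the structural and
  composition features only weakly.
- The NumPy engine is single-threaded by design for reproducibility;
  wall-clock scales linearly with input width × filters.
- One planted site per positive pair; multi-site and partial-site
  positives are not modelled.
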