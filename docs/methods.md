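# Methods

## Model

A hairpin is a pair (sequence, dot-bracket structure) of equal length,
well nested, single bracket tier.  Its *ss-string* attaches the structural
state of every position (`(` → L, `.` → D, `)` → R) to the base, giving
one fully specified symbol per position over the alphabet
{A, C, G, U} × {L, D, R}.  Encoding is lossless; `decode ∘ encode` is the
identity, and every encoded structure has balanced L/R counts with a
nonnegative running L−R balance.  T/t are mapped to U and case is folded
on input, since public hairpin collections mix DNA/RNA conventions.

An *ss-motif* generalizes ss-symbols with the wildcards N (any
nucleotide) and S (any structural state), so a position can carry
sequence information only, structure information only, both, or neither.

### The ⟨L, W⟩ density constraint

Motif validity is defined on the *character* rendering of a pattern — two
characters per position, nucleotide character first:

* the first and last position each carry at least one defined character;
* every contiguous run of `W` characters contains at least `L` defined
  (non-wildcard) characters; a pattern spanning fewer than `W` characters
  must contain at least `L` defined characters in total.

Windows slide per character and are *not* required to align to position
boundaries.  This is deliberately the strictest of the natural readings:
under position-aligned windows the 11-position pattern
`U_S N_S N_S N_S N_L A_L N_L U_S N_S N_S N_L` would count as one valid
motif, whereas character-sliding windows expose an interior 12-character
run with only 3 defined characters and split the pattern into exactly two
maximal valid windows, which matches how over-sparse raw patterns are
expected to subdivide.  A position-aligned mode (`metric="position"`,
windows of `W` whole positions) is kept for sensitivity analysis.

Defaults are `L = 4`, `W = 12` — with fully wildcarded interior positions
this allows at most two all-wildcard positions per six-position window.

### Discovery and maximality

`discover_motifs` returns every pattern that is valid, occurs in at least
`K` distinct corpus strings (sequence support, not occurrence count), and
is *maximal*: no valid pattern that is strictly more specific (wildcard
characters replaced by literals) or longer (extended on either side) has
the identical occurrence list.  The implementation grows patterns
rightward from every seed symbol, propagating occurrence lists and
pruning branches whose completed density windows are violated or whose
support falls below `K`; maximality is enforced afterwards by grouping
patterns on a shift-normalized occurrence signature (identical occurrence
lists up to a uniform start offset necessarily share the signature) and
discarding any pattern subsumed within its group.  The contract is the
output *set*, not the algorithm: `brute_force_discover` re-derives the
same set by exhaustive enumeration over the symbol lattice and the
definitional maximality check, and the test suite requires set equality
on hundreds of randomized tiny corpora.

`K` is supplied as an absolute count; the pipeline derives it as
`round(0.75 · n)` of the class size by default, the canonical
three-quarters support level for this design.  An optional `max_len` caps
pattern length (maximality then holds relative to the capped pattern
space); the pipeline and the acceptance study cap at 6 positions, close
to the mean motif length the method produces, which keeps the
wildcard-combinatorial part of the search bounded.  Raising `K` can never
add motifs: validity and occurrence lists are independent of `K`, so the
catalog at a higher `K` is exactly the lower-`K` catalog filtered by
support (tested as subset inclusion).

Before weighting, catalogs are ordered lexicographically on the compact
motif text so that downstream ranking is reproducible; per-class catalogs
are merged by exact pattern identity, shared motifs receiving origin
`both`.

## Classifier

Features are raw occurrence counts of each motif in each hairpin
(overlaps included).  Raw counts are the default because they are the
simplest reading of "motif frequency"; binary and length-normalized modes
are provided (`mode=` in the feature builders) since the choice is not
forced.  No feature scaling is applied, so linear weights remain
interpretable as per-motif contributions.

The SVM is a soft-margin SVC (scikit-learn underneath; the decision
function `Σ_i α_i y_i k(x_i, x) + b` and its support-vector data are
re-exposed in a self-contained JSON model).  Defaults: `C = 1` for both
kernels and `γ = 1/k` (k = number of features) for the Gaussian kernel —
declared defaults, not estimated ones.  Normal-based feature weights are
`w_j = Σ_i α_i y_i x_ij` over the support vectors, defined for the linear
kernel only; for every training row `w·x + b` reproduces the solver's
decision value to 1e-6 relative tolerance (tested).

Motifs are ranked by **|w_j| descending** with lexicographic tie-breaks.
Magnitude rather than signed ranking is the default because
negative-class-discriminative motifs (large negative weights) belong near
the top of an informativeness ranking; a signed mode is available.
Incremental selection retrains on the top N = step, 2·step, …, k columns
and records ACC/SP/SE on an evaluation set; the best N is the accuracy
argmax, smallest N on ties (parsimony, reproducibility).  The evaluation
set is the held-out test set by default, mirroring the original protocol;
since that leaks the test set into model selection,
`incremental_selection_cv` scores each N by mean accuracy over stratified
folds of the training data instead and refits the winner on all of it.

ACC, SP, SE are confusion-count ratios; the ROC is a threshold sweep over
decision values with trapezoid AUC, which equals the Mann-Whitney rank
statistic (probability a random positive outscores a random negative,
ties half) — asserted property-wise against an independent computation.

## Permutation statistics

**RSS null.**  Each replicate pairs every observed motif with a window
drawn uniformly from a uniformly chosen training ss-string (among strings
long enough), masked to the motif's defined-character layout.  The null
set therefore conserves the length multiset and per-motif masks exactly
(asserted inside the sampler).  Smoothed one-sided empirical p-values
`(r + 1)/(n_reps + 1)` are reported in both directions for each notation
statistic, rather than a single two-sided value, because sidedness is a
per-question choice.  Under this mask-preserving null the layout-only
statistics (combined positions, up/down structure neighbours) are
invariants — every replicate reproduces the observed value and their
p-values are degenerate at 1.  `mask_mode="shuffled"` permutes each
motif's mask positions (conserving per-motif counts of defined nucleotide
and structure notations) and gives those statistics a nondegenerate null;
the mask-preserving mode remains the default.  Null-on-null calibration
(observed sets themselves drawn from the null) yields uniform p-values
for all notation-count statistics (KS-tested).

**Family test.**  The number of catalog motifs present in *every* member
of a family is compared with `n_reps` equally sized uniform subsets of
the precursor corpus; `p = (#{null ≥ observed} + 1)/(n_reps + 1)`.
Default 1000 replicates.

**Positions.**  Motif start positions are normalized as
`x' = (x − mir_start) · d̄ / d`, where `d = mir_end − mir_start` is the
hairpin's mature-arm span and `d̄` the mean span over the annotated set
(or a supplied constant).  `x' = 0` iff the motif starts at the mature 5'
end; the transform is invariant under jointly shifting annotations and
occurrences.  Coordinates are 0-based half-open internally and 1-based
inclusive in on-disk annotation files.

## Corpus hygiene

Multi-branched structures are rejected by the single-loop test (no `(`
after the first `)`, equivalent to "one terminal loop" for well-nested
strings).  Redundant hairpins are removed by a greedy keep-first scan
dropping any record whose global-alignment identity (matches / alignment
columns, end gaps counted) with an already-kept record exceeds the
threshold (default 0.9); greedy keep-first order makes the filter
deterministic and idempotent.  Secondary structures are always inputs —
an optional shell-out to an external `RNAfold` executable is provided as
an interface, but no folding is ever computed internally.

## Synthetic corpora

The generator emulates the study design this method is built for: two
equally sized classes of single-loop hairpins (default 608 + 608,
55–115 nt) drawn from one structural background — stems of 25–45 pairs
(Watson-Crick, G·U wobble with probability 0.1), per-site bulge
probability 0.05, terminal loops of 4–12 nt — differing only in planted
class motifs (default five per class, planted with probability 0.8 per
record).  Plantings overwrite sequence letters in a uniformly chosen
structure-compatible window; windows within a record never overlap, and
class motifs are planted in random per-record order so no motif is
systematically starved of windows.  Default random motifs define every
nucleotide (chance occurrences stay rare) and use `L` for any defined
structure notation (a compatible window then exists in any uninterrupted
stem run).  Family blocks descend from a single ancestral hairpin
carrying a family-private motif; members share the ancestor's structure
and mutate sequence positions outside the family-motif window at rate
0.1, mimicking precursor families whose members are similar along most of
the hairpin.  Mature annotations place `mir_start` a fixed offset
(default 5 nt) into the 5' arm with `mir_end` symmetric on the 3' arm.
Every record passes the hairpin validators and every planting is recorded
in a manifest that the occurrence scanner can verify.

What the generator does *not* emulate: thermodynamic realism (structures
are built, not folded), compensatory mutations in family stems, flanking
genomic context, and the composition biases of real coding-region
hairpins.  Passing tests on these corpora therefore demonstrate that the
machinery recovers planted signal and stays calibrated under a true null
— not that any particular accuracy will be attained on database hairpins.

## Problem sizes and numerics

The test suite runs the discovery-vs-oracle equivalence on 200 random
corpora of ≤ 8 strings × ≤ 20 positions (pattern cap 4); planted-signal
recovery on 20 seeds of 50 + 50 hairpins with 10 planted motifs against
500 masked-window decoys; and null calibration on 100 + 100 signal-free
corpora (5 seeds) plus 50-repetition KS uniformity checks at 99 inner
replicates.  The acceptance study uses a 120 + 120 corpus with ⟨4, 12,
0.75n⟩ discovery capped at 6 positions, a 484/608 train fraction,
selection step 100, 500 RSS replicates over the top-1300 ranked motifs
and 1000 family replicates — the same procedure as a full-size run at
sizes chosen to complete in about a minute.

All stochastic stages draw from generators spawned off a single run seed;
identical configs reproduce outputs byte for byte.  Pipeline run
directories are named by config hash, not timestamp.  Empty patterns,
wildcard-terminal patterns, and `K` above the corpus size are rejected or
return empty catalogs with a warning; degenerate SP/SE denominators are
guarded; ranking and catalog orders break all ties lexicographically.

## Limitations

* Discovery is exponential in the worst case (it is an exhaustive maximal
  pattern search); corpora of hundreds of long hairpins need the
  `max_len` cap, and the maximality guarantee is then relative to the
  capped pattern space.
* The redundancy filter is O(n²) pairwise global alignments.
* The family test assumes exchangeability of members with the corpus;
  p-values on very small catalogs are coarse because the common-motif
  count is a small integer.
* Layout statistics under the default RSS null are degenerate by
  construction (see above); use the shuffled-mask mode to interrogate
  them.
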