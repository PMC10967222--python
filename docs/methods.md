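# Methods

## The cross-impact model

The unit of data is a scored ordered pair: an integer in [−3, +3]
answering how progress on a source goal influences progress on a target
goal (−3 strongly restricting, 0 no influence, +3 strongly promoting).
A complete study of G goals scores all G·(G−1) ordered pairs; the scores
form a signed integer matrix `w` with rows as influencing goals, columns
as influenced goals and a structurally zero diagonal (self-interaction
is never scored).  Scores are integers only — the instrument is a
discrete seven-point scale — so non-integer input is rejected rather
than rounded, and every downstream quantity is exact integer arithmetic.

Influence measures:

- First-order influence of goal g is its row sum `D_g^Out`; influence
  received is the column sum `D_g^In`.
- Second-order influence of A on D sums the products of weights along
  every directed length-2 path: `I²(A→D) = Σ_i w[A,i]·w[i,D]`.  The zero
  diagonal makes the i = A and i = D terms vanish, so self-loops never
  contribute; this is asserted by tests, not special-cased in code.
- Total influence `I_g^Total = D_g^Out + Σ_{j≠g} w[g,j]·D_j^Out`
  propagates each direct score through the neighbour's own out-degree.

The expansion is truncated at second order by definition.  Longer paths
(Katz/eigenvector-style centralities) are a different method and are not
offered, even as an option, to keep the reported numbers interpretable
as "direct plus once-mediated influence".

Rankings use descending competition ranking ("1224"): a goal's rank is
one plus the number of strictly larger values, so ties share a rank.
Display order within ties follows goal-set order; the rank itself is
what carries meaning.

The focal-goal report defines net influence as direct plus second-order
(`net_on[j] = w[F,j] + I²(F→j)`, symmetrically for `net_from`), and
flags a positive feedback loop when both directions of a pair are
strictly positive.  The threshold is configurable (`feedback_threshold`,
default 0, strict inequality); raising it restricts the report to
stronger loops.

## Scoring workflow

The workshop module mirrors the participatory protocol: each group
scores a subset of pairs (stage `initial`), a different group re-scores
the same pairs (stage `review`), and every disagreement is a
discrepancy that must be settled before the matrix can be assembled.
Two resolution routes exist: a plenary consensus score (which may be a
compromise equal to neither group's value) or a plurality vote.  An
exact plurality tie raises an error instead of being tie-broken —
fabricating a majority where none exists would misrepresent the panel —
and the case is expected to go back to consensus.  The voting unit
(participant vs group) is whatever the caller puts in the ballot; the
module does not presume either.  Group-to-pair assignment is data (a
map), not a hardcoded five-group layout.

## Synthetic data generator

The generator emulates the study conditions this package was designed
around: 16 goals, 240 ordered pairs, a sign mixture of 7 restricting /
20 no-influence / 213 promoting interactions, five scoring groups.  Two
sign modes exist: exact class counts (default; placement uniformly at
random over off-diagonal cells, class sizes met exactly, which makes
fixture class sizes deterministic) and per-cell class probabilities
(for law-of-large-numbers-style studies).  Score magnitudes for nonzero
cells are drawn uniformly from {1, 2, 3}: the sign mixture constrains
only signs, and no magnitude distribution is available to emulate, so
uniformity is an explicit assumption rather than an estimate.

Mock workshops deal pairs round-robin to groups, with the reviewer
always the next group in cyclic order (scorer ≠ reviewer whenever there
are ≥ 2 groups).  Each pair's review score is independently perturbed
with probability `discrepancy_rate` by ±1, clipped to the scale and
re-drawn so it always differs from the initial score — small
disagreements, as plausible for expert panels re-scoring the same pair.
A single seed governs generation, with independent sub-streams for the
matrix and the perturbations so that changing the group count cannot
reshuffle matrix cells.

What passing tests show — and do not show.  The generator reproduces
the *structural* properties of a workshop matrix (completeness, sign
mixture, discrete magnitudes, group provenance, a controllable
disagreement rate).  It does not model the correlation structure of
real expert judgments: no clustering of promoting scores around
thematically adjacent goals, no group-level bias, no motivation text
semantics.  Green tests therefore certify the pipeline's correctness
and invariances, not any empirical claim about how actual SDG networks
are wired.

## Perturbation analysis

Rank stability is probed by Monte Carlo: each off-diagonal cell is
independently shifted ±1 with probability p (default 0.1, directions
equiprobable), clipped to [−3, +3]; the chosen ranking metric is
recomputed per replicate and the per-goal frequency of retaining its
unperturbed rank is reported, along with the full rank distribution.
Seeds are explicit arguments; identical seed and settings give
bit-identical results.  Default 100 replicates keeps the analysis
interactive at G = 16.

## Numerical and design choices

- All core quantities are exact integers (numpy int64); no floating
  point enters until perturbation frequencies, which are serialized at
  fixed 6-decimal precision so JSON reports are byte-identical across
  runs.
- Goal identifiers are normalized to upper-case condensed form
  ("sdg 3" → "SDG3") on ingest, giving stable join keys across files;
  display labels travel separately.
- The default goal set is SDG 1–16.  SDG 17 (partnerships for the
  goals) is excluded by default as too broad for pairwise scoring, but
  the goal set is fully configurable and nothing prevents including it.
- Matrix assembly demands completeness: a missing ordered pair is an
  error listing the pairs, because an unscored cell is indistinguishable
  from a scored 0 once in matrix form.  Duplicate final scores are
  tolerated only when they agree.
- The heatmap's diverging blue–white–red scale is anchored at ±3 — the
  instrument's range, not the data's — so zero is always white and
  colors are comparable across studies.  Network exports omit
  zero-weight pairs by default (only actual interactions are drawn);
  `keep_zeros` restores them.
- DOT export uses a small built-in serializer producing plain Graphviz
  syntax (nodes with code/label/degree attributes, edges with
  weight/sign).

## Problem sizes

Tests and the acceptance script run at the study scale where the scale
matters (16 goals, 240 pairs: classification, round trips, reports) and
at small G (3–8) for the brute-force path-enumeration oracles, which are
quadratic per pair; 100 random-matrix oracle comparisons, 50 workshop
round-trip seeds and ≤ 100 perturbation replicates characterize the
behavior fully because every computation is exact — repetition only
exercises placement randomness, not numerical noise.

## Known limitations

- The method's output is only as meaningful as the panel's scores; the
  package validates structure, not judgment.
- Second-order truncation means a goal influential only through long
  chains is under-ranked by construction.
- The magnitude distribution of synthetic scores is an assumption
  (uniform over {1, 2, 3}); analyses sensitive to magnitude skew should
  set `magnitude_dist` explicitly.
- Competition ranking is one convention for ties; published tables
  using fractional or dense ranking will differ on tied goals.
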