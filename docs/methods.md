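# Methods

## Problem and objective

`piswap` refines global pairwise alignments of protein–protein interaction
networks. An alignment is an injective partial map `M` between the vertex
sets of two undirected simple graphs `G_X`, `G_Y`, scored by

```
w(M) = α · Σ_{e∈M} t(e|M) + (1 − α) · Σ_{e∈M} s(e),   α ∈ [0, 1]
```

with `s` a non-negative cross-network similarity (typically BLAST bit
scores, raw or normalized) and `t((x,y)|M)` the number of matched pairs
joining a neighbor of `x` to a neighbor of `y`. Both graphs are treated as
simple: self-loops in input data are dropped (and counted), because `t` and
the edge-correctness metric are defined on neighborhoods of distinct
vertices. Scores are modeled as non-negative reals, not integers, since
normalized similarity data lives in (0, 1]. Partial mappings are allowed
throughout; an unmapped endpoint simply contributes no conserved edges.

A useful identity used everywhere in the implementation: each conserved
edge is seen once from each of its two matched endpoints, so
`Σ_{e∈M} t(e|M) = 2 · (# conserved edges)`. The topology term is therefore
computed as twice the conserved-edge count, and incremental move deltas
only re-examine edges touching a reassigned vertex.

## Seeding

* **Symmetrization.** Directed similarity rows `(i, j)` and `(j, i)` are
  collapsed to one unordered entry holding the larger value (BLAST is not
  symmetric). Duplicate rows within one direction also keep the maximum.
* **Normalization.** Optional division by the global maximum, mapping all
  scores into (0, 1] with the maximum at exactly 1. This is the simplest
  map with that guaranteed range; any positive rescaling leaves the
  optimal matching and the candidate rankings unchanged.
* **Initial matching.** The maximum-weight bipartite matching on `s`
  (the assignment problem), solved with
  `scipy.optimize.linear_sum_assignment` on identifier-sorted score
  matrices. Zero-score pairs are never matched — they add no weight and
  leaving nodes unmapped is legitimate. Among equal-weight optima a
  weight-neutral pairwise-exchange pass pushes toward the lexicographically
  smallest pair list, making the output deterministic and reproducible.
* **α auto-tuning.** `α* = 2·S₀ / (2·S₀ + T₀)` where `S₀` and `T₀` are the
  sequence and topology totals of the initial mapping, clamped to
  [0.01, 0.99]. Pre-clamp, `α*·T₀ = 2·(1 − α*)·S₀` exactly: the refinement
  weighs topology twice as heavily as the (purely sequence-based) start
  realized it. With no sequence signal at all (`S₀ = 0`) the objective
  degenerates and `α = 1` (pure topology) is used unclamped.

## Local search

* **Candidate sets.** `N_c(x)` holds the `c` best-scoring partners of `x`
  (descending score, ties by identifier); default `c = 20`, configurable
  because a value near the maximum degree is sometimes preferable. In
  sequence-free settings candidates are ranked by degree closeness
  (`|deg(x) − deg(y)|` ascending, ties by larger min-degree, then
  identifier) — a cheap topology proxy that needs no scores.
* **Moves and admissibility.** A 2-swap of `(x, y), (x′, y′)` is admissible
  iff `y′ ∈ N_c(x)` or `x′ ∈ N_c(y)`; a reassignment of `x` to an
  *unmatched* `y_new` needs `y_new ∈ N_c(x)`; a 3-move must introduce at
  least one edge whose partner lies in a candidate list. Unmatched-target
  moves are on by default (and toggleable): without them improving
  reassignments to unmatched vertices — common when the initializer leaves
  nodes out or `|Y| > |X|` — would be unreachable.
* **3-Opt neighborhood.** For a triple of matched pairs all five
  non-identity reassignments of the three partners are evaluated (three
  pairwise swaps, two 3-cycles). Triples are enumerated as (admissible
  2-swap) × (third matched pair adjacent in `G_X` or `G_Y` to one of the
  four touched vertices), capped at `10·|M|` triples per scan. This is the
  natural generalization of the 2-swap neighborhood; pairwise-unreachable
  improvements such as cyclically shifted optima are exactly what the
  3-cycles repair.
* **Acceptance and termination.** First strictly improving move in a
  deterministic scan (pairs by x-identifier, candidates in rank order; an
  optional seed shuffles the scan order for robustness studies), with a
  strict-improvement tolerance of 1e−9 to rule out floating-point
  livelock — ties are never accepted. When 3-Opt is enabled, 2-moves are
  scanned to exhaustion before any triple is tried; consequently the 3-Opt
  final objective never falls below the 2-Opt final objective from the same
  start, by construction. The objective strictly increases per accepted
  move and is bounded above, so the loop terminates; `max_iterations`
  (default 10000, far above observed swap counts) caps accepted moves as a
  safety valve and is reported in `terminated_by` when hit. The trajectory
  re-evaluates the full objective after every accepted move, so
  accumulated-delta drift cannot contaminate reported values.

## Evaluation

* **EC ratio** = conserved edges / `min(|E_X|, |E_Y|)`. Normalizing by the
  smaller edge set keeps the statistic comparable when network sizes differ
  by orders of magnitude (a 452-edge network aligned to a 38,000-edge one
  should be able to reach EC 1). Empty edge sets give 0.
* **FC.** Each GO term is standardized to its `is_a` ancestors (term
  included) at depth 1–5 from its namespace root, root excluded; depth is
  the shortest `is_a` hop count, and only `is_a` edges are traversed
  (`part_of` is ignored — the "GO tree" reading). A protein pair scores the
  *median* over the cross product of its term pairs of the Jaccard overlap
  of standardized sets; the mapping's FC is the mean over pairs where both
  proteins have usable terms. Unscorable pairs are excluded from the mean
  rather than scored 0, since typically only 60–70% of network proteins
  carry GO annotations at all; the count of scorable pairs is reported
  alongside.

## Synthetic data

* **Geometric random graphs** (`geometric_random_graph`): `n` uniform
  points in the unit square (dimension configurable), connected at the
  `m` smallest inter-point distances — equivalently the disk graph at the
  smallest admitting radius, trimmed to exactly `m` edges. Exact counts
  matter because a randomized network must match its real counterpart's
  size; the usual radius-parameterized generator only matches in
  expectation.
* **Planted instances** (`planted_instance`): `G_X` is Erdős–Rényi (or
  geometric); `G_Y` is a relabeled copy with a fraction `rho_e` of edges
  removed and the same number of random non-edges added (false
  negatives/positives of interaction screens). True pairs `(x, truth(x))`
  score `s_true ± 10%`; for a fraction `rho_s` of proteins the true-pair
  score is deleted and three random decoy pairs get scores uniform in
  (0, `s_noise`] — orthologs invisible to sequence comparison, plus
  spurious hits. Defaults: `n = 100`, `p = 0.1`, `rho_e = 0.2`,
  `rho_s = 0.3`, `s_true = 1.0`, `s_noise = 0.5`. The score scales put true
  orthologs at the top of the normalized-score range with decoys at most
  half as strong, a regime comparable to cross-species BLAST data.
  Everything is deterministic given the seed.

  What the generator does **not** emulate: scale-free degree structure,
  protein families/paralogy (decoys are uniform, not sequence-clustered),
  and size asymmetry between species. Passing recovery tests therefore
  shows the machinery works under controlled noise, not that real
  cross-species alignments will improve by the same margins.

## Problem sizes in tests and the acceptance script

Exhaustive-oracle tests enumerate all matchings of instances with at most
6 + 6 vertices; recovery studies use 20 replicates at `n = 100` and the
sequence-free robustness runs `n = 80` geometric graphs — sizes at which
every study completes in seconds while leaving hundreds of swap decisions
per run. The acceptance script derives replicate seeds from `--seed`, so
all reported numbers are reproducible.

## Known limitations

* First-improvement scanning makes the *final mapping* depend on scan
  order (any local-search caveat); the objective guarantees do not.
* The lexicographic tie-break of the initial matching canonicalizes via
  pairwise exchanges; exotic multi-cycle ties may settle on a different
  equal-weight optimum.
* FC needs `is_a`-connected ontologies; terms whose only path to the root
  uses other relations standardize to small or empty sets.
* The 3-Opt triple cap (`10·|M|` per scan) trades completeness of the
  triple neighborhood for bounded scan cost; raising it only helps on
  pathological instances.
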