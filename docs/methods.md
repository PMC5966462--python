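# Methods

## Model and assumptions

The detector operates on simple undirected, unweighted graphs. Input
normalisation enforces the model: self-loops are dropped and parallel edges
collapsed (both logged), because the clustering-coefficient and similarity
formulas assume `u ∉ N(u)` and 0/1 adjacency. Disconnected graphs and
isolated vertices are accepted — an isolated vertex trivially self-nominates
and stays a singleton community. Graphs with no edges at all are rejected:
modularity, the objective of the merge phase, is undefined there.

## Voting phase

Each vertex votes once, in ascending order of its local clustering
coefficient `cc(v)` (ordered-pair form). The rationale: a high-degree hub
has a sparse neighbourhood and hence low `cc`, so it votes early, finds no
stronger neighbour, and becomes a candidate before its neighbours' turns —
seed clusters then grow around hubs. Rules, in precedence order, on `u`'s
turn:

1. already nominated, or no neighbour of strictly larger degree → self-vote,
   candidate;
2. otherwise pick the most similar neighbour `v` among those of strictly
   larger degree; if `sim(u,v) = 0` → self-vote, candidate;
3. if `v` has not voted for anyone else → nominate `v`, vote `v`;
4. if `v` voted for `w ≠ v` → vote `w`.

Rule 4 never needs chain resolution: by induction every recorded vote target
is a candidate, which the implementation asserts rather than loops over.
A vertex that has voted for another vertex can never become a candidate
afterwards — later voters that would have picked it are redirected to its
target by rule 4.

Design choices where the procedure is genuinely open:

* **Degree ties count as "locally maximal"** (rule 1 triggers when no
  neighbour has *strictly* larger degree). The candidate pool of rule 2 is
  defined by strict inequality, so any other reading leaves rule 2 empty on
  regular neighbourhoods.
* **`cc(v) = 0` for degree ≤ 1** (degenerate denominator). Such vertices
  cannot head dense clusters; voting them early is harmless because rules
  2–4 still attach them to hubs, or make them singletons.
* **Similarity for non-adjacent pairs** uses the set form
  `|N(u)∩N(v)| / |(N(u)∪N(v))\{u,v}|` with 0/0 → 0. For adjacent pairs this
  equals the `|union|−2` form exactly; for non-adjacent pairs (needed when
  summing over community cross pairs) the literal `−2` denominator could be
  zero or negative, while the set form stays in [0, 1].
* **Tie-breaks** are total orders everywhere: voting order is
  (cc ascending, degree descending, label ascending); the rule-2 argmax
  breaks similarity ties by (degree descending, label ascending). Degree
  expresses influence; labels make the order total and deterministic.

## Merge phase

Seed clusters are the initial communities. Bookkeeping uses the convention
`e_ii = L_i/m`, `e_ij = A_ij/(2m)` for `i ≠ j`, `a_i = (Σ_{v∈C_i} deg v)/(2m)`
— the unique convention under which the closed-form increment
`ΔQ_ij = 2(e_ij − a_i a_j)` equals the exact change of
`Q = Σ_i (e_ii − a_i²)`; the test suite verifies the identity against a
from-scratch double-sum modularity oracle after every merge
(tolerance 1e−9).

Only pairs with `SIM(C_i, C_j) > 0` are mergeable. `SIM` is additive under
merges (it is a sum over cross pairs), so all pairwise vertex similarities
are computed once at initialisation — vectorised through the sparse
common-neighbour matrix `A·A`, which also restricts the candidate pairs to
those at graph distance ≤ 2 — and merged rows are summed thereafter.

The best pair maximises ΔQ with ties broken by larger SIM, then smallest
`(i, j)`. Because merged communities receive fresh ids, `e_ij` and `a_i`
are immutable for live ids, and a lazy-deletion max-heap returns exactly
the brute-force argmax (property-tested) at O(log) amortised cost.

Greedy ΔQ is not monotone, so the procedure records the whole dendrogram
and returns its earliest maximum-Q level, the untouched seed partition
included — guaranteeing the returned Q is never below the seed Q. A
`stop_at_nonpositive` policy is exposed for the cheaper behaviour of
halting at the first non-positive increment; `max_q` is the default.

## Metrics

NMI uses the contingency-table form `2·I / (H₁ + H₂)` with natural
logarithms. Zero-entropy edge cases (either partition a single community)
return 0, the standard limit of 0/0; values are clamped to [0, 1] against
floating-point excursions. An independent entropy-based implementation and
scikit-learn's `normalized_mutual_info_score` serve as oracles in tests.

## Synthetic benchmarks

`lfr_graph` follows the LFR construction: degrees sampled from a truncated
power law (exponent magnitude 2) whose lower cutoff is solved by bisection
to hit the target mean; community sizes from a truncated power law
(exponent magnitude 1) adjusted to sum exactly to `n`; vertices assigned to
communities most-demanding-first under the capacity constraint
(internal degree ≤ size − 1, capped when infeasible); internal and external
stubs wired by random matching with re-queue rounds, dropping irreparable
stubs (a per-community parity stub is dropped rather than externalised, so
`mu = 0` yields strictly intra-community edges). Exponents are stored as
magnitudes. The two standard parameter sets are exported as `LFR_1000`
(n=1000, mean degree 30, max 50, sizes 30–100, mu 0.5) and `LFR_5000`
(n=5000, mean degree 20, max 100, sizes 50–150, mu 0.6).

What the generator emulates: heavy-tailed degrees and community sizes and a
controlled mixing fraction (realised `mu` is within 0.05 of target,
asserted in tests). What it does not: degree-sequence exactness (rounding,
parity and repair drops leave the realised mean degree within a few percent
of target), degree–community correlations, weights, overlap. Passing the
benchmark tests therefore shows recovery under heavy-tailed, mixed
community structure — not performance on any particular real-world network.

`planted_partition` (networkx-backed Bernoulli blocks) and
`ring_of_cliques` (deterministic; two cliques degenerate to a single
bridge) provide hand-checkable fixtures.

## Problem sizes and numerical choices

The benchmark reproduction protocol uses ten seeded instances per parameter
set and reports means; ten 1000-vertex instances run in seconds, ten
5000-vertex instances in a few minutes on one CPU. Property tests run on
random graphs up to 200 vertices, where the from-scratch oracles are cheap.
Float comparisons in tie-breaks are exact (all quantities are small
rationals over `(2m)²`), which, together with the label-based orders, makes
the whole pipeline reproducible bit for bit.

## Known limitations

* Modularity-based merging inherits the resolution limit; very small
  communities attached to large ones may be absorbed.
* The similarity gate requires a shared neighbour for any merge, so
  tree-like regions fragment into singletons that can never merge; the
  max-Q selection mitigates but does not remove this.
* Weighted, directed and overlapping variants are out of scope.
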