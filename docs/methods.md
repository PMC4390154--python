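# Methods

## Model

The detector treats disease-module identification as iterative seed
expansion under a connectivity null. Given an undirected simple interaction
network with `N` nodes and a seed set of size `s0`, the null hypothesis for
any candidate protein of degree `k` is that its neighbors are an unordered
uniform draw from the other `N − 1` proteins, so the number of links to
seeds `k_s` is hypergeometric. The connectivity p-value is the upper tail
`P(X ≥ k_s)`. At each iteration every node adjacent to the current module is
scored, the smallest p-value is absorbed, and the module size `s` grows by
one; `N` is held at the full network size throughout. Because `s` grows,
p-values from different iterations are not comparable with each other and no
p-value threshold is used as a stopping rule; the iteration budget is a
user choice (default 200, where validation signal typically plateaus on
real disease data).

Assumptions worth stating: interactions are unweighted and undirected;
identifiers are opaque strings (no gene-ID mapping); the network is treated
as error-free within a run (noise is studied via the perturbation module,
not modeled in the statistic); and seeds absent from the network are
excluded from `s0` and reported separately rather than counted.

### Seed weighting

A weight `α ≥ 1` on the *original* seeds is implemented by the virtual
duplication transform: `N' = N + (α−1)s0`, seed count `α·s0` plus
agglomerated nodes at weight 1, and for a candidate with `k_s,w` links to
weighted seeds, `k' = k + (α−1)k_s,w` and `k_s' = k_s + (α−1)k_s,w`. For
integer α this is exactly equivalent to materializing `α−1` copies of each
seed with its interactions (verified by a property test against explicit
duplicated graphs); non-integer α is accepted through real-valued
log-gamma binomials and reduces continuously to the integer case.

### Numerical choices

All probability work is in log space via `gammaln`; tail sums use a
log-sum-exp reduction, so p-values far below the underflow point of naive
products (1e-23 and smaller occur on real interactomes) remain exact to
~1e-10 relative error against rational arithmetic. Ties in p-value are
broken by higher `k_s`, then lower `k`, then lexicographic identifier,
making every run fully deterministic. The per-iteration argmin uses the
dominance pruning (per `k_s` class keep lowest `k`, then per `k` keep
highest `k_s`), which is exact because the tail is strictly monotone in
both arguments away from saturation at p = 1; at p = 1 (only possible for
`k_s` classes whose links are forced) the tie-break rule coincides with the
pruning choice. Full rankings memoize one exact evaluation per distinct
`(k, k_s)` pair.

## Localization statistics

LCC significance draws `n_random` node sets of the seed size uniformly —
no degree matching, so the null asks only "how much do equally many random
proteins cluster" — and reports `z = (observed − mean)/sd` plus the
empirical `p = (r+1)/(n+1)`, where `r` counts draws with LCC at least the
observed; the +1 correction keeps a never-exceeded observation at
`p < 1/(n+1)` instead of 0. Default `n_random` is 1e5 (desk-scale; raise to
1e6 for publication-grade empirical p resolution — the z estimate itself is stable well
below that). A null with zero spread sets a `degenerate` flag instead of
crashing. Local modularity R counts, among all edges incident to boundary
nodes (community members with an outside link, each edge once), the
fraction staying inside the community; an unbounded community (no boundary)
has R = 1 by convention, and edges with both endpoints on the boundary are
interior edges.

## Synthetic benchmarks

Two planted-module constructions: *shells* (a start node plus its radius-2
breadth-first ball) and *connectivity-significance modules* (grown from one
start node by the detector's own rule to a target size, 200 by default —
the putative size of a complete disease module). Recovery experiments
remove `floor(f·size)` members uniformly (f ∈ {25%, 50%, 75%} in the
standard protocol; always ≥1 kept and ≥1 removed), rerun the detector from
the remainder, and record recall of the removed members per iteration. The
same protocol accepts a real seed set, optionally confining removal to the
seed LCC, and accepts any ranking callable so the random-walk baseline runs
under identical conditions.

The synthetic background is Barabási–Albert preferential attachment, which
reproduces the two features the statistics are sensitive to — a heavy
degree tail with hubs and a single giant component. It does *not* reproduce
the real interactome's clustering coefficient, community structure, or
ascertainment biases (literature-studied proteins have inflated degrees),
so passing benchmarks demonstrate correctness and the qualitative behavior
of the method, not expected recall on real diseases. Bench sizes used by
the test suite and the acceptance script (backgrounds of 500–2,000 nodes
at mean degree ~10–20, modules of 20–40 nodes, 20–50 replicates, LCC nulls
of 2e3–1e4 draws) are the package's desk-scale defaults; every size is a
parameter and the generators' own defaults keep the full-scale protocol
values (module size 200, removal fractions 25/50/75%, restart 0.4).

## Perturbation and robustness

Pruned networks remove `floor(f·E)` uniformly chosen links keeping all
nodes; partially rewired networks split `floor(f·E)` links into stubs and
re-pair them uniformly (configuration model), re-drawing pairings that
would create self-loops or duplicates for up to 100 shuffle passes and
falling back to degree-preserving double-edge swaps for the rare stubborn
remainder, so the output is always simple with the exact input degree
sequence. Both are bit-reproducible under a seed.

N−1 analysis reruns the detector once per left-out seed. Deviation at
iteration t is `1 − |top-t ∩ top-t|/t` against the original run;
persistence is the fraction of iterations with deviation > 0 (a deviation
"persists" at an iteration iff it is strictly positive there — the
operational reading of an otherwise qualitative notion). The
perturbed-network variant summarizes rankings by the same top-t overlap
curve.

## Random-walk baseline

The comparison prioritizer is a random walk with restart: at each step the
walker moves to a uniform neighbor and resets to a uniform random seed with
probability r = 0.4. Rather than simulating the walker, the implementation
computes the equivalent stationary fixed point `p = r·u + (1−r)·W·p`
(`W` column-normalized adjacency, `u` uniform on seeds) by power iteration
to an L1 tolerance of 1e-10 (max 10,000 steps; both are documented design
choices). Columns
of isolated nodes return their mass to the restart vector so scores always
sum to 1. Non-seeds are ranked by descending score, ties lexicographic.

## Annotation validation

Terms (GO or pathway collections, consumed as flat GMT; evidence-code
filtering and ontology propagation are upstream preprocessing) enriched in
the seeds — one-sided Fisher exact test, Bonferroni-corrected p < 0.05 —
form the reference set; the level defaults to the conventional 0.05 and is
exposed as a parameter. A ranked gene is a true positive iff it carries a reference
term. Window significance at iteration i Fisher-tests the TP count among
the genes ranked in `[i − w/2, i + w/2]` (w = seed count by default, which
makes windows comparable across iterations and to the seed set itself)
against the background rate; the background universe is the annotation
background minus the seeds (windows never contain seeds, which are not part
of the ranking). The synthetic-annotation generator plants `n_terms` terms
of size `coverage·|module|` with a `noise` fraction of members drawn
network-wide, so `noise = 1` is an exact null and `noise = 0, coverage = 1`
makes every term the module.

## Known limitations

- Uniform (not degree-preserving) random sets in the LCC null mean hubs in
  a seed set inflate z slightly; this is the standard protocol but is
  worth remembering when seed degree distributions are extreme.
- The recovery "insensitivity to removal fraction" is a distributional
  statement (overlapping interquartile ranges), not equality of means; at
  small module sizes the 75% condition is noticeably noisier.
- Exact reproduction of a published module on real data can be sensitive to
  the tie order among equal p-values; the tie rule here is documented and
  deterministic but other implementations may differ by a few late picks.
- The CLI loads the network per invocation; for repeated analyses on a
  large interactome use the library API and reuse the `Interactome`.
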