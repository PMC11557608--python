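# Methods

This note records the models implemented in `uprnet`, the conventions and
numerical choices behind them, what the synthetic generator does and does
not emulate, and the known limitations.  It states nothing the test suite
or `scripts/acceptance.py` do not themselves compute.

## Networks and ingestion

The substrate is an undirected simple graph over protein identifiers
(`networkx.Graph`): no self-loops, no parallel edges.  STRING-style TSV
exports list one record per direction with a combined confidence score;
`parse_interaction_tsv` collapses `(a,b)`/`(b,a)` duplicates, drops
self-pairs, applies an **inclusive** score threshold (`score ≥ 0.400` by
default, the database's medium-confidence cut), and auto-detects the
integer 0–999 score scale (any score > 1 divides the column by 1000).
Identifier case is preserved verbatim; no gene-symbol normalization is
attempted.  Isolated nodes survive only when declared through an explicit
node list, since interaction exports cannot carry them.

Reports quote the directed-record count `2M` (`edge_record_count`), the
convention interaction databases use, while the in-memory graph stores `M`
undirected edges.  Density is `2M/(N(N−1))`, which equals
records`/(N(N−1))` under that convention — the published per-organism
densities follow from the printed node and record counts alone, which is
what the density acceptance check exploits.

## Descriptors

- **Closeness** is the raw reciprocal distance sum `C(x) = (Σ_y d(x,y))⁻¹`,
  not the rescaled variant most libraries default to; on a disconnected
  graph the sum runs over the node's own component (the raw formula is
  undefined across components).  The per-organism averages of order 10⁻³
  are on this raw scale.
- **Betweenness** is reported as raw unordered-pair counts (values of
  order 10–180 on ~200-node networks); the min–max-scaled variant is a
  separate column.
- **Clustering** is the realized fraction of neighbor pairs that are
  edges, 0 for degree < 2.
- **Barycenter** is the minimum-eccentricity node; ties break by lower
  total distance, then lexicographic id, so the result is deterministic.
- Distance-based aggregates (diameter, barycenter, average path length
  `l`, efficiency `E`) on a disconnected network are computed on the
  largest connected component with a logged warning.
- **Normalizations**: `k/(N−1)` for degree, `(N−1)·C` for closeness,
  min–max for betweenness (identically 0 when all values coincide).  The
  degree normalization is the per-node fraction of possible neighbors;
  on the published twelve-organism table it reproduces the printed
  normalized degrees to within rounding, which the alternative reading
  `2M/N` does not.
- **Communities**: Louvain at resolution 1.0 (networkx implementation),
  seed-controlled traversal order, modularity of the returned partition.
  An edgeless graph yields singleton communities with `Q = 0`.

## Configuration-model null ensembles

Replicates preserve every node's degree exactly: random stub matching
with rejection of self-loops and multi-edges is attempted first (40
shuffles); failing that, the sequence is realized deterministically by
Havel–Hakimi and randomized with seeded double-edge swaps (4M swaps),
which cannot change the degree sequence.  Sequences with a unique simple
realization (e.g. a star) reject every swap and return that realization,
as they must.

z-scores use the native normalized aggregate against the mean and
**sample (n−1) standard deviation** of the R = 10 replicate aggregates
(small-ensemble convention; R is configurable).  Zero ensemble spread
flags the z-score undefined rather than dividing by zero.

The paired signed-rank test pairs each node's native value with that
node's ensemble-mean value.  The two-sided p-value comes from the exact
permutation distribution of `W⁺` for up to 25 non-zero differences —
computed by dynamic programming over tie-averaged (doubled) ranks, which
equals full 2ⁿ sign enumeration but stays tractable — and from the normal
approximation with continuity correction beyond that.  All-zero
differences are degenerate and return p = 1 with a warning.  Cross-network
comparisons are pairwise Kruskal–Wallis tests with Bonferroni correction
(factor = number of unordered pairs, capped at 1, NaN diagonal).
Dendrograms use Euclidean distance with average linkage (UPGMA), the most
common default, configurable.

## Generalized Hamming Distance

Adjacency weights (1 for an edge, 0 otherwise) are centered by the global
mean over ordered `i ≠ j` pairs, and the distance averages the **squared**
centered differences.  The squared form is deliberate: without the square,
mean-centering forces the sum to vanish identically for every input pair,
so a linear version cannot produce non-zero distances at all (it is kept
as a `linear=True` debug mode).  Consequences worth knowing: identical
networks are at distance 0; a complete and an empty graph are also at
distance 0 (uniform density is removed by centering); the hand-computed
3-node example — path `{ab,bc}` vs `{ab,ac}` — gives exactly 2/3.  Global
(not row-wise) centering is used.  The ensemble statistic is the plain
mean of `dGHD(native, replicate_k)` over the ensemble.

## Robustness

Attack orders rank nodes **once on the intact network** (static ranking;
the least "important" nodes are removed first under `ascending`, ties
lexicographic); `random` is a seeded shuffle.  After each removal the
trace records the exact integer LCC size `n_i` (so `G_i = n_i/N` carries
no float error) and the efficiency drop `ΔE_i = (E−E_i)/E`.

`E_i` keeps the intact network's `N(N−1)` pair count as the fixed
denominator, with removed or mutually unreachable pairs contributing
zero.  This makes `ΔE_i` non-decreasing and bounded in [0,1] along any
removal order — computing `E_i` on the surviving LCC instead can *raise*
efficiency when a small dense component survives, which would make the
drop non-monotone and sign-indefinite.

`R = N⁻¹ Σ G_i` over the full sequence: 0.45 for `K₁₀` under any order,
0.16/0.40 for the 5-star under hub-first/leaves-first orders.  Jump
detection compares `G_{i−1} − G_i` (with `G₀` the intact LCC fraction)
against the threshold **inclusively** ("at least 10%"), in exact rational
arithmetic (`Fraction(n_{i−1}−n_i, N) ≥ Fraction("0.10")`) so a drop of
exactly the threshold — every removal on a complete graph — is flagged
rather than lost to binary rounding.  The threshold is a fraction of the
total N, since G is already N-normalized.

## Structural controllability

Undirected interactions are treated as two opposed directed edges with
**independent** generic weights (dyadic rationals `k/64`, `|w| ∈
[0.5, 1.5]`, random sign), which is the reading of the linear dynamics on
a symmetric pattern that makes structural-controllability theory
applicable; binary weights can produce non-generic rank deficiencies and
are never used for verification.

Minimum dedicated inputs are computed per weakly connected component:
the unmatched in-copies of a maximum matching in the bipartite out/in
doubling must receive inputs (`n_c − |M*|` of them), and accessibility
additionally requires a driver inside every root strongly connected
component of the condensation.  Unmatched nodes are steered into root
SCCs where possible (a weighted-matching construction: real edges weigh
more than all coverage bonuses combined, so coverage never sacrifices
matching cardinality); each root SCC that no unmatched node can cover
contributes one extra driver.  For a connected undirected network the
bidirectionalized graph is strongly connected, the condensation has a
single root, and the count reduces to the classic `max(N − |M*|, 1)`.
The test suite checks the full computation against exhaustive subset
search with numeric generic-weight Kalman ranks on a 100-graph corpus
(directed and undirected, N ≤ 8), where the naive formula alone would
fail on graphs with several inaccessible components.

Alternative minimum sets are enumerated as the minimal unmatched sets of
maximum matchings (feasibility-pruned depth-first search, one
Hopcroft–Karp check per branch), extended by root-SCC representatives
where accessibility requires, deduplicated as node subsets, and truncated
at a cap (default 64) with a flag.  For a component with a perfect
matching every singleton is a valid minimum set.

Kalman verification builds `C = (B, AB, …, A^{N−1}B)` and checks
`rank(C) = N`: exact rational Gaussian elimination for `N ≤ 12` (the
generic weights are exactly representable, so this path has no tolerance
at all), and above that a numeric rank of the controllability matrix
assembled from `A` rescaled by its spectral norm (rank-invariant, keeps
the powers from overflowing) with SVD tolerance.  A failed check is
retried once with a second weight draw before reporting failure.  The
exact cutoff sits at 12 rather than higher because rational entries of
`A^{N−1}` grow without bound and elimination cost explodes; beyond ~64
nodes the numeric Kalman matrix is ill-conditioned to the point of
meaninglessness, so driver results for larger networks report
`verified = False` rather than a numerically hollow `True`.

## Synthetic data

The generator provides three layers:

1. **Canonical graphs** (star, path, cycle, complete, two-clique bridge,
   empty) with deterministic labels — analytic oracles for every stage.
2. **Profile sampling** — exact realization of explicit (Erdős–Gallai
   checked) degree sequences, or planted-partition graphs (default
   `p_in = 0.9`, `p_out = 0.05`, the regime where Louvain recovers the
   planted blocks perfectly, which the acceptance suite asserts).
3. **Organism emulation** — one network per published organism pinning
   the printed node count, edge-record count (hence density, which
   depends on N and M alone), and the barycenter hub label
   (BiP/HSPA5-homolog), with the hub at ~75% of the maximum degree and a
   Pareto-tailed (exponent 2) remainder adjusted to the exact edge-record
   sum.

What the emulation **does not** reproduce: the real networks' clustering,
modularity, diameter, and community counts; their z-score and signed-rank
signatures (a heavy-tailed random graph is itself close to its own
configuration model, so emulated z-scores sit near zero where curated
networks show saturated values); and their driver-node counts (leaf-heavy
synthetic draws can need far larger driver sets than the curated
topologies).  Tests passing on synthetic networks therefore demonstrate
the correctness of the computations and pipeline plumbing, not biological
conclusions about real UPR networks — those require actual database
exports, which the TSV parser ingests directly.

## Determinism and problem sizes

Every randomized step takes a single integer seed and builds one private
`numpy` generator; no global RNG state is touched.  Pipeline sub-seeds
are derived from the config seed by fixed offsets.  Identical
configuration and seeds produce byte-identical report bundles (asserted
in the tests).

Default problem sizes were chosen so the full suite and the acceptance
script each complete in minutes on one core: the oracle corpora use 100
graphs with at most 8 nodes (exhaustive search is exact there), the
planted-community checks use 30 nodes, and the analysis scripts compute
efficiency-drop traces only for networks up to 120 nodes (the all-pairs
recomputation per removal step is the one quadratic-times-N cost in the
battery; LCC traces and R indices cover all sizes).

## Known limitations

- Numeric Kalman ranks beyond ~64 nodes are not trustworthy; driver-set
  *counts* (matching-based) remain exact at any size, only the rank
  cross-check is size-limited.
- The signed-rank normal approximation (n > 25) differs from the exact
  distribution in the extreme tails, as any approximation does.
- GHD is defined only for networks on the identical node set; there is no
  significance test for it here (only ensemble averages).
- The parser deliberately performs no identifier normalization or
  ortholog mapping; cross-organism node matching is the caller's
  responsibility.
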