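# Methods

## Scope and model family

`sbmbench` implements the stochastic block model (SBM) family used in
systematic comparisons of community-detection variants: a graph
`G = (V, E)` with `N` nodes and `M` edges is scored against a partition
`b` of its nodes into `K` blocks by one of twelve log-objectives, all to be
maximized. The family covers

* the profile Poisson log-likelihoods of the standard and degree-corrected
  SBM (SKN, DCKN) and their microcanonical entropy forms (SPC_dense,
  SPC_sparse, DCP);
* marginal likelihoods that integrate the nuisance parameters out and
  therefore compare across different K directly: the exact integrated
  complete likelihood with Jeffrey or uniform pseudo-counts (ICLexJ,
  ICLexU), the Newman–Reinert marginal likelihood and its degree-corrected
  form (SNR, DCNR — the only variants for which empty blocks are legal
  states), and Peixoto's microcanonical formulations (SPC, DCPU, DCPUH);
* nested (hierarchical) versions of the microcanonical models (HSPC,
  HDCPU, HDCPUH) in which the block multigraph of each level is itself
  SBM-distributed, with `K^0 = N` and `K^L = 1`.

All factorial and gamma arithmetic is done in natural-log space via
`lgamma`; `0 log 0 = 0` throughout. Exact big-integer combinatorics
(restricted partitions, multiset coefficients) appear only in test oracles.

## Statistics and conventions

A `BlockState` caches the sufficient statistics every objective consumes:
block sizes `n_r`, stub counts `e_r` (a self-loop contributes 2 to its
node's degree, so `sum_r e_r = 2M`), per-block degree histograms `N_k^r`,
and the block adjacency stored ordered with doubled diagonal
(`E[r, r] = 2 m_rr`, internal edges counted once in `m_rr`). Formulas that
use the single-counted convention (ICLex, SNR diagonal terms) read
`m_rr = E[r, r] / 2`. Moves and merges update the statistics
incrementally; a randomized test suite asserts equality with a fresh
rebuild after arbitrary operation sequences.

Each objective decomposes as `sum_{r<s} pair(r, s) + sum_r diag(r) +
sum_r block(r) + const(K) + const`, where the pair/diag/block terms touch
only the statistics of the named blocks. A single-node move changes only
the rows of its source and target block, so its delta is the difference of
the local terms; a block merge additionally picks up the K-dependent
constant. The kernel computes these local sums in O(K) per delta for every
objective uniformly (K stays below ~30 in all workloads here, where row
access is at least as fast as sparser bookkeeping). Deltas agree with full
recomputation to 1e-9 relative accuracy by test.

### Ambiguous diagonal terms

Two published formulas are typographically ambiguous and are resolved as
follows (both resolutions are validated by brute-force enumeration and
stationarity tests): the ICLex diagonal non-edge count subtracts the
existing internal edges, `zeta_rr = zeta0 + n_r(n_r+1)/2 - m_rr` (a switch
restores the alternative reading), and the Newman–Reinert within-group
factor uses `(p n_r^2 / 2 + 1)` with `p = 2M/N^2`.

### Hierarchical objective

For a hierarchy `b^1..b^L` the objective is the flat graph term
`log P(G | e^1, b^1)` (plus the degree prior for degree-corrected
flavours), plus per-level partition priors for `l = 1..L`, plus multiset
edge-count priors for `l = 2..L` (occupancies of the coarser matrix over
the finer group pairs). The minimal hierarchy — one flat partition plus
the trivial root — then equals the corresponding flat objective minus
exactly `log K`, the cost of describing the root level; the tests pin this
offset, and inserting an identity level over K blocks costs exactly
`log K! + log K`.

## Inference

* **MA / MHA** — Metropolis and Metropolis–Hastings chains over single
  node moves at fixed K, inverse temperature `beta = 1` by default (the
  annealing schedules evaluated in the literature degraded results, so
  `beta` is exposed but not scheduled). The MHA proposal draws a random
  neighbour's block `t` and targets `s` with probability
  `(e_ts + eps)/(e_t + eps K)` (`eps = 0.1` default; uniform moves are
  recovered as `eps -> inf`, and isolated nodes fall back to uniform). The
  acceptance ratio evaluates the reverse proposal on the post-move counts.
  Correctness is established by a chi-square test of the empirical chain
  distribution against `exp(objective)/Z` on a fully enumerable instance —
  a sharp test of the Hastings correction. Moves that would empty a block
  are rejected at fixed K (except under SNR/DCNR, where empty blocks are
  legal). Samplers report exactly `steps` delta evaluations.
* **PAH** — agglomerative heuristic: start from singletons; per sweep each
  block scores `n_mergers = 10` candidate merges drawn with the block-level
  version of the MHA proposal, the best `K/sigma` (`sigma = 2`) distinct
  merges are applied, and `tau = 200` MH steps refine (half at `beta`,
  half at `beta_high = 1e5`, i.e. effectively greedy). Runs at O(K^2)
  merge-delta cost per sweep; intended for the benchmark scales used here
  (up to a few hundred initial blocks).
* **KL** — per sweep, repeatedly take the globally best remaining
  single-node move (ties broken to the lowest node, then lowest block),
  even if negative, each node moving once; then roll back to the best
  prefix. Gains below 1e-9 are treated as floating-point noise, not
  improvement (without this, noise-level prefix gains can recur forever).
  The objective is nondecreasing across sweeps and the algorithm is
  deterministic given its start.
* **KL-EM / KL-G** — one-pass relaxations: score all per-node best moves
  then apply the batch (skipping moves invalidated by emptied blocks), or
  apply each node's best move immediately. Because KL-EM's batch is scored
  against a stale state it can oscillate; it therefore stops when a pass
  fails to improve the actual objective value. Both are cheap but land in
  local optima noticeably more often than full KL — the intended use is
  multiple restarts.
* **Restarts** — `best_of_restarts` draws independent uniform K-block
  starts (resampling until no block is empty) and keeps the run with the
  highest final objective value, aggregating delta counts.
* **Hierarchical fitting** — the published experiments used an adapted
  agglomerative heuristic without stating details; here each level is
  fitted by an agglomerative descent from singletons (edge-guided merge
  candidates, short heated MH refinements), snapshotting the partition at
  every block count and keeping the snapshot that maximizes the full
  hierarchical objective; levels are added greedily until the root. While
  K is large the descent halves K per sweep; below K = 20 it merges one
  pair at a time so every candidate K is actually visited. This is an
  interpretation, not a reproduction, of the original procedure.

Every algorithm counts delta evaluations — the implementation-independent
cost unit. KL's per-sweep count is `(K-1)(N + N(N-1)/2)`; on the 128-node
planted-partition networks typical runs land near the published order of
1.25e5 deltas.

## Model selection

The classic objectives (SKN, DCKN, DCP) grow with K and need a penalty:
MDL (description length of the partition and edge-count matrix, plus the
per-block degree-distribution entropy for degree-corrected models), AIC
with `K(K+1)/2 + K` parameters (plus K for DC), and BIC with the
`K(K+1)/2 log N^3` penalty (DC adds the constant `2 log N`). All criteria
are converted to maximize-direction scores; ties break toward smaller K.
The exhaustive sweep is the default because unimodality of the penalized
score is not guaranteed; golden-section search over K is available
opt-in. Natural logarithms are used for all criteria, consistent with the
objectives (the selection argmax is insensitive to the base in practice).

## Generators

* `sample_sbm` / `sample_dcsbm` — Bernoulli or Poisson pair sampling from
  an `omega` matrix (optionally with propensities `theta`); Poisson mode
  can create multi-edges and optional self-pairs (rate `omega_rr/2`), with
  a collapse option that keeps only one edge per pair.
* **GN test** — the planted 4x32-node partition with mean degree 16,
  parameterised by the expected external degree `k_out` and extended to the
  disassortative range: `P_out = k_out/96`, `P_in = (16 - k_out)/31`
  (derived from the 96 external / 31 internal potential partners per
  node; the mean-degree constraint pins the derivation and is verified by
  a moment test).
* **LFR** — native implementation of the standard 1000-node setup (mean
  degree 20, max 50, degree exponent -2, community-size exponent -1,
  sizes 20..100, mixing `mu_t`): the minimum degree is solved numerically
  so the truncated power law's mean hits 20; internal degrees are
  `(1-mu) k` with stochastic rounding (keeping the realized mixing
  unbiased); nodes are assigned to communities under the capacity
  constraint `k_in <= size - 1`; internal and external stubs are wired by
  configuration model followed by double-edge-swap repair of self-loops,
  duplicates and external edges that landed inside a community. The rare
  irreparably bad edges are dropped. Correctness is contractual, not
  bit-compatible with the original generator: realized mean degree within
  5%, realized mixing within ±0.02, community count typically 14–23.

What the generators do *not* emulate: degree-degree correlations,
clustering/transitivity beyond what the planted structure induces,
weighted or directed edges, and overlapping communities. Benchmark results
therefore speak to block-structured random graphs, not to any particular
real network.

## Evaluation

Partition similarity is AMI with max-normalization and the permutation
(hypergeometric) null model; degenerate normalizers (single-block or
all-singleton references) score 0, and small negative chance-corrected
values are reported unclamped. A benchmark run samples networks along a
mixing grid, runs best-of-restarts inference per (network, model), and
summarizes each model by the trapezoidal area under its mean-AMI curve
normalized by the interval length (AUMIC; grid `k_out = 0..8` step 0.5 for
the GN test, `mu_t = 0..0.5` step 0.1 for LFR). Cell seeds are derived
deterministically from the top-level generator, so results are bitwise
reproducible and independent of model ordering.

## Problem sizes used in the shipped checks

The published full factorial (12 models x 6 algorithms x both benchmarks
x K sweeps, 10 networks x 10 runs each) is deliberately scaled down to
property tests plus reduced reproductions, chosen as the package's own
validation budget: GN summaries use 5 networks per `k_out` with MHA 50k
steps and 5 restarts; the LFR summary uses 3 networks per `mu_t` with MHA
100k steps and 4 restarts; the K-selection sweep on LFR is exercised on a
reduced K grid. Under these conditions the GN AUMIC for the standard SBM
with known K lands near the published 0.91 (with MDL selection near
0.89), and the LFR AUMIC for DCPU with known K near the published 0.89;
`scripts/acceptance.py` recomputes the latter end to end.

## Known limitations

* PAH's merge scoring is O(K^2) per sweep via dense local terms; starting
  from singletons on graphs much beyond ~10^3 nodes becomes slow.
* The DCPUH restricted-partition table is O(2M x N) floats and is built
  lazily per graph; on large graphs this dominates memory for that one
  objective.
* KL recomputes all remaining deltas after every move (the `N^2 K`
  published cost); no incremental delta reuse is attempted.
* Directed, weighted, overlapping and dynamic SBM variants, belief
  propagation, spectral and EM inference are out of scope.
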