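"""Hierarchical (nested) microcanonical SBM objectives and a greedy fitter.

The nested model replaces the flat priors over the edge-count matrix and the
partition with level products: the block multigraph of level ``l-1`` is
itself modelled by an SBM at level ``l``, with ``K^0 = N`` and ``K^L = 1``.
For a hierarchy ``b^1 .. b^L`` the log-objective is

    log P(G | e^1, b^1)            (level-0 graph term, flat form,
                                    plus the degree prior for DC flavours)
  + sum_{l=1..L}   log P(b^l)      (per-level partition prior)
  + sum_{l=2..L}   log P(e^l)      (multiset occupancy of the coarser
                                    matrix over the finer group pairs)

With the minimal hierarchy ``[b, trivial root]`` this reproduces the
corresponding flat objective up to the root partition prior, an exact
``-log K`` offset (the cost of describing the extra level).

Inference follows a greedy level-by-level agglomeration: each level is
coarsened from singletons by scored merges (with short MH refinements using
the flat delta kernel), every intermediate block count is snapshotted, and
the snapshot maximizing the full hierarchical objective becomes the level.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

from .graph import Graph, Partition
from .inference import InferenceConfig, _run_chain
from .objectives import get_objective
from .state import BlockState, HierarchyState, block_multigraph

__all__ = ["hierarchical_objective", "fit_hierarchy", "HIERARCHICAL_NAMES"]

HIERARCHICAL_NAMES = ("HSPC", "HDCPU", "HDCPUH")
_FLAT_OF = {"HSPC": "SPC", "HDCPU": "DCPU", "HDCPUH": "DCPUH"}


def _lf(x):
    return gammaln(np.asarray(x, dtype=float) + 1.0)


def _lms(n, k):
    """Vectorized log multiset coefficient; 0 where k == 0."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + k) - gammaln(k + 1.0) - gammaln(np.maximum(n, 1.0))
    return np.where(k == 0, 0.0, out)


def _pe_term(st: BlockState) -> float:
    """-log of the multiset counts distributing e^l over level pairs."""
    m = st.m_matrix()
    n = st.n_r.astype(float)
    pairs = np.outer(n, n)
    np.fill_diagonal(pairs, n * (n + 1.0) / 2.0)
    terms = _lms(pairs, m)
    iu = np.triu_indices(st.K)
    return -float(terms[iu].sum())


def _pb_term(st: BlockState) -> float:
    """log P(b^l): sizes prior, composition count and the 1/K^{l-1} factor."""
    n_below = st.graph.N
    K = st.K
    return float(_lf(st.n_r).sum() - _lf(n_below)
                 - (gammaln(n_below) - gammaln(K) - gammaln(n_below - K + 1.0))
                 - math.log(n_below))


def _graph_term(st: BlockState, flavor: str) -> float:
    """log P(G | e^1, b^1) (+ degree prior for the DC flavours)."""
    spec = get_objective(_FLAT_OF[flavor])
    params, lq = spec.bind(st.graph)
    m = st.m_matrix()
    diag = np.diag(m)
    iu = np.triu_indices(st.K, k=1)
    v = float(_lf(m[iu]).sum())
    v += float((diag * math.log(2.0) + _lf(diag)).sum())
    v -= params[5]  # const_A
    n = st.n_r
    e = st.e_r
    if flavor == "HSPC":
        nz = n > 0
        v -= float((e[nz] * np.log(n[nz])).sum())
        return v
    v += params[6]  # sum_i log k_i!
    v -= float(_lf(e).sum())
    if flavor == "HDCPU":
        v -= float(_lms(n, e).sum())
    else:  # HDCPUH
        v += float(_lf(st.hist).sum())
        v -= float(_lf(n).sum())
        v -= float(lq[e, np.minimum(n, lq.shape[1] - 1)].sum())
    return v


def hierarchical_objective(hier: HierarchyState, flavor: str) -> float:
    """Full nested-model log objective of a hierarchy."""
    if flavor not in HIERARCHICAL_NAMES:
        raise ValueError(f"flavor must be one of {HIERARCHICAL_NAMES}")
    v = _graph_term(hier.states[0], flavor)
    for idx, st in enumerate(hier.states):
        v += _pb_term(st)
        if idx >= 1:
            v += _pe_term(st)
    return v


def _trivial_partition(n: int) -> Partition:
    return Partition(np.zeros(n, dtype=np.int64), K=1)


def _close(parts: list[Partition], top_k: int) -> list[Partition]:
    if top_k == 1:
        return parts
    return parts + [_trivial_partition(top_k)]


def fit_hierarchy(graph: Graph, flavor: str,
                  config: InferenceConfig | None = None,
                  rng: np.random.Generator | None = None,
                  max_levels: int = 8) -> tuple[HierarchyState, float]:
    """Greedy bottom-up fit of a hierarchy; returns it with its objective."""
    if flavor not in HIERARCHICAL_NAMES:
        raise ValueError(f"flavor must be one of {HIERARCHICAL_NAMES}")
    config = config or InferenceConfig(tau=100, restarts=3)
    rng = rng or np.random.default_rng()
    spec = get_objective(_FLAT_OF[flavor])
    parts: list[Partition] = []
    g = graph
    for _level in range(max_levels):
        if g.N == 1:
            break
        snap_best: Partition | None = None
        score_best = -math.inf
        for _restart in range(max(1, config.restarts)):
            state = BlockState(g, Partition(np.arange(g.N), K=g.N))
            snap_best, score_best = _descend(
                graph, g, parts, state, spec, flavor, config, rng,
                snap_best, score_best)
        assert snap_best is not None
        if snap_best.K == g.N:
            # no coarsening helps: close with the trivial root
            parts.append(_trivial_partition(g.N))
            break
        parts.append(snap_best)
        if snap_best.K == 1:
            break
        g = block_multigraph(BlockState(g, snap_best))
    if parts[-1].K != 1:
        parts.append(_trivial_partition(parts[-1].K))
    hier = HierarchyState(graph, parts)
    return hier, hierarchical_objective(hier, flavor)


def _descend(graph, g, parts, state, spec, flavor, config, rng,
             snap_best, score_best):
    """One agglomerative descent from singletons; returns the best snapshot."""
    while True:
        part = state.partition
        hier = HierarchyState(graph, _close(parts + [part], part.K))
        score = hierarchical_objective(hier, flavor)
        if score > score_best:
            score_best, snap_best = score, part
        if state.K == 1:
            break
        # score candidate merges (edge-guided proposal), apply the best
        # K/sigma of them
        K = state.K
        cand: dict[tuple[int, int], float] = {}
        eps = config.epsilon
        for r in range(K):
            row_r = state.E[r].astype(float)
            tot_r = row_r.sum()
            for _ in range(config.n_mergers):
                if tot_r > 0:
                    t = int(rng.choice(K, p=row_r / tot_r))
                    w = state.E[t] + eps
                    s = int(rng.choice(K, p=w / (state.e_r[t] + eps * K)))
                else:
                    s = int(rng.integers(K))
                if s == r:
                    continue
                key = (min(r, s), max(r, s))
                d = spec.merge_delta(state, *key)
                if key not in cand or d > cand[key]:
                    cand[key] = d
        # halve aggressively while K is large, but take single merges once K
        # is small so that every candidate block count gets snapshotted
        n_merge = max(1, int(K / config.sigma)) if K > 20 else 1
        current = np.arange(K)
        merged = 0
        for (r, s), _d in sorted(cand.items(), key=lambda kv: -kv[1]):
            if merged >= n_merge or state.K == 1:
                break
            cr, cs = int(current[r]), int(current[s])
            if cr == cs:
                continue
            lo, hi = min(cr, cs), max(cr, cs)
            state.merge_blocks(lo, hi)
            current[current == hi] = lo
            current[current > hi] -= 1
            merged += 1
        if state.K > 1 and config.tau:
            half = config.tau // 2
            state = _run_chain(state, spec, config, rng, hastings=True,
                               steps=half).state
            state = _run_chain(state, spec, config, rng, hastings=True,
                               steps=config.tau - half,
                               beta=config.beta_high).state
    return snap_best, score_best
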