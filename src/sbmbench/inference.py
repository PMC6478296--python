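"""Inference algorithms: MCMC samplers, agglomerative merging and local
heuristics, all driven by the shared single-move delta contract.

Four families are provided, named as in the comparison they implement:

* ``MA`` / ``MHA`` — Metropolis and Metropolis-Hastings chains over single
  node moves at fixed K.  The MHA proposal picks a random neighbour's block
  ``t`` and then a target ``s`` with probability ``(e_ts + eps) /
  (e_t + eps K)``; the acceptance uses the Hastings ratio with the reverse
  proposal evaluated on the post-move counts, so the chain satisfies
  detailed balance w.r.t. ``exp(beta * objective)``.
* ``PAH`` — the agglomerative heuristic: start from singletons, score a few
  candidate merges per block with the same proposal, perform the best
  ``K/sigma`` of them, interleave short MH refinements (the second half at
  a very large inverse temperature, i.e. effectively greedy).
* ``KL`` and its relaxations ``KL_EM`` / ``KL_G`` — deterministic local
  search moving every node once per sweep (KL, with rollback to the best
  prefix), or batching / greedily applying per-node best moves.

Every algorithm counts the number of delta evaluations it performs; that
count is the implementation-independent cost unit used by the benchmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .graph import Graph, Partition
from .objectives import Objective, get_objective
from .state import BlockState, MoveProposal


@dataclass
class InferenceConfig:
    """Knobs for all algorithms (unused fields are ignored).

    Defaults follow the configuration the comparison used: ``beta = 1`` (no
    annealing), ``sigma = 2``, ``n_mergers = 10``, ``tau = 200`` and an
    abrupt-heating ``beta_high = 1e5`` for the agglomerative heuristic.
    """

    algorithm: str = "MHA"
    steps: int = 50_000
    beta: float = 1.0
    epsilon: float = 0.1
    sigma: float = 2.0
    n_mergers: int = 10
    tau: int = 200
    beta_high: float = 100_000.0
    restarts: int = 1

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.sigma <= 1:
            raise ValueError("sigma must be > 1")


@dataclass
class InferenceResult:
    """Outcome of one inference run."""

    state: BlockState
    objective: float            # objective of the final state
    best_value: float           # best objective value visited
    best_labels: np.ndarray
    n_deltas: int
    n_moves: int
    seed: int | None = None
    trajectory: list | None = None


def random_partition(n_nodes: int, K: int, rng: np.random.Generator,
                     allow_empty: bool = False) -> Partition:
    """Uniform random K-block labelling; resampled until no block is empty."""
    if K > n_nodes and not allow_empty:
        raise ValueError("cannot fill K blocks with fewer nodes")
    while True:
        labels = rng.integers(0, K, size=n_nodes)
        if allow_empty or len(np.unique(labels)) == K:
            return Partition(labels, K=K, allow_empty=allow_empty)


def _kernel_args(state: BlockState, spec: Objective):
    params, lq = spec.bind(state.graph)
    return (state.labels, state.E, state.e_r, state.n_r, state.hist,
            state.K, params, lq, state.graph.indptr, state.graph.stubs)


_NO_RECORD = np.zeros(1, dtype=np.int64)

#: improvements below this are floating-point noise, not real gains
_GAIN_TOL = 1e-9


def _run_chain(state: BlockState, spec: Objective, config: InferenceConfig,
               rng: np.random.Generator, hastings: bool,
               record: np.ndarray | None = None, thin: int = 1,
               steps: int | None = None, beta: float | None = None,
               ) -> InferenceResult:
    state = state.copy()
    steps = config.steps if steps is None else steps
    beta = config.beta if beta is None else beta
    v0 = spec.value(state)
    if state.K == 1:
        warnings.warn("K = 1: the chain has no valid moves", stacklevel=3)
        return InferenceResult(state, v0, v0, state.labels.copy(), 0, 0)
    seed = int(rng.integers(2**31 - 1))
    best_labels = np.empty_like(state.labels)
    rec = _NO_RECORD if record is None else record
    dsum, bsum, moves = _kernel.mcmc_run(
        steps, beta, config.epsilon, hastings,
        spec.allow_empty, spec.oid, *_kernel_args(state, spec),
        seed, best_labels, rec, thin)
    return InferenceResult(state, v0 + dsum, v0 + bsum, best_labels,
                           n_deltas=steps, n_moves=int(moves), seed=seed)


def metropolis(state: BlockState, spec: Objective, config: InferenceConfig,
               rng: np.random.Generator) -> InferenceResult:
    """Metropolis chain: uniform node and target proposals,
    ``p_accept = min(1, exp(beta * dF))``."""
    return _run_chain(state, spec, config, rng, hastings=False)


def metropolis_hastings(state: BlockState, spec: Objective,
                        config: InferenceConfig,
                        rng: np.random.Generator) -> InferenceResult:
    """Metropolis-Hastings chain with the block-matrix move proposal."""
    return _run_chain(state, spec, config, rng, hastings=True)


def chain_state_counts(state: BlockState, spec: Objective,
                       config: InferenceConfig, rng: np.random.Generator,
                       hastings: bool, thin: int = 1) -> np.ndarray:
    """Visit counts of every labelling (base-K encoded) along a chain.

    Only sensible for tiny instances (the array has ``K**N`` entries).
    """
    record = np.zeros(state.K ** state.graph.N, dtype=np.int64)
    _run_chain(state, spec, config, rng, hastings, record=record, thin=thin)
    return record


# ---------------------------------------------------------------------------
# Kernighan-Lin family
# ---------------------------------------------------------------------------

def kernighan_lin(state: BlockState, spec: Objective,
                  config: InferenceConfig | None = None) -> InferenceResult:
    """Full Kernighan-Lin sweep search.

    Each sweep moves every node exactly once, always taking the globally
    best remaining move (possibly negative), then rolls back to the best
    prefix of the move sequence.  Halts when a sweep yields no gain.
    Deterministic given the start; the objective never decreases.
    """
    state = state.copy()
    spec_ = spec
    N, K = state.graph.N, state.K
    args = lambda: _kernel_args(state, spec_)  # noqa: E731
    n_deltas = 0
    n_moves = 0
    out = np.empty((N, K))
    while True:
        active = np.ones(N, dtype=np.bool_)
        n_deltas += int(_kernel.batch_deltas(
            spec_.oid, *args(), active, spec_.allow_empty, out))
        moves: list[tuple[int, int, int]] = []
        gains: list[float] = []
        for _ in range(N):
            flat = int(np.argmax(out))
            d = out.flat[flat]
            if not np.isfinite(d):
                break  # no legal move left
            i, s = divmod(flat, K)
            r = int(state.labels[i])
            _kernel._shift_node(i, r, s, state.labels, state.E, state.e_r,
                                state.n_r, state.hist, state.graph.indptr,
                                state.graph.stubs)
            moves.append((i, r, s))
            gains.append(float(d))
            active[i] = False
            n_deltas += int(_kernel.batch_deltas(
                spec_.oid, *args(), active, spec_.allow_empty, out))
        if not gains:
            break
        prefix = np.cumsum(gains)
        k_best = int(np.argmax(prefix))
        gain = float(prefix[k_best])
        # gains at floating-point noise level are no improvement; without the
        # tolerance a prefix worth ~1e-13 can recur forever
        keep = k_best + 1 if gain > _GAIN_TOL else 0
        for i, r, s in reversed(moves[keep:]):
            _kernel._shift_node(i, s, r, state.labels, state.E, state.e_r,
                                state.n_r, state.hist, state.graph.indptr,
                                state.graph.stubs)
        n_moves += keep
        if gain <= _GAIN_TOL:
            break
    v = spec_.value(state)
    return InferenceResult(state, v, v, state.labels.copy(), n_deltas, n_moves)


def kl_em(state: BlockState, spec: Objective,
          config: InferenceConfig | None = None) -> InferenceResult:
    """Two-phase relaxation: score the best move of every node, then apply
    the whole batch; repeat until a pass finds no improving move."""
    state = state.copy()
    N, K = state.graph.N, state.K
    out = np.empty((N, K))
    n_deltas = 0
    n_moves = 0
    value = spec.value(state)
    while True:
        active = np.ones(N, dtype=np.bool_)
        n_deltas += int(_kernel.batch_deltas(
            spec.oid, *_kernel_args(state, spec), active, spec.allow_empty, out))
        best_s = np.argmax(out, axis=1)
        best_d = out[np.arange(N), best_s]
        todo = np.flatnonzero(best_d > _GAIN_TOL)
        if todo.size == 0:
            break
        snapshot = state.copy()
        applied = 0
        for i in todo:
            r = int(state.labels[i])
            s = int(best_s[i])
            if s == r:
                continue
            if not spec.allow_empty and state.n_r[r] == 1:
                continue  # batched move invalidated by earlier applications
            _kernel._shift_node(int(i), r, s, state.labels, state.E,
                                state.e_r, state.n_r, state.hist,
                                state.graph.indptr, state.graph.stubs)
            applied += 1
        new_value = spec.value(state)
        # the batch was scored against the pre-pass state; a pass that fails
        # to improve the objective is rolled back (batched moves can
        # oscillate), so the returned state is a fixed point
        if applied == 0 or new_value <= value + _GAIN_TOL:
            state = snapshot
            break
        n_moves += applied
        value = new_value
    v = spec.value(state)
    return InferenceResult(state, v, v, state.labels.copy(), n_deltas, n_moves)


def kl_greedy(state: BlockState, spec: Objective,
              config: InferenceConfig | None = None) -> InferenceResult:
    """Greedy relaxation: sweep the nodes in order, immediately applying
    each node's best improving move; repeat until a clean pass."""
    state = state.copy()
    N, K = state.graph.N, state.K
    row = np.empty(K)
    n_deltas = 0
    n_moves = 0
    improved = True
    while improved:
        improved = False
        for i in range(N):
            n_deltas += int(_kernel.node_deltas(
                spec.oid, *_kernel_args(state, spec), i, spec.allow_empty, row))
            s = int(np.argmax(row))
            if np.isfinite(row[s]) and row[s] > _GAIN_TOL:
                r = int(state.labels[i])
                _kernel._shift_node(i, r, s, state.labels, state.E, state.e_r,
                                    state.n_r, state.hist, state.graph.indptr,
                                    state.graph.stubs)
                n_moves += 1
                improved = True
    v = spec.value(state)
    return InferenceResult(state, v, v, state.labels.copy(), n_deltas, n_moves)


# ---------------------------------------------------------------------------
# Agglomerative heuristic
# ---------------------------------------------------------------------------

def agglomerative_peixoto(graph: Graph, spec: Objective, K_aim: int,
                          config: InferenceConfig,
                          rng: np.random.Generator) -> InferenceResult:
    """Bottom-up merging from singletons down to ``K_aim`` blocks.

    Per sweep: every block scores ``n_mergers`` candidate merges (targets
    drawn with the block-level variant of the MH proposal), the best
    ``K/sigma`` distinct merges are applied, and ``tau`` MH node-move steps
    refine the result (half at ``beta``, half at ``beta_high``).
    """
    N = graph.N
    if not 1 <= K_aim <= N:
        raise ValueError("K_aim must be in 1..N")
    state = BlockState(graph, Partition(np.arange(N), K=N,
                                        allow_empty=spec.allow_empty))
    n_deltas = 0
    n_moves = 0
    eps = config.epsilon
    while state.K > K_aim:
        K = state.K
        candidates: dict[tuple[int, int], float] = {}
        E = state.E
        e = state.e_r
        for r in range(K):
            row_r = E[r].astype(float)
            tot_r = row_r.sum()
            for _ in range(config.n_mergers):
                if tot_r > 0:
                    t = int(rng.choice(K, p=row_r / tot_r))
                else:
                    t = int(rng.integers(K))
                w = E[t] + eps
                s = int(rng.choice(K, p=w / (e[t] + eps * K)))
                if s == r:
                    continue
                key = (min(r, s), max(r, s))
                d = spec.merge_delta(state, *key)
                n_deltas += 1
                if key not in candidates or d > candidates[key]:
                    candidates[key] = d
        n_merge = min(K - K_aim, max(1, int(K / config.sigma)))
        order = sorted(candidates.items(), key=lambda kv: -kv[1])
        current = np.arange(K)  # original block id -> current index
        merged = 0
        for (r, s), _d in order:
            if merged >= n_merge:
                break
            cr, cs = int(current[r]), int(current[s])
            if cr == cs:
                continue
            lo, hi = min(cr, cs), max(cr, cs)
            state.merge_blocks(lo, hi)
            current[current == hi] = lo
            current[current > hi] -= 1
            merged += 1
        if state.K > 1:
            half = config.tau // 2
            res = _run_chain(state, spec, config, rng, hastings=True,
                             steps=half, beta=config.beta)
            state = res.state
            n_moves += res.n_moves
            res = _run_chain(state, spec, config, rng, hastings=True,
                             steps=config.tau - half, beta=config.beta_high)
            state = res.state
            n_moves += res.n_moves
            n_deltas += config.tau
    v = spec.value(state)
    return InferenceResult(state, v, v, state.labels.copy(), n_deltas, n_moves)


# ---------------------------------------------------------------------------
# Restarts
# ---------------------------------------------------------------------------

_ALGORITHMS = {"MA", "MHA", "PAH", "KL", "KL_EM", "KL_G"}


def run_algorithm(state_or_graph, spec: Objective, config: InferenceConfig,
                  rng: np.random.Generator, K: int | None = None,
                  ) -> InferenceResult:
    """Dispatch one run of ``config.algorithm`` from a given start."""
    alg = config.algorithm.upper().replace("-", "_")
    if alg not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {config.algorithm!r}")
    if alg == "PAH":
        graph = state_or_graph.graph if isinstance(state_or_graph, BlockState) \
            else state_or_graph
        if K is None:
            raise ValueError("PAH needs K_aim")
        return agglomerative_peixoto(graph, spec, K, config, rng)
    state = state_or_graph
    if alg == "MA":
        return metropolis(state, spec, config, rng)
    if alg == "MHA":
        return metropolis_hastings(state, spec, config, rng)
    if alg == "KL":
        return kernighan_lin(state, spec, config)
    if alg == "KL_EM":
        return kl_em(state, spec, config)
    return kl_greedy(state, spec, config)


def best_of_restarts(graph: Graph, spec: Objective, K: int,
                     config: InferenceConfig, rng: np.random.Generator,
                     init: Partition | None = None) -> InferenceResult:
    """Run ``config.restarts`` independent runs from uniform random K-block
    starts and keep the one with the highest final objective value.

    Delta and move counts are aggregated over all restarts.
    """
    best: InferenceResult | None = None
    total_deltas = 0
    total_moves = 0
    for _ in range(max(1, config.restarts)):
        if config.algorithm.upper() == "PAH":
            res = run_algorithm(graph, spec, config, rng, K=K)
        else:
            part = init if init is not None else random_partition(
                graph.N, K, rng, allow_empty=spec.allow_empty)
            state = BlockState(graph, part)
            res = run_algorithm(state, spec, config, rng)
        total_deltas += res.n_deltas
        total_moves += res.n_moves
        if best is None or res.objective > best.objective:
            best = res
    assert best is not None
    best.n_deltas = total_deltas
    best.n_moves = total_moves
    return best
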