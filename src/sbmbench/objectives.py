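"""The flat SBM objective functions and their single-move delta contract.

Twelve log-objectives are exposed, named by the abbreviations used throughout
the comparison literature:

========  ==============================================================
SKN       standard SBM profile log-likelihood (Karrer & Newman), with 1/2
SPC       Peixoto's microcanonical standard SBM (includes K selection)
SPC_dense / SPC_sparse
          entropy forms of the standard SBM; the sparse form is SKN - M
DCKN      degree-corrected profile log-likelihood (Karrer & Newman)
DCP       Peixoto's microcanonical degree-corrected entropy form
ICLexJ / ICLexU
          exact integrated complete likelihood (Come & Latouche), with
          Jeffrey (1/2) or uniform (1) prior pseudo-counts
SNR / DCNR
          Newman & Reinert's marginal likelihood, plain and
          degree-corrected; these allow empty blocks
DCPU / DCPUH
          Peixoto's degree-corrected microcanonical SBM with the uniform
          degree prior, or the uniform hyperprior over degree histograms
========  ==============================================================

All values are natural-log scores to be *maximized*; factorials and gamma
functions are evaluated in log space.  Objectives that embed a prior over K
(``includes_K_selection``) can be compared across different block counts
directly; the classic ones need an external criterion
(:mod:`sbmbench.model_selection`).
"""

from __future__ import annotations

import math
import weakref
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._tables import binary_entropy, log_multiset, log_q_table, restricted_partitions_q
from .graph import Graph, Partition
from .state import BlockState, MoveProposal

__all__ = [
    "Objective", "OBJECTIVES", "get_objective", "delta_objective",
    "binary_entropy", "log_multiset", "restricted_partitions_q",
    "SBMParams", "bernoulli_loglik_oracle",
]

_DUMMY_LQ = np.zeros((1, 1))


@dataclass
class SBMParams:
    """Generative parameters: edge probabilities (or rates) and propensities."""

    omega: np.ndarray
    block_sizes: np.ndarray | None = None
    theta: np.ndarray | None = None

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 2 or self.omega.shape[0] != self.omega.shape[1]:
            raise ValueError("omega must be square")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if np.any(self.omega < 0):
            raise ValueError("omega entries must be >= 0")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if np.any(self.theta < 0):
                raise ValueError("theta must be >= 0")


class Objective:
    """One named objective with full evaluation and the delta contract."""

    def __init__(self, name: str, oid: int, *, includes_K_selection: bool,
                 degree_corrected: bool, allow_empty: bool = False,
                 delta_cost_class: str = "O(<k>)",
                 prior0: float = 0.0, zeta_minus_diag: bool = True,
                 needs_simple: bool = False, needs_lq: bool = False):
        self.name = name
        self.oid = oid
        self.direction = "maximize"
        self.includes_K_selection = includes_K_selection
        self.degree_corrected = degree_corrected
        self.allow_empty = allow_empty
        self.delta_cost_class = delta_cost_class
        self.prior0 = prior0
        self.zeta_minus_diag = zeta_minus_diag
        self.needs_simple = needs_simple
        self.needs_lq = needs_lq
        self._cache: "weakref.WeakKeyDictionary" = weakref.WeakKeyDictionary()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Objective({self.name})"

    # -- per-graph constants -------------------------------------------------
    def bind(self, graph: Graph) -> tuple[np.ndarray, np.ndarray]:
        """Per-graph constants: the params vector and (if needed) the
        restricted-partition log table."""
        hit = self._cache.get(graph)
        if hit is not None:
            return hit
        if self.needs_simple and not _is_simple(graph):
            raise ValueError(f"{self.name} is defined for simple graphs only")
        M, N = graph.M, graph.N
        # const_A = sum_{i<j} log A_ij! + sum_i log A_ii!! with A_ii = 2 a_ii,
        # so each node with a_ii loops contributes a_ii log 2 + log a_ii!
        const_a = 0.0
        e = graph.edges
        loop_mask = e[:, 0] == e[:, 1] if e.size else np.zeros(0, dtype=bool)
        loops = graph.loop_counts()
        for a in loops[loops > 0]:
            const_a += a * math.log(2.0) + math.lgamma(a + 1.0)
        nonloop = e[~loop_mask]
        if nonloop.size:
            counts = np.unique(nonloop, axis=0, return_counts=True)[1]
            const_a += float(sum(math.lgamma(c + 1.0) for c in counts if c > 1))
        c_k = float(sum(math.lgamma(k + 1.0) for k in graph.degrees))
        p = 2.0 * M / N**2 if N else 0.0
        params = np.array([float(M), float(N), p, self.prior0,
                           1.0 if self.zeta_minus_diag else 0.0,
                           const_a, c_k])
        lq = log_q_table(2 * M, N) if self.needs_lq else _DUMMY_LQ
        self._cache[graph] = (params, lq)
        return params, lq

    # -- evaluation ------------------------------------------------------------
    def value(self, state: BlockState) -> float:
        """Full objective value of a block state."""
        if not self.allow_empty and np.any(state.n_r == 0):
            raise ValueError(f"{self.name} does not permit empty blocks")
        params, lq = self.bind(state.graph)
        v = _kernel.full_value(self.oid, state.E, state.e_r, state.n_r,
                               state.hist, state.K, params, lq)
        if math.isnan(v):
            raise ValueError(
                f"{self.name} undefined for this state (edge count exceeds "
                "available pairs; multigraph density violation)")
        return float(v)

    def delta(self, state: BlockState, move: MoveProposal) -> float:
        """Objective change of a single-node move, without applying it."""
        if move.source != state.labels[move.node]:
            raise ValueError("move source does not match state")
        if not 0 <= move.target < state.K:
            raise ValueError("delta contract requires an existing target block")
        params, lq = self.bind(state.graph)
        return float(_kernel.move_delta(
            self.oid, state.labels, state.E, state.e_r, state.n_r, state.hist,
            state.K, params, lq, state.graph.indptr, state.graph.stubs,
            move.node, move.target))

    def merge_delta(self, state: BlockState, r: int, s: int) -> float:
        """Objective change of merging block s into block r."""
        if r == s:
            raise ValueError("cannot merge a block with itself")
        params, lq = self.bind(state.graph)
        return float(_kernel.merge_delta(
            self.oid, state.E, state.e_r, state.n_r, state.hist, state.K,
            params, lq, r, s))


def _is_simple(graph: Graph) -> bool:
    if graph.simple:
        return True
    e = graph.edges
    if e.size and np.any(e[:, 0] == e[:, 1]):
        return False
    return not np.any(graph.edge_multiplicities() > 1)


_SLOW = "O(K+<k>)"

OBJECTIVES: dict[str, Objective] = {o.name: o for o in [
    Objective("SKN", _kernel.SKN, includes_K_selection=False,
              degree_corrected=False, delta_cost_class=_SLOW),
    Objective("SPC_dense", _kernel.SPC_DENSE, includes_K_selection=False,
              degree_corrected=False, delta_cost_class=_SLOW),
    Objective("SPC_sparse", _kernel.SPC_SPARSE, includes_K_selection=False,
              degree_corrected=False, delta_cost_class=_SLOW),
    Objective("DCKN", _kernel.DCKN, includes_K_selection=False,
              degree_corrected=True),
    Objective("DCP", _kernel.DCP, includes_K_selection=False,
              degree_corrected=True),
    Objective("ICLexJ", _kernel.ICLEXJ, includes_K_selection=True,
              degree_corrected=False, delta_cost_class=_SLOW,
              prior0=0.5, needs_simple=True),
    Objective("ICLexU", _kernel.ICLEXU, includes_K_selection=True,
              degree_corrected=False, delta_cost_class=_SLOW,
              prior0=1.0, needs_simple=True),
    Objective("SNR", _kernel.SNR, includes_K_selection=True,
              degree_corrected=False, allow_empty=True,
              delta_cost_class=_SLOW),
    Objective("DCNR", _kernel.DCNR, includes_K_selection=True,
              degree_corrected=True, allow_empty=True,
              delta_cost_class=_SLOW),
    Objective("SPC", _kernel.SPC, includes_K_selection=True,
              degree_corrected=False),
    Objective("DCPU", _kernel.DCPU, includes_K_selection=True,
              degree_corrected=True),
    Objective("DCPUH", _kernel.DCPUH, includes_K_selection=True,
              degree_corrected=True, needs_lq=True),
]}

#: the objectives usable at fixed K without further machinery
FLAT_NAMES = list(OBJECTIVES)


def get_objective(name: str) -> Objective:
    try:
        return OBJECTIVES[name]
    except KeyError:
        raise KeyError(f"unknown objective {name!r}; "
                       f"choose from {', '.join(OBJECTIVES)}") from None


def delta_objective(state: BlockState, move: MoveProposal,
                    objective: Objective | str) -> float:
    """Module-level convenience wrapper for the delta contract."""
    if isinstance(objective, str):
        objective = get_objective(objective)
    return objective.delta(state, move)


def bernoulli_loglik_oracle(state: BlockState, params: SBMParams,
                            btilde: np.ndarray) -> float:
    """Reference Bernoulli SBM log-likelihood (for tests and sanity checks).

    ``log P(G, b | omega, btilde)`` for a simple graph: a multinomial term
    for the partition and an independent Bernoulli term per node pair, with
    ``n_rr = n_r (n_r + 1) / 2`` diagonal pair counting.
    """
    if not _is_simple(state.graph):
        raise ValueError("Bernoulli likelihood requires a simple graph")
    omega = np.asarray(params.omega, dtype=float)
    btilde = np.asarray(btilde, dtype=float)
    if omega.shape != (state.K, state.K):
        raise ValueError("omega shape must be (K, K)")
    if np.any(omega <= 0) or np.any(omega >= 1):
        raise ValueError("omega entries must be in (0, 1)")
    if btilde.shape != (state.K,) or abs(btilde.sum() - 1.0) > 1e-9 \
            or np.any(btilde <= 0):
        raise ValueError("btilde must be a positive probability vector")
    n = state.n_r
    ll = float(np.dot(n, np.log(btilde)))
    for r in range(state.K):
        for s in range(r, state.K):
            e_rs = state.m(r, s)
            n_rs = n[r] * n[s] if r != s else n[r] * (n[r] + 1) // 2
            ll += e_rs * math.log(omega[r, s]) \
                + (n_rs - e_rs) * math.log(1.0 - omega[r, s])
    return ll
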