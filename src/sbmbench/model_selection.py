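"""Choosing the number of blocks K for the classic objectives.

The classic profile likelihoods (SKN, DCKN, DCP) grow monotonically with K,
so an external penalty is needed.  Three criteria are provided, each turned
into a *maximize* score so that ``select_k`` is a plain argmax:

* MDL — the description-length penalty: ``log ((K, N)) + log N! -
  sum_r log n_r! + log ((K(K+1)/2, M))``, plus the summed per-block
  degree-distribution entropy for degree-corrected models; subtracted from
  the log-likelihood.
* AIC — ``-(-2 loglik + 2 p)`` with ``p = K(K+1)/2 + K`` parameters
  (plus K degree-distribution parameters for DC models).
* BIC — ``-(-2 loglik + K(K+1)/2 log N^3)`` (DC adds the constant
  ``2 log N``).

Objectives that already include a prior over K use criterion ``none``.
All logarithms are natural, consistent with the objectives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._tables import log_multiset
from .state import BlockState

__all__ = ["SelectionCriterion", "mdl_penalty", "aic_score", "bic_score",
           "penalized_score", "select_k", "golden_section_k"]

_CRITERIA = ("mdl", "aic", "bic", "none")


@dataclass(frozen=True)
class SelectionCriterion:
    """A named penalty; ``dc_variant`` switches in the degree-corrected
    extra terms.  Scores are oriented so that larger is always better."""

    name: str = "mdl"
    dc_variant: bool = False

    def __post_init__(self):
        if self.name not in _CRITERIA:
            raise ValueError(f"criterion must be one of {_CRITERIA}")


def mdl_penalty(state: BlockState, dc: bool = False) -> float:
    """Description-length penalty (to subtract from the log-likelihood)."""
    K, N, M = state.K, state.graph.N, state.graph.M
    pen = log_multiset(K, N) + math.lgamma(N + 1.0)
    pen -= sum(math.lgamma(int(n) + 1.0) for n in state.n_r)
    pen += log_multiset(K * (K + 1) // 2, M)
    if dc:
        # - sum_r n_r sum_k p_k^r log p_k^r  with p_k^r = N_k^r / n_r
        for r in range(K):
            n_r = int(state.n_r[r])
            if n_r == 0:
                continue
            counts = state.hist[r]
            nz = counts[counts > 0] / n_r
            pen += -n_r * float(np.sum(nz * np.log(nz)))
    return pen


def aic_score(objective_value: float, K: int, dc: bool = False) -> float:
    """Negated AIC (larger is better)."""
    params = K * (K + 1) // 2 + K
    if dc:
        params += K
    return -(-2.0 * objective_value + 2.0 * params)


def bic_score(objective_value: float, K: int, N: int, dc: bool = False) -> float:
    """Negated BIC (larger is better)."""
    pen = K * (K + 1) / 2.0 * math.log(float(N) ** 3)
    if dc:
        pen += 2.0 * math.log(N)
    return -(-2.0 * objective_value + pen)


def penalized_score(objective_value: float, state: BlockState,
                    criterion: SelectionCriterion) -> float:
    if criterion.name == "none":
        return objective_value
    if criterion.name == "mdl":
        return objective_value - mdl_penalty(state, dc=criterion.dc_variant)
    if criterion.name == "aic":
        return aic_score(objective_value, state.K, dc=criterion.dc_variant)
    return bic_score(objective_value, state.K, state.graph.N,
                     dc=criterion.dc_variant)


def select_k(results: dict[int, tuple[float, BlockState]],
             criterion: SelectionCriterion) -> tuple[int, BlockState]:
    """Argmax of the penalized score over a K -> (value, state) sweep.

    Ties break toward smaller K.
    """
    if not results:
        raise ValueError("empty result set")
    best_k, best_score = None, -math.inf
    for K in sorted(results):
        value, state = results[K]
        score = penalized_score(value, state, criterion)
        if score > best_score:
            best_k, best_score = K, score
    return best_k, results[best_k][1]


def golden_section_k(score_at, k_min: int, k_max: int) -> int:
    """Golden-section search for the argmax of a unimodal integer score.

    ``score_at(K)`` is called lazily and memoized; on plateaus or weakly
    non-unimodal scores the result may be a local optimum — the exhaustive
    sweep is the safe default.
    """
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    cache: dict[int, float] = {}

    def f(k: int) -> float:
        if k not in cache:
            cache[k] = score_at(k)
        return cache[k]

    a, b = k_min, k_max
    while b - a > 2:
        span = b - a
        c = b - int(round(phi * span))
        d = a + int(round(phi * span))
        if c == d:
            d += 1
        if f(c) >= f(d):
            b = d
        else:
            a = c
    return min(range(a, b + 1), key=lambda k: (-f(k), k))
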