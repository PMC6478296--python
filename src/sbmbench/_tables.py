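"""Shared combinatorial primitives: log-factorials, multiset coefficients and
restricted integer partitions.

All likelihood arithmetic is carried out in natural-log space via ``lgamma``;
the exact big-integer recurrences here exist for the restricted-partition
numbers (needed by the hyperprior degree term) and for test oracles.
"""

from __future__ import annotations

from functools import lru_cache
from math import lgamma, log

import numpy as np
from numba import njit


def log_factorial_table(nmax: int) -> np.ndarray:
    """``t[x] = log(x!)`` for ``x = 0..nmax``."""
    t = np.zeros(nmax + 1)
    np.cumsum(np.log(np.arange(1, nmax + 1)), out=t[1:])
    return t


def xlogx_table(nmax: int) -> np.ndarray:
    """``t[x] = x log x`` with the ``0 log 0 = 0`` convention."""
    t = np.zeros(nmax + 1)
    x = np.arange(1, nmax + 1, dtype=float)
    t[1:] = x * np.log(x)
    return t


def log_multiset(n: int, k: int) -> float:
    """log of the multiset coefficient ((n, k)) = C(n + k - 1, k).

    ``((n, 0)) = 1`` for any ``n >= 0`` (including n = 0).
    """
    if n < 0 or k < 0:
        raise ValueError("multiset coefficient needs n, k >= 0")
    if k == 0:
        return 0.0
    if n == 0:
        raise ValueError("((0, k)) undefined for k > 0")
    return lgamma(n + k) - lgamma(k + 1) - lgamma(n)


@lru_cache(maxsize=None)
def restricted_partitions_q(m: int, n: int) -> int:
    """Number of partitions of the integer ``m`` into at most ``n`` parts.

    Exact big-integer recurrence ``q(m, n) = q(m, n-1) + q(m-n, n)`` with
    ``q(0, n) = 1`` and ``q(m, 0) = 0`` for ``m > 0``.
    """
    if m < 0 or n < 0:
        raise ValueError("restricted partitions need m, n >= 0")
    if m == 0:
        return 1
    if n == 0:
        return 0
    if n > m:
        n = m  # parts larger than m can never be used
    if n == 1:
        return 1
    return restricted_partitions_q(m, n - 1) + restricted_partitions_q(m - n, n)


@njit(cache=True)
def _log_q_fill(table):  # pragma: no cover - exercised via log_q_table
    mmax = table.shape[0] - 1
    nmax = table.shape[1] - 1
    NEG = -np.inf
    for m in range(mmax + 1):
        table[m, 0] = 0.0 if m == 0 else NEG
    for n in range(1, nmax + 1):
        table[0, n] = 0.0
        for m in range(1, mmax + 1):
            a = table[m, n - 1]
            b = table[m - n, n] if m >= n else NEG
            if a == NEG:
                table[m, n] = b
            elif b == NEG:
                table[m, n] = a
            else:
                hi = a if a > b else b
                table[m, n] = hi + np.log(np.exp(a - hi) + np.exp(b - hi))
    return table


def log_q_table(mmax: int, nmax: int) -> np.ndarray:
    """``t[m, n] = log q(m, n)`` computed by a log-sum-exp recurrence."""
    table = np.empty((mmax + 1, nmax + 1))
    return _log_q_fill(table)


def binary_entropy(x: float) -> float:
    """Natural-log binary entropy H(x) = -x log x - (1-x) log(1-x)."""
    if x < 0.0 or x > 1.0:
        raise ValueError("binary entropy needs x in [0, 1]")
    h = 0.0
    if x > 0.0:
        h -= x * log(x)
    if x < 1.0:
        h -= (1.0 - x) * log(1.0 - x)
    return h
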