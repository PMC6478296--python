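"""Independent reference implementations used as test oracles.

Everything here is transcribed directly from the model definitions with
plain Python arithmetic (exact integers and fractions where possible) and
recomputes block statistics by brute-force edge counting.  Nothing imports
the package's kernel, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import lgamma, log

import numpy as np


# ---------------------------------------------------------------------------
# brute-force block statistics
# ---------------------------------------------------------------------------

def block_stats(edges, labels, K):
    """(m, n, e, deg): m[r][s] unordered edge counts (diagonal once),
    block sizes, block stub counts, node degrees."""
    labels = list(labels)
    N = len(labels)
    m = [[0] * K for _ in range(K)]
    deg = [0] * N
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
        r, s = labels[u], labels[v]
        if r == s:
            m[r][r] += 1
        else:
            m[min(r, s)][max(r, s)] += 1
            m[max(r, s)][min(r, s)] += 1
    n = [labels.count(r) for r in range(K)]
    e = [sum(m[r]) + m[r][r] for r in range(K)]
    return m, n, e, deg


def _xlogx(x):
    return x * log(x) if x > 0 else 0.0


# ---------------------------------------------------------------------------
# flat objectives
# ---------------------------------------------------------------------------

def skn(edges, labels, K):
    """(1/2) sum_rs e_rs log(e_rs / n_r n_s), doubled diagonal."""
    m, n, e, _ = block_stats(edges, labels, K)
    v = 0.0
    for r in range(K):
        for s in range(K):
            ers = 2 * m[r][r] if r == s else m[r][s]
            if ers:
                v += 0.5 * ers * log(ers / (n[r] * n[s]))
    return v


def spc_dense(edges, labels, K):
    m, n, e, _ = block_stats(edges, labels, K)
    v = 0.0
    for r in range(K):
        for s in range(K):
            pairs = n[r] * n[s]
            if pairs == 0:
                continue
            x = (2 * m[r][r] if r == s else m[r][s]) / pairs
            h = -_xlogx(x) - _xlogx(1.0 - x)
            v -= 0.5 * pairs * h
    return v


def spc_sparse(edges, labels, K):
    return -len(edges) + skn(edges, labels, K)


def dckn(edges, labels, K):
    m, n, e, _ = block_stats(edges, labels, K)
    v = 0.0
    for r in range(K):
        for s in range(K):
            ers = 2 * m[r][r] if r == s else m[r][s]
            if ers:
                v += ers * log(ers / (e[r] * e[s]))
    return v


def dcp(edges, labels, K):
    _, _, _, deg = block_stats(edges, labels, K)
    nk = {}
    for k in deg:
        nk[k] = nk.get(k, 0) + 1
    return (len(edges) + sum(c * math.log(math.factorial(k)) for k, c in nk.items())
            + 0.5 * dckn(edges, labels, K))


def iclex(edges, labels, K, prior0, zeta_minus_diag=True):
    m, n, e, _ = block_stats(edges, labels, K)
    N = len(list(labels))
    v = 0.0
    for r in range(K):
        for s in range(r, K):
            ers = m[r][s]
            nrs = n[r] * n[s] if r != s else n[r] * (n[r] + 1) // 2
            eta = prior0 + ers
            zeta = prior0 + nrs - (ers if (r != s or zeta_minus_diag) else 0)
            v += (lgamma(2 * prior0) + lgamma(eta) + lgamma(zeta)
                  - lgamma(eta + zeta) - 2 * lgamma(prior0))
    v += lgamma(K * prior0)
    for r in range(K):
        v += lgamma(n[r] + prior0)
    v -= lgamma(N + K * prior0) + K * lgamma(prior0)
    return v


def snr(edges, labels, K):
    m, n, e, _ = block_stats(edges, labels, K)
    N = len(list(labels))
    M = len(edges)
    p = 2.0 * M / N**2
    v = -log(N)                                   # P(K) = 1/N
    v += lgamma(K) - lgamma(N + K)                # (K-1)!/(N+K-1)!
    for r in range(K):
        v += lgamma(n[r] + 1)
    for r in range(K):
        v += (math.log(math.factorial(m[r][r]))
              - (m[r][r] + 1) * log(0.5 * p * n[r] ** 2 + 1.0))
        for s in range(r + 1, K):
            v += (math.log(math.factorial(m[r][s]))
                  - (m[r][s] + 1) * log(p * n[r] * n[s] + 1.0))
    return v


def dcnr(edges, labels, K):
    m, n, e, _ = block_stats(edges, labels, K)
    v = snr(edges, labels, K)
    for r in range(K):
        if n[r] > 0:
            v += (e[r] * log(n[r]) + lgamma(n[r]) - lgamma(n[r] + e[r]))
    return v


# exact-integer microcanonical family --------------------------------------

def _multiset(n, k):
    if k == 0:
        return 1
    return math.comb(n + k - 1, k)


def q_exact(m, n, _cache={}):
    """Restricted partitions of m into at most n parts (exact integers)."""
    if m == 0:
        return 1
    if n == 0:
        return 0
    key = (m, min(n, m))
    if key not in _cache:
        n = min(n, m)
        _cache[key] = q_exact(m, n - 1) + q_exact(m - n, n)
    return _cache[key]


def _graph_count_fraction(edges, labels, K, degree_corrected):
    """Exact-rational P(G|e,b) (or P(G|k,e,b)) of the microcanonical SBM."""
    m, n, e, deg = block_stats(edges, labels, K)
    N = len(list(labels))
    # multiplicities
    mult = {}
    loops = [0] * N
    for u, v in edges:
        if u == v:
            loops[u] += 1
        else:
            key = (min(u, v), max(u, v))
            mult[key] = mult.get(key, 0) + 1
    num = Fraction(1)
    for r in range(K):
        num *= Fraction(2) ** m[r][r] * math.factorial(m[r][r])  # e_rr!!
        for s in range(r + 1, K):
            num *= math.factorial(m[r][s])
    den = Fraction(1)
    for c in mult.values():
        den *= math.factorial(c)
    for a in loops:
        den *= Fraction(2) ** a * math.factorial(a)
    if degree_corrected:
        for k in deg:
            num *= math.factorial(k)
        for r in range(K):
            den *= math.factorial(e[r])
    else:
        for r in range(K):
            den *= Fraction(n[r]) ** e[r]
    return num / den


def _pe_pb_fraction(edges, labels, K):
    N = len(list(labels))
    M = len(edges)
    m, n, e, _ = block_stats(edges, labels, K)
    pe = Fraction(1, _multiset(K * (K + 1) // 2, M))
    pb = Fraction(1)
    for r in range(K):
        pb *= math.factorial(n[r])
    pb /= math.factorial(N)
    pb /= math.comb(N - 1, K - 1)
    pb /= N
    return pe * pb


def _log_fraction(f: Fraction) -> float:
    return math.log(f.numerator) - math.log(f.denominator)


def spc(edges, labels, K):
    f = _graph_count_fraction(edges, labels, K, degree_corrected=False)
    return _log_fraction(f * _pe_pb_fraction(edges, labels, K))


def dcpu(edges, labels, K):
    m, n, e, _ = block_stats(edges, labels, K)
    f = _graph_count_fraction(edges, labels, K, degree_corrected=True)
    for r in range(K):
        f /= _multiset(n[r], e[r])
    return _log_fraction(f * _pe_pb_fraction(edges, labels, K))


def dcpuh(edges, labels, K):
    m, n, e, deg = block_stats(edges, labels, K)
    f = _graph_count_fraction(edges, labels, K, degree_corrected=True)
    labels = list(labels)
    for r in range(K):
        hist = {}
        for i, b in enumerate(labels):
            if b == r:
                hist[deg[i]] = hist.get(deg[i], 0) + 1
        fr = Fraction(1)
        for c in hist.values():
            fr *= math.factorial(c)
        fr /= math.factorial(n[r])
        fr /= q_exact(e[r], n[r])
        f *= fr
    return _log_fraction(f * _pe_pb_fraction(edges, labels, K))


ORACLES = {
    "SKN": skn, "SPC_dense": spc_dense, "SPC_sparse": spc_sparse,
    "DCKN": dckn, "DCP": dcp,
    "ICLexJ": lambda E, b, K: iclex(E, b, K, 0.5),
    "ICLexU": lambda E, b, K: iclex(E, b, K, 1.0),
    "SNR": snr, "DCNR": dcnr,
    "SPC": spc, "DCPU": dcpu, "DCPUH": dcpuh,
}


# ---------------------------------------------------------------------------
# AMI_max (permutation-model expected MI), transcribed from first principles
# ---------------------------------------------------------------------------

def ami_max_reference(a, b):
    a = list(a)
    b = list(b)
    n = len(a)
    ua, ub = sorted(set(a)), sorted(set(b))
    na = {x: a.count(x) for x in ua}
    nb = {y: b.count(y) for y in ub}
    nab = {(x, y): sum(1 for i in range(n) if a[i] == x and b[i] == y)
           for x in ua for y in ub}
    H_a = -sum(c / n * log(c / n) for c in na.values())
    H_b = -sum(c / n * log(c / n) for c in nb.values())
    mi = 0.0
    for (x, y), c in nab.items():
        if c:
            mi += c / n * log(n * c / (na[x] * nb[y]))
    emi = 0.0
    for x in ua:
        ai = na[x]
        for y in ub:
            bj = nb[y]
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                p = math.exp(lgamma(ai + 1) - lgamma(nij + 1) - lgamma(ai - nij + 1)
                             + lgamma(n - ai + 1) - lgamma(bj - nij + 1)
                             - lgamma(n - ai - bj + nij + 1)
                             - (lgamma(n + 1) - lgamma(bj + 1) - lgamma(n - bj + 1)))
                emi += p * (nij / n) * log(n * nij / (ai * bj))
    denom = max(H_a, H_b) - emi
    if denom == 0:
        return 1.0 if a == b else 0.0
    return (mi - emi) / denom
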