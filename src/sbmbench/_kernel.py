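"""Numba kernels: objective evaluation, single-move deltas and MCMC loops.

Every flat objective is decomposed into

    value = sum_{r<s} pair(r, s) + sum_r diag(r) + sum_r block(r)
            + kconst(K) + gconst

where pair/diag/block touch only the statistics of the named blocks.  Moving
one node (or merging two blocks) changes only the rows/columns of the source
and target block, so a delta is the difference of the local terms (plus the
K-dependent constant for merges).  The block count stays small in every
workload here, so the uniform O(K) row access is used for all objectives.

Conventions (shared with :mod:`sbmbench.state`):

* ``E`` is the ordered block adjacency with doubled diagonal,
  ``E[r, s] = m_rs`` for ``r != s`` and ``E[r, r] = 2 m_rr``.
* ``e[r]`` is the stub count of block r, ``n[r]`` its size,
  ``hist[r, k]`` the number of degree-k nodes in block r.
* ``params = [M, N, p, prior0, zeta_minus_diag, const_A, C_k]`` with
  ``p = 2M/N**2``, ``const_A = sum_{i<j} log A_ij! + sum_i log A_ii!!`` and
  ``C_k = sum_i log k_i!``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# objective ids (order mirrors the variant table of the comparison)
SKN = 0
SPC_DENSE = 1
SPC_SPARSE = 2
DCKN = 3
DCP = 4
ICLEXJ = 5
ICLEXU = 6
SNR = 7
DCNR = 8
SPC = 9
DCPU = 10
DCPUH = 11

# params layout
P_M = 0
P_N = 1
P_P = 2
P_PRIOR0 = 3
P_ZDIAG = 4
P_CONSTA = 5
P_CK = 6


@njit(cache=True, inline="always")
def _lf(x):
    """log(x!)"""
    return math.lgamma(x + 1.0)


@njit(cache=True, inline="always")
def _lms(n, k):
    """log multiset coefficient ((n, k)); 0 when k == 0."""
    if k <= 0:
        return 0.0
    return math.lgamma(n + k) - math.lgamma(k + 1.0) - math.lgamma(n)


@njit(cache=True, inline="always")
def _lbinom(a, b):
    """log C(a, b)"""
    return math.lgamma(a + 1.0) - math.lgamma(b + 1.0) - math.lgamma(a - b + 1.0)


@njit(cache=True, inline="always")
def _H(x):
    h = 0.0
    if x > 0.0:
        h -= x * math.log(x)
    if x < 1.0:
        h -= (1.0 - x) * math.log(1.0 - x)
    return h


@njit(cache=True)
def _pair(obj, Ers, nr, ns, er, es, params):
    """Off-diagonal term for ordered pair r < s (counted once)."""
    if obj == SKN or obj == SPC_SPARSE:
        if Ers == 0:
            return 0.0
        return Ers * math.log(Ers / (nr * float(ns)))
    if obj == SPC_DENSE:
        pairs = nr * float(ns)
        if pairs == 0.0:
            return 0.0
        x = Ers / pairs
        if x > 1.0:
            return np.nan
        return -pairs * _H(x)
    if obj == DCKN:
        if Ers == 0:
            return 0.0
        return 2.0 * Ers * math.log(Ers / (er * float(es)))
    if obj == DCP:
        if Ers == 0:
            return 0.0
        return Ers * math.log(Ers / (er * float(es)))
    if obj == ICLEXJ or obj == ICLEXU:
        p0 = params[P_PRIOR0]
        nonedges = nr * float(ns) - Ers
        if nonedges < 0.0:
            return np.nan
        eta = p0 + Ers
        zeta = p0 + nonedges
        return (math.lgamma(2.0 * p0) + math.lgamma(eta) + math.lgamma(zeta)
                - math.lgamma(eta + zeta) - 2.0 * math.lgamma(p0))
    if obj == SNR or obj == DCNR:
        p = params[P_P]
        return _lf(Ers) - (Ers + 1.0) * math.log(p * nr * ns + 1.0)
    # SPC family: product of e_rs!
    return _lf(Ers)


@njit(cache=True)
def _diag(obj, Err, nr, er, params):
    """Diagonal term for block r; ``Err`` is the doubled count 2*m_rr."""
    if obj == SKN or obj == SPC_SPARSE:
        if Err == 0:
            return 0.0
        return 0.5 * Err * math.log(Err / (nr * float(nr)))
    if obj == SPC_DENSE:
        pairs = nr * float(nr)
        if pairs == 0.0:
            return 0.0
        x = Err / pairs
        if x > 1.0:
            return np.nan
        return -0.5 * pairs * _H(x)
    if obj == DCKN:
        if Err == 0:
            return 0.0
        return Err * math.log(Err / (er * float(er)))
    if obj == DCP:
        if Err == 0:
            return 0.0
        return 0.5 * Err * math.log(Err / (er * float(er)))
    m = Err // 2
    if obj == ICLEXJ or obj == ICLEXU:
        p0 = params[P_PRIOR0]
        pairs = nr * (nr + 1.0) / 2.0
        nonedges = pairs - (m if params[P_ZDIAG] != 0.0 else 0)
        if nonedges < 0.0:
            return np.nan
        eta = p0 + m
        zeta = p0 + nonedges
        return (math.lgamma(2.0 * p0) + math.lgamma(eta) + math.lgamma(zeta)
                - math.lgamma(eta + zeta) - 2.0 * math.lgamma(p0))
    if obj == SNR or obj == DCNR:
        p = params[P_P]
        return _lf(m) - (m + 1.0) * math.log(0.5 * p * nr * nr + 1.0)
    # SPC family: e_rr!! = 2^m m!
    return m * math.log(2.0) + _lf(m)


@njit(cache=True)
def _block(obj, nr, er, hist_r, lq, params):
    """Per-block term for block r (size / degree-sequence priors)."""
    if obj == ICLEXJ or obj == ICLEXU:
        return math.lgamma(nr + params[P_PRIOR0])
    if obj == SNR:
        return _lf(nr)
    if obj == DCNR:
        v = _lf(nr)
        if nr > 0:
            v += er * math.log(float(nr)) + math.lgamma(float(nr)) \
                - math.lgamma(float(nr + er))
        return v
    if obj == SPC:
        v = _lf(nr)
        if nr > 0 and er > 0:
            v -= er * math.log(float(nr))
        return v
    if obj == DCPU:
        return _lf(nr) - _lf(er) - _lms(nr, er)
    if obj == DCPUH:
        v = -_lf(er) - lq[er, nr]
        for k in range(hist_r.shape[0]):
            if hist_r[k] > 1:
                v += _lf(hist_r[k])
        return v
    return 0.0


@njit(cache=True)
def _kconst(obj, K, params):
    """K-dependent additive constant (matters for merges / K comparison)."""
    N = params[P_N]
    M = params[P_M]
    if obj == ICLEXJ or obj == ICLEXU:
        p0 = params[P_PRIOR0]
        return math.lgamma(K * p0) - math.lgamma(N + K * p0) - K * math.lgamma(p0)
    if obj == SNR or obj == DCNR:
        return math.lgamma(float(K)) - math.lgamma(N + K)
    if obj == SPC or obj == DCPU or obj == DCPUH:
        return -_lms(K * (K + 1.0) / 2.0, M) - _lbinom(N - 1.0, K - 1.0)
    return 0.0


@njit(cache=True)
def _gconst(obj, params):
    """K-independent additive constant."""
    M = params[P_M]
    N = params[P_N]
    if obj == SPC_SPARSE:
        return -M
    if obj == DCP:
        return M + params[P_CK]
    if obj == SNR or obj == DCNR:
        return -math.log(N)
    if obj == SPC:
        return -params[P_CONSTA] - _lf(N) - math.log(N)
    if obj == DCPU or obj == DCPUH:
        return params[P_CK] - params[P_CONSTA] - _lf(N) - math.log(N)
    return 0.0


@njit(cache=True)
def full_value(obj, E, e, n, hist, K, params, lq):
    v = _kconst(obj, K, params) + _gconst(obj, params)
    for r in range(K):
        v += _diag(obj, E[r, r], n[r], e[r], params)
        v += _block(obj, n[r], e[r], hist[r], lq, params)
        for s in range(r + 1, K):
            v += _pair(obj, E[r, s], n[r], n[s], e[r], e[s], params)
    return v


@njit(cache=True)
def _local(obj, E, e, n, hist, K, params, lq, r, s):
    """Sum of all terms touching blocks r or s (r != s)."""
    v = (_diag(obj, E[r, r], n[r], e[r], params)
         + _diag(obj, E[s, s], n[s], e[s], params)
         + _block(obj, n[r], e[r], hist[r], lq, params)
         + _block(obj, n[s], e[s], hist[s], lq, params)
         + _pair(obj, E[r, s], n[r], n[s], e[r], e[s], params))
    for t in range(K):
        if t == r or t == s:
            continue
        v += _pair(obj, E[r, t], n[r], n[t], e[r], e[t], params)
        v += _pair(obj, E[s, t], n[s], n[t], e[s], e[t], params)
    return v


@njit(cache=True, inline="always")
def _shift_node(i, r, s, labels, E, e, n, hist, indptr, stubs):
    """Move node i from block r to block s, updating all statistics."""
    selfstubs = 0
    for idx in range(indptr[i], indptr[i + 1]):
        j = stubs[idx]
        if j == i:
            selfstubs += 1
        else:
            t = labels[j]
            E[r, t] -= 1
            E[t, r] -= 1
            E[s, t] += 1
            E[t, s] += 1
    if selfstubs > 0:
        E[r, r] -= selfstubs
        E[s, s] += selfstubs
    k = indptr[i + 1] - indptr[i]
    e[r] -= k
    e[s] += k
    n[r] -= 1
    n[s] += 1
    hist[r, k] -= 1
    hist[s, k] += 1
    labels[i] = s


@njit(cache=True)
def move_delta(obj, labels, E, e, n, hist, K, params, lq, indptr, stubs, i, s):
    """Objective change for moving node i to block s (state left untouched)."""
    r = labels[i]
    if s == r:
        return 0.0
    before = _local(obj, E, e, n, hist, K, params, lq, r, s)
    _shift_node(i, r, s, labels, E, e, n, hist, indptr, stubs)
    after = _local(obj, E, e, n, hist, K, params, lq, r, s)
    _shift_node(i, s, r, labels, E, e, n, hist, indptr, stubs)
    return after - before


@njit(cache=True)
def merge_delta(obj, E, e, n, hist, K, params, lq, r, s):
    """Objective change for merging block s into block r (K -> K-1)."""
    before = _local(obj, E, e, n, hist, K, params, lq, r, s)
    # merged block statistics
    Emm = E[r, r] + E[s, s] + 2 * E[r, s]
    nm = n[r] + n[s]
    em = e[r] + e[s]
    hm = hist[r] + hist[s]
    after = (_diag(obj, Emm, nm, em, params)
             + _block(obj, nm, em, hm, lq, params))
    for t in range(K):
        if t == r or t == s:
            continue
        after += _pair(obj, E[r, t] + E[s, t], nm, n[t], em, e[t], params)
    return (after - before
            + _kconst(obj, K - 1, params) - _kconst(obj, K, params))


@njit(cache=True)
def batch_deltas(obj, labels, E, e, n, hist, K, params, lq, indptr, stubs,
                 active, allow_empty, out):
    """Fill ``out[i, s]`` with move deltas for all active nodes.

    Invalid moves (inactive node, s == current block, or a move that would
    empty a block at fixed K) get ``-inf``.  Returns the number of deltas
    actually evaluated.
    """
    N = labels.shape[0]
    count = 0
    for i in range(N):
        if not active[i]:
            for s in range(K):
                out[i, s] = -np.inf
            continue
        r = labels[i]
        blocked = (not allow_empty) and n[r] == 1
        for s in range(K):
            if s == r or blocked:
                out[i, s] = -np.inf
            else:
                out[i, s] = move_delta(obj, labels, E, e, n, hist, K, params,
                                       lq, indptr, stubs, i, s)
                count += 1
    return count


@njit(cache=True)
def node_deltas(obj, labels, E, e, n, hist, K, params, lq, indptr, stubs,
                i, allow_empty, out):
    """Deltas for all target blocks of one node; invalid targets get -inf."""
    r = labels[i]
    blocked = (not allow_empty) and n[r] == 1
    count = 0
    for s in range(K):
        if s == r or blocked:
            out[s] = -np.inf
        else:
            out[s] = move_delta(obj, labels, E, e, n, hist, K, params, lq,
                                indptr, stubs, i, s)
            count += 1
    return count


@njit(cache=True)
def mcmc_run(steps, beta, eps, hastings, allow_empty, obj,
             labels, E, e, n, hist, K, params, lq,
             indptr, stubs, seed, best_labels, record, thin):
    """Metropolis / Metropolis-Hastings chain over node moves at fixed K.

    Mutates ``labels`` and the block statistics in place.  Returns
    ``(delta_sum, best_delta_sum, accepted_moves)`` relative to the initial
    state; ``best_labels`` receives the best state visited.  When ``record``
    has size K**N (tiny instances only) every ``thin``-th chain state is
    counted in it, indexed by the base-K encoding of the label vector.
    """
    np.random.seed(seed)
    N = labels.shape[0]
    cur = 0.0
    best = 0.0
    moves = 0
    cnt = np.zeros(K, dtype=np.int64)
    do_record = record.shape[0] > 1
    for i0 in range(N):
        best_labels[i0] = labels[i0]
    for step in range(steps):
        i = np.random.randint(0, N)
        r = labels[i]
        di = indptr[i + 1] - indptr[i]
        use_h = hastings and di > 0
        # --- proposal ------------------------------------------------------
        if use_h:
            j = stubs[indptr[i] + np.random.randint(0, di)]
            t = labels[j]
            u = np.random.random() * (e[t] + eps * K)
            acc = 0.0
            s = K - 1
            for c in range(K):
                acc += E[t, c] + eps
                if u < acc:
                    s = c
                    break
        else:
            s = np.random.randint(0, K)
        ok = True
        if s == r:
            ok = False  # null move, trivially accepted
        elif (not allow_empty) and n[r] == 1:
            ok = False  # would empty a block at fixed K
        if ok:
            fwd = 1.0
            selfstubs = 0
            if use_h:
                for c in range(K):
                    cnt[c] = 0
                for idx in range(indptr[i], indptr[i + 1]):
                    jj = stubs[idx]
                    if jj == i:
                        selfstubs += 1
                        cnt[r] += 1
                    else:
                        cnt[labels[jj]] += 1
                fwd = 0.0
                for c in range(K):
                    if cnt[c] > 0:
                        fwd += cnt[c] * (E[c, s] + eps) / (e[c] + eps * K)
            before = _local(obj, E, e, n, hist, K, params, lq, r, s)
            _shift_node(i, r, s, labels, E, e, n, hist, indptr, stubs)
            after = _local(obj, E, e, n, hist, K, params, lq, r, s)
            delta = after - before
            log_ratio = 0.0
            if use_h:
                cnt[r] -= selfstubs
                cnt[s] += selfstubs
                rev = 0.0
                for c in range(K):
                    if cnt[c] > 0:
                        rev += cnt[c] * (E[c, r] + eps) / (e[c] + eps * K)
                log_ratio = math.log(rev) - math.log(fwd)
            log_acc = beta * delta + log_ratio
            if log_acc >= 0.0 or np.random.random() < math.exp(log_acc):
                cur += delta
                moves += 1
                if cur > best:
                    best = cur
                    for i0 in range(N):
                        best_labels[i0] = labels[i0]
            else:
                _shift_node(i, s, r, labels, E, e, n, hist, indptr, stubs)
        if do_record and step % thin == 0:
            code = 0
            for q in range(N):
                code = code * K + labels[q]
            record[code] += 1
    return cur, best, moves
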