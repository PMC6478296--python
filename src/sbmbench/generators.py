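"""Synthetic-network generators: SBM samplers and the two planted-partition
benchmarks (extended Girvan-Newman test, LFR-style networks).

The generators are the sole source of test inputs for the whole package.
Their defaults are the benchmark conditions of the comparison study:

* GN test: 4 groups of 32 nodes, mean degree 16, parameterised by the
  expected number ``k_out`` of inter-group edges per node, extended to the
  disassortative range ``P_out >= P_in`` (``k_out`` up to 16).
* LFR: 1000 nodes, mean degree 20, maximum degree 50, degree exponent -2,
  community-size exponent -1, community sizes 20..100, mixing ``mu_t``.

The LFR construction is native: truncated power-law degree and size
sampling, capacity-constrained community assignment, per-node internal /
external stub split, configuration-model wiring and a rewiring pass that
removes self-loops, duplicate edges and misplaced external edges.  Its
contract is statistical (realized mean degree and mixing close to target),
not bit-compatibility with any other generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .graph import Graph, Partition
from .objectives import SBMParams

__all__ = ["GNConfig", "LFRConfig", "sample_sbm", "sample_dcsbm",
           "gn_network", "lfr_network"]


# ---------------------------------------------------------------------------
# plain SBM / degree-corrected samplers
# ---------------------------------------------------------------------------

def _labels_from_sizes(block_sizes) -> np.ndarray:
    sizes = np.asarray(block_sizes, dtype=np.int64)
    if np.any(sizes <= 0):
        raise ValueError("block sizes must be positive")
    return np.repeat(np.arange(sizes.size), sizes)


def sample_sbm(block_sizes, params: SBMParams | np.ndarray, rng,
               mode: str = "bernoulli", self_pairs: bool = False,
               collapse: bool = False) -> tuple[Graph, Partition]:
    """Sample a graph whose edge probabilities depend only on blocks.

    ``bernoulli`` draws each unordered node pair independently with
    probability ``omega_rs``; ``poisson`` draws multiplicities with that
    rate (self-pairs, when enabled, use rate ``omega_rr / 2``).  With
    ``collapse`` any multi-edge is replaced by a single edge.
    """
    omega = params.omega if isinstance(params, SBMParams) else np.asarray(params, float)
    labels = _labels_from_sizes(block_sizes)
    K = omega.shape[0]
    if labels.max() >= K:
        raise ValueError("omega too small for the number of blocks")
    if mode == "bernoulli" and np.any(omega > 1):
        raise ValueError("bernoulli sampling needs omega entries <= 1")
    if mode not in ("bernoulli", "poisson"):
        raise ValueError("mode must be 'bernoulli' or 'poisson'")
    N = labels.size
    starts = np.searchsorted(labels, np.arange(K))
    stops = np.searchsorted(labels, np.arange(K), side="right")
    edges: list[tuple[int, int]] = []
    for r in range(K):
        ir = np.arange(starts[r], stops[r])
        for s in range(r, K):
            w = float(omega[r, s])
            if w == 0.0:
                continue
            if r == s:
                iu, ju = np.triu_indices(ir.size, k=1)
                iu, ju = ir[iu], ir[ju]
            else:
                js = np.arange(starts[s], stops[s])
                iu = np.repeat(ir, js.size)
                ju = np.tile(js, ir.size)
            if mode == "bernoulli":
                hit = rng.random(iu.size) < w
                for a, b in zip(iu[hit], ju[hit]):
                    edges.append((int(a), int(b)))
            else:
                counts = rng.poisson(w, size=iu.size)
                for a, b, c in zip(iu, ju, counts):
                    if c:
                        edges.extend([(int(a), int(b))] * int(c))
        if mode == "poisson" and self_pairs and omega[r, r] > 0:
            counts = rng.poisson(omega[r, r] / 2.0, size=ir.size)
            for a, c in zip(ir, counts):
                if c:
                    edges.extend([(int(a), int(a))] * int(c))
    if collapse:
        edges = sorted(set(edges))
    simple = mode == "bernoulli" or collapse
    g = Graph(edges, n_nodes=N, simple=simple and not self_pairs)
    return g, Partition(labels, K=K, allow_empty=True)


def sample_dcsbm(block_sizes, omega, theta, rng, mode: str = "poisson",
                 self_pairs: bool = False) -> tuple[Graph, Partition]:
    """Degree-corrected sampler: pair (i, j) has Poisson rate
    ``theta_i theta_j omega_rs`` (or Bernoulli probability
    ``1 - exp(-theta_i theta_j omega_rs)``)."""
    omega = np.asarray(omega, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    labels = _labels_from_sizes(block_sizes)
    if theta.size != labels.size:
        raise ValueError("theta length must equal node count")
    N = labels.size
    iu, ju = np.triu_indices(N, k=0 if self_pairs else 1)
    rate = theta[iu] * theta[ju] * omega[labels[iu], labels[ju]]
    if self_pairs:
        rate[iu == ju] /= 2.0
    if mode == "poisson":
        counts = rng.poisson(rate)
    elif mode == "bernoulli":
        counts = (rng.random(rate.size) < -np.expm1(-rate)).astype(np.int64)
    else:
        raise ValueError("mode must be 'bernoulli' or 'poisson'")
    edges: list[tuple[int, int]] = []
    hit = np.flatnonzero(counts)
    for idx in hit:
        edges.extend([(int(iu[idx]), int(ju[idx]))] * int(counts[idx]))
    g = Graph(edges, n_nodes=N)
    return g, Partition(labels, K=omega.shape[0], allow_empty=True)


# ---------------------------------------------------------------------------
# Girvan-Newman planted partition test
# ---------------------------------------------------------------------------

@dataclass
class GNConfig:
    """Extended GN test: ``k_out`` expected inter-group edges per node."""

    k_out: float = 0.0
    groups: int = 4
    group_size: int = 32
    mean_degree: float = 16.0

    @property
    def p_out(self) -> float:
        return self.k_out / ((self.groups - 1) * self.group_size)

    @property
    def p_in(self) -> float:
        return (self.mean_degree - self.k_out) / (self.group_size - 1)


def gn_network(config: GNConfig, rng) -> tuple[Graph, Partition]:
    """One GN-test network: planted 4x32 partition, mean degree 16."""
    if not 0.0 <= config.k_out <= config.mean_degree:
        raise ValueError("k_out must lie in [0, mean_degree]")
    K = config.groups
    omega = np.full((K, K), config.p_out)
    np.fill_diagonal(omega, config.p_in)
    g, part = sample_sbm([config.group_size] * K, SBMParams(omega), rng,
                         mode="bernoulli")
    return g, Partition(part.labels, K=K)


# ---------------------------------------------------------------------------
# LFR-style benchmark
# ---------------------------------------------------------------------------

@dataclass
class LFRConfig:
    """LFR benchmark parameters (defaults: the standard 1000-node setup)."""

    n: int = 1000
    mean_degree: float = 20.0
    max_degree: int = 50
    degree_exponent: float = 2.0
    community_exponent: float = 1.0
    community_size_range: tuple[int, int] = (20, 100)
    mu: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must be in [0, 1)")
        cmin, cmax = self.community_size_range
        if not 1 < cmin <= cmax:
            raise ValueError("bad community size range")
        # largest internal degree must fit inside the largest community
        if (1.0 - self.mu) * self.max_degree >= cmax:
            raise ValueError("infeasible: (1-mu)*k_max must be < c_max")


def _trunc_power_mean(a: float, b: float, gamma: float) -> float:
    """Mean of the continuous power law ``x^-gamma`` truncated to [a, b]."""
    def integral(exp):  # int_a^b x^exp dx
        if abs(exp + 1.0) < 1e-12:
            return math.log(b / a)
        return (b ** (exp + 1) - a ** (exp + 1)) / (exp + 1)
    return integral(1.0 - gamma) / integral(-gamma)


def _sample_trunc_power(a: float, b: float, gamma: float, size, rng):
    """Inverse-CDF sampling of the truncated continuous power law."""
    u = rng.random(size)
    if abs(gamma - 1.0) < 1e-12:
        return a * (b / a) ** u
    e = 1.0 - gamma
    return (a ** e + u * (b ** e - a ** e)) ** (1.0 / e)


def _sample_degrees(cfg: LFRConfig, rng) -> np.ndarray:
    b = float(cfg.max_degree)
    lo, hi = 1.0, b - 1e-9
    f = lambda a: _trunc_power_mean(a, b, cfg.degree_exponent) - cfg.mean_degree  # noqa: E731
    if f(lo) > 0:
        raise ValueError("mean degree below the support of the power law")
    kmin = brentq(f, lo, hi)
    deg = np.rint(_sample_trunc_power(kmin, b, cfg.degree_exponent,
                                      cfg.n, rng)).astype(np.int64)
    deg = np.clip(deg, 1, cfg.max_degree)
    if deg.sum() % 2 == 1:
        i = int(rng.integers(cfg.n))
        deg[i] += 1 if deg[i] < cfg.max_degree else -1
    return deg


def _sample_community_sizes(cfg: LFRConfig, rng, need_at_least: int) -> np.ndarray:
    cmin, cmax = cfg.community_size_range
    for _ in range(1000):
        sizes: list[int] = []
        while sum(sizes) < cfg.n:
            s = int(np.rint(_sample_trunc_power(cmin, cmax,
                                                cfg.community_exponent, 1, rng)[0]))
            sizes.append(min(max(s, cmin), cmax))
        excess = sum(sizes) - cfg.n
        if excess:
            if sizes[-1] - excess >= cmin:
                sizes[-1] -= excess
            else:
                sizes.pop()
                deficit = cfg.n - sum(sizes)
                grow = [i for i in range(len(sizes)) if sizes[i] < cmax]
                while deficit > 0 and grow:
                    i = grow[int(rng.integers(len(grow)))]
                    sizes[i] += 1
                    deficit -= 1
                    if sizes[i] == cmax:
                        grow.remove(i)
                if deficit:
                    continue
        if max(sizes) > need_at_least:
            return np.asarray(sizes, dtype=np.int64)
    raise ValueError("could not sample a feasible community size sequence")


def _assign_communities(kin: np.ndarray, sizes: np.ndarray, rng) -> np.ndarray:
    """Place nodes into communities so that ``kin_i <= size - 1`` everywhere."""
    n_comm = sizes.size
    slots = sizes.copy()
    member = np.full(kin.size, -1, dtype=np.int64)
    order = np.argsort(-kin + rng.random(kin.size) * 0.5)  # desc, random ties
    for i in order:
        feas = np.flatnonzero((slots > 0) & (sizes - 1 >= kin[i]))
        if feas.size == 0:
            raise ValueError("no feasible community for a high-degree node")
        c = int(feas[rng.integers(feas.size)])
        member[i] = c
        slots[c] -= 1
    assert slots.sum() == 0
    return member


def _pair_and_repair(stub_nodes: np.ndarray, rng, member: np.ndarray | None,
                     existing: set, internal: bool,
                     max_passes: int = 300) -> list[tuple[int, int]]:
    """Configuration-model pairing followed by double-edge-swap repair.

    Bad edges are self-loops, duplicates (within this batch or against
    ``existing``) and — for the external batch — edges that land inside a
    community.  Each repair step rewires a bad edge with a random partner
    edge, accepting the swap only if both replacement edges are good.
    """
    stubs = stub_nodes.copy()
    rng.shuffle(stubs)
    n_edge = stubs.size // 2
    edges = [(int(x), int(y)) if x <= y else (int(y), int(x))
             for x, y in zip(stubs[:n_edge], stubs[n_edge:])]
    counts: dict[tuple[int, int], int] = {}
    for e in edges:
        counts[e] = counts.get(e, 0) + 1

    def canon(x, y):
        return (x, y) if x <= y else (y, x)

    def good(x, y):
        if x == y:
            return False
        if member is not None and not internal and member[x] == member[y]:
            return False
        e = canon(x, y)
        return counts.get(e, 0) == 0 and e not in existing

    def is_bad(e):
        x, y = e
        if x == y:
            return True
        if member is not None and not internal and member[x] == member[y]:
            return True
        return counts[e] > 1 or e in existing

    for _ in range(max_passes):
        bad_idx = [i for i, e in enumerate(edges) if is_bad(e)]
        if not bad_idx:
            break
        for i in bad_idx:
            if not is_bad(edges[i]):
                continue  # fixed as a side effect of an earlier swap
            x, y = edges[i]
            for _try in range(20):
                j = int(rng.integers(n_edge))
                if j == i:
                    continue
                u, v = edges[j]
                if rng.random() < 0.5:
                    u, v = v, u
                counts[edges[i]] -= 1
                counts[edges[j]] -= 1
                if good(x, v) and good(u, y) and canon(x, v) != canon(u, y):
                    e1, e2 = canon(x, v), canon(u, y)
                    edges[i], edges[j] = e1, e2
                    counts[e1] = counts.get(e1, 0) + 1
                    counts[e2] = counts.get(e2, 0) + 1
                    break
                counts[edges[i]] += 1
                counts[edges[j]] += 1
    return edges


def lfr_network(config: LFRConfig, rng,
                max_tries: int = 20) -> tuple[Graph, Partition]:
    """Sample one LFR-style benchmark network and its planted partition."""
    last_err: Exception | None = None
    for _ in range(max_tries):
        try:
            return _lfr_once(config, rng)
        except ValueError as err:  # infeasible draw; try again
            last_err = err
    raise ValueError(f"LFR generation failed after {max_tries} tries: {last_err}")


def _lfr_once(config: LFRConfig, rng) -> tuple[Graph, Partition]:
    deg = _sample_degrees(config, rng)
    # stochastic rounding keeps E[kin] = (1 - mu) k exactly
    kin_f = (1.0 - config.mu) * deg
    kin = np.floor(kin_f + rng.random(deg.size)).astype(np.int64)
    kin = np.minimum(kin, deg)
    sizes = _sample_community_sizes(config, rng, need_at_least=int(kin.max()))
    member = _assign_communities(kin, sizes, rng)
    kout = deg - kin

    # parity fixes: internal stubs must be even per community, external even
    for c in range(sizes.size):
        nodes = np.flatnonzero(member == c)
        if kin[nodes].sum() % 2 == 1:
            cand = nodes[kin[nodes] > 0]
            i = int(cand[rng.integers(cand.size)])
            kin[i] -= 1
            if config.mu > 0.0:
                kout[i] += 1
            else:
                deg[i] -= 1
    if kout.sum() % 2 == 1:
        cand = np.flatnonzero(kout > 0)
        i = int(cand[rng.integers(cand.size)])
        kout[i] -= 1
        deg[i] -= 1

    edges: list[tuple[int, int]] = []
    existing: set = set()
    for c in range(sizes.size):
        nodes = np.flatnonzero(member == c)
        stubs = np.repeat(nodes, kin[nodes])
        if stubs.size:
            batch = _pair_and_repair(stubs, rng, member, existing, internal=True)
            edges.extend(batch)
            existing.update(batch)
    if kout.sum():
        stubs = np.repeat(np.arange(config.n), kout)
        batch = _pair_and_repair(stubs, rng, member, existing, internal=False)
        edges.extend(batch)

    # drop the rare residual self-loops/duplicates a stuck repair leaves over;
    # the realized-mean-degree contract below guards against any real loss
    edges = sorted({e for e in edges if e[0] != e[1]})
    g = Graph(edges, n_nodes=config.n, simple=True)
    if abs(g.mean_degree() - config.mean_degree) > 0.05 * config.mean_degree:
        raise ValueError("realized mean degree off target")
    return g, Partition(member, K=sizes.size)


def realized_mixing(graph: Graph, partition: Partition) -> float:
    """Mean over nodes of the fraction of their edges leaving their block."""
    labels = partition.labels
    frac = np.empty(graph.N)
    for i in range(graph.N):
        nbr = graph.neighbors(i)
        if nbr.size == 0:
            frac[i] = 0.0
        else:
            frac[i] = np.mean(labels[nbr] != labels[i])
    return float(frac.mean())
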