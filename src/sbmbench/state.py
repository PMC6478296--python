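"""Block-level sufficient statistics with incremental maintenance.

``BlockState`` caches everything the objectives and samplers read: block
sizes ``n_r``, stub counts ``e_r``, the block adjacency and per-block degree
histograms.  The block adjacency is stored in the ordered/doubled-diagonal
convention ``E[r, s] = m_rs`` (r != s), ``E[r, r] = 2 m_rr``, where ``m_rs``
counts unordered edges once; helpers expose the single-counted view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .graph import Graph, Partition


@dataclass(frozen=True)
class MoveProposal:
    """Single-node move ``(i: r -> s)``; ``s == K`` requests a new block."""

    node: int
    source: int
    target: int


class BlockState:
    """A graph plus a partition plus cached block statistics."""

    def __init__(self, graph: Graph, partition: Partition):
        labels = partition.labels
        if labels.size != graph.N:
            raise ValueError("partition length != node count")
        self.graph = graph
        self.allow_empty = partition.allow_empty
        self.labels = labels.copy()
        self.K = partition.K
        self._rebuild()

    def _rebuild(self) -> None:
        g, K, labels = self.graph, self.K, self.labels
        self.n_r = np.bincount(labels, minlength=K).astype(np.int64)
        self.e_r = np.zeros(K, dtype=np.int64)
        np.add.at(self.e_r, labels, g.degrees)
        E = np.zeros((K, K), dtype=np.int64)
        for u, v in g.edges:
            bu, bv = labels[u], labels[v]
            if bu == bv:
                E[bu, bu] += 2
            else:
                E[bu, bv] += 1
                E[bv, bu] += 1
        self.E = E
        kmax = int(g.degrees.max()) if g.N else 0
        hist = np.zeros((K, kmax + 1), dtype=np.int64)
        np.add.at(hist, (labels, g.degrees), 1)
        self.hist = hist

    # -- derived views -----------------------------------------------------
    def m(self, r: int, s: int) -> int:
        """Unordered edge count between blocks (diagonal counted once)."""
        return int(self.E[r, s]) if r != s else int(self.E[r, r]) // 2

    def m_matrix(self) -> np.ndarray:
        m = self.E.copy()
        np.fill_diagonal(m, np.diag(self.E) // 2)
        return m

    @property
    def partition(self) -> Partition:
        return Partition(self.labels.copy(), K=self.K, allow_empty=self.allow_empty)

    def degree_histogram(self) -> np.ndarray:
        """Global degree histogram N_k."""
        return self.hist.sum(axis=0)

    def copy(self) -> "BlockState":
        new = object.__new__(BlockState)
        new.graph = self.graph
        new.allow_empty = self.allow_empty
        new.labels = self.labels.copy()
        new.K = self.K
        new.n_r = self.n_r.copy()
        new.e_r = self.e_r.copy()
        new.E = self.E.copy()
        new.hist = self.hist.copy()
        return new

    # -- operations ---------------------------------------------------------
    def apply_move(self, move: MoveProposal) -> "BlockState":
        """Apply a single-node move in place (returns self).

        Statistics are updated incrementally; ``target == K`` grows the state
        by one (initially empty) block.
        """
        i, s = move.node, move.target
        r = int(self.labels[i])
        if move.source != r:
            raise ValueError("move source does not match current label")
        if s == self.K:
            self._grow()
        elif not 0 <= s < self.K:
            raise ValueError("target block out of range")
        if s == r:
            return self
        if not self.allow_empty and self.n_r[r] == 1 and s < self.K:
            raise ValueError("move would empty a block (empty blocks disallowed)")
        _kernel._shift_node(i, r, s, self.labels, self.E, self.e_r, self.n_r,
                            self.hist, self.graph.indptr, self.graph.stubs)
        return self

    def _grow(self) -> None:
        K = self.K
        self.E = np.pad(self.E, ((0, 1), (0, 1)))
        self.n_r = np.append(self.n_r, 0)
        self.e_r = np.append(self.e_r, 0)
        self.hist = np.pad(self.hist, ((0, 1), (0, 0)))
        self.K = K + 1

    def merge_blocks(self, r: int, s: int) -> "BlockState":
        """Merge block s into block r in place; labels stay contiguous.

        The lower index keeps its identity; blocks above ``s`` shift down.
        """
        if r == s:
            raise ValueError("cannot merge a block with itself")
        r, s = (r, s) if r < s else (s, r)
        E = self.E
        # row then column: leaves E[r, r] = E_rr + E_ss + 2 E_rs (doubled diag)
        E[r, :] += E[s, :]
        E[:, r] += E[:, s]
        self.E = np.delete(np.delete(E, s, axis=0), s, axis=1)
        self.n_r[r] += self.n_r[s]
        self.e_r[r] += self.e_r[s]
        self.n_r = np.delete(self.n_r, s)
        self.e_r = np.delete(self.e_r, s)
        self.hist[r] += self.hist[s]
        self.hist = np.delete(self.hist, s, axis=0)
        lab = self.labels
        lab[lab == s] = r
        lab[lab > s] -= 1
        self.K -= 1
        return self

    # -- validation ----------------------------------------------------------
    def check(self) -> None:
        """Assert all invariants against a fresh rebuild (test helper)."""
        fresh = BlockState(self.graph,
                           Partition(self.labels, K=self.K,
                                     allow_empty=True))
        assert np.array_equal(fresh.E, self.E)
        assert np.array_equal(fresh.n_r, self.n_r)
        assert np.array_equal(fresh.e_r, self.e_r)
        assert np.array_equal(fresh.hist, self.hist)
        M, N = self.graph.M, self.graph.N
        assert self.m_matrix()[np.triu_indices(self.K)].sum() == M
        assert self.n_r.sum() == N
        assert self.e_r.sum() == 2 * M
        assert np.array_equal(self.e_r, self.E.sum(axis=1))


def build_block_state(graph: Graph, partition: Partition) -> BlockState:
    """Construct a :class:`BlockState` with all statistics computed fresh."""
    return BlockState(graph, partition)


class HierarchyState:
    """Stack of partitions: level l clusters the block multigraph of l-1.

    ``partitions[0]`` assigns the ``N`` nodes to ``K^1`` blocks and the last
    partition must place everything in a single block (``K^L = 1``); the
    implicit level 0 is the all-singleton partition with ``K^0 = N``.
    """

    def __init__(self, graph: Graph, partitions: list[Partition]):
        if not partitions:
            raise ValueError("need at least one level")
        if partitions[-1].K != 1:
            raise ValueError("topmost level must have a single block")
        self.graph = graph
        self.partitions = partitions
        self.states: list[BlockState] = []
        g = graph
        prev_k = graph.N
        for part in partitions:
            if part.N != prev_k:
                raise ValueError("level sizes inconsistent with hierarchy")
            st = BlockState(g, part)
            self.states.append(st)
            g = block_multigraph(st)
            prev_k = part.K
        self.L = len(partitions)

    @property
    def block_counts(self) -> list[int]:
        """``[K^1, ..., K^L]``."""
        return [p.K for p in self.partitions]


def block_multigraph(state: BlockState) -> Graph:
    """The weighted block graph: one node per block, m_rs parallel edges."""
    edges = []
    m = state.m_matrix()
    for r in range(state.K):
        for s in range(r, state.K):
            edges.extend([(r, s)] * int(m[r, s]))
    return Graph(edges, n_nodes=state.K)
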