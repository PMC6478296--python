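"""Undirected graphs and node partitions.

The graph container is deliberately minimal: an undirected multigraph with
self-loops, stored as a CSR-like "stub list" (for every node, the multiset of
neighbour endpoints).  A self-loop contributes two stubs to its node, so the
degree of a node is exactly the length of its stub list and ``sum(k) == 2M``.
This layout is what the incremental block-statistics bookkeeping and the
sampling kernels consume directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class Graph:
    """Undirected (multi)graph with self-loops.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` pairs with 0-based integer node ids.  Repeated
        pairs create multi-edges; ``u == v`` creates a self-loop.
    n_nodes
        Number of nodes.  Defaults to ``max(node id) + 1``.
    simple
        If True, reject multi-edges and self-loops at construction.
    """

    def __init__(self, edges: Iterable[tuple[int, int]], n_nodes: int | None = None,
                 simple: bool = False):
        edges = np.asarray(list(edges), dtype=np.int64)
        if edges.size == 0:
            edges = edges.reshape(0, 2)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("edges must be (u, v) pairs")
        if edges.size and edges.min() < 0:
            raise ValueError("negative node id")
        if n_nodes is None:
            n_nodes = int(edges.max()) + 1 if edges.size else 0
        elif edges.size and edges.max() >= n_nodes:
            raise ValueError("node id out of range")
        self.N = int(n_nodes)
        self.M = int(edges.shape[0])
        # canonical edge list with u <= v
        u = np.minimum(edges[:, 0], edges[:, 1])
        v = np.maximum(edges[:, 0], edges[:, 1])
        order = np.lexsort((v, u))
        self._edges = np.column_stack([u[order], v[order]])
        if simple:
            if np.any(u == v):
                raise ValueError("self-loop in simple graph")
            if self.M and np.any((np.diff(u[order]) == 0) & (np.diff(v[order]) == 0)):
                raise ValueError("multi-edge in simple graph")
        self.simple = bool(simple)
        # stub lists: each edge contributes a stub at both endpoints,
        # self-loops contribute two stubs at their node.
        deg = np.zeros(self.N, dtype=np.int64)
        np.add.at(deg, u, 1)
        np.add.at(deg, v, 1)
        self.degrees = deg
        indptr = np.zeros(self.N + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        stubs = np.empty(2 * self.M, dtype=np.int64)
        fill = indptr[:-1].copy()
        for a, b in self._edges:
            stubs[fill[a]] = b
            fill[a] += 1
            stubs[fill[b]] = a
            fill[b] += 1
        self.indptr = indptr
        self.stubs = stubs

    # -- basic accessors ---------------------------------------------------
    @property
    def edges(self) -> np.ndarray:
        """Canonical ``(M, 2)`` edge array with ``u <= v``."""
        return self._edges

    def neighbors(self, i: int) -> np.ndarray:
        """Stub endpoints of node ``i`` (with multiplicity; self-loops twice)."""
        return self.stubs[self.indptr[i]:self.indptr[i + 1]]

    def loop_counts(self) -> np.ndarray:
        """Number of self-loop *edges* per node (counted once each)."""
        loops = np.zeros(self.N, dtype=np.int64)
        e = self._edges
        sel = e[:, 0] == e[:, 1]
        np.add.at(loops, e[sel, 0], 1)
        return loops

    def edge_multiplicities(self) -> np.ndarray:
        """Multiplicity of each distinct edge, ``(n_distinct,)``."""
        if self.M == 0:
            return np.zeros(0, dtype=np.int64)
        _, counts = np.unique(self._edges, axis=0, return_counts=True)
        return counts

    def mean_degree(self) -> float:
        return 2.0 * self.M / self.N if self.N else 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(N={self.N}, M={self.M}, simple={self.simple})"

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_edgelist(cls, path: str | Path, n_nodes: int | None = None,
                      simple: bool = False) -> "Graph":
        """Read a whitespace-separated ``u v`` edge list ('#' comments)."""
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split()[:2]
                edges.append((int(a), int(b)))
        return cls(edges, n_nodes=n_nodes, simple=simple)

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# N={self.N} M={self.M}\n")
            for a, b in self._edges:
                fh.write(f"{a} {b}\n")

    @classmethod
    def read_gml(cls, path: str | Path, simple: bool = False) -> "Graph":
        import networkx as nx

        g = nx.read_gml(path, label="id")
        mapping = {u: i for i, u in enumerate(sorted(g.nodes()))}
        edges = [(mapping[a], mapping[b]) for a, b in g.edges()]
        return cls(edges, n_nodes=g.number_of_nodes(), simple=simple)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(map(tuple, self._edges))
        return g


@dataclass
class Partition:
    """Node-to-block assignment with blocks ``0..K-1``.

    ``K`` may exceed ``labels.max() + 1`` only when ``allow_empty`` is set
    (the Newman–Reinert objectives treat empty blocks as legal states).
    """

    labels: np.ndarray
    K: int = 0
    allow_empty: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        observed = int(self.labels.max()) + 1 if self.labels.size else 0
        if self.K == 0:
            self.K = observed
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("negative block label")
        if observed > self.K:
            raise ValueError("block label out of range")
        if not self.allow_empty:
            counts = np.bincount(self.labels, minlength=self.K)
            if np.any(counts == 0):
                raise ValueError("empty block (pass allow_empty=True to permit)")

    @property
    def N(self) -> int:
        return self.labels.size

    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    def relabel(self, perm: Sequence[int]) -> "Partition":
        """Apply a block permutation ``perm[old] = new``."""
        perm = np.asarray(perm, dtype=np.int64)
        return Partition(perm[self.labels], K=self.K, allow_empty=self.allow_empty)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read(cls, path: str | Path, allow_empty: bool = False) -> "Partition":
        """Load labels from a single-column CSV or a JSON array."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            labels = json.loads(path.read_text())
        else:
            labels = [int(line.strip()) for line in path.read_text().splitlines()
                      if line.strip() and not line.strip().startswith("#")]
        return cls(np.asarray(labels, dtype=np.int64), allow_empty=allow_empty)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps([int(x) for x in self.labels]))
        else:
            path.write_text("\n".join(str(int(x)) for x in self.labels) + "\n")
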