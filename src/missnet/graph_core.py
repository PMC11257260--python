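"""Undirected simple-graph container and structural primitives.

The whole pipeline operates on unweighted, undirected simple graphs.  Nodes
are integers; a graph produced by the readers or generators is canonicalized
to ids ``0..n-1`` with the original labels retained in a sidecar map, while
subgraph operations (largest connected component, induced subgraph) keep the
parent's ids so that edge sets remain directly comparable across pipeline
stages.

Edges are always stored in canonical order ``(u, v)`` with ``u < v``; every
set operation on edges in this package uses canonical pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


def canonical_edge(u: int, v: int) -> Edge:
    """Return the pair ordered so that the smaller id comes first."""
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Graph:
    """Immutable undirected simple graph over integer node ids.

    Invariants: no self-loops, no duplicate edges, each edge stored once as
    ``(u, v)`` with ``u < v``, and the degree sum equals ``2 m``.
    """

    nodes: frozenset[int]
    edges: frozenset[Edge]
    labels: Mapping[int, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop ({u},{v}) not allowed in a simple graph")
            if u > v:
                raise ValueError(f"edge ({u},{v}) not in canonical order u<v")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references unknown node")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[int, int]],
        nodes: Iterable[int] | None = None,
        labels: Mapping[int, str] | None = None,
    ) -> "Graph":
        """Build a graph from integer pairs, dropping self-loops/duplicates."""
        eset = set()
        nset = set(nodes) if nodes is not None else set()
        for u, v in edges:
            if u == v:
                continue
            eset.add(canonical_edge(int(u), int(v)))
        for u, v in eset:
            nset.add(u)
            nset.add(v)
        return cls(frozenset(nset), frozenset(eset), labels)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        return cls.from_edges(g.edges(), nodes=g.nodes())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    # -- queries ----------------------------------------------------------

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {u: set() for u in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def degree(self, node: int) -> int:
        return sum(1 for u, v in self.edges if u == node or v == node)

    def degrees(self) -> dict[int, int]:
        deg = {u: 0 for u in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def has_edge(self, u: int, v: int) -> bool:
        return canonical_edge(u, v) in self.edges


def _sort_labels(raw_labels: set[str]) -> list[str]:
    # Numeric sort when every label parses as an integer, else lexicographic:
    # keeps integer edge lists in their natural 0..n-1 order.
    try:
        return sorted(raw_labels, key=lambda s: (int(s), s))
    except ValueError:
        return sorted(raw_labels)


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    strict: bool = False,
) -> Graph:
    """Read a whitespace- or comma-delimited edge list into a canonical Graph.

    One edge per line, two endpoint labels per line (extra columns such as
    weights are ignored and logged).  Lines starting with ``#`` are comments.
    Self-loops and duplicate edges are dropped with a logged count (or raise
    when ``strict``).  Node labels are mapped to ``0..n-1`` by sorted order.
    """
    path = Path(path)
    raw_edges: list[tuple[str, str]] = []
    n_selfloops = 0
    n_extra_cols = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                parts = line.replace(",", " ").split()
            else:
                parts = [p.strip() for p in line.split(delimiter) if p.strip()]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            if len(parts) > 2:
                n_extra_cols += 1
            a, b = parts[0], parts[1]
            if a == b:
                if strict:
                    raise ValueError(f"{path}:{lineno}: self-loop {a!r}")
                n_selfloops += 1
                continue
            raw_edges.append((a, b))
    if not raw_edges and n_selfloops == 0:
        raise ValueError(f"{path}: empty edge list")

    labels = _sort_labels({x for e in raw_edges for x in e})
    index = {lab: i for i, lab in enumerate(labels)}
    edges = {canonical_edge(index[a], index[b]) for a, b in raw_edges}
    n_dupes = len(raw_edges) - len(edges)
    if n_selfloops or n_dupes:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path, n_selfloops, n_dupes,
        )
    if n_extra_cols:
        logger.info("%s: ignored extra columns on %d line(s)", path, n_extra_cols)
    return Graph(
        frozenset(range(len(labels))),
        frozenset(edges),
        {i: lab for lab, i in index.items()},
    )


def write_edge_list(graph: Graph, path: str | Path, delimiter: str = " ") -> None:
    """Write edges in sorted canonical order (deterministic output)."""
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges):
            fh.write(f"{u}{delimiter}{v}\n")


def connected_components(graph: Graph) -> list[frozenset[int]]:
    """Components as node sets, largest first; ties by smallest minimum id."""
    comps = nx.connected_components(graph.to_networkx())
    return sorted((frozenset(c) for c in comps), key=lambda c: (-len(c), min(c)))


def largest_connected_component(graph: Graph) -> Graph:
    """Induced subgraph on the largest component (ties: smallest min node id)."""
    if graph.n == 0:
        raise ValueError("empty graph has no connected component")
    return induced_subgraph(graph, connected_components(graph)[0])


def induced_subgraph(graph: Graph, nodes: Iterable[int]) -> Graph:
    """Subgraph on ``nodes`` with every edge whose endpoints both lie in it."""
    nset = frozenset(nodes)
    unknown = nset - graph.nodes
    if unknown:
        raise ValueError(f"unknown node id(s): {sorted(unknown)[:5]}")
    edges = frozenset(e for e in graph.edges if e[0] in nset and e[1] in nset)
    return Graph(nset, edges, graph.labels)


def pagerank_scores(
    graph: Graph,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> dict[int, float]:
    """PageRank by power iteration; scores sum to one.

    Isolated nodes are treated as dangling (their mass is redistributed
    uniformly), so the method is well defined on any graph even though the
    pipeline only calls it on connected components.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    order = sorted(graph.nodes)
    idx = {u: i for i, u in enumerate(order)}
    n = len(order)
    if n == 0:
        return {}
    adj = graph.adjacency()
    deg = np.array([len(adj[u]) for u in order], dtype=float)
    x = np.full(n, 1.0 / n)
    neighbors = [np.array([idx[v] for v in adj[u]], dtype=int) for u in order]
    for _ in range(max_iter):
        new = np.full(n, (1.0 - damping) / n)
        dangling_mass = x[deg == 0].sum()
        new += damping * dangling_mass / n
        contrib = np.where(deg > 0, x / np.maximum(deg, 1.0), 0.0)
        for i, nbrs in enumerate(neighbors):
            if nbrs.size:
                new[i] += damping * contrib[nbrs].sum()
        if np.abs(new - x).sum() < tol:
            x = new
            break
        x = new
    x /= x.sum()
    return {u: float(x[idx[u]]) for u in order}
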