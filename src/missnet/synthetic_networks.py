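"""Synthetic benchmark networks emulating the six-domain corpus envelope.

The corpus the benchmark emulates consists of sparse real-world networks
(21-899 nodes, mean degree about 5) drawn from six domains: biological,
economic, informational, social, technological, and transportation.  Four
generator families reproduce the structural contrasts that distinguish those
domains — community structure (planted partitions), heavy-tailed degree
distributions (preferential attachment), and spatial constraints (random
geometric graphs) — without fitting any individual real network.

All generators are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .graph_core import Graph, largest_connected_component, write_edge_list

N_MIN, N_MAX = 21, 899  #: node-count envelope of the emulated corpus
DEFAULT_MEAN_DEGREE = 5.0

DOMAINS = (
    "biological",
    "economic",
    "informational",
    "social",
    "technological",
    "transportation",
)

#: generator family standing in for each domain (a modeling choice recorded
#: in the suite manifest): community-structured graphs for social and
#: informational networks, heavy-tailed growth for biological and economic
#: ones, spatial graphs for technological and transportation infrastructure.
DOMAIN_FAMILY = {
    "social": "planted_partition",
    "informational": "planted_partition",
    "biological": "heavy_tail",
    "economic": "heavy_tail",
    "technological": "spatial_lattice",
    "transportation": "spatial_lattice",
}


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    family: str
    n: int
    params: dict = field(default_factory=dict)
    domain_label: str = "biological"
    seed: int = 0

    def __post_init__(self) -> None:
        if not N_MIN <= self.n <= N_MAX:
            raise ValueError(f"n={self.n} outside corpus envelope [{N_MIN}, {N_MAX}]")


def _near_equal_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def generate_planted_partition(
    n: int,
    k_communities: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[Graph, list[int]]:
    """Planted-partition graph with near-equal communities.

    Each within-community pair is an edge independently with probability
    ``p_in``, each between-community pair with ``p_out``.  Returns the graph
    and the per-node community labels (ground truth for recovery oracles).
    """
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError("require 0 <= p_out <= p_in <= 1")
    sizes = _near_equal_sizes(n, k_communities)
    g = nx.stochastic_block_model(
        sizes,
        [[p_in if i == j else p_out for j in range(k_communities)] for i in range(k_communities)],
        seed=seed,
    )
    labels = []
    for c, size in enumerate(sizes):
        labels.extend([c] * size)
    return Graph.from_edges(g.edges(), nodes=range(n)), labels


def planted_partition_probs(
    n: int, k_communities: int, mean_degree: float, mixing: float
) -> tuple[float, float]:
    """Solve (p_in, p_out) so expected mean degree and mixing fraction match.

    ``mixing`` is the expected fraction of a node's edges that leave its
    community (0 = perfectly assortative).
    """
    size = n / k_communities
    within_pairs = size - 1.0
    between_pairs = n - size
    p_in = mean_degree * (1.0 - mixing) / within_pairs
    p_out = mean_degree * mixing / between_pairs
    return min(p_in, 1.0), min(p_out, 1.0)


def generate_heavy_tail(n: int, edges_per_node: int, seed: int) -> Graph:
    """Preferential-attachment growth graph (connected, heavy-tailed degrees).

    Each arriving node attaches to ``edges_per_node`` existing nodes with
    probability proportional to degree, so m = (n - edges_per_node) * edges_per_node.
    """
    if not 1 <= edges_per_node < n:
        raise ValueError("require 1 <= edges_per_node < n")
    g = nx.barabasi_albert_graph(n, edges_per_node, seed=seed)
    return Graph.from_edges(g.edges(), nodes=range(n))


def generate_spatial(
    n: int, radius: float, seed: int, return_positions: bool = False
):
    """Random geometric graph on the unit square; LCC only if fragmented.

    With ``return_positions`` the pre-LCC graph and the node coordinates are
    returned as well (used by distance oracles in tests).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    g = nx.random_geometric_graph(n, radius, seed=seed)
    graph = Graph.from_edges(g.edges(), nodes=range(n))
    if graph.m == 0:
        out = Graph(frozenset([min(graph.nodes)]), frozenset())
    else:
        out = largest_connected_component(graph)
    if return_positions:
        return out, graph, nx.get_node_attributes(g, "pos")
    return out


def spatial_radius_for_degree(n: int, mean_degree: float) -> float:
    """Radius giving expected degree ~ mean_degree on the unit square."""
    return math.sqrt(mean_degree / (math.pi * (n - 1)))


@dataclass(frozen=True)
class SuiteConfig:
    """Per-domain composition of the synthetic benchmark suite."""

    counts: dict = field(
        default_factory=lambda: {d: 1 for d in DOMAINS}
    )
    n_range: tuple[int, int] = (100, 400)
    mean_degree: float = DEFAULT_MEAN_DEGREE
    seed: int = 0


def _generate_for_domain(domain: str, n: int, mean_degree: float, seed: int) -> Graph:
    family = DOMAIN_FAMILY[domain]
    if family == "planted_partition":
        # social networks: strongly assortative; informational: looser mixing
        mixing = 0.1 if domain == "social" else 0.25
        k = max(2, n // 50)
        p_in, p_out = planted_partition_probs(n, k, mean_degree, mixing)
        graph, _ = generate_planted_partition(n, k, p_in, p_out, seed)
        return graph
    if family == "heavy_tail":
        # mean degree of the growth model is ~2*edges_per_node
        m_per = max(1, int(math.ceil(mean_degree / 2)))
        if domain == "economic":
            m_per = max(1, m_per - 1)  # economic nets in the corpus are sparser
        return generate_heavy_tail(n, m_per, seed)
    if family == "spatial_lattice":
        deg = mean_degree if domain == "technological" else mean_degree * 0.8
        return generate_spatial(n, spatial_radius_for_degree(n, deg), seed)
    raise ValueError(f"unknown family {family!r}")


def make_benchmark_suite(config: SuiteConfig | None = None) -> list[tuple[str, Graph, str]]:
    """Generate the benchmark suite: list of (network_id, graph, domain).

    Deterministic under the suite seed; per-network seeds are derived by a
    fixed offset so that networks are mutually independent yet reproducible.
    """
    config = config or SuiteConfig()
    rng = np.random.default_rng(config.seed)
    out: list[tuple[str, Graph, str]] = []
    idx = 0
    for domain in DOMAINS:
        for j in range(config.counts.get(domain, 0)):
            # draws are consumed in a fixed order, so the suite is reproducible
            n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
            net_seed = int(config.seed * 10_007 + idx * 101 + 1) % (2**31 - 1)
            graph = _generate_for_domain(domain, n, config.mean_degree, net_seed)
            out.append((f"{domain}_{j}", graph, domain))
            idx += 1
    return out


def write_suite(suite: Sequence[tuple[str, Graph, str]], outdir: str | Path) -> Path:
    """Write the suite as edge-list files plus a manifest table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("network_id\tdomain\tn\tm\tfamily\n")
        for net_id, graph, domain in suite:
            write_edge_list(graph, outdir / f"{net_id}.edgelist")
            fh.write(
                f"{net_id}\t{domain}\t{graph.n}\t{graph.m}\t{DOMAIN_FAMILY[domain]}\n"
            )
    return manifest
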