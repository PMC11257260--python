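"""Twenty graph-subsampling algorithms modelling non-uniform missing-edge patterns.

Each sampler selects a subset of the edges of a connected graph, emulating a
data-collection process.  The registry groups them into five categories:

* ``edge_based`` — uniform or node-mediated edge draws; can hit a target edge
  count exactly.
* ``node_based`` — nodes are sampled (uniformly, by degree, or by PageRank)
  and only edges internal to the sampled node set are kept.
* ``dfs`` — randomized depth-first traversal keeping the tree edges, which
  produces long chains.
* ``neighbor_based`` — a walker or fire grows one explored region; the
  induced subgraph of the explored nodes is returned, so samples are
  connected.
* ``jump_based`` — processes that may teleport or restart elsewhere, which
  can fragment the sample.

Growth-based samplers cannot hit an edge target exactly; they stop at the
first state where the collected edge count reaches the target and the
overshoot (or shortfall) is logged.  Every sampler is deterministic given its
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .graph_core import Edge, Graph, canonical_edge, pagerank_scores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerSpec:
    """Registry entry naming one sampler with parameters and a seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def category(self) -> str:
        return CATEGORY[self.name]


# --------------------------------------------------------------------------
# shared helpers
# --------------------------------------------------------------------------


class _NodeGrower:
    """Incrementally grown node set tracking its induced edge count."""

    def __init__(self, graph: Graph):
        self.adj = graph.adjacency()
        self.nodes: set[int] = set()
        self.edge_count = 0

    def add(self, u: int) -> None:
        if u in self.nodes:
            return
        self.edge_count += len(self.adj[u] & self.nodes)
        self.nodes.add(u)

    def induced_edges(self) -> set[Edge]:
        out = set()
        for u in self.nodes:
            for v in self.adj[u]:
                if v in self.nodes and u < v:
                    out.add((u, v))
        return out


def _uniform_node(graph: Graph, rng: np.random.Generator) -> int:
    order = sorted(graph.nodes)
    return order[int(rng.integers(len(order)))]


def _log_deviation(name: str, achieved: int, target: int) -> None:
    if achieved != target:
        logger.info("%s: achieved %d edges for target %d", name, achieved, target)


# --------------------------------------------------------------------------
# edge-based
# --------------------------------------------------------------------------


def _random_edge(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    """Uniform edge sample without replacement; hits the target exactly."""
    edges = sorted(graph.edges)
    picks = rng.choice(len(edges), size=target, replace=False)
    return {edges[i] for i in picks}


def _random_node_edge(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    """Repeat (uniform node; uniform incident edge) until target distinct edges."""
    order = sorted(u for u, d in graph.degrees().items() if d > 0)
    adj = graph.adjacency()
    out: set[Edge] = set()
    guard = 0
    while len(out) < target and guard < 1000 * target + 1000:
        guard += 1
        u = order[int(rng.integers(len(order)))]
        nbrs = sorted(adj[u])
        v = nbrs[int(rng.integers(len(nbrs)))]
        out.add(canonical_edge(u, v))
    _log_deviation("random_node_edge", len(out), target)
    return out


def _hybrid_node_edge(
    graph: Graph, target: int, rng: np.random.Generator, alpha: float = 0.5
) -> set[Edge]:
    """Per draw: with weight ``alpha`` a uniform-edge move, else a node-edge move."""
    edges = sorted(graph.edges)
    order = sorted(u for u, d in graph.degrees().items() if d > 0)
    adj = graph.adjacency()
    out: set[Edge] = set()
    guard = 0
    while len(out) < target and guard < 1000 * target + 1000:
        guard += 1
        if rng.random() < alpha:
            out.add(edges[int(rng.integers(len(edges)))])
        else:
            u = order[int(rng.integers(len(order)))]
            nbrs = sorted(adj[u])
            out.add(canonical_edge(u, nbrs[int(rng.integers(len(nbrs)))]))
    _log_deviation("hybrid_node_edge", len(out), target)
    return out


def _random_edge_induction(
    graph: Graph, target: int, rng: np.random.Generator, p: float = 0.5
) -> set[Edge]:
    """Stage 1 keeps each edge w.p. ``p``; stage 2 tops up from the subgraph
    induced on the stage-1 node set until the target is reached.

    If stage 1 alone exceeds the target, the stage-1 set is subsampled
    uniformly down to the target.
    """
    edges = sorted(graph.edges)
    keep = rng.random(len(edges)) < p
    stage1 = {e for e, k in zip(edges, keep) if k}
    if len(stage1) >= target:
        picks = rng.choice(len(stage1), size=target, replace=False)
        s1 = sorted(stage1)
        return {s1[i] for i in picks}
    nodes = {x for e in stage1 for x in e}
    candidates = sorted(
        e for e in graph.edges if e[0] in nodes and e[1] in nodes and e not in stage1
    )
    need = min(target - len(stage1), len(candidates))
    picks = rng.choice(len(candidates), size=need, replace=False) if need else []
    out = stage1 | {candidates[i] for i in picks}
    _log_deviation("random_edge_induction", len(out), target)
    return out


# --------------------------------------------------------------------------
# node-based: weighted node draws, induced edges returned
# --------------------------------------------------------------------------


NODE_WEIGHT_FNS: dict[str, Callable[[Graph], dict[int, float]]] = {
    "degree_node": lambda g: {u: float(d) for u, d in g.degrees().items()},
    "random_node": lambda g: {u: 1.0 for u in g.nodes},
    "pagerank_node": pagerank_scores,
}


def _weighted_draws(graph: Graph, weights: dict[int, float], rng: np.random.Generator):
    """Yield nodes without replacement, probability proportional to weight."""
    order = sorted(graph.nodes)
    w = np.array([max(weights[u], 0.0) for u in order], dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    remaining = list(range(len(order)))
    while remaining:
        probs = w[remaining]
        probs = probs / probs.sum()
        j = int(rng.choice(len(remaining), p=probs))
        yield order[remaining.pop(j)]


def node_sampling_order(graph: Graph, method: str, seed: int) -> list[int]:
    """Full draw order a node-based sampler would use (diagnostic view of the
    exact weighted-sampling process the samplers consume)."""
    rng = np.random.default_rng(seed)
    return list(_weighted_draws(graph, NODE_WEIGHT_FNS[method](graph), rng))


def _node_weighted(
    graph: Graph,
    target: int,
    rng: np.random.Generator,
    weight_fn: Callable[[Graph], dict[int, float]],
    name: str,
) -> set[Edge]:
    grower = _NodeGrower(graph)
    for u in _weighted_draws(graph, weight_fn(graph), rng):
        if grower.edge_count >= target:
            break
        grower.add(u)
    _log_deviation(name, grower.edge_count, target)
    return grower.induced_edges()


def _degree_node(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    return _node_weighted(graph, target, rng, NODE_WEIGHT_FNS["degree_node"], "degree_node")


def _random_node(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    return _node_weighted(graph, target, rng, NODE_WEIGHT_FNS["random_node"], "random_node")


def _pagerank_node(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    return _node_weighted(graph, target, rng, NODE_WEIGHT_FNS["pagerank_node"], "pagerank_node")


# --------------------------------------------------------------------------
# depth-first search (tree edges only)
# --------------------------------------------------------------------------


def _dfs(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    """Randomized DFS from a uniform root; collect traversal-tree edges."""
    adj = graph.adjacency()
    root = _uniform_node(graph, rng)
    visited = {root}
    out: set[Edge] = set()
    stack: list[tuple[int, int]] = []
    nbrs = sorted(adj[root])
    rng.shuffle(nbrs)
    stack.extend((v, root) for v in nbrs)
    while stack and len(out) < target:
        v, parent = stack.pop()
        if v in visited:
            continue
        visited.add(v)
        out.add(canonical_edge(parent, v))
        nbrs = sorted(adj[v] - visited)
        rng.shuffle(nbrs)
        stack.extend((w, v) for w in nbrs)
    _log_deviation("dfs", len(out), target)
    return out


# --------------------------------------------------------------------------
# neighbor-based: one explored region, induced edges returned (connected)
# --------------------------------------------------------------------------


def _grow_neighbor_based(
    graph: Graph,
    target: int,
    rng: np.random.Generator,
    step_fn: Callable,
    name: str,
) -> set[Edge]:
    """Shared driver: grow the explored set via ``step_fn`` until the induced
    edge count reaches the target; reseed the walker if it stalls."""
    grower = _NodeGrower(graph)
    start = _uniform_node(graph, rng)
    grower.add(start)
    state: dict = {"current": start, "start": start, "prev": None}
    stall = 0
    max_stall = 100 * graph.n + 1000
    while grower.edge_count < target and len(grower.nodes) < graph.n:
        before = (len(grower.nodes), grower.edge_count)
        step_fn(graph, grower, state, rng)
        if (len(grower.nodes), grower.edge_count) == before:
            stall += 1
            if stall > max_stall:
                # trapped walker: reseed at a uniform explored node
                explored = sorted(grower.nodes)
                state["current"] = explored[int(rng.integers(len(explored)))]
                state["prev"] = None
                logger.info("%s: walker reseeded after stall", name)
                stall = 0
        else:
            stall = 0
    _log_deviation(name, grower.edge_count, target)
    return grower.induced_edges()


def _step_diffusion(graph, grower, state, rng):
    explored = sorted(grower.nodes)
    u = explored[int(rng.integers(len(explored)))]
    nbrs = sorted(grower.adj[u])
    if nbrs:
        grower.add(nbrs[int(rng.integers(len(nbrs)))])


def _make_step_forest_fire(p: float):
    def step(graph, grower, state, rng):
        queue = state.setdefault("queue", [state["current"]])
        if not queue:
            explored = sorted(grower.nodes)
            queue.append(explored[int(rng.integers(len(explored)))])
        u = queue.pop(0)
        unburned = sorted(grower.adj[u] - grower.nodes)
        if not unburned:
            return
        count = min(int(rng.geometric(1.0 - p)), len(unburned))
        picks = rng.choice(len(unburned), size=count, replace=False)
        for i in picks:
            grower.add(unburned[i])
            queue.append(unburned[i])

    return step


def _step_random_walk(graph, grower, state, rng):
    u = state["current"]
    nbrs = sorted(grower.adj[u])
    v = nbrs[int(rng.integers(len(nbrs)))]
    grower.add(v)
    state["prev"], state["current"] = u, v


def _step_nonbacktracking(graph, grower, state, rng):
    u = state["current"]
    nbrs = sorted(grower.adj[u])
    if len(nbrs) > 1 and state["prev"] in grower.adj[u]:
        nbrs = [v for v in nbrs if v != state["prev"]]
    v = nbrs[int(rng.integers(len(nbrs)))]
    grower.add(v)
    state["prev"], state["current"] = u, v


def _make_step_restart(r: float):
    def step(graph, grower, state, rng):
        if rng.random() < r:
            state["current"] = state["start"]
            return
        _step_random_walk(graph, grower, state, rng)

    return step


def _make_step_metropolis(beta: float):
    def step(graph, grower, state, rng):
        u = state["current"]
        nbrs = sorted(grower.adj[u])
        v = nbrs[int(rng.integers(len(nbrs)))]
        accept = min(1.0, (len(grower.adj[u]) / len(grower.adj[v])) ** beta)
        if rng.random() < accept:
            grower.add(v)
            state["prev"], state["current"] = u, v

    return step


def _step_circulated(graph, grower, state, rng):
    # per-node shuffled neighbor queues; reshuffle once a queue empties
    queues = state.setdefault("queues", {})
    u = state["current"]
    if not queues.get(u):
        nbrs = sorted(grower.adj[u])
        rng.shuffle(nbrs)
        queues[u] = nbrs
    v = queues[u].pop()
    grower.add(v)
    state["prev"], state["current"] = u, v


def _step_bfs(graph, grower, state, rng):
    queue = state.setdefault("queue", [state["current"]])
    while queue:
        u = queue[0]
        unvisited = sorted(grower.adj[u] - grower.nodes)
        if unvisited:
            rng.shuffle(unvisited)
            v = unvisited[0]
            grower.add(v)
            queue.append(v)
            return
        queue.pop(0)
    # frontier exhausted inside a full component: nothing left to add
    state["queue"] = [state["current"]]


def _neighbor_based(step_or_factory, name: str, is_factory: bool = False):
    def sampler(graph: Graph, target: int, rng: np.random.Generator, **params):
        step = step_or_factory(**params) if is_factory else step_or_factory
        return _grow_neighbor_based(graph, target, rng, step, name)

    return sampler


# --------------------------------------------------------------------------
# jump-based (fragmented samples allowed)
# --------------------------------------------------------------------------


def _rw_with_jump(
    graph: Graph, target: int, rng: np.random.Generator, jump: float = 0.1
) -> set[Edge]:
    """Random walk that teleports to a uniform node w.p. ``jump``; induced edges."""
    order = sorted(graph.nodes)
    adj = graph.adjacency()
    grower = _NodeGrower(graph)
    current = order[int(rng.integers(len(order)))]
    grower.add(current)
    steps, max_steps = 0, 1000 * graph.n + 10_000
    while grower.edge_count < target and len(grower.nodes) < graph.n and steps < max_steps:
        steps += 1
        if rng.random() < jump:
            current = order[int(rng.integers(len(order)))]
        else:
            nbrs = sorted(adj[current])
            current = nbrs[int(rng.integers(len(nbrs)))]
        grower.add(current)
    _log_deviation("rw_with_jump", grower.edge_count, target)
    return grower.induced_edges()


def _random_node_neighbor(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    """Accumulate closed neighborhoods of uniformly drawn center nodes."""
    order = sorted(graph.nodes)
    perm = rng.permutation(len(order))
    adj = graph.adjacency()
    grower = _NodeGrower(graph)
    for j in perm:
        if grower.edge_count >= target:
            break
        center = order[j]
        grower.add(center)
        for v in sorted(adj[center]):
            grower.add(v)
    _log_deviation("random_node_neighbor", grower.edge_count, target)
    return grower.induced_edges()


def _one_shortest_path(
    adj: dict[int, set[int]], src: int, dst: int, rng: np.random.Generator
) -> list[int] | None:
    """One shortest path, ties broken by uniform random predecessor choice."""
    from collections import deque

    dist = {src: 0}
    preds: dict[int, list[int]] = {}
    q = deque([src])
    while q:
        u = q.popleft()
        if u == dst:
            break
        for v in sorted(adj[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if dst not in dist:
        return None
    path = [dst]
    while path[-1] != src:
        options = preds[path[-1]]
        path.append(options[int(rng.integers(len(options)))])
    return path[::-1]


def _shortest_path(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    """Accumulate edges of shortest paths between uniformly drawn node pairs."""
    order = sorted(graph.nodes)
    adj = graph.adjacency()
    out: set[Edge] = set()
    guard, max_guard = 0, 100 * graph.n + 1000
    while len(out) < target and guard < max_guard:
        guard += 1
        i, j = rng.choice(len(order), size=2, replace=False)
        path = _one_shortest_path(adj, order[i], order[j], rng)
        if path is None:
            continue
        for a, b in zip(path, path[1:]):
            out.add(canonical_edge(a, b))
    _log_deviation("shortest_path", len(out), target)
    return out


def _loop_erased_rw(graph: Graph, target: int, rng: np.random.Generator) -> set[Edge]:
    """Random walk keeping only edges that attach a new node: an undirected tree.

    Covers ``k = min(target + 1, n)`` nodes, hence returns exactly ``k - 1``
    edges regardless of the requested edge count.
    """
    k = min(target + 1, graph.n)
    adj = graph.adjacency()
    current = _uniform_node(graph, rng)
    visited = {current}
    out: set[Edge] = set()
    while len(visited) < k:
        nbrs = sorted(adj[current])
        v = nbrs[int(rng.integers(len(nbrs)))]
        if v not in visited:
            visited.add(v)
            out.add(canonical_edge(current, v))
        current = v
    _log_deviation("loop_erased_rw", len(out), target)
    return out


# --------------------------------------------------------------------------
# registry and dispatcher
# --------------------------------------------------------------------------

#: default parameters for samplers that take any
DEFAULT_PARAMS: dict[str, dict] = {
    "hybrid_node_edge": {"alpha": 0.5},
    "random_edge_induction": {"p": 0.5},
    "forest_fire": {"p": 0.4},
    "rw_with_restart": {"r": 0.1},
    "metropolis_hastings_rw": {"beta": 1.0},
    "rw_with_jump": {"jump": 0.1},
}

_EDGE_BASED = {
    "random_edge": _random_edge,
    "random_node_edge": _random_node_edge,
    "hybrid_node_edge": _hybrid_node_edge,
    "random_edge_induction": _random_edge_induction,
}
_NODE_BASED = {
    "degree_node": _degree_node,
    "random_node": _random_node,
    "pagerank_node": _pagerank_node,
}
_DFS = {"dfs": _dfs}
_NEIGHBOR_BASED = {
    "diffusion": _neighbor_based(_step_diffusion, "diffusion"),
    "forest_fire": _neighbor_based(_make_step_forest_fire, "forest_fire", is_factory=True),
    "nonbacktracking_rw": _neighbor_based(_step_nonbacktracking, "nonbacktracking_rw"),
    "random_walk": _neighbor_based(_step_random_walk, "random_walk"),
    "rw_with_restart": _neighbor_based(_make_step_restart, "rw_with_restart", is_factory=True),
    "metropolis_hastings_rw": _neighbor_based(
        _make_step_metropolis, "metropolis_hastings_rw", is_factory=True
    ),
    "circulated_neighbors_rw": _neighbor_based(_step_circulated, "circulated_neighbors_rw"),
    "bfs": _neighbor_based(_step_bfs, "bfs"),
}
_JUMP_BASED = {
    "rw_with_jump": _rw_with_jump,
    "random_node_neighbor": _random_node_neighbor,
    "shortest_path": _shortest_path,
    "loop_erased_rw": _loop_erased_rw,
}

SAMPLERS: dict[str, Callable] = {
    **_EDGE_BASED, **_NODE_BASED, **_DFS, **_NEIGHBOR_BASED, **_JUMP_BASED,
}

CATEGORY: dict[str, str] = {}
CATEGORY.update({k: "edge_based" for k in _EDGE_BASED})
CATEGORY.update({k: "node_based" for k in _NODE_BASED})
CATEGORY.update({k: "dfs" for k in _DFS})
CATEGORY.update({k: "neighbor_based" for k in _NEIGHBOR_BASED})
CATEGORY.update({k: "jump_based" for k in _JUMP_BASED})

CATEGORIES = ("edge_based", "node_based", "dfs", "neighbor_based", "jump_based")


def all_sampler_specs(seed: int = 0) -> list[SamplerSpec]:
    """One SamplerSpec per registered method, with default parameters."""
    return [
        SamplerSpec(name, dict(DEFAULT_PARAMS.get(name, {})), seed)
        for name in SAMPLERS
    ]


def sample_edges(graph: Graph, spec: SamplerSpec, target_edges: int) -> set[Edge]:
    """Dispatch to the named sampler; returns a subset of the graph's edges.

    The input graph should be connected (the pipeline supplies the largest
    connected component of the observed edges).  Edge-based samplers hit the
    target exactly; growth-based samplers return the first state at or above
    it.
    """
    if spec.name not in SAMPLERS:
        raise ValueError(f"unknown sampler {spec.name!r}")
    if not 1 <= target_edges <= graph.m:
        raise ValueError(
            f"target_edges={target_edges} outside [1, m={graph.m}]"
        )
    rng = np.random.default_rng(spec.seed)
    params = {**DEFAULT_PARAMS.get(spec.name, {}), **spec.params}
    fn = SAMPLERS[spec.name]
    if spec.name in _NEIGHBOR_BASED:
        out = fn(graph, target_edges, rng, **params)
    elif params:
        out = fn(graph, target_edges, rng, **params)
    else:
        out = fn(graph, target_edges, rng)
    assert out <= graph.edges
    return out
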