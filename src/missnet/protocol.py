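"""Experimental split protocol: edge/non-edge sets for one evaluation run.

For a simple graph G = (V, E) with m edges, one run of the pipeline holds out
a uniform 20% test edge set Y (with an equally sized test non-edge set), takes
the largest connected component of the remaining edges E' = E - Y, and asks a
missingness sampler for a training edge set E_sample targeting about 64% of
the original edge count; the remainder Z = E' - E_sample serves as the
validation edge set (about 16%).  Training and validation non-edges are drawn
from the non-edges not used for testing, mutually disjoint.  Classes are
balanced by resampling 10,000 pairs per class with replacement.

The test sets are a function of the run seed only, so they are identical for
every sampler and predictor within a run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .graph_core import Edge, Graph, canonical_edge, largest_connected_component
from .missingness_samplers import SamplerSpec, sample_edges

logger = logging.getLogger(__name__)

DEFAULT_TEST_FRACTION = 0.2
DEFAULT_TRAIN_FRACTION = 0.64
DEFAULT_CLASS_SIZE = 10_000


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic child generator for one protocol stage of one run."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), stage]))


@dataclass
class SplitBundle:
    """All edge and non-edge sets of one experimental run."""

    E_full: frozenset[Edge]
    Y: frozenset[Edge]
    Y_tilde: frozenset[Edge]
    E_prime: frozenset[Edge]
    lcc_nodes: frozenset[int]
    lcc_E_prime: frozenset[Edge]
    E_sample: frozenset[Edge]
    Z: frozenset[Edge]
    train_nonedges: frozenset[Edge]
    val_nonedges: frozenset[Edge]
    run_seed: int
    sampler_name: str = ""
    target_edges: int = 0

    def audit(self) -> None:
        """Re-verify every containment and disjointness invariant; raise on breach."""
        checks = [
            (not (self.Y & self.E_prime), "Y and E_prime overlap"),
            (self.Y | self.E_prime == self.E_full, "Y + E_prime != E_full"),
            (self.E_sample <= self.lcc_E_prime, "E_sample not within LCC edges"),
            (self.lcc_E_prime <= self.E_prime, "LCC edges not within E_prime"),
            (self.Z == self.E_prime - self.E_sample, "Z != E_prime - E_sample"),
            (
                not (self.Y_tilde & (self.train_nonedges | self.val_nonedges)),
                "test non-edges reused for training/validation",
            ),
            (
                not (self.train_nonedges & self.val_nonedges),
                "train/validation non-edges overlap",
            ),
            (
                not ((self.Y_tilde | self.train_nonedges | self.val_nonedges) & self.E_full),
                "a non-edge set contains a true edge",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise AssertionError(f"SplitBundle audit failed: {msg}")


def split_test(
    graph: Graph, fraction: float = DEFAULT_TEST_FRACTION, seed: int = 0
) -> tuple[frozenset[Edge], frozenset[Edge]]:
    """Hold out ``round(fraction * m)`` edges uniformly at random.

    Returns (E_prime, Y).  The draw depends on the seed only, so the same
    seed yields the same test set for every sampler and predictor.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if graph.m < 5:
        raise ValueError("graph has fewer than 5 edges; cannot form splits")
    k = _round_half_up(fraction * graph.m)
    edges = sorted(graph.edges)
    rng = _rng(seed, 1)
    picks = set(rng.choice(len(edges), size=k, replace=False).tolist())
    Y = frozenset(edges[i] for i in picks)
    return frozenset(graph.edges) - Y, Y


def _sample_nonedges(
    graph: Graph,
    count: int,
    rng: np.random.Generator,
    exclude: frozenset[Edge] = frozenset(),
) -> frozenset[Edge]:
    """Uniform non-edges of the graph, without replacement, avoiding ``exclude``."""
    order = sorted(graph.nodes)
    n = len(order)
    available = n * (n - 1) // 2 - graph.m - len(exclude)
    if count > available:
        raise ValueError(f"requested {count} non-edges but only {available} exist")
    if count == 0:
        return frozenset()
    # rejection sampling is fast while the eligible set is plentiful;
    # fall back to full enumeration for dense or nearly exhausted graphs
    if count <= 0.25 * available and n > 40:
        out: set[Edge] = set()
        guard = 0
        while len(out) < count and guard < 200 * count + 10_000:
            guard += 1
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            e = canonical_edge(order[int(i)], order[int(j)])
            if e in graph.edges or e in exclude or e in out:
                continue
            out.add(e)
        if len(out) == count:
            return frozenset(out)
    eligible = sorted(
        e
        for e in (canonical_edge(a, b) for a, b in combinations(order, 2))
        if e not in graph.edges and e not in exclude
    )
    picks = rng.choice(len(eligible), size=count, replace=False)
    return frozenset(eligible[i] for i in picks)


def sample_test_nonedges(graph: Graph, count: int, seed: int = 0) -> frozenset[Edge]:
    """Uniform test non-edges; fixed across samplers/predictors for one seed."""
    return _sample_nonedges(graph, count, _rng(seed, 2))


def make_training_sample(
    lcc: Graph,
    sampler: SamplerSpec,
    target_edges: int,
    E_prime: frozenset[Edge],
) -> tuple[frozenset[Edge], frozenset[Edge]]:
    """Run the missingness sampler on the LCC; return (E_sample, Z).

    ``target_edges`` defaults (at the pipeline level) to 64% of the original
    edge count; samplers that cannot hit it exactly return a close size, and
    the deviation is logged.
    """
    target = min(target_edges, lcc.m)
    if target < 1:
        raise ValueError("LCC too small to draw a training sample")
    if target != target_edges:
        logger.info(
            "target %d exceeds LCC edge count %d; clamped", target_edges, lcc.m
        )
    E_sample = frozenset(sample_edges(lcc, sampler, target))
    if not E_sample:
        raise ValueError(f"sampler {sampler.name} produced no edges")
    if len(E_sample) != target:
        logger.info(
            "%s: sample size deviates from target by %+d",
            sampler.name, len(E_sample) - target,
        )
    return E_sample, frozenset(E_prime) - E_sample


def sample_disjoint_nonedge_sets(
    graph: Graph,
    Y_tilde: frozenset[Edge],
    sizes: tuple[int, int],
    seed: int = 0,
) -> tuple[frozenset[Edge], frozenset[Edge]]:
    """Draw train and validation non-edge sets from the non-edges outside the
    test non-edge set, mutually disjoint."""
    rng = _rng(seed, 3)
    both = _sample_nonedges(graph, sizes[0] + sizes[1], rng, exclude=frozenset(Y_tilde))
    ordered = sorted(both)
    perm = rng.permutation(len(ordered))
    train = frozenset(ordered[i] for i in perm[: sizes[0]])
    val = frozenset(ordered[i] for i in perm[sizes[0]:])
    return train, val


def balance_classes(
    pos_pool, neg_pool, class_size: int = DEFAULT_CLASS_SIZE, seed: int = 0
) -> tuple[list, list]:
    """Uniform draws with replacement: ``class_size`` positives and negatives."""
    if not pos_pool or not neg_pool:
        raise ValueError("cannot balance classes from an empty pool")
    rng = _rng(seed, 4)
    pos = sorted(pos_pool)
    neg = sorted(neg_pool)
    pos_sample = [pos[i] for i in rng.integers(0, len(pos), size=class_size)]
    neg_sample = [neg[i] for i in rng.integers(0, len(neg), size=class_size)]
    return pos_sample, neg_sample


def make_split_bundle(
    graph: Graph,
    sampler: SamplerSpec,
    run_seed: int,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_test_nonedges: int | None = None,
) -> SplitBundle:
    """Construct every edge/non-edge set of one run for one sampler.

    The test split and test non-edges depend only on ``run_seed``; the
    training sample additionally depends on the sampler spec (and its seed).
    """
    E_prime, Y = split_test(graph, test_fraction, run_seed)
    n_tilde = len(Y) if n_test_nonedges is None else n_test_nonedges
    Y_tilde = sample_test_nonedges(graph, n_tilde, run_seed)

    lcc = largest_connected_component(
        Graph(frozenset({x for e in E_prime for x in e}), E_prime, graph.labels)
    )
    target = _round_half_up(train_fraction * graph.m)
    E_sample, Z = make_training_sample(lcc, sampler, target, E_prime)

    # non-edge pools sized to their positive counterparts, capped by feasibility
    n = graph.n
    available = n * (n - 1) // 2 - graph.m - len(Y_tilde)
    want = (len(E_sample), max(len(Z), 1))
    if sum(want) > available:
        scale = available / sum(want)
        want = (int(want[0] * scale), int(want[1] * scale))
        logger.info("non-edge pools scaled down to %s for feasibility", want)
    train_ne, val_ne = sample_disjoint_nonedge_sets(graph, Y_tilde, want, run_seed)

    bundle = SplitBundle(
        E_full=frozenset(graph.edges),
        Y=Y,
        Y_tilde=Y_tilde,
        E_prime=E_prime,
        lcc_nodes=lcc.nodes,
        lcc_E_prime=frozenset(lcc.edges),
        E_sample=E_sample,
        Z=Z,
        train_nonedges=train_ne,
        val_nonedges=val_ne,
        run_seed=run_seed,
        sampler_name=sampler.name,
        target_edges=target,
    )
    bundle.audit()
    return bundle


def sample_graph(bundle: SplitBundle) -> Graph:
    """The observed training graph: the nodes and edges of E_sample only.

    Nodes the sampler removed entirely are absent here; predictors assign
    their sentinel (minimum) score to any candidate pair touching one.
    """
    nodes = frozenset({x for e in bundle.E_sample for x in e})
    return Graph(nodes, bundle.E_sample)
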