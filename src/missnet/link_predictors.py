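"""Nine link-prediction scoring methods from four algorithm families.

Every method maps an observed sample graph (and, for supervised methods, the
training/validation sets of a :class:`~missnet.protocol.SplitBundle`) to a
:class:`ScoreTable` over candidate node pairs.  Higher score = more likely a
missing edge.  Families:

* local similarity — Adamic-Adar, Jaccard, preferential attachment;
* network embedding — spectral embedding, node2vec dot product, node2vec
  edge embedding (Hadamard pair vectors + logistic regression);
* matrix completion — modularity block densities and an MDL-selected
  degree-corrected stochastic block model;
* ensemble — "top stacking": a random forest over topological pair features,
  trained on validation-set edges so the positives were *not* available when
  the features were computed (training on feature-set edges overfits badly).

Sentinel policy: a candidate pair with an endpoint absent from the sample
graph cannot be scored structurally and receives the table's minimum score,
i.e. it ranks last.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.linalg import eigsh
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV

from ._skipgram import simulate_walks, train_skipgram
from .graph_core import Edge, Graph, canonical_edge, pagerank_scores
from .protocol import DEFAULT_CLASS_SIZE, SplitBundle, balance_classes

logger = logging.getLogger(__name__)

FAMILY: dict[str, str] = {
    "adamic_adar": "local",
    "jaccard": "local",
    "preferential_attachment": "local",
    "spectral": "embedding",
    "node2vec_dot": "embedding",
    "node2vec_edge": "embedding",
    "modularity": "matrix_completion",
    "mdl_dcsbm": "matrix_completion",
    "top_stacking": "ensemble",
}
FAMILIES = ("local", "embedding", "matrix_completion", "ensemble")

PATH_LENGTH_CAP = 10

FEATURE_NAMES = (
    "degree_u",
    "degree_v",
    "common_neighbors",
    "adamic_adar",
    "jaccard",
    "resource_allocation",
    "preferential_attachment",
    "clustering_u",
    "clustering_v",
    "shortest_path_capped",
    "pagerank_u",
    "pagerank_v",
    "same_community",
)


@dataclass(frozen=True)
class PredictorSpec:
    """Registry entry naming one predictor with parameters and a seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def family(self) -> str:
        return FAMILY[self.name]


def all_predictor_specs(seed: int = 0) -> list[PredictorSpec]:
    return [PredictorSpec(name, {}, seed) for name in FAMILY]


@dataclass
class ScoreTable:
    """Finite real scores for a fixed set of candidate pairs."""

    entries: dict[Edge, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for pair, s in self.entries.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite score for pair {pair}")

    def __getitem__(self, pair: Edge) -> float:
        return self.entries[canonical_edge(*pair)]

    def scores(self, pairs: Iterable[Edge]) -> np.ndarray:
        return np.array([self[p] for p in pairs])


def _finish_table(
    scored: dict[Edge, float], missing: list[Edge], provenance: str
) -> ScoreTable:
    """Assign the sentinel (table minimum) to pairs with absent endpoints."""
    sentinel = min(scored.values()) if scored else 0.0
    for pair in missing:
        scored[pair] = sentinel
    return ScoreTable(scored, provenance)


def _split_pairs(sample: Graph, pairs: Iterable[Edge]) -> tuple[list[Edge], list[Edge]]:
    present, absent = [], []
    for p in pairs:
        p = canonical_edge(*p)
        (present if p[0] in sample.nodes and p[1] in sample.nodes else absent).append(p)
    return present, absent


# --------------------------------------------------------------------------
# local similarity indices
# --------------------------------------------------------------------------


def score_local(sample: Graph, pairs: Iterable[Edge], index: str) -> ScoreTable:
    """Adamic-Adar, Jaccard, or preferential-attachment similarity.

    adamic_adar(i,j) = sum over common neighbors z of 1/ln(deg z);
    jaccard(i,j) = |N(i) & N(j)| / |N(i) | N(j)| (0 for an empty union);
    preferential_attachment(i,j) = deg(i) * deg(j).
    """
    if index not in ("adamic_adar", "jaccard", "preferential_attachment"):
        raise ValueError(f"unknown local index {index!r}")
    adj = sample.adjacency()
    present, absent = _split_pairs(sample, pairs)
    scored: dict[Edge, float] = {}
    for u, v in present:
        nu, nv = adj[u], adj[v]
        if index == "adamic_adar":
            # a common neighbor has degree >= 2, so ln(deg) > 0
            s = sum(1.0 / math.log(len(adj[z])) for z in nu & nv)
        elif index == "jaccard":
            union = len(nu | nv)
            s = len(nu & nv) / union if union else 0.0
        else:
            s = float(len(nu) * len(nv))
        scored[(u, v)] = s
    return _finish_table(scored, absent, index)


# --------------------------------------------------------------------------
# shared supervised helpers
# --------------------------------------------------------------------------


def _train_pairs(
    bundle: SplitBundle, class_size: int, seed: int
) -> tuple[list[Edge], np.ndarray]:
    """Balanced training pairs: positives from E_sample, negatives from the
    training non-edge pool."""
    pos, neg = balance_classes(
        bundle.E_sample, bundle.train_nonedges, class_size, seed
    )
    return pos + neg, np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])


def _fit_logistic(
    X: np.ndarray, y: np.ndarray, seed: int, cv: bool = True
) -> LogisticRegression:
    """Logistic classifier; regularization chosen by 5-fold cross-validation."""
    if cv:
        grid = GridSearchCV(
            LogisticRegression(max_iter=1000, random_state=seed),
            {"C": [0.1, 1.0, 10.0]},
            cv=5,
            n_jobs=1,
        )
        grid.fit(X, y)
        return grid.best_estimator_
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(X, y)
    return clf


def _hadamard(emb: dict[int, np.ndarray], pairs: Sequence[Edge]) -> np.ndarray:
    return np.array([emb[u] * emb[v] for u, v in pairs])


def _classifier_table(
    emb: dict[int, np.ndarray],
    sample: Graph,
    bundle: SplitBundle,
    pairs: Iterable[Edge],
    provenance: str,
    seed: int,
    class_size: int,
    cv: bool,
) -> ScoreTable:
    """Hadamard pair vectors + logistic classifier on balanced training pairs."""
    train_pairs, y = _train_pairs(bundle, class_size, seed)
    usable = [p for p in train_pairs if p[0] in emb and p[1] in emb]
    y = np.array(
        [yy for p, yy in zip(train_pairs, y) if p[0] in emb and p[1] in emb]
    )
    if len(set(y.tolist())) < 2:
        # degenerate training data (e.g. a clique sample has no internal
        # non-edges): fall back to an uninformative constant score
        logger.warning("%s: single-class training data; constant scores", provenance)
        present0, absent = _split_pairs(sample, pairs)
        return _finish_table({p: 0.5 for p in present0}, absent, provenance)
    clf = _fit_logistic(_hadamard(emb, usable), y, seed, cv)
    present0, absent = _split_pairs(sample, pairs)
    present = [p for p in present0 if p[0] in emb and p[1] in emb]
    absent += [p for p in present0 if p[0] not in emb or p[1] not in emb]
    scored = {}
    if present:
        probs = clf.predict_proba(_hadamard(emb, present))[:, 1]
        scored = {p: float(s) for p, s in zip(present, probs)}
    return _finish_table(scored, absent, provenance)


# --------------------------------------------------------------------------
# network embedding
# --------------------------------------------------------------------------


def score_spectral(
    sample: Graph,
    bundle: SplitBundle,
    pairs: Iterable[Edge],
    dim: int = 16,
    seed: int = 0,
    class_size: int = DEFAULT_CLASS_SIZE,
    cv: bool = True,
) -> ScoreTable:
    """Spectral embedding of the normalized adjacency + logistic classifier.

    Node vectors are the leading eigenvector coordinates of
    D^{-1/2} A D^{-1/2}; pair vectors are Hadamard products.
    """
    order = sorted(sample.nodes)
    n = len(order)
    if n < 3:
        raise ValueError("sample graph too small for spectral embedding")
    k = min(dim, n - 2)
    if k < dim:
        logger.warning("spectral dim clipped from %d to %d", dim, k)
    idx = {u: i for i, u in enumerate(order)}
    A = np.zeros((n, n))
    for u, v in sample.edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    d = A.sum(axis=1)
    dinv = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-12)), 0.0)
    An = dinv[:, None] * A * dinv[None, :]
    vals, vecs = eigsh(An, k=k, which="LA", v0=np.ones(n) / math.sqrt(n))
    # deterministic sign: largest-magnitude coordinate positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    emb = {u: vecs[idx[u]] for u in order}
    return _classifier_table(
        emb, sample, bundle, pairs, "spectral", seed, class_size, cv
    )


def score_node2vec(
    sample: Graph,
    bundle: SplitBundle,
    pairs: Iterable[Edge],
    variant: str = "dot",
    dimensions: int = 32,
    walks_per_node: int = 10,
    walk_length: int = 40,
    window: int = 5,
    epochs: int = 2,
    seed: int = 0,
    class_size: int = DEFAULT_CLASS_SIZE,
    cv: bool = True,
) -> ScoreTable:
    """Skip-gram node embeddings from random walks on the sample graph.

    ``dot``: score = inner product of endpoint vectors.  ``edge_embedding``:
    Hadamard pair vectors fed to a logistic classifier trained on balanced
    edge/non-edge pairs.  Walk biases are uniform (return and in-out
    parameters both 1).  Deterministic: single-threaded, seeded.
    """
    if variant not in ("dot", "edge_embedding"):
        raise ValueError(f"unknown node2vec variant {variant!r}")
    order = sorted(sample.nodes)
    idx = {u: i for i, u in enumerate(order)}
    adj_idx = {idx[u]: sorted(idx[v] for v in nbrs) for u, nbrs in sample.adjacency().items()}
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 11]))
    walks = simulate_walks(adj_idx, walks_per_node, walk_length, rng)
    W = train_skipgram(
        walks, len(order), dim=dimensions, window=window, epochs=epochs, rng=rng
    )
    emb = {u: W[idx[u]] for u in order}
    if variant == "edge_embedding":
        return _classifier_table(
            emb, sample, bundle, pairs, "node2vec_edge", seed, class_size, cv
        )
    present, absent = _split_pairs(sample, pairs)
    scored = {(u, v): float(emb[u] @ emb[v]) for u, v in present}
    return _finish_table(scored, absent, "node2vec_dot")


# --------------------------------------------------------------------------
# matrix completion (block models)
# --------------------------------------------------------------------------


def _block_stats(sample: Graph, labels: dict[int, int]):
    """Per-block-pair edge counts, block sizes, and block degree sums."""
    blocks = sorted(set(labels.values()))
    sizes = {r: 0 for r in blocks}
    for u in sample.nodes:
        sizes[labels[u]] += 1
    m_rs: dict[tuple[int, int], int] = {}
    kappa = {r: 0 for r in blocks}
    for u, v in sample.edges:
        r, s = sorted((labels[u], labels[v]))
        m_rs[(r, s)] = m_rs.get((r, s), 0) + 1
        kappa[labels[u]] += 1
        kappa[labels[v]] += 1
    return blocks, sizes, m_rs, kappa


def _dcsbm_loglik(m_rs: dict, kappa: dict) -> float:
    """Karrer-Newman degree-corrected log-likelihood (up to constants).

    Unordered-pair form: sum over r < s of m_rs ln(m_rs / (k_r k_s)) plus
    diagonal terms m_rr ln(2 m_rr / k_r^2), with k the block degree sums.
    """
    ll = 0.0
    for (r, s), m in m_rs.items():
        if m == 0:
            continue
        denom = kappa[r] * kappa[s]
        if denom > 0:
            ll += m * math.log((2 * m if r == s else m) / denom)
    return ll


def _description_length(sample: Graph, labels: dict[int, int]) -> float:
    """MDL-style objective: negative DCSBM log-likelihood plus model cost.

    The model cost charges ln(2m) per block-pair parameter and ln(B) per node
    label, so it grows with the number of blocks and selects B.
    """
    blocks, _, m_rs, kappa = _block_stats(sample, labels)
    B = len(blocks)
    two_m = 2 * sample.m
    fit = -_dcsbm_loglik(m_rs, kappa)
    cost = (B * (B + 1) / 2) * math.log(max(two_m, 2)) + sample.n * math.log(max(B, 2))
    return fit + cost


def _relabel(labels: dict[int, int]) -> dict[int, int]:
    remap: dict[int, int] = {}
    out = {}
    for u in sorted(labels):
        b = labels[u]
        if b not in remap:
            remap[b] = len(remap)
        out[u] = remap[b]
    return out


def fit_block_model(
    sample: Graph, model: str = "modularity", seed: int = 0, restarts: int = 3
) -> tuple[dict[int, int], dict[tuple[int, int], float]]:
    """Fit a community/block structure and its block density table.

    ``modularity``: greedy agglomerative modularity maximization.
    ``mdl_dcsbm``: a degree-corrected stochastic block model fitted by
    agglomerative block merges plus local node moves minimizing a
    minimum-description-length objective (restarts keep variance down); the
    number of blocks is selected by the objective.

    Returns (labels, density) where density[(r, s)] is observed edges between
    blocks r and s divided by the number of possible pairs.
    """
    if sample.m == 0:
        raise ValueError("cannot fit a block model to an empty graph")
    g = sample.to_networkx()
    comms = list(nx.community.greedy_modularity_communities(g))
    base = {u: i for i, c in enumerate(comms) for u in c}
    if model == "modularity":
        labels = _relabel(base)
    elif model == "mdl_dcsbm":
        best_labels, best_dl = None, math.inf
        rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 13]))
        for t in range(restarts):
            init = dict(base)
            if t > 0:  # perturb: reassign a random 20% of nodes to random blocks
                B0 = max(base.values()) + 1
                nodes = sorted(init)
                for u in rng.choice(nodes, size=max(1, len(nodes) // 5), replace=False):
                    init[int(u)] = int(rng.integers(B0))
            labels_t = _mdl_refine(sample, init)
            dl = _description_length(sample, labels_t)
            if dl < best_dl - 1e-9:
                best_labels, best_dl = labels_t, dl
        labels = _relabel(best_labels)
    else:
        raise ValueError(f"unknown block model {model!r}")

    blocks, sizes, m_rs, _ = _block_stats(sample, labels)
    density: dict[tuple[int, int], float] = {}
    for r in blocks:
        for s in blocks:
            if s < r:
                continue
            m = m_rs.get((r, s), 0)
            possible = (
                sizes[r] * (sizes[r] - 1) // 2 if r == s else sizes[r] * sizes[s]
            )
            density[(r, s)] = m / possible if possible else 0.0
    return labels, density


def _mdl_refine(sample: Graph, labels: dict[int, int]) -> dict[int, int]:
    """Greedy block merges then node-level moves, minimizing description length."""
    labels = dict(labels)
    adj = sample.adjacency()
    improved = True
    while improved:
        improved = False
        # merge phase: best improving pair of blocks
        blocks = sorted(set(labels.values()))
        if len(blocks) > 1:
            cur = _description_length(sample, labels)
            best = (0.0, None)
            for i, r in enumerate(blocks):
                for s in blocks[i + 1 :]:
                    trial = {u: (r if b == s else b) for u, b in labels.items()}
                    gain = cur - _description_length(sample, trial)
                    if gain > best[0] + 1e-9:
                        best = (gain, (r, s))
            if best[1] is not None:
                r, s = best[1]
                labels = {u: (r if b == s else b) for u, b in labels.items()}
                improved = True
        # move phase: one sweep of single-node moves to neighboring blocks
        for u in sorted(labels):
            cur = _description_length(sample, labels)
            here = labels[u]
            candidates = sorted({labels[v] for v in adj[u]} - {here})
            for b in candidates:
                labels[u] = b
                if _description_length(sample, labels) < cur - 1e-9:
                    here = b
                    cur = _description_length(sample, labels)
                    improved = True
            labels[u] = here
    return labels


def score_block_density(
    sample: Graph,
    pairs: Iterable[Edge],
    model: str = "modularity",
    seed: int = 0,
) -> ScoreTable:
    """Score candidate pairs from a fitted block structure.

    modularity: score(i,j) = density(block_i, block_j).
    mdl_dcsbm:  score(i,j) = theta_i * theta_j * omega(block_i, block_j) with
    theta the within-block degree propensity and omega the block edge counts
    (the degree-corrected expected-edge score).
    """
    labels, density = fit_block_model(sample, model, seed)
    present, absent = _split_pairs(sample, pairs)
    scored: dict[Edge, float] = {}
    if model == "mdl_dcsbm":
        _, _, m_rs, kappa = _block_stats(sample, labels)
        deg = sample.degrees()
        for u, v in present:
            r, s = sorted((labels[u], labels[v]))
            omega = float(2 * m_rs.get((r, s), 0) if r == s else m_rs.get((r, s), 0))
            tu = deg[u] / kappa[labels[u]] if kappa[labels[u]] else 0.0
            tv = deg[v] / kappa[labels[v]] if kappa[labels[v]] else 0.0
            scored[(u, v)] = tu * tv * omega
    else:
        for u, v in present:
            r, s = sorted((labels[u], labels[v]))
            scored[(u, v)] = density[(r, s)]
    return _finish_table(scored, absent, model)


# --------------------------------------------------------------------------
# ensemble: topological feature stacking
# --------------------------------------------------------------------------


def _bfs_distances(adj: dict[int, set[int]], src: int, cap: int) -> dict[int, int]:
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        if dist[u] >= cap:
            continue
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def extract_pair_features(sample: Graph, pairs: Sequence[Edge]) -> np.ndarray:
    """Topological feature matrix for candidate pairs (rows follow ``pairs``).

    Features (fixed order, see FEATURE_NAMES): endpoint degrees, common
    neighbors, Adamic-Adar, Jaccard, resource allocation, preferential
    attachment, endpoint local clustering, shortest path (capped), endpoint
    PageRank, same-community indicator.  A pair with an absent endpoint gets
    the sentinel vector: zeros with the path length at the cap.
    """
    adj = sample.adjacency()
    clustering = nx.clustering(sample.to_networkx()) if sample.n else {}
    pr = pagerank_scores(sample) if sample.n else {}
    comms = (
        list(nx.community.greedy_modularity_communities(sample.to_networkx()))
        if sample.m
        else []
    )
    comm_of = {u: i for i, c in enumerate(comms) for u in c}
    sources = {canonical_edge(*p)[0] for p in pairs if p[0] in sample.nodes}
    dists = {s: _bfs_distances(adj, s, PATH_LENGTH_CAP) for s in sources}

    rows = []
    for p in pairs:
        u, v = canonical_edge(*p)
        if u not in sample.nodes or v not in sample.nodes:
            row = [0.0] * len(FEATURE_NAMES)
            row[FEATURE_NAMES.index("shortest_path_capped")] = float(PATH_LENGTH_CAP)
            rows.append(row)
            continue
        nu, nv = adj[u], adj[v]
        cn = nu & nv
        union = len(nu | nv)
        sp = dists[u].get(v, PATH_LENGTH_CAP)
        rows.append(
            [
                float(len(nu)),
                float(len(nv)),
                float(len(cn)),
                sum(1.0 / math.log(len(adj[z])) for z in cn),
                len(cn) / union if union else 0.0,
                sum(1.0 / len(adj[z]) for z in cn),
                float(len(nu) * len(nv)),
                float(clustering.get(u, 0.0)),
                float(clustering.get(v, 0.0)),
                float(min(sp, PATH_LENGTH_CAP)),
                float(pr.get(u, 0.0)),
                float(pr.get(v, 0.0)),
                1.0 if comm_of.get(u, -1) == comm_of.get(v, -2) else 0.0,
            ]
        )
    return np.asarray(rows)


def score_topstacking(
    sample: Graph,
    bundle: SplitBundle,
    pairs: Iterable[Edge],
    seed: int = 0,
    class_size: int = DEFAULT_CLASS_SIZE,
    n_estimators: int = 100,
    cv: bool = True,
    leaky: bool = False,
) -> ScoreTable:
    """Random forest over topological pair features.

    Features are computed from the sample graph only.  Training positives are
    drawn (balanced, with replacement) from the validation edges Z = E' -
    E_sample — edges that were *not* available when the features were
    computed — and negatives from the validation non-edge pool.  Training on
    E_sample edges instead (``leaky=True``, kept for regression testing)
    produces drastic overfitting, because detecting edges already baked into
    the features is a different problem from predicting unseen ones.
    """
    pos_pool = bundle.E_sample if leaky else bundle.Z
    if not pos_pool:
        raise ValueError(
            "validation edge set Z is empty; use a smaller training target fraction"
        )
    pos, neg = balance_classes(pos_pool, bundle.val_nonedges, class_size, seed)
    if not leaky:
        assert not (set(pos) & bundle.E_sample), "training positives leak into E_sample"
    X = extract_pair_features(sample, pos + neg)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed % (2**31), n_jobs=1
    )
    if cv:
        grid = GridSearchCV(
            rf, {"max_depth": [None, 10], "max_features": ["sqrt", None]}, cv=5, n_jobs=1
        )
        grid.fit(X, y)
        clf = grid.best_estimator_
    else:
        rf.fit(X, y)
        clf = rf
    pairs = [canonical_edge(*p) for p in pairs]
    probs = clf.predict_proba(extract_pair_features(sample, pairs))[:, 1]
    return ScoreTable({p: float(s) for p, s in zip(pairs, probs)}, "top_stacking")


# --------------------------------------------------------------------------
# dispatcher
# --------------------------------------------------------------------------


def score_pairs(
    spec: PredictorSpec,
    sample: Graph,
    bundle: SplitBundle,
    pairs: Sequence[Edge],
) -> ScoreTable:
    """Score candidate pairs with the named predictor."""
    name, params = spec.name, dict(spec.params)
    if name in ("adamic_adar", "jaccard", "preferential_attachment"):
        return score_local(sample, pairs, name)
    if name == "spectral":
        return score_spectral(sample, bundle, pairs, seed=spec.seed, **params)
    if name in ("node2vec_dot", "node2vec_edge"):
        variant = "dot" if name == "node2vec_dot" else "edge_embedding"
        return score_node2vec(
            sample, bundle, pairs, variant=variant, seed=spec.seed, **params
        )
    if name in ("modularity", "mdl_dcsbm"):
        return score_block_density(sample, pairs, model=name, seed=spec.seed)
    if name == "top_stacking":
        return score_topstacking(sample, bundle, pairs, seed=spec.seed, **params)
    raise ValueError(f"unknown predictor {name!r}")
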