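"""Minimal skip-gram-with-negative-sampling trainer for node embeddings.

Trains word2vec-style input vectors from random-walk corpora with vectorized
minibatch SGD.  Deterministic given the generator passed in (single-threaded
by construction).
"""

from __future__ import annotations

import numpy as np


def walk_pairs(walks: list[list[int]], window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within the window along each walk."""
    centers: list[int] = []
    contexts: list[int] = []
    for walk in walks:
        L = len(walk)
        for i, c in enumerate(walk):
            lo = max(0, i - window)
            hi = min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(walk[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_skipgram(
    walks: list[list[int]],
    n_nodes: int,
    dim: int = 32,
    window: int = 5,
    negative: int = 5,
    epochs: int = 2,
    lr: float = 0.025,
    batch: int = 64,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Return an (n_nodes, dim) embedding matrix.

    Negative contexts are drawn from the unigram distribution raised to the
    3/4 power, as in word2vec.
    """
    rng = rng or np.random.default_rng(0)
    centers, contexts = walk_pairs(walks, window)
    if centers.size == 0:
        return np.zeros((n_nodes, dim))

    freq = np.bincount(
        np.concatenate([w for w in map(np.asarray, walks)]), minlength=n_nodes
    ).astype(float)
    noise = freq**0.75
    noise /= noise.sum()

    W = (rng.random((n_nodes, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((n_nodes, dim))  # output vectors

    n_pairs = centers.size
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            idx = order[s : s + batch]
            c = centers[idx]
            pos = contexts[idx]
            neg = rng.choice(n_nodes, size=(idx.size, negative), p=noise)

            wc = W[c]  # (B, d)
            # positive pass
            z = np.einsum("bd,bd->b", wc, C[pos])
            g = lr * (1.0 / (1.0 + np.exp(-np.clip(z, -30, 30))) - 1.0)  # sigmoid - 1
            dW = g[:, None] * C[pos]
            np.add.at(C, pos, -g[:, None] * wc)
            # negative pass
            zn = np.einsum("bd,bnd->bn", wc, C[neg])
            gn = lr * (1.0 / (1.0 + np.exp(-np.clip(zn, -30, 30))))
            dW += np.einsum("bn,bnd->bd", gn, C[neg])
            np.add.at(C, neg.ravel(), -(gn[..., None] * wc[:, None, :]).reshape(-1, dim))
            np.add.at(W, c, -dW)
    return W


def simulate_walks(
    adjacency: dict[int, list[int]],
    walks_per_node: int = 10,
    walk_length: int = 40,
    rng: np.random.Generator | None = None,
) -> list[list[int]]:
    """Unbiased random walks (the p = q = 1 special case of biased walks)."""
    rng = rng or np.random.default_rng(0)
    nodes = sorted(adjacency)
    walks: list[list[int]] = []
    for _ in range(walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < walk_length:
                nbrs = adjacency[walk[-1]]
                if not nbrs:
                    break
                walk.append(nbrs[int(rng.integers(len(nbrs)))])
            walks.append(walk)
    return walks
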