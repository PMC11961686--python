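"""Structural node embeddings: biased second-order random walks plus a
skip-gram fit with negative sampling (node2vec-style).

The walk bias follows the usual return / in-out parameterization: from the
previous node t standing at v, the unnormalized probability of stepping to
x is 1/p if x == t, 1 if x is also a neighbor of t, and 1/q otherwise
(p = q = 1 reduces to uniform random walks).  The walk corpus is fit with
skip-gram + negative sampling (SGNS) implemented directly on numpy arrays
in minibatches; everything is driven by one seed, so embeddings are
reproducible bit-for-bit.

Isolated nodes never enter the corpus and are assigned the zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class WalkParams:
    """Random-walk and skip-gram hyperparameters."""

    p: float = 1.0  # return parameter
    q: float = 1.0  # in-out parameter
    num_walks: int = 10
    walk_length: int = 80
    window: int = 10
    dimensions: int = 64
    negative: int = 5
    epochs: int = 1
    learning_rate: float = 0.025
    seed: int = 0


@dataclass
class StructuralEmbedding:
    """N × d node embedding matrix with the parameters that produced it."""

    vectors: np.ndarray
    params: WalkParams


def _adjacency_lists(n_nodes: int, edges: np.ndarray) -> list[np.ndarray]:
    neigh: list[set[int]] = [set() for _ in range(n_nodes)]
    for i, j in np.asarray(edges, dtype=int).reshape(-1, 2):
        if i != j:
            neigh[i].add(j)
            neigh[j].add(i)
    return [np.array(sorted(s), dtype=int) for s in neigh]


def generate_walks(
    n_nodes: int, edges: np.ndarray, params: WalkParams, rng: np.random.Generator
) -> list[np.ndarray]:
    """Second-order biased walks, ``num_walks`` starts per non-isolated node."""
    adj = _adjacency_lists(n_nodes, edges)
    adj_sets = [set(a.tolist()) for a in adj]
    walks: list[np.ndarray] = []
    nodes = np.arange(n_nodes)
    uniform = params.p == 1.0 and params.q == 1.0
    for _ in range(params.num_walks):
        order = rng.permutation(nodes)
        for start in order:
            if adj[start].size == 0:
                continue
            walk = [int(start)]
            while len(walk) < params.walk_length:
                cur = walk[-1]
                nbrs = adj[cur]
                if nbrs.size == 0:
                    break
                if uniform or len(walk) == 1:
                    nxt = int(nbrs[rng.integers(nbrs.size)])
                else:
                    prev = walk[-2]
                    w = np.where(
                        nbrs == prev, 1.0 / params.p,
                        np.where([x in adj_sets[prev] for x in nbrs], 1.0, 1.0 / params.q),
                    )
                    nxt = int(nbrs[rng.choice(nbrs.size, p=w / w.sum())])
                walk.append(nxt)
            walks.append(np.array(walk, dtype=int))
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks:
        length = walk.size
        for offset in range(1, window + 1):
            if length <= offset:
                continue
            centers.append(walk[:-offset])
            contexts.append(walk[offset:])
            centers.append(walk[offset:])
            contexts.append(walk[:-offset])
    if not centers:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(centers), np.concatenate(contexts)


def _fit_sgns(
    n_nodes: int,
    centers: np.ndarray,
    contexts: np.ndarray,
    params: WalkParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Minibatch SGNS over (center, context) pairs; returns input vectors."""
    d = params.dimensions
    emb_in = (rng.random((n_nodes, d)) - 0.5) / d
    emb_out = np.zeros((n_nodes, d))
    if centers.size == 0:
        return np.zeros((n_nodes, d))
    # unigram^0.75 noise distribution over observed contexts
    counts = np.bincount(contexts, minlength=n_nodes).astype(float)
    noise = counts ** 0.75
    noise /= noise.sum()
    batch = 8192
    n_pairs = centers.size
    total_steps = params.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            lr = params.learning_rate * max(1.0 - step / max(total_steps, 1), 1e-2)
            step += 1
            sel = order[lo:lo + batch]
            c, ctx = centers[sel], contexts[sel]
            neg = rng.choice(n_nodes, size=(sel.size, params.negative), p=noise)
            v_c = emb_in[c]  # (B, d)
            u_pos = emb_out[ctx]  # (B, d)
            u_neg = emb_out[neg]  # (B, k, d)
            s_pos = expit((v_c * u_pos).sum(1))  # (B,)
            s_neg = expit(np.einsum("bd,bkd->bk", v_c, u_neg))
            g_pos = (s_pos - 1.0)[:, None]  # d/d(score) of -log sigmoid
            g_neg = s_neg[:, :, None]
            grad_c = g_pos * u_pos + np.einsum("bk,bkd->bd", s_neg, u_neg)
            np.add.at(emb_in, c, -lr * grad_c)
            np.add.at(emb_out, ctx, -lr * g_pos * v_c)
            np.add.at(emb_out, neg.ravel(),
                      -lr * (g_neg * v_c[:, None, :]).reshape(-1, d))
    return emb_in


def structural_embeddings(
    n_nodes: int, edges: np.ndarray, params: WalkParams | None = None
) -> StructuralEmbedding:
    """Embed every node of the (undirected) graph; fully seeded.

    Isolated nodes get the zero vector; with ``dimensions`` exceeding what a
    tiny walk corpus can constrain the fit simply stays close to its small
    random initialization.
    """
    params = params or WalkParams()
    if params.dimensions < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(params.seed)
    walks = generate_walks(n_nodes, edges, params, rng)
    centers, contexts = _skipgram_pairs(walks, params.window)
    vectors = _fit_sgns(n_nodes, centers, contexts, params, rng)
    seen = np.zeros(n_nodes, dtype=bool)
    if centers.size:
        seen[np.unique(np.concatenate([centers, contexts]))] = True
    vectors[~seen] = 0.0
    return StructuralEmbedding(vectors=vectors, params=params)
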