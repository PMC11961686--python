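"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from mslgat.model import GATLayerParams, HeadParams


def dense_gat_oracle(h: np.ndarray, a_mat, layer: GATLayerParams,
                     activation=None) -> np.ndarray:
    """Dense masked-softmax evaluation of one attention layer.

    Independent of the package's edge-list implementation: attention scores
    are computed for every node pair, masked with -inf where no edge
    exists, row-softmaxed, and aggregated with plain matrix products.
    """
    dense = np.asarray(a_mat.todense() if sparse.issparse(a_mat) else a_mat)
    h = np.atleast_2d(h)
    outs = []
    for head in layer.heads:
        wh = h @ head.W
        e = wh @ head.a_self[:, None] + (wh @ head.a_neigh[:, None]).T
        e = np.where(e >= 0, e, head.slope * e)
        e = np.where(dense > 0, e, -np.inf)
        e -= np.nanmax(np.where(np.isfinite(e), e, np.nan), axis=1, keepdims=True)
        expe = np.where(np.isfinite(e), np.exp(e), 0.0)
        alpha = expe / expe.sum(axis=1, keepdims=True)
        out = alpha @ wh
        outs.append(out if activation is None else activation(out))
    z = layer.head_logits - layer.head_logits.max()
    w = np.exp(z) / np.exp(z).sum()
    return np.tensordot(w, np.stack(outs), axes=1)


def random_layer(rng: np.random.Generator, f_in: int, f_out: int,
                 heads: int) -> GATLayerParams:
    hp = [HeadParams(W=rng.normal(size=(f_in, f_out)),
                     a_self=rng.normal(size=f_out),
                     a_neigh=rng.normal(size=f_out))
          for _ in range(heads)]
    return GATLayerParams(heads=hp, head_logits=rng.normal(size=heads))


def random_graph(rng: np.random.Generator, n: int, p: float = 0.3):
    """Random symmetric adjacency with self-loops, plus its edge list."""
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    from mslgat.graph import adjacency
    return edges, adjacency(n, edges, self_loops=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_planted_graph():
    from mslgat.simulate import SyntheticSpec, generate_planted_graph
    return generate_planted_graph(
        SyntheticSpec(n_nodes=60, n_features=8, edge_prob=0.08, seed=0))


@pytest.fixture(scope="session")
def tiny_config():
    from mslgat.model import ModelConfig
    return ModelConfig(d1=8, d2=8, d3=4, dense_dims=(8, 4), heads=2,
                       dropout=0.0, epochs=5, seed=0)
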