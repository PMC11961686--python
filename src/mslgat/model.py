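"""The multi stacked-layer graph attention network (MSL-GAT).

Three graph-attention layers, each with K attention heads whose outputs are
combined by a *learnable weighted average* (a softmax over per-layer head
logits, so the head weights always form a simplex), a residual connection
adding the first layer's output to the second's, and three dense
classification blocks ending in a per-node sigmoid — the probability that a
gene is a personalized driver gene.

Per head, attention between node i and neighbor j is

    e_ij = LeakyReLU(a^T [W h_i || W h_j]),   alpha_ij = softmax_{j in N(i)} e_ij

and the head output is sigma(sum_j alpha_ij W h_j).  The layer stack is

    H1 = Dropout(BN(LeakyReLU(GAT1(X, A))))
    H2 = LeakyReLU(GAT2(H1, A))
    R  = H1 + H2                       (residual)
    Hf = Dropout(BN(R))
    H3 = Dropout(BN(LeakyReLU(GAT3(Hf, A))))
    p  = sigmoid(dense3(dense2(dense1(H3))))

Self-loops keep every attention neighborhood non-empty.  Training is
full-batch Adam on binary cross-entropy over the train-mask nodes, with
batch normalization computed over the node dimension (running statistics
for evaluation).  Everything is seeded and runs in float64 numpy via the
autodiff engine in :mod:`mslgat.autodiff`.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from . import autodiff as ad
from .autodiff import Tensor
from .graph import PatientGraph, adjacency

# ---------------------------------------------------------------------------
# configuration & parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    d1 and d2 must match unless ``residual_projection`` is enabled, because
    the residual adds the first layer's output to the second's.
    """

    d1: int = 64
    d2: int = 64
    d3: int = 32
    dense_dims: tuple[int, int] = (64, 16)
    heads: int = 8
    dropout: float = 0.5
    leaky_slope: float = 0.01
    epochs: int = 200
    learning_rate: float = 1e-3
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    residual_projection: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.d1 != self.d2 and not self.residual_projection:
            raise ValueError("residual connection needs d1 == d2 "
                             "(or residual_projection=True)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class HeadParams:
    """One attention head: projection W (F_in × F_out) and attention vector
    a of length 2·F_out, split into the half applied to the updated node's
    own projection (a_self) and the half applied to the neighbor's (a_neigh)."""

    W: np.ndarray
    a_self: np.ndarray
    a_neigh: np.ndarray
    slope: float = 0.01

    @property
    def a(self) -> np.ndarray:
        return np.concatenate([self.a_self, self.a_neigh])


@dataclass
class GATLayerParams:
    heads: list[HeadParams]
    head_logits: np.ndarray  # length K; softmax gives the head-weight simplex

    def head_weights(self) -> np.ndarray:
        z = self.head_logits - self.head_logits.max()
        e = np.exp(z)
        return e / e.sum()


@dataclass
class BatchNormParams:
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    momentum: float = 0.1
    eps: float = 1e-5
    fitted: bool = False

    @classmethod
    def create(cls, dim: int) -> "BatchNormParams":
        return cls(np.ones(dim), np.zeros(dim), np.zeros(dim), np.ones(dim))


@dataclass
class DenseBlockParams:
    W: np.ndarray
    b: np.ndarray
    bn: BatchNormParams | None
    dropout: float
    is_final: bool = False


@dataclass
class MSLGATParams:
    """All model parameters: three GAT layers with their post-layer batch
    norms, and three dense blocks."""

    gat1: GATLayerParams
    gat2: GATLayerParams
    gat3: GATLayerParams
    bn1: BatchNormParams
    bn_res: BatchNormParams
    bn3: BatchNormParams
    dense: list[DenseBlockParams]
    residual_proj: np.ndarray | None = None
    config: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class ForwardTrace:
    """Intermediate activations of one forward pass."""

    total_h1: np.ndarray
    total_h2: np.ndarray
    h_residual: np.ndarray
    h_final: np.ndarray
    total_h3: np.ndarray
    dense_activations: list[np.ndarray]
    probabilities: np.ndarray


@dataclass
class TrainReport:
    train_loss: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    best_epoch: int
    seed: int


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_gat_layer(rng, f_in: int, f_out: int, heads: int, slope: float) -> GATLayerParams:
    hp = []
    for _ in range(heads):
        hp.append(HeadParams(
            W=_glorot(rng, f_in, f_out),
            a_self=rng.uniform(-0.1, 0.1, size=f_out),
            a_neigh=rng.uniform(-0.1, 0.1, size=f_out),
            slope=slope,
        ))
    return GATLayerParams(heads=hp, head_logits=np.zeros(heads))


def init_params(n_features: int, config: ModelConfig) -> MSLGATParams:
    """Seeded Glorot initialization of every trainable array."""
    rng = np.random.default_rng(config.seed)
    s = config.leaky_slope
    gat1 = _init_gat_layer(rng, n_features, config.d1, config.heads, s)
    gat2 = _init_gat_layer(rng, config.d1, config.d2, config.heads, s)
    gat3 = _init_gat_layer(rng, config.d2, config.d3, config.heads, s)
    dd1, dd2 = config.dense_dims
    dense = [
        DenseBlockParams(_glorot(rng, config.d3, dd1), np.zeros(dd1),
                         BatchNormParams.create(dd1), config.dropout),
        DenseBlockParams(_glorot(rng, dd1, dd2), np.zeros(dd2),
                         BatchNormParams.create(dd2), config.dropout),
        DenseBlockParams(_glorot(rng, dd2, 1), np.zeros(1), None,
                         0.0, is_final=True),
    ]
    proj = None
    if config.residual_projection and config.d1 != config.d2:
        proj = _glorot(rng, config.d1, config.d2)
    return MSLGATParams(gat1, gat2, gat3,
                        BatchNormParams.create(config.d1),
                        BatchNormParams.create(config.d2),
                        BatchNormParams.create(config.d3),
                        dense, proj, config)


# ---------------------------------------------------------------------------
# spec-level building blocks (numpy in / numpy out)
# ---------------------------------------------------------------------------


def attention_coefficients(h: np.ndarray, head: HeadParams,
                           neighbors_of_i: np.ndarray, i: int) -> np.ndarray:
    """Attention row alpha_ij of node ``i`` over its neighborhood.

    e_ij = LeakyReLU(a^T [W h_i || W h_j]); alpha is the softmax of e over
    the neighborhood, so it sums to 1.
    """
    neighbors_of_i = np.asarray(neighbors_of_i, dtype=int)
    if neighbors_of_i.size == 0:
        raise ValueError("node has an empty neighborhood; add self-loops "
                         "(adjacency(..., self_loops=True)) before attention")
    h = np.atleast_2d(np.asarray(h, dtype=float))
    wh = h @ np.atleast_2d(head.W)
    e = wh[i] @ head.a_self + wh[neighbors_of_i] @ head.a_neigh
    e = np.where(e >= 0, e, head.slope * e)
    e -= e.max()
    expe = np.exp(e)
    return expe / expe.sum()


def aggregate_neighborhood(alpha: np.ndarray, head: HeadParams, h: np.ndarray,
                           neighbors_of_i: np.ndarray, activation=None) -> np.ndarray:
    """sigma(sum_j alpha_ij W h_j) for one node (identity activation default)."""
    alpha = np.asarray(alpha, dtype=float)
    if not np.isclose(alpha.sum(), 1.0):
        raise ValueError("attention row must be normalized")
    h = np.atleast_2d(np.asarray(h, dtype=float))
    wh = h[np.asarray(neighbors_of_i, dtype=int)] @ np.atleast_2d(head.W)
    out = alpha @ wh
    return out if activation is None else activation(out)


def weighted_multihead(head_outputs, head_weights) -> np.ndarray:
    """Learnable weighted average of the K head outputs (component-wise).

    ``head_weights`` must be a simplex: nonnegative, summing to 1.
    """
    outputs = [np.asarray(o, dtype=float) for o in head_outputs]
    w = np.asarray(head_weights, dtype=float)
    if len(outputs) != w.size:
        raise ValueError(f"{len(outputs)} head outputs but {w.size} weights")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-3:
        # the loose sum tolerance admits hand-rounded simplex weights
        raise ValueError("head weights must be nonnegative and sum to 1")
    shapes = {o.shape for o in outputs}
    if len(shapes) != 1:
        raise ValueError(f"head outputs have mismatched shapes: {shapes}")
    return np.tensordot(w, np.stack(outputs), axes=1)


# ---------------------------------------------------------------------------
# autodiff forward pass
# ---------------------------------------------------------------------------


def _edge_index(a: sparse.spmatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed (src, dst) arrays from a symmetric adjacency matrix."""
    coo = sparse.coo_matrix(a)
    return coo.col.astype(int), coo.row.astype(int)  # messages flow src -> dst


def _gat_layer_t(h: Tensor, src: np.ndarray, dst: np.ndarray, n: int,
                 layer_t: dict, slope: float, activation) -> Tensor:
    """Edge-list (sparse) evaluation of one GAT layer on autodiff tensors."""
    head_outs = []
    for ht in layer_t["heads"]:
        wh = h @ ht["W"]  # (N, d)
        e_self = ad.sum_(ad.mul(ad.gather(wh, dst), ht["a_self"]), axis=1)
        e_neigh = ad.sum_(ad.mul(ad.gather(wh, src), ht["a_neigh"]), axis=1)
        # a^T [Wh_i || Wh_j] with i = dst (the updated node), j = src
        e = ad.leaky_relu(ad.add(e_self, e_neigh), slope)
        alpha = ad.segment_softmax(e, dst, n)
        msgs = ad.mul(ad.gather(wh, src), alpha_col(alpha))
        out = ad.segment_sum(msgs, dst, n)
        head_outs.append(out if activation is None else activation(out))
    w = ad.softmax(layer_t["head_logits"], axis=0)
    combined = None
    for k, out in enumerate(head_outs):
        term = ad.mul(out, ad.gather(w, np.array([k])))
        combined = term if combined is None else ad.add(combined, term)
    return combined


def alpha_col(alpha: Tensor) -> Tensor:
    """Reshape a per-edge scalar to a column for broadcasting over features."""
    return ad._make(alpha.value[:, None], (alpha,), (lambda g: g[:, 0],))


_ACTIVATIONS = {
    None: None,
    "leaky_relu": lambda t: ad.leaky_relu(t, 0.01),
    "sigmoid": ad.sigmoid,
}


def gat_layer_forward(h_in: np.ndarray, a: sparse.spmatrix | np.ndarray,
                      layer: GATLayerParams, activation: str | None = None) -> np.ndarray:
    """One GAT layer on plain arrays: K heads (attention + aggregation, with
    per-head activation sigma) combined by the learnable weighted average.

    ``activation`` is the per-head sigma: None (identity), "leaky_relu" or
    "sigmoid".
    """
    h_in = np.atleast_2d(np.asarray(h_in, dtype=float))
    n = h_in.shape[0]
    if layer.heads[0].W.shape[0] != h_in.shape[1]:
        raise ValueError(
            f"input has {h_in.shape[1]} features but head projections expect "
            f"{layer.heads[0].W.shape[0]}")
    src, dst = _edge_index(a)
    layer_t = _layer_tensors(layer, requires_grad=False)
    out = _gat_layer_t(Tensor(h_in), src, dst, n, layer_t,
                       layer.heads[0].slope, _ACTIVATIONS[activation])
    return out.value


def _layer_tensors(layer: GATLayerParams, requires_grad: bool) -> dict:
    return {
        "heads": [{
            "W": Tensor(h.W, requires_grad=requires_grad),
            "a_self": Tensor(h.a_self, requires_grad=requires_grad),
            "a_neigh": Tensor(h.a_neigh, requires_grad=requires_grad),
        } for h in layer.heads],
        "head_logits": Tensor(layer.head_logits, requires_grad=requires_grad),
    }


def _bn_t(x: Tensor, bn: BatchNormParams, gamma: Tensor, beta: Tensor,
          mode: str, update_running: bool) -> Tensor:
    if mode == "train":
        mu = ad.mean_(x, axis=0, keepdims=True)
        var = ad.mean_(ad.power(ad.sub(x, mu), 2.0), axis=0, keepdims=True)
        if update_running:
            m = bn.momentum
            bn.running_mean = (1 - m) * bn.running_mean + m * mu.value.ravel()
            n = x.shape[0]
            unbiased = var.value.ravel() * (n / max(n - 1, 1))
            bn.running_var = (1 - m) * bn.running_var + m * unbiased
            bn.fitted = True
        xhat = ad.div(ad.sub(x, mu), ad.sqrt(ad.add(var, Tensor(bn.eps))))
    else:
        if not bn.fitted:
            raise RuntimeError("batch-norm running statistics are unfitted; "
                               "run training (or a train-mode pass) first")
        xhat = ad.div(ad.sub(x, Tensor(bn.running_mean)),
                      Tensor(np.sqrt(bn.running_var + bn.eps)))
    return ad.add(ad.mul(xhat, gamma), beta)


def dense_block_forward(x: np.ndarray, block: DenseBlockParams, mode: str = "eval",
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """One dense classification block on plain arrays.

    Non-final: linear -> LeakyReLU -> BN -> dropout.  Final: linear ->
    sigmoid, emitting the probability directly (BN/dropout would destroy
    the probability scale, so the final block skips them).
    """
    t = _dense_block_t(Tensor(np.atleast_2d(x)), block,
                       _dense_tensors(block, False), mode,
                       rng if mode == "train" else None, update_running=False)
    return t.value


def _dense_tensors(block: DenseBlockParams, requires_grad: bool) -> dict:
    d = {"W": Tensor(block.W, requires_grad=requires_grad),
         "b": Tensor(block.b, requires_grad=requires_grad)}
    if block.bn is not None:
        d["gamma"] = Tensor(block.bn.gamma, requires_grad=requires_grad)
        d["beta"] = Tensor(block.bn.beta, requires_grad=requires_grad)
    return d


def _dense_block_t(x: Tensor, block: DenseBlockParams, bt: dict, mode: str,
                   rng, update_running: bool, slope: float = 0.01,
                   return_logits: bool = False) -> Tensor:
    z = ad.add(x @ bt["W"], bt["b"])
    if block.is_final:
        return z if return_logits else ad.sigmoid(z)
    h = ad.leaky_relu(z, slope)
    h = _bn_t(h, block.bn, bt["gamma"], bt["beta"], mode, update_running)
    return ad.dropout(h, block.dropout, rng if mode == "train" else None)


def _forward_t(x_t: Tensor, src, dst, n: int, params: MSLGATParams, tensors: dict,
               mode: str, rng, update_running: bool) -> tuple[Tensor, dict]:
    cfg = params.config
    slope = cfg.leaky_slope
    drop = cfg.dropout if mode == "train" else 0.0

    g1 = _gat_layer_t(x_t, src, dst, n, tensors["gat1"], slope, None)
    h1 = _bn_t(ad.leaky_relu(g1, slope), params.bn1,
               tensors["bn1_gamma"], tensors["bn1_beta"], mode, update_running)
    total_h1 = ad.dropout(h1, drop, rng)

    g2 = _gat_layer_t(total_h1, src, dst, n, tensors["gat2"], slope, None)
    total_h2 = ad.leaky_relu(g2, slope)

    res_in = total_h1
    if params.residual_proj is not None:
        res_in = total_h1 @ tensors["residual_proj"]
    h_residual = ad.add(res_in, total_h2)
    h_final = ad.dropout(
        _bn_t(h_residual, params.bn_res, tensors["bnres_gamma"],
              tensors["bnres_beta"], mode, update_running), drop, rng)

    g3 = _gat_layer_t(h_final, src, dst, n, tensors["gat3"], slope, None)
    total_h3 = ad.dropout(
        _bn_t(ad.leaky_relu(g3, slope), params.bn3, tensors["bn3_gamma"],
              tensors["bn3_beta"], mode, update_running), drop, rng)

    h = total_h3
    dense_acts = []
    for bi, block in enumerate(params.dense):
        h = _dense_block_t(h, block, tensors[f"dense{bi}"], mode, rng,
                           update_running, slope, return_logits=block.is_final)
        dense_acts.append(h)
    logits = h  # (N, 1)
    trace = {
        "total_h1": total_h1, "total_h2": total_h2, "h_residual": h_residual,
        "h_final": h_final, "total_h3": total_h3, "dense": dense_acts,
    }
    return logits, trace


def _all_tensors(params: MSLGATParams, requires_grad: bool) -> dict:
    t = {
        "gat1": _layer_tensors(params.gat1, requires_grad),
        "gat2": _layer_tensors(params.gat2, requires_grad),
        "gat3": _layer_tensors(params.gat3, requires_grad),
        "bn1_gamma": Tensor(params.bn1.gamma, requires_grad),
        "bn1_beta": Tensor(params.bn1.beta, requires_grad),
        "bnres_gamma": Tensor(params.bn_res.gamma, requires_grad),
        "bnres_beta": Tensor(params.bn_res.beta, requires_grad),
        "bn3_gamma": Tensor(params.bn3.gamma, requires_grad),
        "bn3_beta": Tensor(params.bn3.beta, requires_grad),
    }
    for bi, block in enumerate(params.dense):
        t[f"dense{bi}"] = _dense_tensors(block, requires_grad)
    if params.residual_proj is not None:
        t["residual_proj"] = Tensor(params.residual_proj, requires_grad)
    return t


def _flat_tensor_items(tensors: dict, prefix: str = "") -> list[tuple[str, Tensor]]:
    items: list[tuple[str, Tensor]] = []
    for key, val in tensors.items():
        name = f"{prefix}{key}"
        if isinstance(val, Tensor):
            items.append((name, val))
        elif isinstance(val, dict):
            items.extend(_flat_tensor_items(val, f"{name}."))
        elif isinstance(val, list):
            for i, sub in enumerate(val):
                items.extend(_flat_tensor_items(sub, f"{name}.{i}."))
    return items


def forward_pass(X: np.ndarray, a: sparse.spmatrix | np.ndarray,
                 params: MSLGATParams, mode: str = "eval",
                 seed: int | None = None) -> tuple[np.ndarray, ForwardTrace]:
    """Full forward pass on plain arrays, returning per-node probabilities
    and the trace of intermediate activations.

    In eval mode dropout is the identity and BN uses running statistics
    (raising if they were never fitted); repeated eval calls are
    deterministic.  ``seed`` drives the train-mode dropout masks.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != a.shape[0]:
        raise ValueError("X row count does not match adjacency size")
    src, dst = _edge_index(a)
    rng = np.random.default_rng(seed) if mode == "train" else None
    tensors = _all_tensors(params, requires_grad=False)
    logits, trace = _forward_t(Tensor(X), src, dst, X.shape[0], params, tensors,
                               mode, rng, update_running=(mode == "train"))
    probs = 0.5 * (1.0 + np.tanh(0.5 * logits.value.ravel()))
    ft = ForwardTrace(
        total_h1=trace["total_h1"].value, total_h2=trace["total_h2"].value,
        h_residual=trace["h_residual"].value, h_final=trace["h_final"].value,
        total_h3=trace["total_h3"].value,
        dense_activations=[t.value for t in trace["dense"]],
        probabilities=probs,
    )
    return probs, ft


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    """Adaptive-moment gradient descent over a flat dict of arrays."""

    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for name, g in grads.items():
            if g is None:
                continue
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            arrays[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def compute_loss_and_grads(params: MSLGATParams, X: np.ndarray,
                           a, mask: np.ndarray, labels: np.ndarray,
                           mode: str = "train", rng=None,
                           update_running: bool = True):
    """One differentiated pass: BCE over the masked nodes plus gradients
    for every trainable array (flat name -> grad)."""
    src, dst = _edge_index(a)
    tensors = _all_tensors(params, requires_grad=True)
    logits, _ = _forward_t(Tensor(np.atleast_2d(X)), src, dst, X.shape[0],
                           params, tensors, mode, rng, update_running)
    idx = np.flatnonzero(mask)
    masked = ad.gather(logits, idx)
    loss = ad.bce_with_logits(masked, labels[idx].reshape(-1, 1))
    loss.backward()
    flat = dict(_flat_tensor_items(tensors))
    grads = {name: t.grad for name, t in flat.items()}
    return float(loss.value), grads, flat


def _param_arrays(params: MSLGATParams) -> dict[str, np.ndarray]:
    """Flat name -> live array view of every trainable parameter."""
    out: dict[str, np.ndarray] = {}
    for lname, layer in (("gat1", params.gat1), ("gat2", params.gat2),
                         ("gat3", params.gat3)):
        for k, h in enumerate(layer.heads):
            out[f"{lname}.heads.{k}.W"] = h.W
            out[f"{lname}.heads.{k}.a_self"] = h.a_self
            out[f"{lname}.heads.{k}.a_neigh"] = h.a_neigh
        out[f"{lname}.head_logits"] = layer.head_logits
    for bname, bn in (("bn1", params.bn1), ("bnres", params.bn_res),
                      ("bn3", params.bn3)):
        out[f"{bname}_gamma"] = bn.gamma
        out[f"{bname}_beta"] = bn.beta
    for bi, block in enumerate(params.dense):
        out[f"dense{bi}.W"] = block.W
        out[f"dense{bi}.b"] = block.b
        if block.bn is not None:
            out[f"dense{bi}.gamma"] = block.bn.gamma
            out[f"dense{bi}.beta"] = block.bn.beta
    if params.residual_proj is not None:
        out["residual_proj"] = params.residual_proj
    return out


def train_model(graph: PatientGraph, config: ModelConfig | None = None,
                log=None) -> tuple[MSLGATParams, TrainReport]:
    """Full-batch training of the network on the graph's train mask.

    Per epoch: one Adam step on train-mask BCE (train mode, seeded dropout),
    then an eval-mode pass recording validation loss/accuracy.  The
    parameters of the best validation-loss epoch are returned.
    """
    config = config or ModelConfig()
    y_train = graph.labels[graph.train_mask]
    if y_train.size == 0 or len(np.unique(y_train)) < 2:
        raise ValueError("training mask must contain both classes")
    params = init_params(graph.n_features, config)
    a = adjacency(graph.n_nodes, graph.edges, self_loops=True)
    optimizer = _Adam(config.learning_rate)
    arrays = _param_arrays(params)
    master_rng = np.random.default_rng(config.seed)
    report = TrainReport([], [], [], best_epoch=-1, seed=config.seed)
    best_val = np.inf
    best_params = copy.deepcopy(params)
    y = graph.labels.astype(float)
    for epoch in range(config.epochs):
        rng = np.random.default_rng(master_rng.integers(2 ** 31))
        loss, grads, _ = compute_loss_and_grads(
            params, graph.X, a, graph.train_mask, y, "train", rng)
        optimizer.step(arrays, grads)
        report.train_loss.append(loss)
        probs, _ = forward_pass(graph.X, a, params, mode="eval")
        vmask = graph.val_mask if graph.val_mask.any() else graph.train_mask
        pv = np.clip(probs[vmask], 1e-12, 1 - 1e-12)
        yv = y[vmask]
        val_loss = float(-(yv * np.log(pv) + (1 - yv) * np.log(1 - pv)).mean())
        val_acc = float(((probs[vmask] >= 0.5).astype(int) == yv).mean())
        report.val_loss.append(val_loss)
        report.val_accuracy.append(val_acc)
        if val_loss < best_val:
            best_val = val_loss
            report.best_epoch = epoch
            best_params = copy.deepcopy(params)
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} "
                f"train_loss={loss:.4f} val_loss={val_loss:.4f} val_acc={val_acc:.4f}")
    return (best_params if config.epochs > 0 else params), report


def predict_scores(params: MSLGATParams, graph: PatientGraph) -> pd.DataFrame:
    """Per-gene driver probabilities and the 0.5-threshold labels
    (probability exactly 0.5 classifies positive)."""
    if graph.n_features != params.gat1.heads[0].W.shape[0]:
        raise ValueError(
            f"graph has {graph.n_features} features but the model expects "
            f"{params.gat1.heads[0].W.shape[0]}")
    a = adjacency(graph.n_nodes, graph.edges, self_loops=True)
    probs, _ = forward_pass(graph.X, a, params, mode="eval")
    return pd.DataFrame({
        "gene": graph.nodes,
        "probability": probs,
        "label": (probs >= 0.5).astype(int),
    })


# ---------------------------------------------------------------------------
# checkpointing: plain-text arrays + a JSON manifest
# ---------------------------------------------------------------------------


def save_checkpoint(params: MSLGATParams, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = dict(_param_arrays(params))
    for bname, bn in (("bn1", params.bn1), ("bnres", params.bn_res),
                      ("bn3", params.bn3)):
        arrays[f"{bname}_running_mean"] = bn.running_mean
        arrays[f"{bname}_running_var"] = bn.running_var
    for bi, block in enumerate(params.dense):
        if block.bn is not None:
            arrays[f"dense{bi}.running_mean"] = block.bn.running_mean
            arrays[f"dense{bi}.running_var"] = block.bn.running_var
    manifest = {
        "config": asdict(params.config),
        "fitted": params.bn1.fitted,
        "arrays": {},
    }
    for name, arr in arrays.items():
        fname = name.replace(".", "_") + ".txt"
        np.savetxt(out / fname, np.atleast_1d(arr).reshape(arr.shape[0], -1)
                   if arr.ndim > 0 else arr, fmt="%.17g")
        manifest["arrays"][name] = {"file": fname, "shape": list(arr.shape)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_checkpoint(in_dir: str | Path) -> MSLGATParams:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg_d = manifest["config"]
    cfg_d["dense_dims"] = tuple(cfg_d["dense_dims"])
    cfg_d["split"] = tuple(cfg_d["split"])
    config = ModelConfig(**cfg_d)
    arrays = {}
    for name, meta in manifest["arrays"].items():
        arr = np.loadtxt(src / meta["file"], ndmin=2)
        arrays[name] = arr.reshape(meta["shape"])
    f_in = arrays["gat1.heads.0.W"].shape[0]
    params = init_params(f_in, config)
    live = _param_arrays(params)
    for name, arr in arrays.items():
        if name in live:
            live[name][...] = arr
    for bname, bn in (("bn1", params.bn1), ("bnres", params.bn_res),
                      ("bn3", params.bn3)):
        bn.running_mean[...] = arrays[f"{bname}_running_mean"]
        bn.running_var[...] = arrays[f"{bname}_running_var"]
        bn.fitted = manifest["fitted"]
    for bi, block in enumerate(params.dense):
        if block.bn is not None:
            block.bn.running_mean[...] = arrays[f"dense{bi}.running_mean"]
            block.bn.running_var[...] = arrays[f"dense{bi}.running_var"]
            block.bn.fitted = manifest["fitted"]
    return params
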