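"""Gene interaction graph construction: PPI-restricted edges, node feature
assembly and the adjacency matrix consumed by the attention network.

Nodes are the selected genomic elements; edges are protein-protein
interaction (PPI) edges restricted to pairs whose endpoints are both
selected.  The node feature matrix X concatenates molecular features
(mutation frequency, expression, methylation, CNV summaries), optional
system-level features, structural embeddings of the graph topology, and the
dual-evidence priority weight — every column min-max scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import sparse

from .preprocess import ElementSet

UNKNOWN_LABEL = -1


@dataclass
class PPINetwork:
    """Undirected PPI edge list; (a, b) and (b, a) are the same edge."""

    edges: list[tuple[str, str]]
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PPINetwork":
        edges, conf = [], {}
        for a, b, c in df[["gene_a", "gene_b", "confidence"]].itertuples(index=False):
            if a == b:
                raise ValueError(f"self-edge {a!r}-{b!r} in PPI input")
            key = (a, b) if a <= b else (b, a)
            if key not in conf:
                edges.append(key)
            conf[key] = float(c)
        return cls(edges=edges, confidence=conf)


@dataclass
class PatientGraph:
    """A gene graph with features, partial labels and split masks.

    ``labels`` uses -1 for unknown; masks are disjoint boolean vectors over
    nodes and cover only labeled nodes.
    """

    nodes: list[str]
    edges: np.ndarray  # (E, 2) int array of undirected node-index pairs
    X: np.ndarray  # (N, F) in [0, 1]
    labels: np.ndarray  # (N,) int in {0, 1, -1}
    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.nodes)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and self.edges.max() >= n:
            raise ValueError("edge endpoint out of range")
        if self.X.shape[0] != n:
            raise ValueError(f"X has {self.X.shape[0]} rows for {n} nodes")
        masks = self.train_mask.astype(int) + self.val_mask.astype(int) + self.test_mask.astype(int)
        if (masks > 1).any():
            raise ValueError("train/val/test masks must be disjoint")
        if ((masks == 1) & (self.labels == UNKNOWN_LABEL)).any():
            raise ValueError("masks may only cover labeled nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_network(elements: ElementSet, ppi: PPINetwork) -> tuple[list[str], np.ndarray]:
    """Restrict the PPI network to the selected elements.

    Nodes are the element gene ids (element order preserved); edges are the
    PPI edges with both endpoints selected, deduplicated and
    orientation-collapsed.  Elements without PPI coverage become isolated
    nodes.
    """
    nodes = elements.gene_ids
    index = {g: i for i, g in enumerate(nodes)}
    pairs = set()
    for a, b in ppi.edges:
        if a in index and b in index:
            i, j = index[a], index[b]
            pairs.add((min(i, j), max(i, j)))
    edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    return nodes, edges


def adjacency(n_nodes: int, edges: np.ndarray, self_loops: bool = True) -> sparse.csr_matrix:
    """Symmetric binary adjacency matrix (CSR), self-loops on by default.

    Self-loops keep every node's attention neighborhood non-empty.
    Duplicate edges collapse to a single 1 (idempotent).
    """
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    if self_loops:
        diag = np.arange(n_nodes)
        rows = np.concatenate([rows, diag])
        cols = np.concatenate([cols, diag])
    data = np.ones_like(rows, dtype=np.float64)
    a = sparse.csr_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))
    a.data[:] = 1.0  # collapse duplicates to binary
    return a


def minmax_scale_columns(matrix: np.ndarray) -> np.ndarray:
    """Min-max scale each column to [0, 1]; constant columns map to 0."""
    m = np.asarray(matrix, dtype=float)
    lo = m.min(axis=0, keepdims=True)
    hi = m.max(axis=0, keepdims=True)
    span = hi - lo
    return np.where(span > 0, (m - lo) / np.where(span > 0, span, 1.0), 0.0)


def assemble_features(
    molecular: np.ndarray,
    structural: np.ndarray | None = None,
    system_level: np.ndarray | None = None,
    priority_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate [molecular | system_level | structural | priority_weight]
    and min-max scale every column to [0, 1]."""
    blocks = [np.atleast_2d(np.asarray(molecular, dtype=float))]
    n = blocks[0].shape[0]
    for block in (system_level, structural):
        if block is not None:
            arr = np.asarray(block, dtype=float)
            if arr.shape[0] != n:
                raise ValueError(
                    f"feature block row count {arr.shape[0]} != node count {n}")
            blocks.append(arr)
    if priority_weight is not None:
        w = np.asarray(priority_weight, dtype=float).reshape(-1, 1)
        if w.shape[0] != n:
            raise ValueError(f"priority weight length {w.shape[0]} != node count {n}")
        blocks.append(w)
    return minmax_scale_columns(np.concatenate(blocks, axis=1))


def stratified_split_masks(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, seeded train/val/test masks over the labeled nodes.

    Unknown labels (-1) are left out of every mask.  Within each class the
    (shuffled) nodes are cut at the cumulative fractions, so class balance
    is preserved across splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    labels = np.asarray(labels)
    n = labels.size
    train = np.zeros(n, dtype=bool)
    val = np.zeros(n, dtype=bool)
    test = np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_cls = idx.size
        n_train = int(round(fractions[0] * n_cls))
        n_val = int(round(fractions[1] * n_cls))
        train[idx[:n_train]] = True
        val[idx[n_train:n_train + n_val]] = True
        test[idx[n_train + n_val:]] = True
    return train, val, test


def export_graph(graph: PatientGraph, out_dir: str | Path) -> None:
    """Write X (dense TSV), the edge index (TSV) and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(graph.X, index=graph.nodes).to_csv(
        out / "X.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(graph.edges, columns=["source", "target"]).to_csv(
        out / "edges.tsv", sep="\t", index=False)
    sidecar = {
        "nodes": graph.nodes,
        "labels": graph.labels.tolist(),
        "train_mask": graph.train_mask.astype(int).tolist(),
        "val_mask": graph.val_mask.astype(int).tolist(),
        "test_mask": graph.test_mask.astype(int).tolist(),
        "metadata": graph.metadata,
    }
    (out / "graph.json").write_text(json.dumps(sidecar))


def load_graph(in_dir: str | Path) -> PatientGraph:
    """Inverse of :func:`export_graph`."""
    src = Path(in_dir)
    x_df = pd.read_csv(src / "X.tsv", sep="\t", index_col="gene_id")
    edges = pd.read_csv(src / "edges.tsv", sep="\t").to_numpy(dtype=int)
    sidecar = json.loads((src / "graph.json").read_text())
    return PatientGraph(
        nodes=sidecar["nodes"],
        edges=edges,
        X=x_df.to_numpy(dtype=float),
        labels=np.asarray(sidecar["labels"], dtype=int),
        train_mask=np.asarray(sidecar["train_mask"], dtype=bool),
        val_mask=np.asarray(sidecar["val_mask"], dtype=bool),
        test_mask=np.asarray(sidecar["test_mask"], dtype=bool),
        metadata=sidecar.get("metadata", {}),
    )
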