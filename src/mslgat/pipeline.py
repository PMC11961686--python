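"""End-to-end orchestration: omics tables on disk -> element set ->
patient graph ready for training.

The cohort-mode pipeline (the tested default) builds one graph over all
selected elements; per-patient mode filters that graph down to the
elements carrying evidence (mutation or differential expression) in a
single patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .embeddings import WalkParams, structural_embeddings
from .graph import (PatientGraph, PPINetwork, assemble_features, build_network,
                    stratified_split_masks)
from .preprocess import (ElementSet, binarize_mutations, integrate_elements,
                         normalize_expression, select_differential,
                         welch_differential)


@dataclass
class PipelineConfig:
    """Preprocessing and graph-construction settings."""

    min_mutation_freq: float = 0.05
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    use_structural: bool = True
    walk_params: WalkParams | None = None
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0


def load_tables(data_dir: str | Path) -> dict:
    """Read the cohort TSVs written by the simulator (or any conforming set)."""
    d = Path(data_dir)
    tables = {
        "mutations": io.read_mutations(d / "mutations.tsv"),
        "expression": io.read_matrix(d / "expression.tsv"),
        "methylation": io.read_matrix(d / "methylation.tsv"),
        "cnv": io.read_matrix(d / "cnv.tsv"),
        "ppi": io.read_ppi(d / "ppi.tsv"),
        "labels": io.read_labels(d / "labels.tsv"),
    }
    classes = pd.read_csv(d / "gene_classes.tsv", sep="\t")
    tables["class_map"] = dict(zip(classes["gene"], classes["class"]))
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    tables["tumor"] = samples.loc[samples["group"] == "tumor", "sample_id"].tolist()
    tables["normal"] = samples.loc[samples["group"] == "normal", "sample_id"].tolist()
    de_path = d / "differential.tsv"
    tables["differential"] = io.read_differential(de_path) if de_path.exists() else None
    return tables


def select_elements(tables: dict, config: PipelineConfig) -> tuple[ElementSet, pd.DataFrame]:
    """Run the preprocessing filters and return the element set plus the
    binary mutation matrix of retained genes."""
    mut_matrix, mutated_genes = binarize_mutations(
        tables["mutations"], tables["tumor"], config.min_mutation_freq)
    differential = tables["differential"]
    if differential is None:
        # two-group Welch stand-in on the simulated tumor/normal design
        differential = welch_differential(
            tables["expression"], tables["tumor"], tables["normal"])
    selected = select_differential(differential, config.lfc_min, config.fdr_max)
    class_map = tables["class_map"]
    degs = {g for g in selected if class_map.get(g) == "coding"}
    dens = {g for g in selected if class_map.get(g) == "noncoding"}
    elements = integrate_elements(set(mutated_genes), degs, dens, class_map)
    return elements, mut_matrix


def molecular_features(elements: ElementSet, tables: dict,
                       mut_matrix: pd.DataFrame) -> np.ndarray:
    """Per-element molecular summaries: mutation frequency, mean normalized
    tumor expression, mean methylation beta, mean absolute CNV call."""
    genes = elements.gene_ids
    n_tumor = len(tables["tumor"])
    mut_freq = np.array([
        mut_matrix.loc[g].sum() / n_tumor if g in mut_matrix.index else 0.0
        for g in genes])
    expr_norm = normalize_expression(tables["expression"])
    expr_mean = np.array([
        expr_norm.loc[g, tables["tumor"]].mean() if g in expr_norm.index else 0.0
        for g in genes])
    meth = tables["methylation"]
    meth_mean = np.array([
        meth.loc[g].mean() if g in meth.index else 0.0 for g in genes])
    cnv = tables["cnv"]
    cnv_mean = np.array([
        np.abs(cnv.loc[g].to_numpy()).mean() if g in cnv.index else 0.0
        for g in genes])
    return np.stack([mut_freq, expr_mean, meth_mean, cnv_mean], axis=1)


def build_graph(data_dir: str | Path, config: PipelineConfig | None = None) -> PatientGraph:
    """Omics tables -> PatientGraph with features, labels and split masks."""
    config = config or PipelineConfig()
    tables = load_tables(data_dir)
    elements, mut_matrix = select_elements(tables, config)
    if len(elements) == 0:
        raise ValueError("no genomic elements survive the preprocessing filters")
    nodes, edges = build_network(elements, PPINetwork.from_frame(tables["ppi"]))
    molecular = molecular_features(elements, tables, mut_matrix)
    structural = None
    if config.use_structural:
        wp = config.walk_params or WalkParams(seed=config.seed)
        structural = structural_embeddings(len(nodes), edges, wp).vectors
    X = assemble_features(molecular, structural=structural,
                          priority_weight=elements.weights())
    label_series = tables["labels"]
    labels = np.array([label_series.get(g, -1) for g in nodes], dtype=int)
    train, val, test = stratified_split_masks(labels, config.split, config.seed)
    return PatientGraph(
        nodes=nodes, edges=edges, X=X, labels=labels,
        train_mask=train, val_mask=val, test_mask=test,
        metadata={"n_elements": len(elements),
                  "dual_evidence": int((elements.weights() > 1).sum())},
    )


def patient_subgraph(graph: PatientGraph, patient_genes: set[str]) -> PatientGraph:
    """Per-patient mode: restrict the cohort graph to the elements carrying
    evidence in one patient (plus their induced edges)."""
    keep = np.array([g in patient_genes for g in graph.nodes])
    if not keep.any():
        raise ValueError("patient has no selected elements in the cohort graph")
    new_index = -np.ones(graph.n_nodes, dtype=int)
    new_index[keep] = np.arange(keep.sum())
    kept_edges = graph.edges[keep[graph.edges[:, 0]] & keep[graph.edges[:, 1]]]
    return PatientGraph(
        nodes=[g for g, k in zip(graph.nodes, keep) if k],
        edges=new_index[kept_edges],
        X=graph.X[keep],
        labels=graph.labels[keep],
        train_mask=graph.train_mask[keep],
        val_mask=graph.val_mask[keep],
        test_mask=graph.test_mask[keep],
        metadata=dict(graph.metadata, patient_filtered=True),
    )
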