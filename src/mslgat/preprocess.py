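"""Gene-level omics preprocessing: mutation binarization, expression
normalization, differential selection and element integration.

The pipeline turns raw per-gene omics tables into the selected set of
genomic elements (coding genes and non-coding RNAs) that seed graph
construction:

1. somatic mutations are collapsed to a binary gene × sample matrix,
   keeping non-synonymous consequence classes only and genes mutated in at
   least 5% of the cohort;
2. expression is log2(x+1)-transformed and min-max scaled per gene;
3. differentially expressed genes/non-coding RNAs are selected by an
   absolute log2 fold-change threshold combined with Benjamini-Hochberg
   FDR control;
4. the union of mutated and differential elements forms the element set,
   with elements supported by both evidence types prioritized by a larger
   weight (dual-evidence elements are the most likely driver events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_NONSYNONYMOUS = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
})
DUAL_EVIDENCE_WEIGHT = 2.0
SINGLE_EVIDENCE_WEIGHT = 1.0


@dataclass(frozen=True)
class Element:
    """A selected genomic element with its evidence flags."""

    gene_id: str
    element_class: str  # "coding" | "noncoding"
    mutated: bool
    differential: bool
    priority_weight: float


@dataclass
class ElementSet:
    """The integrated coding/non-coding elements feeding graph construction."""

    elements: list[Element] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.elements]

    def weights(self) -> np.ndarray:
        return np.array([e.priority_weight for e in self.elements])


def binarize_mutations(
    mutations: pd.DataFrame,
    cohort: list[str],
    min_freq: float = 0.05,
    allowed_classes: frozenset[str] | set[str] = DEFAULT_NONSYNONYMOUS,
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse mutation records to a binary gene × sample matrix.

    Entry (g, s) is 1 iff sample ``s`` carries at least one record for gene
    ``g`` whose consequence class is in ``allowed_classes``.  Genes are
    retained iff their mutated-sample fraction is >= ``min_freq``
    (inclusive, so 5/100 survives the default 5% filter).

    Returns the binary matrix restricted to retained genes (rows ordered by
    gene id) and the retained gene list.
    """
    if not 0.0 < min_freq < 1.0:
        raise ValueError(f"min_freq must be in (0, 1), got {min_freq}")
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if not allowed_classes:
        raise ValueError("allowed_classes must be non-empty")
    cohort = list(cohort)
    cohort_set = set(cohort)
    unknown = set(mutations["Tumor_Sample_Barcode"]) - cohort_set
    if unknown:
        raise ValueError(f"mutation record references sample {sorted(unknown)[0]!r} "
                         "which is not in the cohort")

    kept = mutations[mutations["Variant_Classification"].isin(allowed_classes)]
    genes = sorted(set(kept["Hugo_Symbol"]))
    matrix = pd.DataFrame(0, index=genes, columns=cohort, dtype=int)
    if len(kept):
        pairs = kept[["Hugo_Symbol", "Tumor_Sample_Barcode"]].drop_duplicates()
        matrix.values[
            matrix.index.get_indexer(pairs["Hugo_Symbol"]),
            matrix.columns.get_indexer(pairs["Tumor_Sample_Barcode"]),
        ] = 1
    freq = matrix.sum(axis=1) / len(cohort)
    retained = [g for g in genes if freq[g] >= min_freq]
    return matrix.loc[retained], retained


def normalize_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) transform followed by per-gene min-max scaling to [0, 1].

    Constant genes (min == max after the transform) map to all zeros.
    """
    values = expression.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be nonnegative")
    logged = np.log2(values + 1.0)
    lo = logged.min(axis=1, keepdims=True)
    hi = logged.max(axis=1, keepdims=True)
    span = hi - lo
    scaled = np.where(span > 0, (logged - lo) / np.where(span > 0, span, 1.0), 0.0)
    return pd.DataFrame(scaled, index=expression.index, columns=expression.columns)


def benjamini_hochberg(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns the monotone q-values and the significance flags: hypothesis i
    is rejected iff its p-value is <= the largest satisfied rank threshold
    ``(k/m) * alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_ranked, 1.0)
    thresholds = np.arange(1, m + 1) * alpha / m
    satisfied = np.nonzero(ranked <= thresholds)[0]
    cutoff = ranked[satisfied[-1]] if satisfied.size else -np.inf
    return q, p <= cutoff


def select_differential(
    differential: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> set[str]:
    """Select genes with |log2FC| >= ``lfc_min`` and FDR q-value < ``fdr_max``.

    If the table has no ``qvalue`` column, q-values are computed from
    ``pvalue`` with :func:`benjamini_hochberg`.
    """
    if "qvalue" in differential.columns:
        q = differential["qvalue"].to_numpy(dtype=float)
    elif "pvalue" in differential.columns:
        q, _ = benjamini_hochberg(differential["pvalue"].to_numpy(dtype=float))
    else:
        raise ValueError("differential table needs a 'pvalue' or 'qvalue' column")
    lfc = differential["log2FC"].to_numpy(dtype=float)
    keep = (np.abs(lfc) >= lfc_min) & (q < fdr_max)
    return set(differential.loc[keep, "gene"])


def welch_differential(
    expression: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Two-group Welch t-test on log2(x+1) expression — a synthetic-data
    stand-in for a dedicated RNA-Seq differential tool, used so the
    end-to-end pipeline runs without external differential tables.

    Returns a differential table (gene, log2FC, pvalue, qvalue) with
    log2FC = mean_a - mean_b on the log2 scale and BH-adjusted q-values.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    logged = np.log2(expression.to_numpy(dtype=float) + 1.0)
    idx_a = expression.columns.get_indexer(group_a)
    idx_b = expression.columns.get_indexer(group_b)
    if (idx_a < 0).any() or (idx_b < 0).any():
        raise ValueError("group sample ids missing from the expression matrix")
    a, b = logged[:, idx_a], logged[:, idx_b]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance genes: uninformative
    q, _ = benjamini_hochberg(pvals)
    return pd.DataFrame({
        "gene": expression.index,
        "log2FC": lfc,
        "pvalue": pvals,
        "qvalue": q,
    })


def integrate_elements(
    mutated: set[str],
    degs: set[str],
    dens: set[str],
    class_map: dict[str, str],
    dual_weight: float = DUAL_EVIDENCE_WEIGHT,
    single_weight: float = SINGLE_EVIDENCE_WEIGHT,
) -> ElementSet:
    """Union of mutated genes, DEGs and DENs with dual-evidence prioritization.

    Elements supported by both mutation and differential evidence receive
    ``dual_weight`` (> ``single_weight``): concordant evidence across omics
    layers is the strongest indicator of a driver event.
    """
    if dual_weight <= single_weight:
        raise ValueError("dual-evidence weight must exceed single-evidence weight")
    differential = degs | dens
    union = sorted(mutated | differential)
    missing = [g for g in union if g not in class_map]
    if missing:
        raise ValueError(f"gene {missing[0]!r} missing from class_map")
    elements = []
    for gene in union:
        is_mut = gene in mutated
        is_diff = gene in differential
        weight = dual_weight if (is_mut and is_diff) else single_weight
        elements.append(Element(gene, class_map[gene], is_mut, is_diff, weight))
    return ElementSet(elements)
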