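"""Confusion-matrix metrics, top-k driver-gene ranking metrics, and the
patient-level decision rule.

Accuracy, precision, recall and F1 follow the standard definitions:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 P R / (P + R)

with the 0/0 cases defined as 0.  The top-k metrics rank genes by predicted
driver probability (ties broken by gene id for reproducibility) and score
the top k against the known driver set.  The patient-level rule summarizes
a patient's per-gene driver probabilities into a single cancer-risk score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "classification_metrics",
    "topk_gene_metrics",
    "patient_level_prediction",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Standard 2×2 confusion counts for binary vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy / precision / recall / F1 from confusion counts (0/0 -> 0)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    p = _safe_div(counts.tp, counts.tp + counts.fp)
    r = _safe_div(counts.tp, counts.tp + counts.fn)
    return MetricsReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=p,
        recall=r,
        f1=_safe_div(2.0 * p * r, p + r),
    )


def topk_gene_metrics(scores: dict[str, float], known_drivers: set[str],
                      k: int = 100) -> MetricsReport:
    """Precision / recall / F1 of the top-k ranked genes against a known
    driver set.

    Genes are ranked by probability descending with stable gene-id
    tie-breaking; ``k`` is capped at the number of scored genes.  Recall is
    relative to the full known-driver set (accuracy is not meaningful for a
    ranking cut, so it is reported as the precision of the cut).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not known_drivers:
        raise ValueError("known driver set is empty")
    if not scores:
        raise ValueError("no gene scores supplied")
    k = min(k, len(scores))
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    top = {gene for gene, _ in ranked[:k]}
    hits = len(top & known_drivers)
    p = hits / k
    r = hits / len(known_drivers)
    return MetricsReport(accuracy=p, precision=p, recall=r,
                         f1=_safe_div(2.0 * p * r, p + r))


def patient_level_prediction(gene_probabilities, m: int = 10,
                             rule: str = "mean_top_m") -> tuple[float, int]:
    """Aggregate one patient's per-gene driver probabilities into a cancer
    risk score and a binary call (score >= 0.5 -> positive).

    Rules: ``mean_top_m`` (mean of the m largest probabilities, m capped at
    the gene count — the default, emphasizing the strongest driver
    evidence), ``max``, or ``mean``.
    """
    probs = np.asarray(list(gene_probabilities), dtype=float)
    if probs.size == 0:
        raise ValueError("patient has no gene probabilities")
    if rule == "mean_top_m":
        if m < 1:
            raise ValueError("m must be >= 1")
        m = min(m, probs.size)
        score = float(np.sort(probs)[::-1][:m].mean())
    elif rule == "max":
        score = float(probs.max())
    elif rule == "mean":
        score = float(probs.mean())
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return score, int(score >= 0.5)
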