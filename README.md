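# mslgat

Personalized cancer driver-gene classification with a **multi stacked-layer
graph attention network** (MSL-GAT) over multi-omics gene interaction
graphs.

Cancer cohorts such as bladder-cancer studies profile patients across
somatic mutations, RNA expression, copy-number calls and DNA methylation.
Only a small subset of the altered genes — the *personalized driver genes*
(PDGs), coding or non-coding — actually drive tumor initiation and
progression. This package implements a graph-learning tool for
prioritizing those genes: selected genomic elements become nodes of a
protein-protein-interaction (PPI) restricted graph, their multi-omics
summaries become node features, and a three-layer graph attention network
classifies each node as driver / non-driver, from which a patient-level
cancer risk score can be derived. It is aimed at computational biologists
who want a transparent, fully seeded reference implementation that runs
end-to-end on synthetic cohorts — no downloads, no GPU.

## The model

For node *i* with feature vector *h<sub>i</sub>*, each attention head with
projection **W** and attention vector **a** scores every neighbor *j*:

```
e_ij = LeakyReLU(aᵀ [W h_i ‖ W h_j])          α_ij = softmax_{j ∈ N(i)} e_ij
h'_i = σ( Σ_{j ∈ N(i)} α_ij W h_j )
```

Each layer runs K = 8 heads in parallel and combines them by a **learnable
weighted average**: per-layer logits are softmaxed into a simplex
(w₁, …, w_K) and the layer output is Σ<sub>k</sub> w<sub>k</sub> ·
h'<sub>i</sub><sup>(k)</sup>, so heads that capture the informative
interactions earn larger weights instead of being concatenated or averaged
uniformly. The full stack is

```
Total_h1   = Dropout(BN(LeakyReLU(GAT1(X, A))))
Total_h2   = LeakyReLU(GAT2(Total_h1, A))
h_residual = Total_h1 + Total_h2                   # residual shortcut
h_final    = Dropout(BN(h_residual))
Total_h3   = Dropout(BN(LeakyReLU(GAT3(h_final, A))))
p          = sigmoid(dense3(dense2(dense1(Total_h3))))
```

with batch normalization over the node dimension, dropout 0.5, LeakyReLU
slope α = 0.01, and three dense blocks (amplify → compress → decide). The
network is trained full-batch with Adam on binary cross-entropy over the
training-mask nodes under a stratified 80/10/10 split, 200 epochs by
default. Performance is reported as accuracy, precision, recall and F1
from the confusion matrix, plus top-k ranking metrics against a known
driver list.

The surrounding pipeline implements the standard multi-omics filters:
binary mutation encoding restricted to non-synonymous classes with a ≥ 5%
cohort-frequency cutoff, log2(x+1) + per-gene min-max expression
normalization, Benjamini–Hochberg FDR control with an |log2FC| ≥ 1
differential threshold, and union-based element integration where genes
supported by both mutation and differential evidence get double priority
weight. Structural node embeddings come from biased second-order random
walks fit with skip-gram negative sampling.

The model and its gradients are implemented on a small reverse-mode
autodiff engine over float64 numpy arrays (`mslgat.autodiff`); analytic
gradients are verified against central finite differences in the test
suite.

## Worked example

Train on a synthetic planted-driver graph (150 genes, 20% drivers whose
features are shifted by two noise standard deviations):

```python
import numpy as np
from sklearn.metrics import roc_auc_score

from mslgat import (SyntheticSpec, generate_planted_graph, ModelConfig,
                    train_model, predict_scores, confusion_counts,
                    classification_metrics, topk_gene_metrics)

graph = generate_planted_graph(SyntheticSpec(n_nodes=150, driver_fraction=0.2,
                                             effect_size=2.0, seed=0))
params, report = train_model(graph, ModelConfig(epochs=80, seed=0))
scores = predict_scores(params, graph)

mask = graph.test_mask
y_true = graph.labels[mask]
y_pred = scores["label"].to_numpy()[mask]
probs = scores["probability"].to_numpy()

print(f"best epoch: {report.best_epoch}")
print(f"test AUROC: {roc_auc_score(y_true, probs[mask]):.4f}")
m = classification_metrics(confusion_counts(y_true, y_pred))
print(f"test accuracy={m.accuracy:.4f} precision={m.precision:.4f} "
      f"recall={m.recall:.4f} f1={m.f1:.4f}")
known = {g for g, y in zip(graph.nodes, graph.labels) if y == 1}
t = topk_gene_metrics(dict(zip(scores["gene"], scores["probability"])), known, k=30)
print(f"top-30 precision={t.precision:.4f} recall={t.recall:.4f} f1={t.f1:.4f}")
```

Output:

```
best epoch: 78
test AUROC: 0.9444
test accuracy=0.7333 precision=0.4286 recall=1.0000 f1=0.6000
top-30 precision=0.6333 recall=0.6333 f1=0.6333
```

The test mask holds 15 genes (3 drivers). The model ranks drivers far
above non-drivers (AUROC 0.94) and recovers all three (recall 1.0); at the
fixed 0.5 threshold it also flags four non-drivers, which caps precision —
the ranking metrics (top-30) are the more informative summary at this
scale. Longer training on larger graphs sharpens both (see the acceptance
suite: 300 genes / 200 epochs reaches AUROC ≈ 0.99).

The same flow is available from the shell:

```bash
mslgat simulate --seed 0 --n-nodes 300 --out data/
mslgat build-graph --data data/ --seed 0 --out graph/
mslgat train --graph graph/ --seed 0 --out model/
mslgat predict --model model/ --graph graph/ --out pred/
mslgat evaluate --predictions pred/predictions.tsv --graph graph/ --out eval/
```

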