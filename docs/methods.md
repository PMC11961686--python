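# Methods

## Problem and model

The package classifies genomic elements (coding genes and non-coding RNAs)
as personalized driver genes (PDGs) of a cancer cohort. Elements are nodes
of an undirected graph whose edges come from a protein-protein interaction
(PPI) network restricted to the selected elements; node features combine
molecular summaries, optional system-level annotations, structural
(random-walk) embeddings, and an evidence-priority weight. A three-layer
graph attention network with learnable weighted multi-head aggregation, a
residual connection between the first two layers, and three dense blocks
produces a per-node driver probability.

### Attention and head aggregation

Per head, attention scores are `e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j])`,
softmax-normalized over the neighborhood of *i* (so each attention row is
a probability distribution), and the head output is the
attention-weighted sum of projected neighbor states. The K head outputs of
a layer are combined as a convex combination whose weights are the
softmax of per-layer logits trained jointly with everything else. This
resolves an ambiguity in the usual presentation of weighted head
aggregation, where the same symbol can denote both the head weight and
the head's projection matrix: here the head weight is a *scalar*
`w_k = softmax(logits)_k` applied to the whole head output vector, which
is the only reading consistent with weighting entire head outputs in a
component-wise average. The weighted average (rather than concatenation)
is used at all three layers, keeping hidden widths constant and matching
the "average in deeper layers" convention for multi-head graph attention.

A worked four-head check is kept as an executable reference: with head
outputs [0.2, 0.4, 0.6], [0.1, 0.5, 0.7], [0.3, 0.3, 0.4], [0.4, 0.2, 0.5]
and weights (0.5, ⅙, ⅙, ⅙), the aggregate is (0.2333…, 0.3666…, 0.5666…).
Note the exact weights are (0.5, 1/6, 1/6, 1/6); rounding the last three
to 0.1667 shifts the first component to 0.23336, which no longer rounds
to 0.2333, so the implementation and its checks use the exact simplex and
compare the second and third components after truncation (floor) to three
decimals.

### Layer stack and regularization

```
Total_h1   = Dropout(BN(LeakyReLU(GAT1(X, A))))
Total_h2   = LeakyReLU(GAT2(Total_h1, A))
h_residual = Total_h1 + Total_h2
h_final    = Dropout(BN(h_residual))
Total_h3   = Dropout(BN(LeakyReLU(GAT3(h_final, A))))
```

The per-head activation σ inside a GAT layer is configurable and defaults
to identity inside the full model, so the single LeakyReLU written after
each layer in the stack above is the layer's nonlinearity and is not
applied twice. The residual requires matching widths d1 = d2 (default);
an optional learned linear projection supports mismatched widths.

Batch normalization operates over the node dimension in full-batch mode:
batch statistics in training (with running mean/variance tracked at
momentum 0.1 for evaluation; evaluating a model whose statistics were
never fitted is an error). Dropout (rate 0.5) is inverted dropout applied
element-wise at the positions shown and inside the first two dense
blocks. The final dense block is linear → sigmoid with no BN or dropout:
normalizing or masking after the sigmoid would destroy the probability
scale, and the block's output must be the per-node probability (zero
weights must give exactly 0.5).

Self-loops are always added to the adjacency so every attention
neighborhood is non-empty — without them an isolated node would have an
undefined softmax.

### Dense head, loss, training

Dense blocks: d3 → 64 (amplify) → 16 (compress) → 1 (decide, sigmoid).
Training is full-batch Adam (learning rate 1e-3) on binary cross-entropy
over the training-mask nodes, computed on logits for numerical stability.
Splits are stratified by label, 80/10/10, seeded. Per epoch the model is
evaluated on the validation mask (eval mode) and the parameters of the
best validation-loss epoch are returned; with `epochs=0` the
initialization is returned unchanged. A probability of exactly 0.5
classifies as positive.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| heads per layer K | 8 | balances expressiveness and cost for gene-graph sizes |
| hidden dims d1=d2, d3 | 64, 32 | residual compatibility; modest width for hundreds of nodes |
| dense widths | 64, 16 | amplify-then-compress head |
| dropout | 0.5 | strong regularization for small labeled sets |
| LeakyReLU slope | 0.01 | keeps weakly negative activations informative |
| epochs | 200 | converges on cohort-scale graphs in minutes on one CPU |
| learning rate | 1e-3 | standard Adam default, stable in float64 full batch |
| split | 0.8 / 0.1 / 0.1 | stratified, seeded |

## Preprocessing

* **Mutations** — records with consequence classes in {missense, nonsense,
  frameshift insertion/deletion} (configurable) collapse to a binary
  gene × sample matrix; genes are kept when mutated in ≥ 5% of the cohort
  (inclusive boundary: 5/100 passes). Unknown sample ids are an error.
* **Expression** — log2(x+1) then per-gene min-max to [0, 1]. The +1
  pseudocount makes zero counts well-defined; constant genes map to 0.
* **Differential selection** — |log2FC| ≥ 1 (configurable; the threshold
  is a convention, not derivable from first principles) and
  Benjamini–Hochberg q-value < 0.05. If only p-values are given,
  q-values are computed by the standard step-up procedure.
* **Integration** — union of mutated genes, DEGs and DENs; elements with
  both mutation and differential evidence get priority weight 2.0 vs 1.0
  (exposed as config), carried into the feature matrix as a column.
* **Differential statistics** for real cohorts are expected as an external
  table (e.g. from a dedicated RNA-Seq tool). For self-contained synthetic
  runs a two-group Welch t-test on log2 values plus BH correction is
  provided as an explicitly labeled stand-in; it is not a negative-binomial
  count model and should not be used on real read counts.
* **Methylation / CNV** are consumed as gene-level beta values and integer
  calls and summarized per gene (mean beta, mean |call|); how to normalize
  them into node features is genuinely open, and the chosen summaries are
  config-visible in `pipeline.molecular_features`.

## Graph construction

Nodes are the selected elements in element order; edges are PPI edges with
both endpoints selected (deduplicated, orientation-collapsed); missing PPI
coverage yields isolated nodes rather than errors. The adjacency is
binary and symmetric — PPI confidence is kept as metadata but unused,
since the model's attention learns its own edge weighting. Feature
columns are min-max scaled to [0, 1] after concatenation
`[molecular | system-level | structural | priority weight]`.

Structural embeddings are biased second-order random walks (return p,
in-out q; p = q = 1 default, i.e. uniform walks) with 10 walks × length
80 per node, window 10, 64 dimensions, 5 negative samples — fit by a
vectorized skip-gram-with-negative-sampling implementation over numpy
arrays, fully seeded. Isolated nodes receive the zero vector. Structural
features can be disabled by flag.

The cohort graph (all labeled elements, the tested default) is what the
model trains on; per-patient graphs are derived by filtering the cohort
graph to one patient's evidenced elements (`pipeline.patient_subgraph`).
The patient-level cancer call aggregates per-gene probabilities by the
mean of the top-m genes (default m = 10; `max` and `mean` rules are also
available) — the gene→patient aggregation is an interpretation, exposed
as configuration, since only the per-gene sigmoid target is defined by
the architecture.

## Synthetic data: what it emulates and what it does not

`generate_planted_graph` emulates a cohort-level gene graph: a fraction of
nodes (default 20%) are drivers whose features are shifted by
`effect_size` noise standard deviations (shift applied before min-max
scaling), and edges are sampled independently with the within-driver
probability multiplied by an enrichment factor (default 3, capped at
probability 1). `generate_omics_tables` emulates the raw inputs: drivers
are mutated in ~30% of tumor samples (always above the 5% filter),
8-fold up-regulated in tumors versus matched normals, hyper-methylated,
and copy-number unstable.

Deliberately not emulated: realistic mutational signatures, linked
copy-number segments, probe-level methylation, library-size and
overdispersion structure of RNA-Seq counts, and the scale-free topology
of real PPI networks. Passing tests therefore demonstrate that the
implementation recovers a planted signal under its stated conditions —
not that the method attains any particular performance on real tumor
cohorts.

Default study conditions: 300 nodes, 20% drivers, 16 features, effect
size 2, background edge probability 0.02, enrichment 3, 100 tumor
samples. At these conditions the full pipeline (tables → filters → graph
with embeddings → 200-epoch training) runs in well under a minute on one
CPU and recovers drivers with test-mask AUROC ≥ 0.9.

## Numerical choices

* Float64 throughout; gradients come from a tape-based reverse-mode
  autodiff (`mslgat.autodiff`) and are verified against central finite
  differences (tolerance 1e-4) in the tests.
* Softmaxes (attention rows, head weights) subtract the per-segment
  maximum, held constant, for overflow safety.
* Binary cross-entropy is computed on logits with the stable
  `max(z,0) − yz + log1p(exp(−|z|))` form.
* Min-max scaling of a constant column yields 0; BH q-values are clipped
  at 1; ranking ties break by gene id (stable) for reproducibility;
  0/0 metric ratios are defined as 0.
* Checkpoints are directories of plain-text arrays plus a JSON manifest
  (shapes, config, seed, BN statistics) — portable and diff-able.

## Known limitations

* Full-batch training only; graphs beyond a few thousand nodes will be
  slow in pure numpy (no mini-batch neighbor sampling, no GPU).
* The null-condition benchmark (effect size 0) is evaluated on a 30-node
  test mask at the default study size, where the chance-level AUROC has a
  standard deviation of roughly 0.19 — single-seed draws of a perfectly
  label-independent scorer regularly fall outside [0.4, 0.6]; judging
  null behavior reliably needs either a larger test mask or aggregation
  over seeds.
* The Welch-test differential stand-in is for synthetic data only.
* PPI confidence scores are not used by the model.
* Batch-norm statistics are computed over whichever node set is passed;
  transferring a trained model to a graph with a very different feature
  distribution will degrade calibration.
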