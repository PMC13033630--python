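# csgnn

Essential-protein prediction from temporal gene expression with a
correlation-guided subgraph graph neural network.

## The problem

Essential proteins are those whose loss is lethal or severely impairs
growth; finding them computationally from protein–protein interaction (PPI)
networks and expression data is a long-standing task in systems biology.
Static network centrality ignores that interactions are condition-dependent:
proteins acting together show *temporally coherent* expression. This package
implements a pipeline that builds its own association graph from expression
dynamics and learns node-level essentiality scores on it:

1. **Activity filtering.** Each protein's temporal profile
   `d_i = (x_{i,1}, …, x_{i,M})` is thresholded at a protein-specific
   dynamic cutoff

   `Threshold_i = μ_i + 2σ_i / (1 + Var_i)`

   (population moments of the profile); values below the threshold are set
   to 0, yielding the activity matrix `X′` used as node features.
2. **Correlation-guided graph.** Pairwise Pearson correlation of the
   activity rows, binarized strictly at `τ = 0.6`, gives the adjacency `A`;
   `A²` identifies two-hop reachability. Each node `i` has a first-order
   neighborhood `N1(i)`, a second-order neighborhood `N2(i)` and a union
   context `C(i) = N1 ∪ N2`.
3. **Two layers of order-specific graph attention.** Per structural order
   `m`, scores `e_ij = LeakyReLU(q_mᵀ [W h_i ‖ W h_j])` are softmax-
   normalized over `N_m(i)` and aggregate neighbor projections through a
   ReLU; the two orders are concatenated after each layer.
4. **Interaction-aware readout.** For `j ∈ C(i)` the pair descriptor
   `h_pair(i,j) = [h_i + h_j ‖ h_i ⊙ h_j ‖ h_i ‖ h_j]` (length `8d`) is
   weighted by re-normalized second-layer attention and summed into `h̄_i`,
   which a two-layer perceptron decodes into an essentiality probability;
   `δ = 0.5` thresholds hard labels and nodes are ranked by score.

Training is transductive: AdamW (lr `1e-4`, weight decay `1e-4`),
mini-batches of 64 target nodes with full-graph message passing,
30 epochs, learning rate halved after 3 epochs without validation-AUROC
improvement, checkpoint selected by validation AUROC on a stratified
70/10/20 node split. Evaluation covers AUROC, recall, MCC, F1, PPV and
top-N counts, plus a degree-centrality baseline ranking.

Because real inputs (DIP networks, GEO expression series, curated
essentiality lists) require downloads, the package ships a first-class
synthetic generator that plants periodic co-expression modules with
module-correlated essentiality and an optional planted-partition
interaction graph — every stage is testable offline.

## Worked example

```python
import csgnn

# 600 proteins, 12 planted modules, 24 time points, 40% of modules "core"
data = csgnn.generate_dataset(csgnn.SyntheticConfig(seed=1))

clf = csgnn.CSGNNClassifier(d=32, random_state=1)
clf.fit(data.expression, data.labels)
report = clf.evaluate(data.labels)        # held-out test split metrics
print(f"test AUROC {report.auc:.4f}  F1 {report.f1:.4f}  "
      f"top-100 {report.top_n[100]}")
```

Output:

```
test AUROC 0.8996  F1 0.8000  top-100 83
```

The AUROC is measured on the 20% of nodes whose labels were held out; the
top-100 count says how many of the 100 highest-scored proteins are truly
essential (218 of the 600 nodes are essential in this draw, so a perfect
ranker would reach 100). The module-membership oracle for this draw scores
0.896 — essentiality is random within modules, so module identity is all a
ranker can learn.

The same workflow is available from the shell:

```bash
csgnn run-all --config config.yaml --out results/run1
```

which writes the synthetic dataset (or loads configured TSV inputs), the
checkpoint plus JSON sidecar, a per-epoch training log, ranked
predictions, and metric/top-N tables, together with the resolved
configuration and seed for byte-reproducibility.

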