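# Methods

## Problem and model

`scgraphmap` transfers cell-type labels from an annotated scRNA-seq
reference to a single-cell spatial transcriptomics (scST) query. Both
datasets are embedded in one heterogeneous graph whose nodes are cells
(reference and query together) and genes (the shared informative panel),
so the gene nodes act as anchors that couple the two datasets: weights
learned by fitting the reference labels apply unchanged to the query
cells that express the same genes.

### Graph

Five relation types, each with its own learnable transformation per
layer:

| relation | connects | built from |
|---|---|---|
| `cell_self_loop` | cell → itself | all cells |
| `gene_self_loop` | gene → itself | all gene nodes |
| `cell_similar_to_cell` | cell → cell | directed kNN (k = 5, Euclidean on scaled features) within each dataset; reference edges joining different labels removed |
| `gene_expressed_by_cell` | gene → cell | normalized expression > 0 |
| `cell_express_gene` | cell → gene | reverse of the above |

Gene nodes are the intersection across datasets of (top-2000 dispersion
HVGs ∪ per-group top-50 DEGs); panels at or below 2000 genes skip HVG
selection and use every gene. Per-cell input features are the union of
all DEG lists restricted to shared genes, z-scaled per dataset, so
reference and query cells share one input dimension. DEGs use one-vs-rest
Welch t-tests with Benjamini–Hochberg adjustment (keep adjusted p < 0.05,
rank ascending, ties by |t| descending then gene id); the unlabeled query
is first pre-clustered with Leiden at resolution 0.4.

### Network

With σ = LeakyReLU (slope 0.05) and LN = layer normalization:

* layer 0: `h_c = LN(σ(W_c0 x + b_c))` for cells;
  `h_g = LN(σ(mean_{expressing cells} W_cg0 x + b_g))` for genes;
* layers 1..L (L = 2, 512 hidden units): each node sums, over its
  incident relations, the mean of relation-transformed neighbor
  embeddings, plus a self term and node-type bias, then σ and LN. Empty
  neighborhoods contribute zero; duplicate edges are collapsed before the
  mean.
* classifier: each expression edge (cell i, gene j) is scored
  `e_ij = σ(v · [W_c h_i ‖ W_g h_j])`, softmax-normalized over the
  genes each cell expresses (`att_ij`), and the cell's logits are
  `Σ_j att_ij W_g h_j + b_out`, softmaxed into class probabilities.

The loss on reference cells is class-weighted cross entropy (weights
∝ 1/√class size, rescaled to sum to C) with label smoothing ε = 0.1 and
an L2 complexity penalty λ Σ θ² (λ = 0.01) over the weight matrices and
the attention vector v (not the biases).

## Numerical and design choices

* **Autodiff**: the network runs on a small reverse-mode engine over
  numpy/scipy-sparse written for this package (`_autodiff.py`); every
  operation's gradient is tested against central finite differences, and
  the full forward pass against an explicit-loop oracle on toy graphs.
* **Label smoothing sign**: the smoothing term is implemented as a
  uniform-target cross entropy (it *adds* `−(ε/Cm) Σ log y'`); a
  `smoothing_sign="printed"` switch flips the sign for comparison. With
  the flipped sign the term rewards overconfidence, so the standard form
  is the default.
* **L2 as decoupled weight decay**: λ Σ θ² evaluated at initialization
  (~2.6 M parameters) is ~30× larger than the data-fit term, and because
  the LN + LeakyReLU blocks are positively homogeneous, differentiating
  it through Adam shrinks all weights function-preservingly until the
  un-normalized classifier head collapses to chance. The penalty is
  therefore applied as decoupled weight decay (each weight multiplied by
  `1 − lr·λ` per step), the modern reading of "penalizing model
  complexity"; the recorded loss still includes the λ Σ θ² value.
* **Layer normalization** carries no learnable affine parameters: the
  model's parameter set is exactly the per-relation weights, biases,
  classifier maps and attention vector.
* **Initialization**: Xavier-uniform weights, zero biases, seeded.
* **Optimizer**: Adam, lr 5e-3, full-graph steps, 1000 iterations by
  default, with a linear learning-rate ramp over the first 30 iterations
  (Adam's initial near-sign-magnitude steps otherwise swing the wide
  classifier head by several logits and can stall early training).
  Gradient clipping (global norm 5) is off until instability is
  detected — the data-fit loss jumping above 3× its previous value —
  and stays on for the remainder of the run.
* **Checkpoint selection**: a 10% stratified hold-out of reference cells
  is scored every 10 iterations; the checkpoint with the best trailing
  5-evaluation mean hold-out accuracy is kept (ties to the latest).
* **Precision**: float32 parameters and activations (float64 available
  via `ModelConfig(dtype=...)` and used in the oracle tests); the loss
  trace accumulates in float64.
* **Attention softmax** is computed with max-subtraction per cell; cells
  expressing no gene node are rejected at graph assembly, so every
  attention row is well defined.

## Post-analysis

* **Unknown cells**: a query cell is unknown iff its top predicted
  probability is below the median over all query cells AND its type's
  average distance to the reference exceeds 4 (or the type was declared
  low-confidence). The per-type distance is the mean, over the type's
  query cells, of each cell's mean Euclidean distance to its 5 nearest
  reference cells after joint 50-dimensional PCA of the cell embeddings.
  At inference types are the predicted labels; when the query carries its
  own annotation (re-annotation benchmarks), grouping by that annotation
  is used (`unknown_flags_by_annotation`), because a type missing from
  the reference scatters across predicted labels and its large distances
  would otherwise be averaged away with well-matched cells.
* **Gene modules**: Leiden (resolution 1.0, configurable; the resolution
  governing module granularity is not externally fixed) on a 15-NN graph
  of last-layer gene embeddings; module ids ordered by size.
* **Gene importance**: per cell type, the mean attention a gene receives
  from the type's expressing cells (attention exists only on expression
  edges, so non-expressing cells are excluded from the mean); every entry
  lies in [0, 1].
* **Metrics**: accuracy, macro F1 and weighted F1 over the union of truth
  and predicted classes, with F1 = 0 on the missing side — dropping a
  rare type is penalized.

## Synthetic data

The generator emulates a paired scRNA-seq reference and targeted-panel
scST query with shared type structure. Counts are gamma-Poisson
(negative binomial, dispersion 5) with log-normal library sizes
(σ = 0.25). Each of 5 types owns 10 marker genes enriched 2⁴ = 16× over
a low background (mean 0.5 counts/gene), mimicking panels designed from
robustly expressed markers; the query keeps a 150-of-300 gene panel
(all markers plus the highest-expressed background genes), is scaled by
a platform depth factor 0.5, and receives 10% extra dropout — producing
MERFISH-like sparsity (~30% nonzero entries). Defaults: 200 reference and
200 query cells per type, seed 7. Types can be withheld from the
reference while remaining in the query.

What the generator does **not** emulate: spatial autocorrelation and
segmentation artifacts, batch/ambient effects, doublets, gene-gene
correlation beyond type structure, or continuous differentiation
gradients. Passing benchmarks therefore demonstrate the machinery is
correct and well-behaved in the designed regime, not performance on any
particular tissue.

## Benchmark problem sizes

The standard studies use the default generator (1000 + 1000 cells, 150
gene nodes) and train for 300 iterations — past the hold-out accuracy
plateau for every realization tried, so run-to-run trajectory noise does
not leak into study results — putting a full run in the minutes range on
one core. At the default seed the headline benchmark converges by 200
iterations. The open-set (withheld-type) study needs converged
confidence on the known types before the confidence gap to unknown cells
emerges; it is stable from the plateau onward and unchanged at the full
default budget of 1000 iterations. Down-sampling robustness thins the
query counts binomially at rates 1.0–0.2 (dropping cells emptied by
thinning) and scores every rate, including 1.0, with the same
instrument.

## Known limitations

* Within a cell's softmax, the cell-side attention term is constant and
  cancels except through the LeakyReLU kink, so the attention ranking of
  genes is largely shared across cells; cell identity enters the
  classifier mainly through which genes a cell expresses. Dense,
  untargeted panels blur this signal and degrade both annotation and
  open-set detection.
* Full-graph training materializes all embeddings at once; graphs beyond
  a few hundred thousand cells need the neighbor-sampling escape hatch or
  more memory.
* The unknown-cell distance threshold (4) is an absolute scale on
  PCA-reduced, layer-normalized embeddings; it transfers across runs of
  this model but is not dimensionless.
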