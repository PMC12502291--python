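# scgraphmap

Reference-based cell-type annotation for single-cell spatial
transcriptomics (scST). An annotated scRNA-seq reference and an
unlabeled spatial query (MERFISH, seqFISH, STARmap, osmFISH, …) are
joined in one heterogeneous graph over two node types — cells and genes —
and a graph neural network with an attention classifier learns to map
expression to cell types on the reference, then transfers the labels to
the query cells through the shared gene nodes. The package also rejects
query cells whose type is missing from the reference (open-set
detection), extracts gene modules from the learned gene embeddings, and
reports attention-based gene importance per cell type.

## Model in brief

Cells and genes are nodes; five typed relations (self-loops for both
node types, within-dataset expression kNN between cells, and
expression edges cell ↔ gene) each carry their own weights. With σ a
LeakyReLU and LN layer normalization, node embeddings update as

    h_i^(l) = LN( σ( Σ_{r} (1/|N_r(i)|) Σ_{j∈N_r(i)} W_r^(l) h_j^(l−1)
                     + W_self^(l) h_i^(l−1) + b^(l) ) )

for L = 2 layers of 512 units. A per-edge attention score
`e_ij = σ(vᵀ[W_c h_i ‖ W_g h_j])`, normalized over each cell's expressed
genes, weights the gene class-vectors `W_g h_j` into per-cell logits.
Training minimizes a class-weighted (w_c ∝ 1/√m_c), label-smoothed
(ε = 0.1) cross entropy with an L2 complexity penalty (λ = 0.01) on the
reference cells only, with Adam at lr 5e-3.

A query cell is flagged *unknown* when its prediction confidence falls
below the query-wide median **and** its cell type sits further than a
threshold (default 4) from the reference in PCA-reduced embedding space
(mean distance to 5 nearest reference cells, averaged per type).

## Worked example

```python
import scgraphmap as sgm

# paired synthetic datasets with known ground truth:
# 5 cell types, 300-gene reference, 150-gene query panel,
# 200 reference + 200 query cells per type
ref, query, truth = sgm.simulate_pair(sgm.SimSpec())

cfg = sgm.PipelineConfig(
    seed=7,
    model=sgm.ModelConfig(init_seed=7),
    training=sgm.TrainConfig(n_iterations=200, seed=7),
)
results = sgm.CellTypeTransfer(ref, query, cfg).fit()
print(results.summary())
```

```
Cell-type label transfer (heterogeneous cell-gene graph attention)
====================================================================
reference cells:      1000
query cells:          1000
gene nodes:           150
feature genes:        52
classes:              5
training iterations:  200 (selected checkpoint: 180)
final training loss:  52.5002
gene modules:         8
cells flagged unknown: 128 / 1000

predicted composition:
  type_1                  212
  type_2                  199
  type_0                  197
  type_4                  139
  unknown                 128
  type_3                  125

held-out query accuracy: 0.9850
macro F1:                0.9851
weighted F1:             0.9851
```

The accuracy / F1 lines score the transferred labels (before unknown
flagging) against the generator's ground truth; "gene modules" counts
Leiden communities in the learned gene-embedding space. The unknown
flags are conservative on this platform-shifted query — one predicted
type's embedding distance sits just above the default threshold of 4,
so its low-confidence cells are rejected; the threshold is a config
knob (`UnknownConfig.distance_threshold`). `results.predictions`
holds the per-cell probability rows, `results.importance` the cell-type
× gene attention matrix, and `results.save(run_dir)` writes
predictions TSV, loss trace, checkpoint, gene-module and importance
tables and metrics JSON.

The same workflow from the shell:

```bash
scgraphmap simulate --out data/
scgraphmap annotate --ref data/reference.h5ad --query data/query.h5ad \
    --out run/ --truth data/truth.tsv
scgraphmap evaluate --predictions run/predictions.tsv --truth data/truth.tsv
```

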