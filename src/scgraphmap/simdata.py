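"""Paired reference/query simulation with known ground truth.

Counts follow a negative-binomial model (gamma-Poisson mixture) with
log-normal library sizes.  Each cell type up-shifts its own marker genes
by a fixed log2 fold change.  The query emulates a targeted spatial gene
panel: it keeps only a subset of the reference genes (always including
every marker), applies a multiplicative platform depth factor, and an
extra per-entry dropout mask.  Types can be withheld from the reference
while remaining in the query to exercise unknown-cell detection.

Defaults define the package's standard benchmark: 5 types, 300 reference
genes, a 150-gene panel, 10 markers per type at log2FC 2, and 200 + 200
cells per type, seed 7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .data import ExpressionDataset, QUERY, REFERENCE


@dataclass
class SimSpec:
    n_types: int = 5
    n_genes_ref: int = 300
    panel_size_query: int = 150
    markers_per_type: int = 10
    marker_log2fc: float = 4.0       # canonical markers are strongly enriched
                                     # (~16x) in their own type
    baseline_mean: float = 0.5       # low background expression: most panel
                                     # genes are silent outside the types they
                                     # mark, as in imaging-based panels
    dispersion: float = 5.0          # NB shape; smaller = more overdispersed
    dropout_rate: float = 0.1        # extra query-specific zero probability;
                                     # imaging-based assays detect panel genes
                                     # efficiently, so extra zeros are modest
    platform_scale: float = 0.5      # query depth multiplier
    cells_per_type_ref: int = 200
    cells_per_type_query: int = 200
    libsize_sigma: float = 0.25      # log-normal library-size spread
    withheld_types: Tuple[str, ...] = ()
    seed: int = 7

    def validate(self) -> None:
        if self.panel_size_query > self.n_genes_ref:
            raise ValueError("panel cannot exceed the reference gene set")
        if self.markers_per_type * self.n_types > self.n_genes_ref:
            raise ValueError("more markers than genes")
        if self.markers_per_type * self.n_types > self.panel_size_query:
            raise ValueError("panel too small to hold every marker")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.platform_scale <= 0 or self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("scales and dispersion must be positive")
        bad = set(self.withheld_types) - set(self.type_names())
        if bad:
            raise ValueError(f"withheld_types not in the type set: {sorted(bad)}")
        if len(self.withheld_types) >= self.n_types:
            raise ValueError("cannot withhold every type")

    def type_names(self) -> List[str]:
        return [f"type_{i}" for i in range(self.n_types)]

    def gene_names(self) -> List[str]:
        return [f"gene_{i:04d}" for i in range(self.n_genes_ref)]

    def marker_map(self) -> Dict[str, List[str]]:
        """Deterministic assignment of marker genes to types."""
        genes = self.gene_names()
        out = {}
        for i, t in enumerate(self.type_names()):
            lo = i * self.markers_per_type
            out[t] = genes[lo : lo + self.markers_per_type]
        return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(np.float64)


def simulate_pair(
    spec: SimSpec = SimSpec(),
) -> Tuple[ExpressionDataset, ExpressionDataset, np.ndarray]:
    """Generate (reference, query, query truth labels).

    Bit-exactly reproducible under a fixed spec (single seeded generator,
    fixed draw order).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = np.array(spec.gene_names(), dtype=object)
    types = spec.type_names()
    markers = spec.marker_map()

    # per-gene baseline means (shared across datasets); marker genes are
    # floored at the nominal baseline, mimicking panel design where markers
    # are chosen among robustly expressed genes
    base = rng.gamma(2.0, spec.baseline_mean / 2.0, size=spec.n_genes_ref) + 0.02
    fc = 2.0**spec.marker_log2fc
    gene_pos = {g: i for i, g in enumerate(genes)}
    all_markers = [g for t in types for g in markers[t]]
    for g in all_markers:
        base[gene_pos[g]] = max(base[gene_pos[g]], spec.baseline_mean)

    type_means = {}
    for t in types:
        mu = base.copy()
        for g in markers[t]:
            mu[gene_pos[g]] *= fc
        type_means[t] = mu

    # panel: all markers first, then the largest-baseline background genes
    marker_genes = [g for t in types for g in markers[t]]
    background = [g for g in genes if g not in set(marker_genes)]
    background_sorted = sorted(
        background, key=lambda g: (-base[gene_pos[g]], g)
    )
    panel = marker_genes + background_sorted[: spec.panel_size_query - len(marker_genes)]
    panel_idx = np.array([gene_pos[g] for g in panel])

    ref_types = [t for t in types if t not in set(spec.withheld_types)]

    def sample_block(t: str, n_cells: int, scale: float) -> np.ndarray:
        lib = np.exp(rng.normal(0.0, spec.libsize_sigma, size=n_cells)) * scale
        mu = np.outer(lib, type_means[t])
        return _nb_counts(rng, mu, spec.dispersion)

    ref_blocks, ref_labels = [], []
    for t in ref_types:
        ref_blocks.append(sample_block(t, spec.cells_per_type_ref, 1.0))
        ref_labels += [t] * spec.cells_per_type_ref
    ref_X = np.vstack(ref_blocks)

    query_blocks, query_labels = [], []
    for t in types:
        query_blocks.append(sample_block(t, spec.cells_per_type_query, spec.platform_scale))
        query_labels += [t] * spec.cells_per_type_query
    query_X = np.vstack(query_blocks)[:, panel_idx]
    if spec.dropout_rate > 0:
        keep = rng.random(query_X.shape) >= spec.dropout_rate
        query_X = query_X * keep

    # guard against all-zero cells (possible at extreme dropout/depth):
    # give each a single pseudo-read in its type's strongest marker
    zero = np.flatnonzero(query_X.sum(axis=1) == 0)
    panel_pos = {g: i for i, g in enumerate(panel)}
    for i in zero:
        t = query_labels[i]
        target = markers[t][0] if t in markers else panel[0]
        query_X[i, panel_pos[target]] = 1.0
    zero_r = np.flatnonzero(ref_X.sum(axis=1) == 0)
    for i in zero_r:
        t = ref_labels[i]
        ref_X[i, gene_pos[markers[t][0]]] = 1.0

    ref = ExpressionDataset(
        matrix=ref_X,
        cell_ids=np.array([f"ref_{i}" for i in range(len(ref_X))], dtype=object),
        gene_ids=genes,
        origin=REFERENCE,
        labels=np.array(ref_labels, dtype=object),
    )
    truth = np.array(query_labels, dtype=object)
    query = ExpressionDataset(
        matrix=query_X,
        cell_ids=np.array([f"query_{i}" for i in range(len(query_X))], dtype=object),
        gene_ids=np.array(panel, dtype=object),
        origin=QUERY,
        labels=truth.copy(),
    )
    return ref, query, truth


def downsample_counts(
    dataset: ExpressionDataset, rate: float, seed: int = 0
) -> ExpressionDataset:
    """Binomial thinning of raw counts: keep each read with prob ``rate``."""
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must be in (0, 1]")
    if dataset.stage != "raw":
        raise ValueError("downsampling applies to raw counts")
    if rate == 1.0:
        return dataset
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(dataset.matrix.astype(np.int64), rate).astype(np.float64)
    return dataset.with_matrix(thinned, stage="raw")
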