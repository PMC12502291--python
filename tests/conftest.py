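import numpy as np
import pytest

from scgraphmap.data import ExpressionDataset, QUERY, REFERENCE
from scgraphmap.hetgraph import HeteroGraph
from scgraphmap.nnmodel import ModelConfig, ModelState
from scgraphmap.simdata import SimSpec, simulate_pair


def make_toy_graph(
    rng: np.random.Generator,
    n_ref: int = 4,
    n_query: int = 3,
    n_genes: int = 5,
    n_features: int = 6,
    density: float = 0.6,
) -> HeteroGraph:
    """Small random but structurally valid heterogeneous graph."""
    n = n_ref + n_query
    expr = rng.random((n, n_genes)) < density
    for i in range(n):  # every cell must express at least one gene node
        if not expr[i].any():
            expr[i, rng.integers(n_genes)] = True
    ceg = np.argwhere(expr)
    gec = ceg[:, ::-1].copy()
    origin = np.array([REFERENCE] * n_ref + [QUERY] * n_query, dtype=object)
    knn = []
    for i in range(n):
        same = [j for j in range(n) if origin[j] == origin[i] and j != i]
        for j in rng.choice(same, size=min(2, len(same)), replace=False):
            knn.append((i, int(j)))
    edges = {
        "cell_self_loop": np.column_stack([np.arange(n), np.arange(n)]),
        "gene_self_loop": np.column_stack([np.arange(n_genes), np.arange(n_genes)]),
        "cell_similar_to_cell": np.array(knn, dtype=np.int64),
        "gene_expressed_by_cell": gec.astype(np.int64),
        "cell_express_gene": ceg.astype(np.int64),
    }
    return HeteroGraph(
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        cell_origin=origin,
        gene_ids=np.array([f"g{k}" for k in range(n_genes)], dtype=object),
        edges=edges,
        cell_features=rng.normal(size=(n, n_features)),
        feature_genes=[f"f{j}" for j in range(n_features)],
    )


def make_toy_state(
    n_features: int = 6,
    n_classes: int = 3,
    hidden_dim: int = 8,
    seed: int = 0,
) -> ModelState:
    cfg = ModelConfig(hidden_dim=hidden_dim, init_seed=seed, dtype="float64")
    state = ModelState(cfg, n_features, n_classes)
    rng = np.random.default_rng(seed + 1)
    for p in state.params.values():  # non-zero biases exercise every term
        p.data = rng.normal(scale=0.3, size=p.data.shape)
    return state


@pytest.fixture
def toy_graph():
    return make_toy_graph(np.random.default_rng(11))


@pytest.fixture
def toy_state():
    return make_toy_state()


@pytest.fixture(scope="session")
def small_sim():
    """A quick separable pair for pipeline-level tests."""
    spec = SimSpec(
        n_types=3,
        n_genes_ref=120,
        panel_size_query=80,
        markers_per_type=8,
        cells_per_type_ref=60,
        cells_per_type_query=60,
        seed=11,
    )
    ref, query, truth = simulate_pair(spec)
    return spec, ref, query, truth


@pytest.fixture(scope="session")
def default_benchmark():
    """The headline benchmark run, shared by the acceptance tests.

    200 training iterations: the hold-out accuracy plateau at this
    problem size and seed.
    """
    from scgraphmap.benchmark import run_label_transfer

    res, truth, metrics = run_label_transfer(seed=7, n_iterations=200)
    return res, truth, metrics
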