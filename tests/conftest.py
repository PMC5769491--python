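import numpy as np
import pandas as pd
import pytest

import kerahet as kh
from kerahet.synthetic import ExpressionSimSpec


def make_expr(values, genes=None, cells=None):
    """Small expression matrix from a nested list / array of TPM values."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return kh.ExpressionMatrix(genes, cells, values)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulated co-culture shared across tests."""
    spec = ExpressionSimSpec(seed=11)
    expr, ann, truth = kh.simulate_expression(spec)
    return spec, expr, ann, truth


@pytest.fixture(scope="session")
def default_statemap(default_sim):
    """Clustering + pseudotransition on the default simulation, with the
    cluster -> true-state correspondence resolved by majority vote."""
    _, expr, ann, truth = default_sim
    genes = kh.select_analysis_genes(expr)
    clusters = kh.embed_and_cluster(expr, genes, 5, seed=0)
    ct = pd.crosstab(clusters["state"], truth.cells["true_state"].to_numpy())
    mapping = ct.idxmax(axis=1)  # cluster letter -> true state letter
    assert sorted(mapping.values) == list("ABCDE"), "cluster map not bijective"
    on_path = sorted(
        (c for c, t in mapping.items() if t in "ABCD"), key=lambda c: mapping[c]
    )
    ann2 = ann.drop(columns=["state", "pseudotime"]).merge(clusters, on="cell_id")
    ordered = kh.order_pseudotransition(
        expr,
        ann2,
        on_path,
        seed=0,
        start_state=on_path[0],
        genes=clusters.attrs["ordering_genes"],
    )
    return genes, clusters, mapping, on_path, ordered


@pytest.fixture(scope="session")
def null_sim():
    """A simulation with no planted effects: states are exchangeable labels."""
    spec = ExpressionSimSpec(
        n_genes=2000,
        n_cells_control=150,
        n_cells_treated=150,
        n_marker_genes_per_state=0,
        n_dispersed_genes=0,
        n_dynamic_genes=0,
        seed=42,
    )
    expr, ann, truth = kh.simulate_expression(spec)
    return spec, expr, ann, truth
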