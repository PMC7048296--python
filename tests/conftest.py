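import numpy as np
import pandas as pd
import pytest

from cshmmtf.model_core import (
    CellAssignment,
    ExpressionMatrix,
    ModelParameters,
    TreeTopology,
)
from cshmmtf.synthetic_data import make_ground_truth, simulate_expression


def make_chain_model(n_genes: int = 3, lambda_g: float = 1.0) -> ModelParameters:
    """Two-path chain D0 -> D1 -> D2 with simple deterministic parameters."""
    topo = TreeTopology(
        nodes=["D0", "D1", "D2"],
        root="D0",
        paths={"p0": ("D0", "D1"), "p1": ("D1", "D2")},
    )
    gene_ids = [f"g{i}" for i in range(n_genes)]
    base = np.arange(n_genes, dtype=float)
    return ModelParameters(
        topology=topo,
        g={"D0": base, "D1": base + 1.0, "D2": base - 1.0},
        K={"p0": np.full(n_genes, 2.0), "p1": np.full(n_genes, 1.0)},
        sigma2=np.full(n_genes, 0.5),
        B={"D0": {"p0": 1.0}, "D1": {"p1": 1.0}},
        omega=pd.DataFrame(0, index=gene_ids, columns=["TFa"], dtype=int),
        phi=pd.DataFrame(-1.0, index=["p0", "p1"], columns=["TFa"]),
        lambda_g=lambda_g,
        gene_ids=gene_ids,
    )


def make_fork_model(n_genes: int = 2, b1: float = 0.5) -> ModelParameters:
    """One split: D0 -> D1, then D1 -> {D2, D3} with branch probs (b1, 1-b1)."""
    topo = TreeTopology(
        nodes=["D0", "D1", "D2", "D3"],
        root="D0",
        paths={"p0": ("D0", "D1"), "p1": ("D1", "D2"), "p2": ("D1", "D3")},
    )
    gene_ids = [f"g{i}" for i in range(n_genes)]
    base = np.zeros(n_genes)
    return ModelParameters(
        topology=topo,
        g={"D0": base, "D1": base + 1.0, "D2": base + 3.0, "D3": base - 2.0},
        K={p: np.full(n_genes, 2.0) for p in ("p0", "p1", "p2")},
        sigma2=np.full(n_genes, 0.25),
        B={"D0": {"p0": 1.0}, "D1": {"p1": b1, "p2": 1.0 - b1}},
        omega=pd.DataFrame(index=gene_ids, dtype=int),
        phi=pd.DataFrame(-1.0, index=["p0", "p1", "p2"], columns=[]),
        lambda_g=1.0,
        gene_ids=gene_ids,
    )


@pytest.fixture(scope="session")
def fork_truth():
    """Small one-split ground truth with planted TFs, shared across tests."""
    truth = make_ground_truth(
        n_genes=200, n_tfs=3, topology_spec="fork2", targets_per_tf=30, seed=11
    )
    expr, assignment = simulate_expression(truth, cells_per_path=40, seed=11)
    return truth, expr, assignment


@pytest.fixture()
def chain_model():
    return make_chain_model()


@pytest.fixture()
def fork_model():
    return make_fork_model()


def expression_from_values(values, time_labels=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(g)],
        [f"c{j}" for j in range(n)],
        np.zeros(n, dtype=int) if time_labels is None else np.asarray(time_labels),
    )


def assignment_on(path_ids, times) -> CellAssignment:
    times = np.asarray(times, dtype=float)
    return CellAssignment(
        [f"c{j}" for j in range(len(times))],
        np.asarray(path_ids, dtype=object),
        times,
    )
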