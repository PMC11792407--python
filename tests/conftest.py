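import numpy as np
import pandas as pd
import pytest

from heteronet import ExpressionMatrix, simulate_single_dataset


@pytest.fixture(scope="session")
def module_dataset():
    """Standard module fixture: 5 planted 100-gene modules (cor 0.6) plus
    100 background genes, 30 samples."""
    x, truth = simulate_single_dataset(
        seed=3, n_genes=600, module_sizes=(100,) * 5, module_cor=0.6,
        n_samples=30)
    return x, truth


@pytest.fixture()
def tiny_expression():
    """Hand-sized FPKM matrix with full metadata (2 genes x 4 samples)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [10.0, 0.0, 5.0, 2.0]],
        index=pd.Index(["gA", "gB"], name="gene"),
        columns=["s1", "s2", "s3", "s4"])
    meta = pd.DataFrame({
        "group": ["WW", "WW", "YY", "YY"],
        "stage": [1, 1, 1, 1],
        "replicate": [1, 2, 1, 2],
    }, index=values.columns)
    return ExpressionMatrix(values=values, meta=meta, kind="fpkm")


def make_expression(values: np.ndarray, genes=None, samples=None,
                    kind="fpkm", **kwargs) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=samples)
    meta = pd.DataFrame({"group": "WW", "stage": 1,
                         "replicate": range(1, len(samples) + 1)},
                        index=frame.columns)
    return ExpressionMatrix(values=frame, meta=meta, kind=kind, **kwargs)
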