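import numpy as np
import pandas as pd
import pytest

from mastsig.io import CountMatrix, SignatureSet
from mastsig.simulate import (
    BulkSimParams,
    CellSimParams,
    simulate_bulk_priming,
    simulate_tissue_cells,
)


@pytest.fixture(scope="session")
def small_bulk():
    """Planted bulk priming experiment at reduced gene count."""
    params = BulkSimParams(
        n_genes=400,
        n_unique_deg_per_condition=15,
        n_shared_deg=30,
        seed=42,
    )
    return simulate_bulk_priming(params)


@pytest.fixture(scope="session")
def toy_signatures():
    return SignatureSet(
        {
            "IFNG": [f"ifng_{i}" for i in range(10)],
            "IL33": [f"il33_{i}" for i in range(10)],
            "IL4IL13": [f"il4_{i}" for i in range(10)],
            "TGFB": [f"tgfb_{i}" for i in range(10)],
        }
    )


@pytest.fixture(scope="session")
def tissue_cells(toy_signatures):
    """Single-cell dataset with planted utilization bias and IL33 shift."""
    params = CellSimParams(
        n_cells=1200,
        n_genes=300,
        utilization={"healthy": (0.5, 0.5), "copd": (0.75, 0.25)},
        signature_shift={"copd": {"IL33": 0.5}},
        seed=7,
    )
    return simulate_tissue_cells(params, toy_signatures)


@pytest.fixture()
def tiny_counts():
    counts = np.array([[10, 20], [0, 5], [3, 3]])
    return CountMatrix(
        counts,
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        pd.DataFrame({"condition": ["a", "b"]}, index=["s1", "s2"]),
    )
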