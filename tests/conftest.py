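import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rgstable import CountMatrix, CtTable, simulate_counts

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 genes x 3 samples, all positive."""
    df = pd.DataFrame(
        {"s1": [10, 100, 5, 40], "s2": [12, 90, 7, 44], "s3": [9, 110, 6, 38]},
        index=["gA", "gB", "gC", "gD"],
    )
    return CountMatrix(df, groups={"s1": "AK", "s2": "AK", "s3": "SCC"})


@pytest.fixture
def sim_small():
    """Small seeded simulation shared across tests."""
    return simulate_counts(n_genes=400, seed=11)


def make_ct(ct_matrix: pd.DataFrame, groups: dict[str, str], replicates: int = 1) -> CtTable:
    """Build a CtTable from a gene x sample Ct matrix (identical replicates)."""
    rows = []
    for r in range(1, replicates + 1):
        for g in ct_matrix.index:
            for s in ct_matrix.columns:
                rows.append(
                    {
                        "sample": s,
                        "group": groups[s],
                        "gene": g,
                        "replicate": r,
                        "ct": float(ct_matrix.loc[g, s]),
                    }
                )
    return CtTable(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
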