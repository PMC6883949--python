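import numpy as np
import pandas as pd
import pytest

from lncnet.config import SimulationConfig
from lncnet.simulate import simulate_cohort
from lncnet import expression as ex


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort shared across tests (seed 7)."""
    return simulate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def default_log2(default_dataset):
    cm = default_dataset.to_count_matrix()
    return ex.log2_with_pseudocount(ex.compute_fpkm(cm))


@pytest.fixture()
def small_config():
    return SimulationConfig(
        n_genes=400, n_lncrna=60, n_planted_regulators=2, targets_per_regulator=20,
        n_de_per_tissue=20, n_ts_per_tissue=8, n_metabolites=100, n_qtl=12, seed=11,
    )


def make_expression(values: np.ndarray, tissues: list[str], scale: str = "log2fpkm",
                    n_per_tissue: int | None = None) -> ex.ExpressionMatrix:
    """Small helper: wrap a raw matrix into an ExpressionMatrix.

    Columns are grouped into equal-sized consecutive tissue blocks.
    """
    n_genes, n_samples = values.shape
    n_per_tissue = n_per_tissue or n_samples // len(tissues)
    sample_ids, rows = [], []
    for t_i, t in enumerate(tissues):
        for j in range(n_per_tissue):
            sid = f"A{j + 1:03d}.{t}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "animal": f"A{j + 1:03d}", "tissue": t,
                         "sex": "male", "group": "high" if j % 2 else "low", "year": 1})
    meta = pd.DataFrame(rows).set_index("sample_id")
    frame = pd.DataFrame(values, index=[f"G{i}" for i in range(n_genes)],
                         columns=sample_ids)
    return ex.ExpressionMatrix(values=frame, scale=scale, sample_meta=meta)
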