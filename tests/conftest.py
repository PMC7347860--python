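import numpy as np
import pandas as pd
import pytest

from tei.core_io import ExpressionTable
from tei.synthetic_data import (
    default_cell_config,
    default_dev_config,
    default_regional_config,
    gen_developmental,
    gen_regional_microarray,
    gen_single_cell,
)


@pytest.fixture(scope="session")
def regional():
    """Default regional microarray simulation (table, meta, truth)."""
    return gen_regional_microarray(default_regional_config(seed=11))


@pytest.fixture(scope="session")
def single_cell():
    return gen_single_cell(default_cell_config(seed=11))


@pytest.fixture(scope="session")
def developmental():
    return gen_developmental(default_dev_config(seed=11))


@pytest.fixture
def tiny_table():
    """4 samples x 4 gene-level features with a 2-structure ontology."""
    rng = np.random.default_rng(0)
    genes = ["GRIA1", "GRIA2", "GRIA3", "GRIA4"]
    values = pd.DataFrame(
        rng.uniform(4, 12, size=(4, 4)),
        index=[f"s{i}" for i in range(4)], columns=genes,
    )
    meta = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b"],
        "age": [30.0, 30.0, 40.0, 40.0],
        "region": ["R1", "R1", "R1", "R1"],
        "structure": ["X", "X", "Y", "Y"],
        "substructure": ["x1", "x2", "y1", "y2"],
    }, index=values.index)
    return ExpressionTable(values, "log2", None, meta)


def probe_fixture_frame():
    """17-probe x 4-sample frame mirroring the microarray design:
    4 probes each for GRIA1-3 and 5 for GRIA4."""
    rng = np.random.default_rng(7)
    rows = []
    for gene, k in (("GRIA1", 4), ("GRIA2", 4), ("GRIA3", 4), ("GRIA4", 5)):
        for j in range(k):
            rows.append({"feature_id": f"{gene}_p{j + 1}", "gene_symbol": gene,
                         **{f"s{i}": rng.uniform(4, 12) for i in range(4)}})
    return pd.DataFrame(rows)
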