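import numpy as np
import pandas as pd
import pytest

import tastecourse as tc


def make_matrix(values, kind="rpkm", lengths=None, totals=None, stages=None):
    """Small StageMatrix from a 2-D array (genes x stages)."""
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    stages = stages or [f"d{2 * (i + 1)}" for i in range(s)]
    ids = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    lengths = pd.Series(lengths if lengths is not None else [1000] * n, index=ids)
    totals_s = None
    if totals is not None:
        totals_s = pd.Series(totals, index=stages, dtype=float)
    return tc.StageMatrix(
        values=pd.DataFrame(values, index=ids, columns=stages),
        lengths_bp=lengths,
        value_kind=kind,
        mapped_totals=totals_s,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated two-replicate dataset, shared across tests."""
    return tc.generate_dataset(tc.SimConfig(seed=1))


@pytest.fixture(scope="session")
def seven_stage_design():
    stages = [f"d{d}" for d in (2, 4, 6, 8, 10, 12, 14)]
    return tc.build_design(stages, [1e7] * 7, [1.2e7] * 7)
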