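import numpy as np
import pandas as pd
import pytest

from monoqtl.datamodel import CTMatrix


@pytest.fixture
def tiny_ct() -> CTMatrix:
    """3 cells x 2 genes with one missing CT."""
    values = pd.DataFrame(
        [[20.0, 25.0], [28.0, np.nan], [22.0, 30.0]],
        index=pd.Index(["c1", "c2", "c3"], name="cell_id"),
        columns=["GENE_A", "GENE_B"],
    )
    meta = pd.DataFrame(
        {
            "individual_id": ["I01", "I01", "I02"],
            "cell_type": ["CL", "CL", "NCL"],
            "capture_flag": ["singlet", "singlet", "singlet"],
        },
        index=values.index,
    )
    return CTMatrix(values, meta)


@pytest.fixture
def mixed_capture_ct() -> CTMatrix:
    """5 cells with two doublets."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.uniform(15, 27, size=(5, 3)),
        index=pd.Index([f"c{i}" for i in range(5)], name="cell_id"),
        columns=["G1", "G2", "G3"],
    )
    meta = pd.DataFrame(
        {
            "individual_id": ["I01"] * 5,
            "cell_type": ["CL"] * 5,
            "capture_flag": ["singlet", "doublet", "singlet", "doublet", "singlet"],
        },
        index=values.index,
    )
    return CTMatrix(values, meta)
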