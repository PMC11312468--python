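import numpy as np
import pandas as pd
import pytest

from cytosummary import ModelDims, SingleCellTable, init_model


def make_table(rows, features=("Feat_a", "Feat_b")):
    """Build a SingleCellTable from (plate, well, compound, x...) tuples."""
    meta = pd.DataFrame(
        {
            "plate_id": [r[0] for r in rows],
            "well_id": [r[1] for r in rows],
            "compound_id": [r[2] for r in rows],
            "moa": np.nan,
            "dose": np.nan,
        }
    )
    X = np.array([r[3:] for r in rows], dtype=float)
    return SingleCellTable(meta=meta, X=X, features=list(features))


@pytest.fixture
def small_model():
    return init_model(8, ModelDims(D=8, N=16, H=8, L=12), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_well_table():
    return make_table(
        [
            ("P1", "A01", "cmpd1", 1.0, 3.0),
            ("P1", "A01", "cmpd1", 3.0, 5.0),
            ("P1", "A02", "cmpd2", 0.0, 1.0),
            ("P1", "A02", "cmpd2", 2.0, 2.0),
        ]
    )
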