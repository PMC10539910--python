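import numpy as np
import pandas as pd
import pytest

from soilbiome.io_formats import ChemistryTable, OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    rng = np.random.default_rng(7)
    counts = rng.poisson(8, size=(12, 20))
    counts[:, 0] += 5  # guarantee no empty samples
    return OtuTable(
        [f"S{i}" for i in range(12)], [f"O{j}" for j in range(20)], counts
    )


@pytest.fixture
def chem_frame() -> pd.DataFrame:
    rng = np.random.default_rng(3)
    n = 24
    return pd.DataFrame(
        {
            "SOM": rng.normal(23, 4, n).clip(1),
            "pH": rng.normal(6.5, 0.4, n).clip(4, 9),
            "TN": rng.normal(1.25, 0.2, n).clip(0.1),
            "AN": rng.normal(80, 15, n).clip(1),
            "AP": rng.normal(40, 12, n).clip(1),
            "AK": rng.normal(260, 60, n).clip(1),
        },
        index=[f"S{i}" for i in range(n)],
    )


@pytest.fixture
def chemistry(chem_frame) -> ChemistryTable:
    return ChemistryTable(chem_frame)
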