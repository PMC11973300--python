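import numpy as np
import pandas as pd
import pytest

from qmp.simulate import CommunitySpec, simulate_study
from qmp.tables_io import CountTable


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study at the default conditions (6 subjects, d0/d1,
    dominant taxon knocked down to FC 0.3), shared across tests."""
    return simulate_study(CommunitySpec(), seed=7)


@pytest.fixture()
def small_counts():
    data = pd.DataFrame(
        [[10.0, 0.0, 5.0, 250.0], [4.0, 8.0, 0.0, 750.0], [1.0, 2.0, 3.0, 4.0]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CountTable(data)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
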