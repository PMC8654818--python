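import warnings

import numpy as np
import pandas as pd
import pytest

from cotslink.models import ConvergenceWarning
from cotslink.simulate import TruthParams, WorldConfig


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # desk-scale chains legitimately trip the strict R-hat/ESS flags;
    # the flag itself is asserted where it matters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_world():
    return WorldConfig(
        n_grid_sites=5,
        reefs_per_site=2,
        years=(2000, 2003),
        tows_per_reef_year=6,
        transects_per_reef=6,
        seed=11,
    )


@pytest.fixture
def truth():
    return TruthParams()


@pytest.fixture
def toy_tow_table():
    """Hand-sized manta-tow table with both zonings and two reef-years."""
    return pd.DataFrame(
        {
            "reef_id": ["A", "A", "A", "B", "B", "B"],
            "grid_site": ["S1"] * 6,
            "year": [2000, 2000, 2001, 2000, 2000, 2001],
            "tow_index": [1, 2, 1, 1, 2, 1],
            "cots_count": [4, 0, 1, 0, 2, 3],
            "cover_code": ["3", "0", "5U", "2L", "1", "4U"],
            "zoning": ["open", "open", "open", "closed", "closed", "closed"],
        }
    )
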