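import numpy as np
import pytest

from effidiff import (DMUSet, load_fixture, load_region_partition)


@pytest.fixture(scope="session")
def table1():
    """Published 30-province x 9-year efficiency panel."""
    return load_fixture("table1_efficiency_panel")


@pytest.fixture(scope="session")
def table4():
    """Published annual Theil-index series, 2008-2016."""
    return load_fixture("table4_theil_series")


@pytest.fixture(scope="session")
def three_region():
    return load_region_partition("china_three_region")


@pytest.fixture
def two_dmu():
    """A(x=1, y=1) dominates B(x=2, y=1): closed-form scores 2.0 and 0.5."""
    return DMUSet(X=np.array([[1.0], [2.0]]), Y=np.array([[1.0], [1.0]]),
                  unit_ids=["A", "B"])
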