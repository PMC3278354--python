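import numpy as np
import pandas as pd
import pytest

from mipheno.data_model import AssayTable, GroupingSpec


@pytest.fixture
def toy_table() -> AssayTable:
    """Two plates, two attributes, one missing cell."""
    return AssayTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "plate": ["a", "a", "a", "b", "b", "b"],
                "attr1": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                "attr2": [5.0, 6.0, np.nan, 7.0, 8.0, 9.0],
            }
        ),
        factor_columns=("plate",),
        attribute_columns=("attr1", "attr2"),
    )


@pytest.fixture
def toy_spec() -> GroupingSpec:
    return GroupingSpec.single("plate", ("attr1", "attr2"))
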