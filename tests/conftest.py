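import numpy as np
import pandas as pd
import pytest

from ctcflow.channels import CHANNELS
from ctcflow.io import load_table2_fixture


@pytest.fixture(scope="session")
def table2():
    """The packaged 23-patient cohort table with derived groups."""
    return load_table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


def make_events(values: np.ndarray, compensated: bool = True) -> pd.DataFrame:
    """Hand-built event table from an (n, 5) intensity array."""
    frame = pd.DataFrame(np.asarray(values, dtype=float), columns=list(CHANNELS))
    frame.insert(0, "event_id", np.arange(len(frame)))
    frame.attrs["compensated"] = compensated
    return frame
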