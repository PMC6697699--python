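import numpy as np
import pandas as pd
import pytest

from gliomics import OmicsMatrix, SampleDesign, generate_study
from gliomics.core import CORTEX, NTRK, PDGFRA


@pytest.fixture(scope="session")
def design():
    return SampleDesign.from_groups({CORTEX: 3, PDGFRA: 4, NTRK: 3})


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by read-only tests."""
    return generate_study(seed=11)


def make_matrix(values, design, layer="proteome", scale="log2",
                features=None):
    """Build an OmicsMatrix from a 2-D array (features x samples)."""
    values = np.asarray(values, dtype=float)
    if features is None:
        features = [f"F{i:03d}" for i in range(1, len(values) + 1)]
    df = pd.DataFrame(values, index=features, columns=list(design.sample_ids))
    return OmicsMatrix(layer, df, design, scale=scale)


@pytest.fixture
def tiny_design():
    return SampleDesign.from_groups({"a": 2, "b": 2, "c": 2})
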