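import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabolinker import datasets

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def ccna2_fixture():
    """Reference/alternate sequence pair carrying the packaged variant
    records, plus the gene model (built once; alignment is the slow
    part)."""
    ref, alt, model = datasets.build_ccna2_sequences(seed=1)
    return ref, alt, model


@pytest.fixture(scope="session")
def ccna2_variants():
    return datasets.load_ccna2_variants()


@pytest.fixture
def balanced_design():
    """12-sample fully balanced 3-line x 2-sex x 2-diet design (1 per
    cell)."""
    rows = []
    for line in ("BFMI", "B6", "F1"):
        for sex in ("M", "F"):
            for diet in ("SMD", "HFD"):
                rows.append((f"{line}_{sex}_{diet}", line, sex, diet))
    return pd.DataFrame(
        rows, columns=["sample", "line", "sex", "diet"]
    ).set_index("sample")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
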