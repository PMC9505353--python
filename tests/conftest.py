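import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from abomics.haplotypes import default_panel

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220825)


def genotype_frame(rows, columns=None):
    """Small genotype matrix helper (rows of per-SNP counted-allele counts)."""
    arr = np.asarray(rows, dtype=float)
    if columns is None:
        columns = [f"snp{j+1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=columns)
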