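import numpy as np
import pytest

from phylopart import create_hapmat


@pytest.fixture
def toy_hapmat():
    """4 sequences x 4 SNVs at 1-4 kbp."""
    matrix = [
        [0, 0, 0, 1],
        [1, 0, 1, 0],
        [1, 1, 0, 0],
        [0, 0, 1, 1],
    ]
    return create_hapmat(
        matrix,
        snv_names=["SNV1", "SNV2", "SNV3", "SNV4"],
        hap_names=["h1", "h2", "h3", "h4"],
        positions=[1000, 2000, 3000, 4000],
    )


@pytest.fixture
def dup_row_hapmat():
    """h1 and h3 are identical, so they cannot be distinguished."""
    matrix = [
        [0, 1, 0],
        [1, 0, 1],
        [0, 1, 0],
        [1, 1, 0],
    ]
    return create_hapmat(
        matrix,
        snv_names=["s1", "s2", "s3"],
        hap_names=["h1", "h2", "h3", "h4"],
        positions=[100, 200, 300],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
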