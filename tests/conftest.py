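import numpy as np
import pytest

from smrg.growing import Seed, grow
from smrg.phantom import standard_suite

#: manual seed on the Y-branch trunk, shared by growing and acceptance tests
YBRANCH_SEED = Seed(8, 100, 64)


@pytest.fixture(scope="session")
def ybranch_high():
    """High-contrast Y-branch phantom: (rendered stack, ground truth)."""
    return standard_suite("ybranch", "high")


@pytest.fixture(scope="session")
def ybranch_segmentation(ybranch_high):
    """grow() result on the high-contrast Y-branch (computed once)."""
    stack, _ = ybranch_high
    return grow(stack, [YBRANCH_SEED])


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))
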