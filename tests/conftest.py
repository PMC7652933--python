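import numpy as np
import pytest

from njcones import DissimilarityMap

# The two 5-taxon dissimilarity matrices of the published worked example
# (taxa a..e).  NJ gives the same unrooted topology for both but different
# agglomeration orders: first cherry (a,b) for WORKED_D, (c,e) for WORKED_DP.
WORKED_D = [
    [0, 3, 5, 4, 7],
    [3, 0, 10, 3, 7],
    [5, 10, 0, 6, 5],
    [4, 3, 6, 0, 2],
    [7, 7, 5, 2, 0],
]
WORKED_DP = [
    [0, 2, 4, 1, 9],
    [2, 0, 10, 3, 8],
    [4, 10, 0, 6, 5],
    [1, 3, 6, 0, 7],
    [9, 8, 5, 7, 0],
]

FIG4_ORDERED_NEWICK = "(3(c,1(a,b)),2(e,f),d)"


@pytest.fixture
def worked_d() -> DissimilarityMap:
    return DissimilarityMap.from_matrix(list("abcde"), WORKED_D)


@pytest.fixture
def worked_dp() -> DissimilarityMap:
    return DissimilarityMap.from_matrix(list("abcde"), WORKED_DP)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201027)
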