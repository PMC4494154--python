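import pytest

import recapture as rc

MASTER_SEED = 42


@pytest.fixture(scope="session")
def table1_df():
    """Full two-occasion estimator comparison at the study's 1000 replicates."""
    return rc.reproduce_table1(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def table2_df():
    """Full Chao M-occasion study at the study's 1000 replicates."""
    return rc.reproduce_table2(seed=MASTER_SEED)


def lp_second_order_mean(cells: rc.CellProbabilities, N: int) -> float:
    """Expected Lincoln-Petersen mean including its O(1/m) ratio bias.

    LP is unbiased to first order; the leading small-sample term comes from
    E[1/m] > 1/E[m]:  bias ~= (E n1 * E n2 / E m) * var(m)/E[m]^2, with
    m ~ Binomial(N, p11).
    """
    En1 = N * cells.p1
    En2 = N * cells.p01
    Em = N * cells.p11
    cv2 = (1.0 - cells.p11) / (N * cells.p11)
    return N + (En1 * En2 / Em) * cv2
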