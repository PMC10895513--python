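import numpy as np
import pytest

import famnet as fn
from famnet.preprocessing import spearman_matrix

BRIDGES = [("m_guilt", "f_guilt"), ("m_selfharm", "f_selfharm")]


@pytest.fixture(scope="session")
def truth18():
    """Strong-signal two-community parent truth (all |pcor| >= 0.15)."""
    truth = fn.build_true_network(
        9, 9, within_density=0.2, bridge_pairs=BRIDGES,
        weight_low=0.18, weight_high=0.35, seed=7,
    )
    assert np.abs(truth.pcor[truth.pcor != 0]).min() >= 0.15
    return truth


@pytest.fixture(scope="session")
def truth6():
    return fn.build_true_network(
        3, 3, within_density=0.4, bridge_pairs=[("m_sad", "f_sad")],
        weight_low=0.15, weight_high=0.3, seed=2,
    )


@pytest.fixture(scope="session")
def table18(truth18):
    return fn.sample_family_data(truth18, 4000, seed=11)


@pytest.fixture(scope="session")
def net18(table18):
    return fn.estimate_network(table18)


@pytest.fixture(scope="session")
def estimator():
    def estimate(df):
        return fn.select_ggm(spearman_matrix(df))

    return estimate
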