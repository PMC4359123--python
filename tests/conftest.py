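import numpy as np
import pytest

import olfthresh as ot


@pytest.fixture(scope="session")
def normosmic():
    return ot.preset("normosmic")


@pytest.fixture(scope="session")
def nshap_gamma():
    return ot.preset("nshap_gamma")


@pytest.fixture(scope="session")
def proto16():
    return ot.ConstantStimuliProtocol(tuple(range(1, 17)))


@pytest.fixture(scope="session")
def small_table(normosmic, proto16):
    """100-subject, 16-item simulated response table (fixed seed)."""
    rng = np.random.default_rng(1234)
    truths = normosmic.sample_thresholds(100, rng)
    table = ot.simulate_constant_stimuli(truths, normosmic.beta, proto16, rng)
    return table, truths
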