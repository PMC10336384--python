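import numpy as np
import pytest

from crosscause import LogisticParams, simulate_logistic_pair


@pytest.fixture(scope="session")
def coupled_logistic():
    """One realization of the benchmark logistic pair (x1 drives x2)."""
    ts = simulate_logistic_pair(LogisticParams(C1=0.0, C2=0.1, L=400, seed=42))
    return ts.channel("x1"), ts.channel("x2")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
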