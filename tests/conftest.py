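import numpy as np
import pytest

from alstructure import PSDParams, alpha_prototype, simulate_psd


@pytest.fixture(scope="session")
def small_psd():
    """A small PSD-design dataset with ground truth (m=2000, n=100, d=3)."""
    params = PSDParams(m=2000, n=100, d=3, alpha=alpha_prototype("a2", 3), seed=42)
    return simulate_psd(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
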