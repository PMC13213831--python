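import numpy as np
import pytest

from neqcycle import SimSpec, sample_works


@pytest.fixture
def crooks_workset():
    """A mid-sized Crooks-consistent Gaussian work set with planted ΔG = −2."""
    return sample_works(
        SimSpec(dG_true=-2.0, dissipation=1.0, n_forward=500, n_reverse=500, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
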