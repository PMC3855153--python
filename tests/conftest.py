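import numpy as np
import pytest

from noisenet import build_motif, simulate


@pytest.fixture(scope="session")
def faithful_datasets():
    """One n=2000 equal-noise sample per motif at the default coupling."""
    return {
        kind: simulate(build_motif(kind, 2.0, (1.0, 1.0, 1.0)), 2000, seed=101)
        for kind in ("common_effect", "three_chain", "ffl_type1")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
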