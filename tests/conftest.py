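import numpy as np
import pytest

from metastab.synthdata import SynthSpec, generate_dataset

# architecture small enough for fast unit tests; the full-size defaults are
# exercised by the acceptance suite
TINY = dict(d1=16, d2=16, d_s=16, d_g=16, att_dim=8, predictor_hidden=16,
            heads=2, embed_epochs=2, batch_size=32)


@pytest.fixture(scope="session")
def synth1000():
    """Shared clean synthetic set used by round-trip / invariant tests."""
    ds, truth = generate_dataset(SynthSpec(n=1000, noise=0.0, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def tiny_params():
    return dict(TINY)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
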