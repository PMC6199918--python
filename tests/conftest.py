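import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sessions():
    """Small deterministic synthetic data shared by protocol-level tests."""
    from gammadecoder.synthetic_data import SynthConfig, generate

    cfg = SynthConfig(
        n_sessions=2,
        trials_per_session=10,
        n_neural=8,
        n_emg=2,
        n_latents=2,
        seed=42,
    )
    sessions, truth = generate(cfg)
    return cfg, sessions, truth
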