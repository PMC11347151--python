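import numpy as np
import pytest

from smterm.synthetic_data import GeneratorConfig, simulate_ensemble


@pytest.fixture(scope="session")
def noisy_ensemble_200():
    """Shared medium ensemble at default noise for classifier statistics."""
    cfg = GeneratorConfig(n_traces=200, seed=11, p_active=0.8,
                          p_recycling_given_termination=0.05)
    traces, truth = simulate_ensemble(cfg)
    return cfg, traces, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
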