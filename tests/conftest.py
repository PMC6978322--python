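import numpy as np
import pytest

from termcycle.simulate import TraceSimConfig, simulate_trace


@pytest.fixture(scope="session")
def noiseless_trace():
    """One noiseless, never-lost, non-sliding trace and its truth."""
    cfg = TraceSimConfig(
        seed=42,
        noise_sd=0.0,
        D_slide=0.0,
        p_retain=1.0,
        p_antisense=0.0,
        p_sense_reinit=0.0,
        k_RNAP=0.0,
        k_PB=0.0,
        lambda_cv=0.0,
        r_cv=0.0,
    )
    trace, truth = simulate_trace(cfg)
    return cfg, trace, truth


@pytest.fixture(scope="session")
def noisy_sliding_trace():
    """A long-lived sliding molecule with realistic noise."""
    cfg = TraceSimConfig(
        seed=7,
        k_RNAP=1e-6,
        k_PB=1e-6,
        p_retain=1.0,
        p_antisense=0.0,
        p_sense_reinit=0.0,
        p_stick=0.0,
        p_unstick=1.0,
        p_initial_slide=1.0,
    )
    trace, truth = simulate_trace(cfg)
    return cfg, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
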