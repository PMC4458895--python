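import pytest

from rodfold.simulate import (TIRFSimConfig, saturated_noiseless_config,
                              simulate_afm_trace, simulate_tirf_movie)


@pytest.fixture(scope="session")
def saturated_trace():
    """Noiseless 13-domain trace in which every domain unfolds before
    detachment (session-scoped: several tests inspect it)."""
    cfg = saturated_noiseless_config(seed=3)
    return simulate_afm_trace(cfg)


@pytest.fixture(scope="session")
def noiseless_movie():
    """Noise-free two-fluorophore movie at 59 nm true separation."""
    cfg = TIRFSimConfig(separation=59.0, shot_noise=False,
                        read_noise_sd=0.0, seed=7)
    return cfg, *simulate_tirf_movie(cfg)
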