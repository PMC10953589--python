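import numpy as np
import pytest

from evquant import ImageSimConfig, QuantConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def recovery_sim_cfg():
    """Frame config for detection benchmarks: effective SNR >= 8, EV-sized
    spots only (no aggregates, which deliberately swallow neighbours)."""
    def _make(seed: int) -> ImageSimConfig:
        return ImageSimConfig(
            seed=seed,
            spot_count=12,
            n_speck=5,
            n_aggregate=0,
            amplitude_distribution=("lognormal", {"median": 14000.0, "sigma": 0.25}),
        )

    return _make


@pytest.fixture
def default_quant_cfg():
    return QuantConfig()
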