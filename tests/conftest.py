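import numpy as np
import pytest

import treebreed as tb


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def calibrated():
    """Factory: fully calibrated genome for a named scenario."""

    def _build(name: str, seed: int = 0, **overrides):
        scenario = tb.scenario_from_name(name, **overrides)
        rng = np.random.default_rng(seed)
        p, effects, sigma2_e = tb.build_calibrated_genome(scenario, rng)
        return scenario, p, effects, sigma2_e, rng

    return _build


@pytest.fixture
def founder_population(calibrated):
    """Factory: calibrated genome plus its founder population."""

    def _build(name: str, seed: int = 0, **overrides):
        scenario, p, effects, sigma2_e, rng = calibrated(name, seed, **overrides)
        founders = tb.create_founders(scenario, p, effects, sigma2_e, rng)
        return scenario, p, effects, sigma2_e, founders, rng

    return _build
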