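import numpy as np
import pytest

from udsim import FitnessParams, ScenarioConfig, run
from udsim.experiments import reversal_threshold


@pytest.fixture(scope="session")
def default_params() -> FitnessParams:
    """Intact constructs cost 5% per copy, mutated constructs 4%."""
    return FitnessParams(0.95, 0.95, 0.96, 0.96)


@pytest.fixture(scope="session")
def wildtype_threshold(default_params) -> float:
    """Minimal wild-type release ratio reversing an established drive (m=0,
    eps=0.95, release at generation 100), shared across tests."""
    return reversal_threshold("wildtype", default_params, release_generation=100)


@pytest.fixture(scope="session")
def collapse_runs():
    """Full mutation-collapse trajectories for m in {1e-4, 1e-5, 1e-6}."""
    out = {}
    for m in (1e-4, 1e-5, 1e-6):
        cfg = ScenarioConfig(
            m=m, generations=200_000, thin=1, stop_at_wild_freq=1 - 1e-6
        )
        out[m] = run(cfg)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
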