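import numpy as np
import pytest
from hypothesis import settings

from elfarol import SimulationParams, run_ensemble

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def paper_params() -> SimulationParams:
    """The headline study conditions: M=100, B=60, mu=0.01, T=300."""
    return SimulationParams(
        n_agents=100, capacity=60, stepsize=0.01, horizon=300, regime="partial"
    )


@pytest.fixture(scope="session")
def table_ensembles():
    """Both 1,000-run ensembles at the study conditions (session-cached)."""
    partial = run_ensemble(
        SimulationParams(regime="partial"), 1000, np.random.SeedSequence(1, spawn_key=(0,))
    )
    full = run_ensemble(
        SimulationParams(regime="full"), 1000, np.random.SeedSequence(1, spawn_key=(1,))
    )
    return partial, full
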