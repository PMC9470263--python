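import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# single fixed master seed for the whole suite, set up front
TEST_SEED = 0


@pytest.fixture(scope="session")
def test_seed() -> int:
    return TEST_SEED


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(TEST_SEED)


# ---------------------------------------------------------------------------
# heavyweight shared experiment results (computed once per session)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def hotspot_reports():
    """Signal + negative-control end-to-end experiment (shared)."""
    from preyfield.pipeline import encounter_experiment

    sig = encounter_experiment(TEST_SEED, hotspot_amplitude_db=12.0,
                               n_draws=10_000)
    cache = sig.pop("reuse")
    null = encounter_experiment(TEST_SEED, hotspot_amplitude_db=0.0,
                                n_draws=10_000, _cache=cache)
    null.pop("reuse")
    return sig, null


@pytest.fixture(scope="session")
def hmm_recovery():
    from preyfield.pipeline import hmm_recovery_experiment

    return hmm_recovery_experiment(TEST_SEED)


@pytest.fixture(scope="session")
def ctcrw_recovery():
    from preyfield.pipeline import ctcrw_recovery_experiment

    return ctcrw_recovery_experiment(TEST_SEED)
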