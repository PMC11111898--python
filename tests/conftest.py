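import warnings

import pytest
from hypothesis import HealthCheck, settings

import avsin
from avsin.simulate import SimConfig, simulate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def lexicon():
    return avsin.load_bundled_lexicon()


@pytest.fixture(scope="session")
def equivalences():
    return avsin.load_equivalences()


@pytest.fixture(scope="session")
def small_experiment(lexicon):
    """A 24-participant simulated experiment scored end-to-end (shared)."""
    result = simulate_experiment(
        SimConfig(n_participants=24, n_words=32, seed=11), lexicon
    )
    scored = avsin.scored_to_frame(
        avsin.score_trials(result.trials, result.lexicon)
    )
    return result, scored


@pytest.fixture(scope="session")
def recovery_experiment(lexicon):
    """Identifiable-mode simulation: reconstruction off, deletion slips."""
    config = SimConfig(
        n_participants=60,
        n_words=64,
        seed=7,
        lexical_reconstruction=False,
        slip_model="delete",
        catch_trials_per_participant=0,
    )
    result = simulate_experiment(config, lexicon)
    scored = avsin.scored_to_frame(
        avsin.score_trials(result.trials, result.lexicon)
    )
    return result, scored
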