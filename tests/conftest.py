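import numpy as np
import pytest

from envdecode.conditions import StimulusCondition, make_conditions
from envdecode.population import sample_population
from envdecode.simulate import simulate_session

#: Small config for pipeline-level tests: one session, 12 neurons, 4 trials,
#: one contrast, light DE and robustness settings.
SMALL_COUNTS = {
    '["ON", "low"]': 2, '["OFF", "low"]': 2,
    '["ON", "medium"]': 2, '["OFF", "medium"]': 2,
    '["ON", "high"]': 2, '["OFF", "high"]': 2,
}

SMALL_CONFIG = {
    "stimulus": {"n_trials": 2},
    "population": {"n_sessions": 1, "total_counts": SMALL_COUNTS},
    "de": {"max_generations": 60, "termination_threshold": 5e-3},
    "robustness": {"n_sigma": 4, "n_realizations": 5},
}


@pytest.fixture(scope="session")
def tiny_condition():
    return StimulusCondition(envelope_frequency=1.0, contrast_level="strong",
                             envelope_amplitude=0.497, duration=1.0, n_trials=4)


@pytest.fixture(scope="session")
def tiny_session(tiny_condition):
    pop = sample_population({("ON", "low"): 2, ("OFF", "medium"): 2}, seed=3,
                            session_id="tiny")
    return simulate_session(pop, [tiny_condition], seed=7)


@pytest.fixture(scope="session")
def nine_conditions():
    return make_conditions()


def random_decoding_instance(rng, m=None, t=2000):
    """Random (rates, target) with a planted linear relation plus noise."""
    m = m or rng.integers(2, 11)
    R = rng.standard_normal((m, t)) + rng.standard_normal((m, 1))
    w_true = rng.standard_normal(m)
    S = w_true @ R + 0.5 * rng.standard_normal(t) + rng.standard_normal()
    return R, S
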