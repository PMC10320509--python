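import numpy as np
import pytest

from envdecode.conditions import StimulusCondition, make_conditions
from envdecode.population import apply_feedback_inactivation, sample_population
from envdecode.simulate import (band_limited_carrier, instantaneous_rate,
                                simulate_session)


def _flat(session):
    return [t for cid in session.spike_times
            for trials in session.spike_times[cid] for t in trials]


def test_simulation_deterministic():
    pop = sample_population({("ON", "low"): 2}, seed=0)
    conds = [make_conditions()[8]]
    a = simulate_session(pop, conds, seed=11)
    b = simulate_session(pop, conds, seed=11)
    for ta, tb in zip(_flat(a), _flat(b)):
        np.testing.assert_array_equal(ta, tb)
    np.testing.assert_array_equal(a.behavior["1Hz_strong"],
                                  b.behavior["1Hz_strong"])


def test_spike_times_within_bounds_and_sorted(tiny_session, tiny_condition):
    for trials in tiny_session.spike_times[tiny_condition.condition_id]:
        for t in trials:
            if len(t):
                assert t[0] >= 0 and t[-1] < tiny_condition.duration
                assert np.all(np.diff(t) > 0)


def test_envelope_and_carrier_shapes(tiny_session, tiny_condition):
    cid = tiny_condition.condition_id
    env = tiny_session.envelopes[cid]
    assert env.size == tiny_condition.n_samples
    assert np.max(env) == pytest.approx(tiny_condition.envelope_amplitude,
                                        rel=1e-3)
    car = tiny_session.carriers[cid]
    assert np.std(car) == pytest.approx(1.0, rel=0.05)


def test_carrier_band_limited():
    rng = np.random.default_rng(0)
    car = band_limited_carrier(40000, rng)
    freqs = np.fft.rfftfreq(car.size, d=1 / 2000.0)
    power = np.abs(np.fft.rfft(car)) ** 2
    inband = power[(freqs >= 5) & (freqs <= 15)].sum()
    assert inband / power.sum() > 0.95


def test_mean_rate_tracks_baseline():
    pop = sample_population({("OFF", "high"): 3}, seed=4)
    cond = StimulusCondition(envelope_frequency=1.0, contrast_level="weak",
                             envelope_amplitude=0.091, duration=1.0,
                             n_trials=30)
    sess = simulate_session(pop, [cond], seed=5)
    for nid, neuron in enumerate(pop.neurons):
        counts = [len(t) for t in sess.spike_times[cond.condition_id][nid]]
        rate = np.mean(counts) / cond.duration
        assert rate == pytest.approx(neuron.baseline_rate, rel=0.35, abs=5)


def test_instantaneous_rate_nonnegative(tiny_condition):
    pop = sample_population({("ON", "low"): 1}, seed=6)
    rng = np.random.default_rng(0)
    car = band_limited_carrier(tiny_condition.n_samples, rng)
    lam = instantaneous_rate(pop.neurons[0], tiny_condition, car)
    assert np.all(lam >= 0)


def test_common_random_numbers_across_states():
    """Same seed: non-target neurons spike identically in both states."""
    pop_c = sample_population({("ON", "low"): 2, ("OFF", "medium"): 2}, seed=7)
    pop_i, extra = apply_feedback_inactivation(pop_c, seed=8)
    conds = [make_conditions()[6]]
    cid = conds[0].condition_id
    sc = simulate_session(pop_c, conds, seed=13)
    si = simulate_session(pop_i, conds,
                          behavior_params={"attenuation":
                                           extra["behavior_attenuation"]},
                          seed=13, feedback_state="inactivated")
    np.testing.assert_array_equal(sc.carriers[cid], si.carriers[cid])
    for nid, n in enumerate(pop_c.neurons):
        if n.cell_type != ("ON", "low"):
            for a, b in zip(sc.spike_times[cid][nid], si.spike_times[cid][nid]):
                np.testing.assert_array_equal(a, b)


def test_behavior_attenuation_halves_modulation():
    pop = sample_population({("ON", "low"): 1}, seed=9)
    conds = [make_conditions()[8]]
    cid = conds[0].condition_id
    full = simulate_session(pop, conds, seed=1)
    half = simulate_session(pop, conds, behavior_params={"attenuation": 0.5},
                            seed=1)
    amp = lambda b: (np.max(b) - np.min(b)) / 2
    assert amp(half.behavior[cid]) == pytest.approx(
        0.5 * amp(full.behavior[cid]), rel=0.15)


def test_clipping_rare(tiny_session):
    assert tiny_session.clipped_fraction <= 0.01
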