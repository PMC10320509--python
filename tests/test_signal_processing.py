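import numpy as np
import pytest

from envdecode.conditions import SAMPLE_RATE
from envdecode.signal_processing import (BUTTERWORTH_CUTOFFS, bin_spikes,
                                         butterworth_rate, classify_polarity,
                                         classify_rate_class, compute_sta,
                                         correlation_summary, estimate_tuning,
                                         is_clear_responder, kaiser_rate,
                                         pairwise_correlations,
                                         trial_averaged_rate)


def test_bin_spikes_counts_and_grid():
    train = bin_spikes([0.0004, 0.0012, 0.5], duration=1.0)
    assert train.values.size == 2000
    assert train.values.sum() == 3
    assert train.values[0] == 1 and train.values[2] == 1
    assert train.values[1000] == 1


def test_bin_spikes_rejects_bad_input():
    with pytest.raises(ValueError):
        bin_spikes([0.5, 0.2], duration=1.0)
    with pytest.raises(ValueError):
        bin_spikes([1.2], duration=1.0)


def test_butterworth_cutoffs_pinned():
    assert BUTTERWORTH_CUTOFFS == {0.1: 0.15, 0.5: 0.3, 1.0: 1.5}


def test_filtered_rate_preserves_mean_rate():
    rng = np.random.default_rng(0)
    spikes = np.sort(rng.uniform(0, 10, 500))
    train = bin_spikes(spikes, duration=10.0)
    rate = butterworth_rate(train, envelope_frequency=0.1).rate
    assert np.mean(rate) == pytest.approx(50.0, rel=0.05)


def test_butterworth_accepts_matrix():
    x = np.zeros((3, 2000))
    x[:, 1000] = 1
    out = butterworth_rate(x, envelope_frequency=1.0)
    assert out.rate.shape == (3, 2000)


def test_kaiser_rate_runs():
    train = bin_spikes(np.linspace(0.01, 0.99, 30), duration=1.0)
    out = kaiser_rate(train, stimulus_frequency=1.0)
    assert out.filter_kind == "kaiser"
    assert out.rate.shape == (2000,)


def test_trial_averaged_equals_mean_of_filtered():
    rng = np.random.default_rng(1)
    trains = [bin_spikes(np.sort(rng.uniform(0, 2, 50)), 2.0)
              for _ in range(4)]
    avg = trial_averaged_rate(trains, envelope_frequency=0.5).rate
    manual = np.mean([butterworth_rate(t, 0.5).rate for t in trains], axis=0)
    np.testing.assert_allclose(avg, manual, atol=1e-9)


def _sinusoidal_spikes(rng, base, mod, phase, f, duration, n_trials):
    n = int(duration * SAMPLE_RATE)
    t = np.arange(n) / SAMPLE_RATE
    lam = np.maximum(0, base + mod * np.sin(2 * np.pi * f * t + phase))
    p = lam / SAMPLE_RATE
    return [t[rng.random(n) < p] for _ in range(n_trials)]


def test_estimate_tuning_recovers_gain_and_phase():
    rng = np.random.default_rng(2)
    trials = _sinusoidal_spikes(rng, base=60, mod=30, phase=0.8, f=1.0,
                                duration=1.0, n_trials=200)
    tune = estimate_tuning(trials, envelope_frequency=1.0,
                           envelope_amplitude=0.5, duration=1.0)
    assert tune.gain == pytest.approx(30 / 0.5, rel=0.1)
    assert tune.preferred_phase == pytest.approx(0.8, abs=0.15)


def test_clear_responder_threshold():
    rng = np.random.default_rng(3)
    strong = estimate_tuning(_sinusoidal_spikes(rng, 40, 20, 0, 0.1, 10, 20),
                             0.1, 0.5, 10.0)
    flat = estimate_tuning(_sinusoidal_spikes(rng, 40, 0, 0, 0.1, 10, 20),
                           0.1, 0.5, 10.0)
    assert is_clear_responder(strong)
    assert not is_clear_responder(flat)


def test_sta_polarity_on_synthetic_cells():
    rng = np.random.default_rng(4)
    n = 200000
    carrier = np.convolve(rng.standard_normal(n), np.ones(100) / 100, "same")
    carrier /= carrier.std()
    t = np.arange(n) / SAMPLE_RATE
    for sign, label in ((1.0, "ON"), (-1.0, "OFF")):
        lam = 40 * (1 + 0.6 * sign * carrier)
        spikes = t[rng.random(n) < np.maximum(lam, 0) / SAMPLE_RATE]
        _, slope = compute_sta(spikes, carrier)
        assert classify_polarity(slope) == label


def test_classify_rate_class():
    assert classify_rate_class(10) == "low"
    assert classify_rate_class(20) == "medium"
    assert classify_rate_class(30) == "high"


def test_pairwise_correlations_structure():
    rng = np.random.default_rng(5)
    base = rng.standard_normal(500)
    rates = np.stack([base, base + 0.01 * rng.standard_normal(500),
                      rng.standard_normal(500)])
    df = pairwise_correlations(rates, neuron_types=["a", "a", "b"],
                               condition_id="c", state="control")
    assert len(df) == 3
    r01 = df[(df.i == 0) & (df.j == 1)].iloc[0]
    assert r01.r > 0.99 and r01.same_type
    assert not df[(df.i == 0) & (df.j == 2)].iloc[0].same_type
    summ = correlation_summary(df)
    assert summ["n_pairs"] == 3
    assert 0 <= summ["frac_above"] <= 1


def test_pairwise_correlations_skips_flat_traces():
    rates = np.vstack([np.zeros(100), np.random.default_rng(0).random((2, 100))])
    df = pairwise_correlations(rates)
    assert set(zip(df.i, df.j)) == {(1, 2)}
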