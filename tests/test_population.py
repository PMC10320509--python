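import numpy as np
import pytest

from envdecode.population import (BASELINE_RANGES, FULL_COUNTS,
                                  GAIN_RANGE_1HZ, ON_LOW_GAIN_RANGE_1HZ,
                                  apply_feedback_inactivation, rate_class_of,
                                  sample_population,
                                  split_counts_across_sessions)


def test_sample_population_counts_and_ranges():
    counts = {("ON", "low"): 3, ("OFF", "high"): 2}
    pop = sample_population(counts, seed=0)
    assert pop.size == 5
    assert len(pop.type_indices(("ON", "low"))) == 3
    for n in pop.neurons:
        lo, hi = BASELINE_RANGES[n.rate_class]
        assert lo <= n.baseline_rate <= hi
        assert n.rate_class == rate_class_of(n.baseline_rate)
        g_lo, g_hi = (ON_LOW_GAIN_RANGE_1HZ if n.cell_type == ("ON", "low")
                      else GAIN_RANGE_1HZ)
        assert g_lo <= n.envelope_gain_at_1hz <= g_hi
        assert 0 <= n.carrier_modulation_depth <= 1


def test_gain_tuning_is_high_pass():
    pop = sample_population({("ON", "medium"): 1}, seed=1)
    n = pop.neurons[0]
    assert n.envelope_gain(0.1) < n.envelope_gain(0.5) < n.envelope_gain(1.0)
    assert n.envelope_gain(1.0) == pytest.approx(n.envelope_gain_at_1hz)


def test_sampling_deterministic_in_seed():
    a = sample_population(FULL_COUNTS, seed=5)
    b = sample_population(FULL_COUNTS, seed=5)
    c = sample_population(FULL_COUNTS, seed=6)
    assert a.neurons == b.neurons
    assert a.neurons != c.neurons


def test_inactivation_redraws_only_target_phases():
    pop = sample_population({("ON", "low"): 4, ("OFF", "medium"): 4}, seed=2)
    new, extra = apply_feedback_inactivation(pop, seed=9)
    assert extra["behavior_attenuation"] == 0.5
    assert new.phase_concentration_by_type[("ON", "low")] == 8.0
    changed = 0
    for old, nn in zip(pop.neurons, new.neurons):
        assert nn.baseline_rate == old.baseline_rate
        assert nn.envelope_gain_at_1hz == old.envelope_gain_at_1hz
        assert nn.carrier_modulation_depth == old.carrier_modulation_depth
        if old.cell_type == ("ON", "low"):
            changed += int(nn.envelope_phase != old.envelope_phase)
        else:
            assert nn.envelope_phase == old.envelope_phase
    assert changed >= 3  # redrawn phases almost surely differ


def test_inactivated_phases_concentrate():
    pop = sample_population({("ON", "low"): 200}, seed=3)
    new, _ = apply_feedback_inactivation(pop, seed=4)
    phases = np.array([n.envelope_phase for n in new.neurons])
    # kappa=8 von Mises has circular SD ~ 0.37 rad; uniform has ~1.8
    assert np.abs(np.angle(np.mean(np.exp(1j * phases)))) < 0.2
    assert np.std(np.angle(np.exp(1j * phases))) < 0.6


def test_split_counts_preserves_totals_and_balance():
    parts = split_counts_across_sessions(FULL_COUNTS, 7)
    assert len(parts) == 7
    for ct in FULL_COUNTS:
        per = [p.get(ct, 0) for p in parts]
        assert sum(per) == FULL_COUNTS[ct]
        assert max(per) - min(per) <= 1
    sizes = [sum(p.values()) for p in parts]
    assert sum(sizes) == 134


def test_split_counts_single_session_is_full():
    parts = split_counts_across_sessions(FULL_COUNTS, 1)
    assert parts == [FULL_COUNTS]
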