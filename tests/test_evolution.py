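import numpy as np
import pytest

from envdecode import evolution
from envdecode.evolution import (DEConfig, DEState, initialize, mutate,
                                 recombine, select, selection_probabilities,
                                 step)


def quad(target):
    def f(W):
        W = np.atleast_2d(W)
        return np.sum((W - target) ** 2, axis=1)
    return f


def test_config_validation():
    with pytest.raises(ValueError):
        DEConfig(n_pop=3)
    with pytest.raises(ValueError):
        DEConfig(crossover_rate=1.5)
    with pytest.raises(ValueError):
        DEConfig(crossover_mode="bogus")


def test_selection_probabilities_order_and_normalization():
    p = selection_probabilities(np.array([1.0, 2.0, 4.0]))
    assert p.sum() == pytest.approx(1.0)
    assert p[0] > p[1] > p[2]          # lower fitness, higher probability


def test_selection_probabilities_uniform_when_equal():
    p = selection_probabilities(np.array([3.0, 3.0, 3.0, 3.0]))
    np.testing.assert_allclose(p, 0.25)


def test_selection_probabilities_handles_nonpositive():
    p = selection_probabilities(np.array([-1.0, 0.0, 2.0]))
    assert p.sum() == pytest.approx(1.0)
    assert p[0] > p[1] > p[2]


def test_mutation_uses_three_distinct_donors():
    rng = np.random.default_rng(0)
    cfg = DEConfig(n_pop=5, vectorized_fitness=True)
    state = initialize(quad(np.zeros(3)), 3, cfg, rng)
    # F=0.5 mutation is a linear combination within the population span
    trial = mutate(state, 0, cfg, rng)
    assert trial.shape == (3,)


def test_recombine_forces_one_component():
    rng = np.random.default_rng(1)
    cfg = DEConfig(crossover_rate=0.0)   # nothing crosses except the forced one
    trial = np.ones(6)
    current = np.zeros(6)
    out = recombine(trial, current, cfg, rng)
    assert out.sum() == 1.0


def test_recombine_per_member_mode():
    rng = np.random.default_rng(2)
    cfg = DEConfig(crossover_mode="per_member", crossover_rate=1.0)
    out = recombine(np.ones(4), np.zeros(4), cfg, rng)
    np.testing.assert_array_equal(out, np.ones(4))


def test_select_is_strict():
    w, f = select(np.ones(2), np.zeros(2), 1.0, 1.0)
    np.testing.assert_array_equal(w, np.zeros(2))
    w, f = select(np.ones(2), np.zeros(2), 0.5, 1.0)
    np.testing.assert_array_equal(w, np.ones(2))


def test_step_never_worsens_members():
    cfg = DEConfig(n_pop=10, seed=3, vectorized_fitness=True)
    rng = np.random.default_rng(cfg.seed)
    state = initialize(quad(np.array([1.0, -1.0])), 2, cfg, rng)
    new = step(state, quad(np.array([1.0, -1.0])), cfg, rng)
    assert np.all(new.fitness <= state.fitness)
    assert new.generation == 1


def test_run_converges_on_quadratic():
    target = np.array([2.0, -1.0, 0.5])
    cfg = DEConfig(init_half_range=3.0, seed=4, vectorized_fitness=True,
                   termination_threshold=1e-6)
    res = evolution.run(quad(target), 3, cfg)
    assert res.converged
    np.testing.assert_allclose(res.weights, target, atol=0.01)
    best = res.history["best_fitness"].to_numpy()
    assert np.all(np.diff(best) <= 0)    # elitism: monotone non-increasing


def test_run_deterministic_in_seed():
    cfg = DEConfig(seed=5, vectorized_fitness=True, max_generations=30,
                   termination_threshold=0.0)
    a = evolution.run(quad(np.zeros(2)), 2, cfg)
    b = evolution.run(quad(np.zeros(2)), 2, cfg)
    np.testing.assert_array_equal(a.weights, b.weights)
    assert a.history.equals(b.history)


def test_run_reports_nonconvergence():
    cfg = DEConfig(seed=6, vectorized_fitness=True, max_generations=5,
                   termination_threshold=0.0)
    res = evolution.run(quad(np.zeros(4)), 4, cfg)
    assert not res.converged
    assert res.n_generations == 5
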