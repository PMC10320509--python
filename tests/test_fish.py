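import numpy as np
import pytest

from envdecode.decoder import fit_optimal_weights
from envdecode.evolution import DEConfig
from envdecode.fish import (fit_fish_decoder, global_fitness,
                            make_global_fitness, transfer_matrix)


def _toy_problem(rng, m=4, n_cond=3, t=300):
    rates, targets = [], []
    w_true = rng.standard_normal(m)
    for _ in range(n_cond):
        R = rng.standard_normal((m, t))
        targets.append(w_true @ R + 0.2 * rng.standard_normal(t))
        rates.append(R)
    return rates, targets, w_true


def test_global_fitness_is_sum_of_condition_rmses():
    rng = np.random.default_rng(0)
    rates, targets, _ = _toy_problem(rng)
    w = rng.standard_normal(4)
    total = global_fitness(w, rates, targets)
    manual = 0.0
    for R, S in zip(rates, targets):
        Rc = R - R.mean(axis=1, keepdims=True)
        Sc = S - S.mean()
        manual += np.sqrt(np.mean((w @ Rc - Sc) ** 2))
    assert total == pytest.approx(manual)


def test_global_fitness_batch_matches_loop():
    rng = np.random.default_rng(1)
    rates, targets, _ = _toy_problem(rng)
    W = rng.standard_normal((5, 4))
    batch = global_fitness(W, rates, targets)
    loop = [global_fitness(w, rates, targets) for w in W]
    np.testing.assert_allclose(batch, loop)


def test_make_global_fitness_enforces_condition_count():
    rng = np.random.default_rng(2)
    rates, targets, _ = _toy_problem(rng, n_cond=3)
    with pytest.raises(ValueError):
        make_global_fitness(rates, targets, n_conditions_expected=9)
    fn = make_global_fitness(rates, targets, n_conditions_expected=3)
    assert fn(np.zeros((1, 4))).shape == (1,)


def test_fish_decoder_approaches_closed_form():
    rng = np.random.default_rng(3)
    rates, targets, _ = _toy_problem(rng, m=4, n_cond=3, t=300)
    cfg = DEConfig(seed=0, vectorized_fitness=True,
                   termination_threshold=1e-5)
    fit = fit_fish_decoder(rates, targets, cfg, n_conditions_expected=3)
    # closed-form reference: pooled centered least squares
    Rc = np.concatenate([R - R.mean(axis=1, keepdims=True) for R in rates], 1)
    Sc = np.concatenate([S - S.mean() for S in targets])
    w_ls, *_ = np.linalg.lstsq(Rc.T, Sc, rcond=None)
    f_de = global_fitness(fit.weights.weights, rates, targets)
    f_ls = global_fitness(w_ls, rates, targets)
    assert f_de <= 1.05 * f_ls
    assert fit.weights.scope == "global"
    assert fit.weights.target_kind == "behavior"


def test_transfer_matrix_diagonal_is_best_on_average():
    rng = np.random.default_rng(4)
    m, t = 4, 400
    rates, targets, weights = {}, {}, {}
    for cid in ("a", "b"):
        R = rng.standard_normal((m, t))
        w = rng.standard_normal(m)
        S = w @ R + 0.1 * rng.standard_normal(t)
        rates[cid], targets[cid] = R, S
        weights[cid] = fit_optimal_weights(R, S, scope=cid)
    grid = transfer_matrix(weights, rates, targets)
    assert grid.shape == (2, 2)
    assert np.all(grid.to_numpy() > 0)
    assert grid.loc["a", "a"] > grid.loc["b", "a"]
    assert grid.loc["b", "b"] > grid.loc["a", "b"]
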