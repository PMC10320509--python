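import numpy as np
import pytest

from conftest import random_decoding_instance
from envdecode.decoder import (evaluation_rmse, fit_optimal_weights,
                               performance, predict, split_trials)


def test_matches_lstsq_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        R, S = random_decoding_instance(rng, t=500)
        w = fit_optimal_weights(R, S)
        Rc = R - R.mean(axis=1, keepdims=True)
        Sc = S - S.mean()
        w_ls, *_ = np.linalg.lstsq(Rc.T, Sc, rcond=None)
        np.testing.assert_allclose(w.weights, w_ls, atol=1e-8)


def test_perfect_reconstruction_when_noiseless():
    rng = np.random.default_rng(1)
    R = rng.standard_normal((4, 300))
    S = np.array([1.0, -2.0, 0.5, 3.0]) @ R + 7.0
    w = fit_optimal_weights(R, S)
    res = predict(w, R, S)
    assert res.rmse < 1e-8
    assert performance(res.predicted, S - w.target_mean) > 1e8


def test_training_means_used_at_evaluation():
    rng = np.random.default_rng(2)
    R, S = random_decoding_instance(rng, m=3, t=400)
    w = fit_optimal_weights(R, S)
    R2 = R + 5.0   # shifted evaluation rates
    r_manual = np.sqrt(np.mean((
        w.weights @ (R2 - w.rate_mean[:, None]) - (S - w.target_mean)) ** 2))
    assert evaluation_rmse(w, R2, S) == pytest.approx(r_manual)


def test_rcond_truncates_rank():
    rng = np.random.default_rng(3)
    base = rng.standard_normal(300)
    R = np.vstack([base, base + 1e-6 * rng.standard_normal(300),
                   rng.standard_normal(300)])
    S = base + rng.standard_normal(300)
    exact = fit_optimal_weights(R, S)
    trunc = fit_optimal_weights(R, S, rcond=1e-2)
    assert trunc.rank < exact.rank
    assert np.all(np.isfinite(trunc.weights))


def test_zero_variance_target_rejected():
    with pytest.raises(ValueError):
        fit_optimal_weights(np.random.default_rng(0).random((2, 50)),
                            np.ones(50))


def test_split_trials_halves():
    train, test = split_trials(list(range(20)))
    assert train == list(range(10)) and test == list(range(10, 20))
    train, test = split_trials([1, 2, 3])
    assert train == [1, 2] and test == [3]
    with pytest.raises(ValueError):
        split_trials([1])
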