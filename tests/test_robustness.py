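import numpy as np
import pytest

from envdecode.robustness import (DEFAULT_SIGMA_GRID, RobustnessCurve,
                                  compare_states, fit_attenuation_slope,
                                  performance_ratio, perturb_weights,
                                  robustness_curve)


def _quadratic_rmse(center):
    def fn(W):
        W = np.atleast_2d(W)
        return 1.0 + np.sum((W - center) ** 2, axis=1)
    return fn


def test_default_grid_shape():
    assert DEFAULT_SIGMA_GRID[0] == 0.0
    assert DEFAULT_SIGMA_GRID.size == 13
    assert DEFAULT_SIGMA_GRID[1] == pytest.approx(0.01)
    assert DEFAULT_SIGMA_GRID[-1] == pytest.approx(10.0)


def test_perturb_weights_statistics():
    w = np.array([1.0, -2.0, 3.0])
    P = perturb_weights(w, sigma=0.5, n_realizations=5000, seed=0)
    assert P.shape == (5000, 3)
    np.testing.assert_allclose(P.mean(axis=0), w, atol=0.05)
    np.testing.assert_allclose(P.std(axis=0), 0.5, atol=0.05)


def test_ratio_at_sigma_zero_is_exactly_100():
    w = np.array([0.3, -0.7])
    assert performance_ratio(_quadratic_rmse(w), w, sigma=0.0) == 100.0


def test_uniform_rmse_doubling_gives_exactly_50():
    w = np.array([1.0, 1.0])
    fn = _quadratic_rmse(w)

    def doubled(W):
        W = np.atleast_2d(W)
        out = fn(w[None, :])[0] * np.ones(W.shape[0])
        same = np.all(W == w[None, :], axis=1)
        return np.where(same, out, 2 * out)

    assert performance_ratio(doubled, w, sigma=0.1, seed=1) == 50.0


def test_curve_monotone_for_quadratic_rmse():
    w = np.array([0.5, -0.5, 1.0])
    curve = robustness_curve(_quadratic_rmse(w), w, seed=2)
    assert curve.mean_ratio[0] == 100.0
    assert np.all(curve.mean_ratio[1:] <= 100.0)
    assert curve.mean_ratio[-1] < curve.mean_ratio[1]


def test_curve_validation():
    with pytest.raises(ValueError):
        RobustnessCurve(sigma_grid=[0.0, 0.1], mean_ratio=[99.0, 80.0],
                        sigma_scale=1.0, n_realizations=30,
                        decoder_scope="local")
    with pytest.raises(ValueError):
        RobustnessCurve(sigma_grid=[0.2, 0.1], mean_ratio=[80.0, 90.0],
                        sigma_scale=1.0, n_realizations=30,
                        decoder_scope="local")


def test_common_noise_reproducible_across_states():
    rng = np.random.default_rng(3)
    Z = rng.standard_normal((30, 3))
    w1, w2 = np.array([1.0, 0.0, -1.0]), np.array([1.1, 0.1, -0.9])
    c1 = robustness_curve(_quadratic_rmse(w1), w1, sigma_scale=0.5,
                          common_noise=Z)
    c1b = robustness_curve(_quadratic_rmse(w1), w1, sigma_scale=0.5,
                           common_noise=Z)
    np.testing.assert_array_equal(c1.mean_ratio, c1b.mean_ratio)
    c2 = robustness_curve(_quadratic_rmse(w2), w2, sigma_scale=0.5,
                          common_noise=Z)
    assert not np.array_equal(c1.mean_ratio[1:], c2.mean_ratio[1:])


def test_slope_conventions():
    sig = np.array([0.0, 0.01, 0.1, 1.0, 10.0])
    # global: log10(ratio) linear in sigma with slope -0.1
    ratio_g = 100.0 * 10 ** (-0.1 * sig)
    ratio_g[0] = 100.0
    cg = RobustnessCurve(sig, ratio_g, 1.0, 30, "global")
    assert fit_attenuation_slope(cg) == pytest.approx(-0.1, abs=1e-9)
    assert cg.slope_convention == "log10(ratio) vs sigma"
    # local: ratio linear in log10(sigma) with slope -20
    ratio_l = 100.0 + -20.0 * np.log10(np.where(sig > 0, sig, 1.0))
    ratio_l[0] = 100.0
    cl = RobustnessCurve(sig, ratio_l, 1.0, 30, "local")
    assert fit_attenuation_slope(cl) == pytest.approx(-20.0, abs=1e-9)
    assert cl.slope_convention == "ratio vs log10(sigma)"


def test_slope_needs_three_points():
    c = RobustnessCurve(np.array([0.0, 0.1]), np.array([100.0, 90.0]),
                        1.0, 30, "local")
    with pytest.raises(ValueError):
        fit_attenuation_slope(c)


def test_compare_states_direction_and_counts():
    ctrl = [-1.0, -1.2, -0.8, -1.1, -0.9, -1.0, -1.05]
    inact = [c - 0.5 for c in ctrl]
    comp = compare_states(ctrl, inact, alternative="less")
    assert comp.n == 7 and comp.n_steeper == 7
    assert comp.p_value < 0.05 and comp.rejects
    two = compare_states(ctrl, inact)
    assert two.alternative == "two-sided"


def test_compare_states_degenerate():
    comp = compare_states([1.0, 2.0], [1.0, 2.0])
    assert comp.degenerate and not comp.rejects
    with pytest.raises(ValueError):
        compare_states([1.0], [2.0])
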