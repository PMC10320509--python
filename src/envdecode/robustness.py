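"""Weight-noise robustness: perturb decoder weights with iid
Gaussian noise, measure the performance ratio

    ratio(sigma) = 100 * <(1/RMSE)_sigma> / (1/RMSE)_{sigma=0}

averaged over realizations, fit attenuation slopes, and compare the control
and inactivated states across sessions.

Two distinct slope conventions are used, never mixed: the global (fish)
decoder regresses log10(ratio) on sigma; the
local decoder regresses ratio on log10(sigma) (excluding sigma=0).  "RMSE"
is the local decoder's per-condition RMSE or the global decoder's sum of
RMSEs, supplied here as an ``rmse_fn`` over weight vectors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon

#: Default sigma grid in units of SD(weights): 0 plus 12 log-spaced values.
DEFAULT_SIGMA_GRID = np.concatenate([[0.0], np.logspace(-2, 1, 12)])

DEFAULT_N_REALIZATIONS = 30


@dataclass
class RobustnessCurve:
    """Performance-ratio curve over a sigma grid."""

    sigma_grid: np.ndarray          # relative sigmas, units of sigma_scale
    mean_ratio: np.ndarray          # percentage per sigma
    sigma_scale: float              # weight units per grid unit
    n_realizations: int
    decoder_scope: str              # "local" or "global"
    state: str = ""
    session_id: str = ""
    condition_id: str = ""
    slope: float | None = None
    slope_convention: str = ""

    def __post_init__(self):
        self.sigma_grid = np.asarray(self.sigma_grid, float)
        self.mean_ratio = np.asarray(self.mean_ratio, float)
        if self.sigma_grid.size != self.mean_ratio.size:
            raise ValueError("grid and ratios must have equal length")
        if np.any(np.diff(self.sigma_grid) < 0):
            raise ValueError("sigma grid must be sorted ascending")
        if self.decoder_scope not in ("local", "global"):
            raise ValueError("decoder_scope must be 'local' or 'global'")
        zero = self.sigma_grid == 0
        if np.any(zero) and not np.all(self.mean_ratio[zero] == 100.0):
            raise ValueError("ratio at sigma=0 must equal 100 exactly")
        if np.any(self.mean_ratio < 0):
            raise ValueError("ratios must be non-negative")


def perturb_weights(weights: np.ndarray, sigma: float,
                    n_realizations: int = DEFAULT_N_REALIZATIONS,
                    seed: int = 0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """(n_realizations, M) perturbed copies: w + N(0, sigma^2) per component."""
    w = np.asarray(weights, float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = sigma * rng.standard_normal((n_realizations, w.size))
    return w[None, :] + noise


def performance_ratio(rmse_fn, weights: np.ndarray, sigma: float,
                      n_realizations: int = DEFAULT_N_REALIZATIONS,
                      seed: int = 0,
                      rng: np.random.Generator | None = None,
                      perturbations: np.ndarray | None = None) -> float:
    """Performance-ratio percentage for one sigma.

    ``rmse_fn`` maps a weight vector (or an (N, M) batch, in which case it
    must return an (N,) array) to the decoding RMSE.  ``perturbations`` may
    supply pre-drawn perturbed weight sets (e.g. common random numbers
    across states).
    """
    w = np.asarray(weights, float)
    r0 = _eval_rmse(rmse_fn, w[None, :])[0]
    if not np.isfinite(r0) or r0 == 0:
        raise ValueError("baseline RMSE must be finite and nonzero")
    if perturbations is None:
        perturbations = perturb_weights(w, sigma, n_realizations, seed, rng)
    if np.all(perturbations == w[None, :]):
        return 100.0     # sigma = 0: the ratio is exactly 100, no averaging noise
    rs = _eval_rmse(rmse_fn, perturbations)
    return float(100.0 * np.mean(1.0 / rs) / (1.0 / r0))


def _eval_rmse(rmse_fn, W: np.ndarray) -> np.ndarray:
    try:
        out = np.asarray(rmse_fn(W), float)
        if out.shape == (W.shape[0],):
            return out
    except Exception:
        pass
    return np.array([float(rmse_fn(w)) for w in W])


def robustness_curve(rmse_fn, weights: np.ndarray,
                     sigma_grid: np.ndarray | None = None,
                     sigma_scale: float | None = None,
                     n_realizations: int = DEFAULT_N_REALIZATIONS,
                     seed: int = 0,
                     decoder_scope: str = "local",
                     state: str = "", session_id: str = "",
                     condition_id: str = "",
                     common_noise: np.ndarray | None = None) -> RobustnessCurve:
    """Performance ratio evaluated over a sigma grid.

    Parameters
    ----------
    sigma_grid : relative sigmas; default 0 plus 12 log-spaced 0.01..10.
    sigma_scale : weight units per grid unit; default SD(weights).  Passing
        the SD of the *control-state* weights for both states makes the
        comparison share an absolute noise scale.
    common_noise : optional (n_realizations, M) standard-normal draws reused
        for every sigma (and, when shared by the caller, across states).
    """
    w = np.asarray(weights, float)
    grid = DEFAULT_SIGMA_GRID.copy() if sigma_grid is None else \
        np.asarray(sigma_grid, float)
    if grid.size == 0:
        raise ValueError("sigma grid must not be empty")
    scale = float(np.std(w)) if sigma_scale is None else float(sigma_scale)
    if scale <= 0:
        raise ValueError("sigma_scale must be positive")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_realizations, w.size)) \
        if common_noise is None else np.asarray(common_noise, float)
    if Z.shape != (n_realizations, w.size):
        raise ValueError("common_noise must be (n_realizations, M)")
    ratios = []
    for s in grid:
        pert = w[None, :] + (s * scale) * Z
        ratios.append(performance_ratio(rmse_fn, w, s * scale,
                                        n_realizations, perturbations=pert))
    return RobustnessCurve(sigma_grid=grid, mean_ratio=np.array(ratios),
                           sigma_scale=scale, n_realizations=n_realizations,
                           decoder_scope=decoder_scope, state=state,
                           session_id=session_id, condition_id=condition_id)


def fit_attenuation_slope(curve: RobustnessCurve,
                          decoder_scope: str | None = None) -> float:
    """Least-squares attenuation slope under the scope's convention.

    global: log10(ratio) regressed on sigma (sigma=0 included, ratio>0
    required); local: ratio regressed on log10(sigma) (sigma=0 excluded).
    More negative means performance falls off faster (less robust).
    """
    scope = decoder_scope or curve.decoder_scope
    sig = curve.sigma_grid
    ratio = curve.mean_ratio
    if scope == "global":
        keep = ratio > 0
        x, y = sig[keep], np.log10(ratio[keep])
    elif scope == "local":
        keep = (sig > 0) & (ratio > 0)
        x, y = np.log10(sig[keep]), ratio[keep]
    else:
        raise ValueError("decoder_scope must be 'local' or 'global'")
    if x.size < 3:
        raise ValueError("need >= 3 usable grid points for a slope fit")
    slope = float(np.polyfit(x, y, 1)[0])
    curve.slope = slope
    curve.slope_convention = ("log10(ratio) vs sigma" if scope == "global"
                              else "ratio vs log10(sigma)")
    return slope


@dataclass
class StateComparison:
    """Paired Wilcoxon comparison of per-session attenuation slopes."""

    differences: np.ndarray      # inactivated - control, one per session
    statistic: float
    p_value: float
    n: int
    alternative: str
    degenerate: bool = False
    n_steeper: int = 0           # sessions where inactivated is more negative

    @property
    def rejects(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05


def compare_states(control_slopes, inactivated_slopes,
                   alternative: str = "two-sided") -> StateComparison:
    """Wilcoxon signed-rank test on per-session slope differences.

    ``alternative='less'`` encodes the directional hypothesis that slopes
    are more negative (steeper attenuation) after inactivation; the default
    is two-sided.
    """
    c = np.asarray(control_slopes, float)
    i = np.asarray(inactivated_slopes, float)
    if c.shape != i.shape or c.ndim != 1:
        raise ValueError("state slope vectors must be paired 1-D arrays")
    if c.size < 2:
        raise ValueError("need >= 2 paired sessions for the signed-rank test")
    diff = i - c
    n_steeper = int(np.sum(diff < 0))
    if np.all(diff == 0):
        return StateComparison(differences=diff, statistic=float("nan"),
                               p_value=float("nan"), n=diff.size,
                               alternative=alternative, degenerate=True,
                               n_steeper=0)
    res = wilcoxon(diff, alternative=alternative)
    return StateComparison(differences=diff, statistic=float(res.statistic),
                           p_value=float(res.pvalue), n=diff.size,
                           alternative=alternative, n_steeper=n_steeper)
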