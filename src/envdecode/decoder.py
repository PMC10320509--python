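"""Local optimal linear decoding: closed-form weights and inverse-RMSE
performance.

A weighted sum of trial-averaged filtered firing rates predicts either the
envelope waveform or the behavioral (EOD-frequency) trace.  With the
time-means removed, the RMSE-minimizing weights have the closed form

    w = Cov(fR)^+ <fR S>

where Cov(fR) is the M x M time-covariance of the rates, <fR_i S> the
time cross-correlation of rate i with the target, and ^+ the Moore-Penrose
pseudo-inverse (the minimum-norm least-squares solution when the covariance
is rank deficient).  Weights are fit per condition ("local" decoder) on the
first half of trials and evaluated on the held-out half; performance is
1/RMSE.

A single envelope period smoothed at a fraction of a hertz holds only a few
effective temporal degrees of freedom, so the sample covariance of a
multi-neuron session is ill conditioned and the exact solution generalizes
poorly across trial halves.  `fit_optimal_weights` therefore accepts an
`rcond` spectral truncation threshold; the default (``None``) keeps the
exact pseudo-inverse, while the session pipeline passes a finite threshold
(see `pipeline`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DecoderWeights:
    weights: np.ndarray            # (M,)
    target_kind: str               # "stimulus" or "behavior"
    scope: str                     # condition_id for local, "global" otherwise
    state: str = ""                # feedback state used for training
    train_trials: tuple = ()
    rate_mean: np.ndarray | None = None   # training-segment rate means (M,)
    target_mean: float = 0.0              # training-segment target mean
    rank: int = -1                        # effective covariance rank used


@dataclass
class DecodingResult:
    predicted: np.ndarray
    rmse: float
    condition_id: str = ""
    state: str = ""

    @property
    def performance(self) -> float:
        """Inverse RMSE; infinite (flagged perfect) when rmse == 0."""
        return float("inf") if self.rmse == 0 else 1.0 / self.rmse


def split_trials(trials, fraction: float = 0.5):
    """First ceil(n * fraction) trials train, remainder test, order kept."""
    trials = list(trials)
    n = len(trials)
    if n < 2:
        raise ValueError("need at least two trials to split")
    k = int(np.ceil(n * fraction))
    k = min(max(k, 1), n - 1)
    return trials[:k], trials[k:]


def fit_optimal_weights(rates: np.ndarray, target: np.ndarray,
                        target_kind: str = "stimulus",
                        scope: str = "local", state: str = "",
                        rcond: float | None = None) -> DecoderWeights:
    """Closed-form RMSE-minimizing weights.

    Parameters
    ----------
    rates : (M, T) array
        Trial-averaged filtered firing rates (spikes/s); time-means are
        removed internally and recorded.
    target : (T,) array
        Target waveform on the same grid; its mean is removed and recorded.
    rcond : float or None
        Relative eigenvalue cutoff for the covariance pseudo-inverse.
        ``None`` keeps the exact (machine-precision) pseudo-inverse, which
        equals the unconstrained least-squares minimizer.

    Returns
    -------
    DecoderWeights
    """
    R = np.asarray(rates, float)
    S = np.asarray(target, float)
    if R.ndim != 2 or S.ndim != 1 or R.shape[1] != S.size:
        raise ValueError("rates must be (M, T) and target (T,)")
    mu_r = R.mean(axis=1)
    mu_s = float(S.mean())
    Rc = R - mu_r[:, None]
    Sc = S - mu_s
    if not np.any(Sc):
        raise ValueError("target waveform has zero variance")
    T = Rc.shape[1]
    cov = Rc @ Rc.T / T
    xcorr = Rc @ Sc / T
    eff_rcond = np.finfo(float).eps * max(cov.shape) if rcond is None else rcond
    pinv, rank = _pinv_with_rank(cov, eff_rcond)
    if rank < cov.shape[0]:
        logger.info("covariance rank %d < M=%d; pseudo-inverse truncated",
                    rank, cov.shape[0])
    w = pinv @ xcorr
    return DecoderWeights(weights=w, target_kind=target_kind, scope=scope,
                          state=state, rate_mean=mu_r, target_mean=mu_s,
                          rank=rank)


def _pinv_with_rank(cov: np.ndarray, rcond: float):
    evals, evecs = np.linalg.eigh(cov)
    thresh = rcond * evals.max() if evals.size else 0.0
    keep = evals > thresh
    inv = np.zeros_like(evals)
    inv[keep] = 1.0 / evals[keep]
    return (evecs * inv) @ evecs.T, int(keep.sum())


def predict(weights: DecoderWeights, rates: np.ndarray,
            target: np.ndarray | None = None,
            condition_id: str = "", state: str = "") -> DecodingResult:
    """Apply weights to (mean-removed) rates; RMSE against the target.

    Means recorded at training time are subtracted from both the rates and
    the target, so evaluation is consistent with the fit and leaks nothing
    from the test segment.
    """
    R = np.asarray(rates, float)
    if R.shape[0] != weights.weights.size:
        raise ValueError("weight length does not match number of neurons")
    mu_r = weights.rate_mean if weights.rate_mean is not None else R.mean(axis=1)
    pred = weights.weights @ (R - mu_r[:, None])
    if target is None:
        return DecodingResult(predicted=pred, rmse=float("nan"),
                              condition_id=condition_id, state=state)
    Sc = np.asarray(target, float) - weights.target_mean
    if Sc.size != pred.size:
        raise ValueError("rate and target grids do not match")
    return DecodingResult(predicted=pred,
                          rmse=float(np.sqrt(np.mean((pred - Sc) ** 2))),
                          condition_id=condition_id, state=state)


def performance(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Inverse RMSE between two mean-consistent waveforms."""
    r = float(np.sqrt(np.mean((np.asarray(predicted) - np.asarray(actual)) ** 2)))
    return float("inf") if r == 0 else 1.0 / r


def evaluation_rmse(weights: DecoderWeights, rates: np.ndarray,
                    target: np.ndarray) -> float:
    return predict(weights, rates, target).rmse
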