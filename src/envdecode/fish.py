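"""The "fish decoder": one weight vector over all nine conditions.

A single set of weights maps trial-averaged filtered rates to the behavioral
(EOD-frequency) trace in every condition at once.  The fitness is
the unweighted sum over conditions of the per-condition RMSE, with rates and
targets mean-removed per condition so conditions of different durations and
baselines are commensurable.  Weights are found with the differential
evolution optimizer, trained on the first half of control trials; the same
weights are then evaluated on the held-out control trials and on all
inactivated-state trials.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evolution
from .decoder import DecoderWeights
from .evolution import DEConfig, DEResult

logger = logging.getLogger(__name__)


def _center_condition(rates: np.ndarray, target: np.ndarray):
    R = np.asarray(rates, float)
    S = np.asarray(target, float)
    if R.ndim != 2 or S.ndim != 1 or R.shape[1] != S.size:
        raise ValueError("each condition needs (M, T) rates and a (T,) target")
    return R - R.mean(axis=1, keepdims=True), S - S.mean()


def global_fitness(weights: np.ndarray, rates_by_condition,
                   targets_by_condition) -> float | np.ndarray:
    """Sum over conditions of RMSE(w . fR_c, S_c), mean-removed.

    `weights` may be a single (M,) vector or an (N, M) batch; the batch form
    returns an (N,) fitness array (used by the vectorized DE path).
    """
    rates_by_condition = list(rates_by_condition)
    targets_by_condition = list(targets_by_condition)
    if not rates_by_condition or \
            len(rates_by_condition) != len(targets_by_condition):
        raise ValueError("need matching, non-empty rates and targets lists")
    W = np.asarray(weights, float)
    single = W.ndim == 1
    if single:
        W = W[None, :]
    total = np.zeros(W.shape[0])
    for R, S in zip(rates_by_condition, targets_by_condition):
        Rc, Sc = _center_condition(R, S)
        if W.shape[1] != Rc.shape[0]:
            raise ValueError("weight length does not match neuron count")
        err = W @ Rc - Sc[None, :]
        total += np.sqrt(np.mean(err ** 2, axis=1))
    return float(total[0]) if single else total


def make_global_fitness(rates_by_condition, targets_by_condition,
                        n_conditions_expected: int | None = 9):
    """Vectorized fitness closure over pre-centered condition data.

    The global decoder is defined over the full stimulus set; by default a
    session missing any of the nine conditions is rejected
    (`n_conditions_expected=None` lifts the check, e.g. for reduced tests).
    """
    rates_by_condition = [np.asarray(R, float) for R in rates_by_condition]
    targets_by_condition = [np.asarray(S, float) for S in targets_by_condition]
    if n_conditions_expected is not None and \
            len(rates_by_condition) != n_conditions_expected:
        raise ValueError(
            f"global decoder needs all {n_conditions_expected} conditions, "
            f"got {len(rates_by_condition)}")
    centered = [_center_condition(R, S)
                for R, S in zip(rates_by_condition, targets_by_condition)]

    def fitness(W: np.ndarray) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, float))
        total = np.zeros(W.shape[0])
        for Rc, Sc in centered:
            err = W @ Rc - Sc[None, :]
            total += np.sqrt(np.mean(err ** 2, axis=1))
        return total

    return fitness


@dataclass
class FishDecoderFit:
    """Control-trained global weights plus the DE convergence record."""

    weights: DecoderWeights
    de_result: DEResult

    @property
    def converged(self) -> bool:
        return self.de_result.converged


def fit_fish_decoder(train_rates_by_condition, train_targets_by_condition,
                     de_config: DEConfig | None = None,
                     state: str = "control",
                     n_conditions_expected: int | None = 9,
                     weight_scale: float | None = None) -> FishDecoderFit:
    """Fit the global decoder with DE on (control) training data.

    Parameters
    ----------
    train_rates_by_condition, train_targets_by_condition :
        Per-condition (M, T_c) trial-averaged rates and (T_c,) behavior
        targets from the training trial half.
    weight_scale :
        Sets the DE initialization half-range in weight units; defaults to
        the scale of the closed-form least-squares solution on the pooled
        conditions, so the initial population brackets the optimum.
    """
    de_config = de_config or DEConfig(vectorized_fitness=True)
    fitness = make_global_fitness(train_rates_by_condition,
                                  train_targets_by_condition,
                                  n_conditions_expected)
    M = np.asarray(train_rates_by_condition[0]).shape[0]
    if weight_scale is None:
        weight_scale = _least_squares_scale(train_rates_by_condition,
                                            train_targets_by_condition)
    cfg_kwargs = {k: getattr(de_config, k) for k in (
        "n_pop", "mutation_factor", "crossover_rate", "crossover_mode",
        "termination_window", "termination_threshold", "max_generations",
        "seed")}
    cfg = DEConfig(init_half_range=de_config.init_half_range * weight_scale,
                   vectorized_fitness=True, **cfg_kwargs)
    result = evolution.run(fitness, M, cfg)
    if not result.converged:
        logger.warning("fish decoder DE did not converge (fitness %.4g)",
                       result.fitness)
    means = [np.asarray(R, float).mean(axis=1) for R in train_rates_by_condition]
    weights = DecoderWeights(weights=result.weights, target_kind="behavior",
                             scope="global", state=state,
                             rate_mean=np.mean(means, axis=0),
                             target_mean=float(np.mean(
                                 [np.mean(t) for t in train_targets_by_condition])),
                             rank=M)
    return FishDecoderFit(weights=weights, de_result=result)


def _least_squares_scale(rates_by_condition, targets_by_condition) -> float:
    """Scale (SD) of the pooled closed-form least-squares weights."""
    Rc, Sc = [], []
    for R, S in zip(rates_by_condition, targets_by_condition):
        r, s = _center_condition(R, S)
        Rc.append(r)
        Sc.append(s)
    R = np.concatenate(Rc, axis=1)
    S = np.concatenate(Sc)
    w, *_ = np.linalg.lstsq(R.T, S, rcond=1e-2)
    sd = float(np.std(w))
    return sd if sd > 0 else 1.0


def transfer_matrix(weights_by_condition: dict,
                    test_rates_by_condition: dict,
                    test_targets_by_condition: dict) -> pd.DataFrame:
    """Cross-condition performance grid for the local decoders.

    Entry (a, b) is the performance (1/RMSE) of condition-a weights applied
    to condition b's evaluation data.  Rates and target are centered on the
    evaluation condition's own means, so cross-condition entries measure
    waveform mismatch rather than baseline offsets.
    """
    cids = list(weights_by_condition)
    grid = np.empty((len(cids), len(cids)))
    for i, a in enumerate(cids):
        w = weights_by_condition[a]
        wv = w.weights if isinstance(w, DecoderWeights) else np.asarray(w, float)
        for j, b in enumerate(cids):
            Rc, Sc = _center_condition(test_rates_by_condition[b],
                                       test_targets_by_condition[b])
            rmse = float(np.sqrt(np.mean((wv @ Rc - Sc) ** 2)))
            grid[i, j] = np.inf if rmse == 0 else 1.0 / rmse
    return pd.DataFrame(grid, index=cids, columns=cids)
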