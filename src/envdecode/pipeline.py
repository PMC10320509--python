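"""End-to-end experiment: paired control/inactivated sessions through
simulation, spike processing, local and global decoding, weight-noise
robustness, and the summary report.

Paired design and variance reduction
------------------------------------
Each session's inactivated state is simulated with the *same* simulation
seed as its control, so the carrier, the Bernoulli draws and the behavioral
noise stream are common random numbers; only the homogenized ON-low phases
and the attenuated behavioral gain differ.  Robustness perturbations reuse
one standard-normal draw per (session, scope, condition) across both states
and all sigmas, and both states share an absolute noise scale set by the SD
of the control-state weights.

Robustness protocol
-------------------
Local decoders are fit per condition and state on the training trial half
and perturbed on the held-out half; a session's local slope is the median
of the nine per-condition slopes (ratio vs log10 sigma).  The global (fish)
decoder is refit per state with the DE optimizer — both states' data are
processed in the same manner — and perturbed on the held-out halves under
the global convention (log10 ratio vs sigma).  The control-trained fish
decoder is additionally evaluated, unchanged, on all inactivated-state
trials (the behavioral-transfer contract).
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import make_conditions
from .decoder import fit_optimal_weights, predict
from .evolution import DEConfig
from .fish import FishDecoderFit, fit_fish_decoder, make_global_fitness
from .population import (FULL_COUNTS, apply_feedback_inactivation,
                         sample_population, split_counts_across_sessions)
from .robustness import (StateComparison, compare_states,
                         fit_attenuation_slope, robustness_curve)
from .signal_processing import (bin_spikes, butterworth_rate, classify_polarity,
                                compute_sta, correlation_summary,
                                estimate_tuning, pairwise_correlations)
from .simulate import simulate_session
from .stats import ks_two_sample, paired_compare, pearson

logger = logging.getLogger(__name__)

STAGES = ("simulate", "process", "decode_local", "decode_global",
          "robustness", "report")

STATES = ("control", "inactivated")

DEFAULT_CONFIG = {
    "stimulus": {
        "base_amplitude": 1.0,
        "contrast_fractions": [0.091, 0.232, 0.497],
        "n_trials": 20,
    },
    "population": {
        "n_sessions": 7,
        "total_counts": None,          # None -> the full six-type counts
    },
    "inactivation": {
        "target_type": ["ON", "low"],
        "kappa_new": 8.0,
        "behavior_attenuation": 0.5,
    },
    "decoder": {
        "rcond": 1e-2,
        "train_fraction": 0.5,
    },
    "de": {
        "n_pop": 50,
        "mutation_factor": 0.5,
        "crossover_rate": 0.9,
        "crossover_mode": "per_component",
        "init_half_range": 1.0,
        "termination_window": 20,
        "termination_threshold": 1e-3,
        "max_generations": 2000,
    },
    "robustness": {
        "sigma_min": 0.01,             # units of SD(control weights)
        "sigma_max": 0.5,
        "n_sigma": 12,
        "n_realizations": 30,
        "alternative": "less",         # directional: steeper after inactivation
    },
    "stats": {
        "high_corr_threshold": 0.9,
        "lilliefors_alpha": 0.05,
    },
}


class PipelineError(RuntimeError):
    """A stage-labeled pipeline failure (partial outputs are retained)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def resolve_config(config: dict | None = None) -> dict:
    """Merge a partial config over the defaults (one nesting level deep)."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (config or {}).items():
        if section not in merged:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in merged[section]:
                raise ValueError(f"unknown key {section}.{key}")
            merged[section][key] = val
    return merged


def load_config(path) -> dict:
    """Read a YAML or JSON config file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        return yaml.safe_load(text) or {}
    return json.loads(text)


def config_hash(config: dict, seed: int) -> str:
    """Stable hash of the resolved config and the master seed."""
    blob = json.dumps({"config": config, "seed": seed}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic child seed (< 2**31) from the master seed and keys."""
    blob = json.dumps([int(master_seed), *[str(k) for k in keys]])
    digest = hashlib.sha256(blob.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def sigma_grid_from_config(rb: dict) -> np.ndarray:
    return np.concatenate([
        [0.0],
        np.logspace(np.log10(rb["sigma_min"]), np.log10(rb["sigma_max"]),
                    int(rb["n_sigma"]))])


# ---------------------------------------------------------------------------
# per-session computations
# ---------------------------------------------------------------------------

def build_session_pair(config: dict, seed: int, session_index: int):
    """Sample the paired populations and simulate both states (CRN)."""
    st = config["stimulus"]
    conditions = make_conditions(base_amplitude=st["base_amplitude"],
                                 contrast_fractions=st["contrast_fractions"],
                                 n_trials=st["n_trials"])
    pop_cfg = config["population"]
    totals = pop_cfg["total_counts"]
    if totals is not None:
        totals = {tuple(json.loads(k)) if isinstance(k, str) else tuple(k): v
                  for k, v in totals.items()}
    counts = split_counts_across_sessions(totals, pop_cfg["n_sessions"])
    ina = config["inactivation"]
    pop_c = sample_population(
        counts[session_index],
        seed=derive_seed(seed, "population", session_index),
        session_id=f"session{session_index}")
    pop_i, extra = apply_feedback_inactivation(
        pop_c, target_type=tuple(ina["target_type"]),
        kappa_new=ina["kappa_new"],
        behavior_attenuation=ina["behavior_attenuation"],
        seed=derive_seed(seed, "inactivation", session_index))
    sim_seed = derive_seed(seed, "simulate", session_index)
    sessions = {
        "control": simulate_session(pop_c, conditions, seed=sim_seed,
                                    feedback_state="control"),
        "inactivated": simulate_session(
            pop_i, conditions,
            behavior_params={"attenuation": extra["behavior_attenuation"]},
            seed=sim_seed, feedback_state="inactivated"),
    }
    return conditions, sessions


def process_state(session, conditions, train_fraction: float = 0.5):
    """Rates and response statistics for one session state.

    Returns a dict with per-condition trial-averaged Butterworth rates for
    the training half, the held-out half and all trials, plus correlation
    and tuning tables.
    """
    rates = {"train": {}, "test": {}, "all": {}}
    corr_frames = []
    tuning_rows = []
    for cond in conditions:
        cid = cond.condition_id
        per_neuron = session.spike_times[cid]
        n_trials = cond.n_trials
        k = max(1, min(int(np.ceil(n_trials * train_fraction)), n_trials - 1))
        mean_bin = {"train": [], "test": [], "all": []}
        for nid, trials in enumerate(per_neuron):
            mat = np.stack([bin_spikes(t, cond.duration).values
                            for t in trials]).astype(float)
            mean_bin["train"].append(mat[:k].mean(axis=0))
            mean_bin["test"].append(mat[k:].mean(axis=0))
            mean_bin["all"].append(mat.mean(axis=0))
            tune = estimate_tuning(trials, cond.envelope_frequency,
                                   cond.envelope_amplitude, cond.duration)
            neuron = session.population.neurons[nid]
            tuning_rows.append({
                "session_id": session.population.session_id,
                "state": session.feedback_state, "condition_id": cid,
                "neuron_id": neuron.neuron_id, "polarity": neuron.polarity,
                "rate_class": neuron.rate_class, "gain": tune.gain,
                "preferred_phase": tune.preferred_phase,
                "true_gain": neuron.envelope_gain(cond.envelope_frequency),
                "true_phase": neuron.envelope_phase,
            })
        for scope in rates:
            rates[scope][cid] = butterworth_rate(
                np.stack(mean_bin[scope]), cond.envelope_frequency).rate
        types = [n.cell_type for n in session.population.neurons]
        corr = pairwise_correlations(rates["all"][cid], neuron_types=types,
                                     condition_id=cid,
                                     state=session.feedback_state)
        corr["session_id"] = session.population.session_id
        target = ("ON", "low")
        corr["both_target_type"] = [
            types[int(i)] == target and types[int(j)] == target
            for i, j in zip(corr["i"], corr["j"])]
        corr_frames.append(corr)
    # ON/OFF classification from the carrier STA; use the condition with the
    # most samples (longest duration, then highest contrast) for SNR
    sta_cond = max(conditions, key=lambda c: (c.n_samples, c.contrast_level))
    sta_rows = []
    for nid, trials in enumerate(session.spike_times[sta_cond.condition_id]):
        neuron = session.population.neurons[nid]
        try:
            _, slope = compute_sta(trials, session.carriers[sta_cond.condition_id])
            called = classify_polarity(slope)
        except ValueError:
            slope, called = float("nan"), "unclassified"
        sta_rows.append({
            "session_id": session.population.session_id,
            "state": session.feedback_state, "neuron_id": neuron.neuron_id,
            "sta_slope": slope, "polarity_called": called,
            "polarity_true": neuron.polarity,
        })
    return {
        "rates": rates,
        "correlations": pd.concat(corr_frames, ignore_index=True),
        "tuning": pd.DataFrame(tuning_rows),
        "sta": pd.DataFrame(sta_rows),
        "train_trials": k,
    }


def fit_local_decoders(processed, conditions, session, rcond: float):
    """Per-condition stimulus decoders for one state; weights + RMSE rows."""
    weights = {}
    rows = []
    for cond in conditions:
        cid = cond.condition_id
        w = fit_optimal_weights(processed["rates"]["train"][cid],
                                session.envelopes[cid],
                                target_kind="stimulus", scope=cid,
                                state=session.feedback_state, rcond=rcond)
        res = predict(w, processed["rates"]["test"][cid],
                      session.envelopes[cid], condition_id=cid,
                      state=session.feedback_state)
        weights[cid] = w
        rows.append({
            "session_id": session.population.session_id,
            "state": session.feedback_state, "condition_id": cid,
            "test_rmse": res.rmse, "performance": res.performance,
            "rank": w.rank,
        })
    return weights, rows


def _behavior_targets(session, conditions, scope: str, train_fraction: float):
    """Behavior targets per condition.

    The behavioral trace is a single session-level recording per condition
    (not per trial), so the same trace is the target for either trial half.
    """
    del scope, train_fraction
    return [session.behavior[c.condition_id] for c in conditions]


def fit_global_decoders(processed_by_state, conditions, sessions,
                        config: dict, seed: int, session_index: int):
    """Per-state fish-decoder fits plus the control-trained transfer row."""
    de_cfg = config["de"]
    fits: dict[str, FishDecoderFit] = {}
    for state in STATES:
        cfg = DEConfig(vectorized_fitness=True,
                       seed=derive_seed(seed, "de", session_index, state),
                       **{k: de_cfg[k] for k in (
                           "n_pop", "mutation_factor", "crossover_rate",
                           "crossover_mode", "init_half_range",
                           "termination_window", "termination_threshold",
                           "max_generations")})
        rates = [processed_by_state[state]["rates"]["train"][c.condition_id]
                 for c in conditions]
        targets = _behavior_targets(sessions[state], conditions, "train",
                                    config["decoder"]["train_fraction"])
        fits[state] = fit_fish_decoder(rates, targets, cfg, state=state,
                                       n_conditions_expected=len(conditions))
    # transfer contract: control weights on held-out control and on all
    # inactivated trials
    w_ctrl = fits["control"].weights.weights
    rows = []
    for state, scope in (("control", "test"), ("inactivated", "all")):
        fit_eval = make_global_fitness(
            [processed_by_state[state]["rates"][scope][c.condition_id]
             for c in conditions],
            _behavior_targets(sessions[state], conditions, scope,
                              config["decoder"]["train_fraction"]),
            n_conditions_expected=len(conditions))
        rows.append({
            "session_id": sessions[state].population.session_id,
            "eval_state": state, "eval_scope": scope,
            "sum_rmse_control_weights": float(fit_eval(w_ctrl)[0]),
            "sum_rmse_state_weights": float(
                fit_eval(fits[state].weights.weights)[0]),
            "de_converged": fits[state].converged,
            "de_generations": fits[state].de_result.n_generations,
        })
    return fits, rows


def _centered_eval(rates: np.ndarray, target: np.ndarray):
    Rc = rates - rates.mean(axis=1, keepdims=True)
    Sc = target - target.mean()
    return Rc, Sc


def _local_rmse_fn(rates: np.ndarray, target: np.ndarray):
    Rc, Sc = _centered_eval(np.asarray(rates, float), np.asarray(target, float))

    def rmse(W):
        W = np.atleast_2d(np.asarray(W, float))
        return np.sqrt(np.mean((W @ Rc - Sc[None, :]) ** 2, axis=1))

    return rmse


def _global_rmse_fn(rates_list, targets_list):
    centered = [_centered_eval(np.asarray(R, float), np.asarray(S, float))
                for R, S in zip(rates_list, targets_list)]

    def rmse(W):
        W = np.atleast_2d(np.asarray(W, float))
        total = np.zeros(W.shape[0])
        for Rc, Sc in centered:
            total += np.sqrt(np.mean((W @ Rc - Sc[None, :]) ** 2, axis=1))
        return total

    return rmse


def run_session_robustness(processed_by_state, conditions, sessions,
                           local_weights, fish_fits, config: dict,
                           seed: int, session_index: int):
    """Robustness curves and slopes for one session, both states.

    The sigma scale comes from the control-state weights and the
    standard-normal perturbation draws are shared across states.
    """
    rb = config["robustness"]
    grid = sigma_grid_from_config(rb)
    n_real = int(rb["n_realizations"])
    curves = []
    slope_rows = []
    local_slopes = {}
    sid = sessions["control"].population.session_id
    for state in STATES:
        per_cond = []
        for cond in conditions:
            cid = cond.condition_id
            w = local_weights[state][cid].weights
            scale = float(np.std(local_weights["control"][cid].weights))
            Z = np.random.default_rng(
                derive_seed(seed, "perturb", session_index, "local", cid)
            ).standard_normal((n_real, w.size))
            fn = _local_rmse_fn(processed_by_state[state]["rates"]["test"][cid],
                                sessions[state].envelopes[cid])
            curve = robustness_curve(fn, w, sigma_grid=grid,
                                     sigma_scale=scale, n_realizations=n_real,
                                     decoder_scope="local", state=state,
                                     session_id=sid, condition_id=cid,
                                     common_noise=Z)
            per_cond.append(fit_attenuation_slope(curve))
            curves.append(curve)
        local_slopes[state] = float(np.median(per_cond))
        slope_rows.append({"session_id": sid, "state": state, "scope": "local",
                           "slope": local_slopes[state]})
    global_slopes = {}
    scale_g = float(np.std(fish_fits["control"].weights.weights))
    Zg = {}
    for state in STATES:
        w = fish_fits[state].weights.weights
        Z = Zg.setdefault(w.size, np.random.default_rng(
            derive_seed(seed, "perturb", session_index, "global")
        ).standard_normal((n_real, w.size)))
        fn = _global_rmse_fn(
            [processed_by_state[state]["rates"]["test"][c.condition_id]
             for c in conditions],
            _behavior_targets(sessions[state], conditions, "test",
                              config["decoder"]["train_fraction"]))
        curve = robustness_curve(fn, w, sigma_grid=grid, sigma_scale=scale_g,
                                 n_realizations=n_real, decoder_scope="global",
                                 state=state, session_id=sid,
                                 common_noise=Z)
        global_slopes[state] = fit_attenuation_slope(curve)
        curves.append(curve)
        slope_rows.append({"session_id": sid, "state": state, "scope": "global",
                           "slope": global_slopes[state]})
    return curves, slope_rows, local_slopes, global_slopes


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def _comparison_dict(comp: StateComparison) -> dict:
    return {
        "n": comp.n, "statistic": comp.statistic, "p_value": comp.p_value,
        "alternative": comp.alternative, "degenerate": comp.degenerate,
        "n_steeper_after_inactivation": comp.n_steeper,
        "mean_difference": float(np.mean(comp.differences)),
        "differences": [float(d) for d in comp.differences],
    }


def _curves_frame(curves) -> pd.DataFrame:
    rows = []
    for c in curves:
        for s, r in zip(c.sigma_grid, c.mean_ratio):
            rows.append({"session_id": c.session_id, "state": c.state,
                         "scope": c.decoder_scope, "condition_id": c.condition_id,
                         "sigma": float(s), "sigma_scale": c.sigma_scale,
                         "mean_ratio": float(r)})
    return pd.DataFrame(rows)


def _weights_frame(local_by_session, fish_by_session) -> pd.DataFrame:
    rows = []
    for sid, per_state in local_by_session.items():
        for state, by_cond in per_state.items():
            for cid, w in by_cond.items():
                for nid, val in enumerate(w.weights):
                    rows.append({"session_id": sid, "state": state,
                                 "scope": cid, "neuron_id": nid,
                                 "weight": float(val)})
    for sid, per_state in fish_by_session.items():
        for state, fit in per_state.items():
            for nid, val in enumerate(fit.weights.weights):
                rows.append({"session_id": sid, "state": state,
                             "scope": "global", "neuron_id": nid,
                             "weight": float(val)})
    return pd.DataFrame(rows)


def run_experiment(config: dict | None = None, seed: int = 0,
                   outdir=None, stages=STAGES,
                   save_spikes: bool = False) -> dict:
    """Run the experiment end to end (or a prefix of stages).

    Returns the report bundle as a dict; when `outdir` is given, every table
    is also written as CSV and the report as JSON, each carrying the config
    hash and master seed.  Failures raise `PipelineError` labeled with the
    stage; outputs of completed stages are already on disk.
    """
    cfg = resolve_config(config)
    chash = config_hash(cfg, seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(
            {"config": cfg, "seed": seed, "config_hash": chash}, indent=2,
            sort_keys=True))
    stages = tuple(stages)
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
    want = {st: st in stages for st in STAGES}
    n_sessions = cfg["population"]["n_sessions"]
    t0 = time.time()

    report = {"config_hash": chash, "seed": seed, "stages": list(stages),
              "n_sessions": n_sessions}
    corr_frames, tuning_frames, sta_frames = [], [], []
    local_rmse_rows, fish_rows, slope_rows, curve_list = [], [], [], []
    local_by_session, fish_by_session = {}, {}
    local_slopes = {st: [] for st in STATES}
    global_slopes = {st: [] for st in STATES}
    behavior_amp = {st: [] for st in STATES}
    clipped = []

    for s in range(n_sessions):
        stage = "simulate"
        try:
            conditions, sessions = build_session_pair(cfg, seed, s)
        except Exception as e:     # noqa: BLE001 - re-labeled below
            raise PipelineError(stage, str(e)) from e
        sid = sessions["control"].population.session_id
        clipped.append({st: sessions[st].clipped_fraction for st in STATES})
        for st in STATES:
            amp = sessions[st].behavior_params["gain"] * \
                sessions[st].behavior_params.get("attenuation", 1.0)
            behavior_amp[st].append(amp)
        if save_spikes and out is not None:
            from .storage import save_session
            for st in STATES:
                save_session(sessions[st], out / "sessions" / f"{sid}_{st}",
                             config_hash=chash)
        if not want["process"]:
            continue

        stage = "process"
        try:
            processed = {st: process_state(sessions[st], conditions,
                                           cfg["decoder"]["train_fraction"])
                         for st in STATES}
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        for st in STATES:
            corr_frames.append(processed[st]["correlations"])
            tuning_frames.append(processed[st]["tuning"])
            sta_frames.append(processed[st]["sta"])
        if not want["decode_local"]:
            continue

        stage = "decode_local"
        try:
            local_by_session[sid] = {}
            for st in STATES:
                w, rows = fit_local_decoders(processed[st], conditions,
                                             sessions[st],
                                             cfg["decoder"]["rcond"])
                local_by_session[sid][st] = w
                local_rmse_rows.extend(rows)
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        if not want["decode_global"]:
            continue

        stage = "decode_global"
        try:
            fits, rows = fit_global_decoders(processed, conditions, sessions,
                                             cfg, seed, s)
            fish_by_session[sid] = fits
            fish_rows.extend(rows)
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        if not want["robustness"]:
            continue

        stage = "robustness"
        try:
            curves, srows, loc, glo = run_session_robustness(
                processed, conditions, sessions, local_by_session[sid],
                fits, cfg, seed, s)
            curve_list.extend(curves)
            slope_rows.extend(srows)
            for st in STATES:
                local_slopes[st].append(loc[st])
                global_slopes[st].append(glo[st])
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        logger.info("session %d/%d done (%.0f s elapsed)", s + 1, n_sessions,
                    time.time() - t0)

    # ---- assemble tables -------------------------------------------------
    tables = {}
    if corr_frames:
        tables["correlations"] = pd.concat(corr_frames, ignore_index=True)
        tables["tuning"] = pd.concat(tuning_frames, ignore_index=True)
        tables["sta"] = pd.concat(sta_frames, ignore_index=True)
    if local_rmse_rows:
        tables["rmse_local"] = pd.DataFrame(local_rmse_rows)
    if fish_rows:
        tables["fish_eval"] = pd.DataFrame(fish_rows)
    if local_by_session and (want["decode_global"] or want["decode_local"]):
        tables["weights"] = _weights_frame(local_by_session, fish_by_session)
    if curve_list:
        tables["robustness_curves"] = _curves_frame(curve_list)
        tables["robustness_slopes"] = pd.DataFrame(slope_rows)

    report["clipped_fraction"] = clipped
    logger.info("computation finished (%.1f s)", time.time() - t0)

    # ---- report stage ----------------------------------------------------
    if want["report"]:
        stage = "report"
        try:
            report.update(_build_report(cfg, tables, local_slopes,
                                        global_slopes, behavior_amp))
        except Exception as e:
            raise PipelineError(stage, str(e)) from e

    if out is not None:
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
    report["tables"] = tables
    return report


def _build_report(cfg, tables, local_slopes, global_slopes, behavior_amp):
    rep = {}
    thr = cfg["stats"]["high_corr_threshold"]
    if "correlations" in tables:
        corr = tables["correlations"]
        by_state = {}
        for st in STATES:
            sub = corr[corr["state"] == st]
            summ = correlation_summary(sub, high=thr)
            wt = sub[sub["both_target_type"]]
            summ["frac_above_within_target_type"] = (
                float(np.mean(wt["r"] > thr)) if len(wt) else float("nan"))
            summ["n_pairs_within_target_type"] = int(len(wt))
            by_state[st] = summ
        rep["correlation_summary"] = by_state
        D, p = ks_two_sample(corr[corr["state"] == "control"]["r"],
                             corr[corr["state"] == "inactivated"]["r"])
        rep["correlation_ks"] = {"D": D, "p_value": p}
    if "sta" in tables:
        sta = tables["sta"]
        ok = sta["polarity_called"] != "unclassified"
        rep["sta_polarity_accuracy"] = float(np.mean(
            sta.loc[ok, "polarity_called"] == sta.loc[ok, "polarity_true"]))
    n_done = len(local_slopes["control"])
    alt = cfg["robustness"]["alternative"]
    if n_done >= 2:
        comps = {}
        for scope, slopes in (("local", local_slopes), ("global", global_slopes)):
            comps[scope] = {
                "configured": _comparison_dict(compare_states(
                    slopes["control"], slopes["inactivated"], alternative=alt)),
                "two_sided": _comparison_dict(compare_states(
                    slopes["control"], slopes["inactivated"],
                    alternative="two-sided")),
            }
        rep["robustness_comparison"] = comps
        pc = paired_compare(behavior_amp["control"], behavior_amp["inactivated"]) \
            if len(set(behavior_amp["control"])) > 1 else None
        rep["behavior_attenuation"] = {
            "control_mean_gain": float(np.mean(behavior_amp["control"])),
            "inactivated_mean_gain": float(np.mean(behavior_amp["inactivated"])),
            "paired_test": None if pc is None else {
                "test_used": pc.test_used, "p_value": pc.p_value},
        }
    elif n_done == 1:
        rep["robustness_comparison"] = {
            "skipped": "across-session tests need >= 2 sessions"}
    if "tuning" in tables:
        tun = tables["tuning"]
        ctrl = tun[tun["state"] == "control"]
        good = ctrl[ctrl["true_gain"] > 0]
        rel_err = np.abs(good["gain"] - good["true_gain"]) / good["true_gain"]
        rep["tuning_gain_median_rel_error"] = float(np.median(rel_err))
        rep["tuning_gain_vs_true_pearson"] = pearson(good["gain"],
                                                     good["true_gain"])
    return rep
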