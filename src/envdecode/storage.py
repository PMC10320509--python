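"""Text-based on-disk interchange for simulated sessions.

A session state is written as a directory with three files:

- ``spikes.csv``  — condition_id, neuron_id, trial, spike_time (s)
- ``traces.csv``  — condition_id, sample, envelope, carrier, behavior
- ``meta.json``   — session/population metadata, behavior parameters,
  stimulus conditions, simulation seed and (optionally) the config hash

The round trip is exact up to CSV float formatting (repr round-trips
doubles, so in practice bit-exact).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import StimulusCondition
from .population import NeuronSpec, PopulationSpec
from .simulate import SessionData


def save_session(session: SessionData, outdir, config_hash: str = "") -> Path:
    """Write one session state; returns the directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    spike_rows = []
    for cond in session.conditions:
        cid = cond.condition_id
        for nid, trials in enumerate(session.spike_times[cid]):
            for trial, times in enumerate(trials):
                for t in np.asarray(times, float):
                    spike_rows.append((cid, nid, trial, float(t)))
    pd.DataFrame(spike_rows, columns=["condition_id", "neuron_id", "trial",
                                      "spike_time"]) \
        .to_csv(out / "spikes.csv", index=False)

    trace_frames = []
    for cond in session.conditions:
        cid = cond.condition_id
        trace_frames.append(pd.DataFrame({
            "condition_id": cid,
            "sample": np.arange(cond.n_samples),
            "envelope": session.envelopes[cid],
            "carrier": session.carriers[cid],
            "behavior": session.behavior[cid],
        }))
    pd.concat(trace_frames, ignore_index=True) \
        .to_csv(out / "traces.csv", index=False)

    pop = session.population
    meta = {
        "session_id": pop.session_id,
        "feedback_state": session.feedback_state,
        "rng_seed": session.rng_seed,
        "clipped_fraction": session.clipped_fraction,
        "config_hash": config_hash,
        "behavior_params": session.behavior_params,
        "phase_concentration_by_type": {
            json.dumps(list(k)): v
            for k, v in pop.phase_concentration_by_type.items()},
        "neurons": [{
            "neuron_id": n.neuron_id, "polarity": n.polarity,
            "rate_class": n.rate_class, "baseline_rate": n.baseline_rate,
            "envelope_gain_at_1hz": n.envelope_gain_at_1hz,
            "gain_exponent": n.gain_exponent,
            "envelope_phase": n.envelope_phase,
            "carrier_modulation_depth": n.carrier_modulation_depth,
        } for n in pop.neurons],
        "conditions": [{
            "envelope_frequency": c.envelope_frequency,
            "contrast_level": c.contrast_level,
            "envelope_amplitude": c.envelope_amplitude,
            "duration": c.duration,
            "carrier_band": list(c.carrier_band),
            "n_trials": c.n_trials,
            "sample_rate": c.sample_rate,
        } for c in session.conditions],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def load_session(indir) -> SessionData:
    """Reconstruct a SessionData from a saved session directory."""
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    conditions = [StimulusCondition(
        envelope_frequency=c["envelope_frequency"],
        contrast_level=c["contrast_level"],
        envelope_amplitude=c["envelope_amplitude"],
        duration=c["duration"], carrier_band=tuple(c["carrier_band"]),
        n_trials=c["n_trials"], sample_rate=c["sample_rate"])
        for c in meta["conditions"]]
    neurons = tuple(NeuronSpec(**n) for n in meta["neurons"])
    pop = PopulationSpec(
        neurons=neurons,
        phase_concentration_by_type={
            tuple(json.loads(k)): v
            for k, v in meta["phase_concentration_by_type"].items()},
        session_id=meta["session_id"])

    traces = pd.read_csv(indir / "traces.csv")
    spikes = pd.read_csv(indir / "spikes.csv")
    envelopes, carriers, behavior, spike_times = {}, {}, {}, {}
    for cond in conditions:
        cid = cond.condition_id
        tr = traces[traces["condition_id"] == cid].sort_values("sample")
        envelopes[cid] = tr["envelope"].to_numpy()
        carriers[cid] = tr["carrier"].to_numpy()
        behavior[cid] = tr["behavior"].to_numpy()
        sp = spikes[spikes["condition_id"] == cid]
        per_neuron = []
        for nid in range(len(neurons)):
            sn = sp[sp["neuron_id"] == nid]
            per_neuron.append([
                np.sort(sn.loc[sn["trial"] == t, "spike_time"].to_numpy())
                for t in range(cond.n_trials)])
        spike_times[cid] = per_neuron
    return SessionData(population=pop, feedback_state=meta["feedback_state"],
                       conditions=conditions, envelopes=envelopes,
                       carriers=carriers, spike_times=spike_times,
                       behavior=behavior, behavior_params=meta["behavior_params"],
                       rng_seed=meta["rng_seed"],
                       clipped_fraction=meta["clipped_fraction"])
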