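"""Forward model: spike trains and behavior for one recording session.

For each condition, a frozen band-limited noise carrier c(t) (5-15 Hz,
unit variance, shared by all trials as in the experiments) is amplitude
modulated by the sinusoidal envelope.  Each neuron's instantaneous rate is

    lambda_i(t) = max(0, b_i + g_i(f) A sin(2 pi f t + phi_i))
                  * (1 + m_i s_i c_hat(t))

with b_i the baseline rate, g_i(f) the high-pass envelope gain, phi_i the
preferred envelope phase, m_i the carrier modulation depth and s_i = +1 (ON)
or -1 (OFF).  Spikes are drawn as independent Bernoulli events per 0.5 ms
bin, so a bin never holds more than one spike (the bin is shorter than the
cells' refractory period).  Behavior is the animal's EOD frequency tracking
the envelope:  EOD(t) = f0 + G_b A sin(2 pi f t + phi_b) + Gaussian noise,
with G_b scaled down after feedback inactivation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .conditions import SAMPLE_RATE, StimulusCondition
from .population import PopulationSpec

#: Behavioral envelope-following parameters: baseline EOD frequency (Hz),
#: envelope-following gain (Hz per mV/cm), behavioral phase (rad), and the
#: additive noise SD as a fraction of the behavioral modulation amplitude.
DEFAULT_BEHAVIOR = {
    "f0": 800.0,
    "gain": 10.0,
    "phase": -0.5,
    "noise_fraction": 0.1,
    "attenuation": 1.0,
}


@dataclass
class SessionData:
    """All spike trains, stimuli and behavior for one session in one state."""

    population: PopulationSpec
    feedback_state: str                      # "control" or "inactivated"
    conditions: list                         # list of StimulusCondition
    envelopes: dict                          # condition_id -> (n_samples,) mV/cm
    carriers: dict                           # condition_id -> (n_samples,) normalized
    spike_times: dict                        # condition_id -> list[neuron][trial] arrays (s)
    behavior: dict                           # condition_id -> (n_samples,) EOD freq, Hz
    behavior_params: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOR))
    rng_seed: int = 0
    clipped_fraction: float = 0.0

    @property
    def n_neurons(self) -> int:
        return self.population.size

    def condition(self, condition_id: str) -> StimulusCondition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)


def band_limited_carrier(n_samples: int, rng,
                         band=(5.0, 15.0),
                         sample_rate: float = SAMPLE_RATE) -> np.ndarray:
    """Unit-variance noise carrier: white Gaussian noise through a 4th-order
    Butterworth band-pass, renormalized."""
    x = rng.standard_normal(n_samples)
    b, a = butter(4, [band[0] / (sample_rate / 2), band[1] / (sample_rate / 2)],
                  btype="band")
    y = filtfilt(b, a, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def instantaneous_rate(neuron, condition: StimulusCondition,
                       carrier: np.ndarray) -> np.ndarray:
    """Noise-free instantaneous firing rate lambda_i(t) in spikes/s."""
    n = condition.n_samples
    t = np.arange(n) / condition.sample_rate
    f = condition.envelope_frequency
    drive = neuron.baseline_rate + neuron.envelope_gain(f) * \
        condition.envelope_amplitude * np.sin(2 * np.pi * f * t + neuron.envelope_phase)
    sign = 1.0 if neuron.polarity == "ON" else -1.0
    lam = np.maximum(0.0, drive) * (1.0 + neuron.carrier_modulation_depth * sign * carrier)
    return np.clip(lam, 0.0, condition.sample_rate)


def _spikes_from_rate(lam: np.ndarray, n_trials: int, rng,
                      sample_rate: float) -> list:
    p = lam / sample_rate          # Bernoulli probability per 0.5 ms bin
    draws = rng.random((n_trials, lam.size)) < p[None, :]
    dt = 1.0 / sample_rate
    return [np.flatnonzero(row) * dt for row in draws]


def simulate_session(pop: PopulationSpec,
                     conditions,
                     behavior_params: dict | None = None,
                     seed: int = 0,
                     feedback_state: str = "control") -> SessionData:
    """Simulate spike trains and behavior for every condition and trial.

    Deterministic given `seed`.  Rate-clipping events (rate forced into
    [0, sample_rate]) are counted; if more than 1% of bins clip, a warning
    is emitted.
    """
    bp = dict(DEFAULT_BEHAVIOR)
    if behavior_params:
        bp.update(behavior_params)
    rng = np.random.default_rng(seed)

    envelopes, carriers, spike_times, behavior = {}, {}, {}, {}
    clipped = 0
    total = 0
    for cond in conditions:
        n = cond.n_samples
        t = np.arange(n) / cond.sample_rate
        f = cond.envelope_frequency
        env = cond.envelope_amplitude * np.sin(2 * np.pi * f * t)
        car = band_limited_carrier(n, rng, cond.carrier_band, cond.sample_rate)
        per_neuron = []
        for neuron in pop.neurons:
            lam = instantaneous_rate(neuron, cond, car)
            # half-wave rectification is part of the rate model; only bins
            # clipped at the Bernoulli ceiling (one spike per bin) count here
            clipped += int(np.sum(lam >= cond.sample_rate))
            total += n
            per_neuron.append(_spikes_from_rate(lam, cond.n_trials, rng,
                                                cond.sample_rate))
        g_b = bp["gain"] * bp.get("attenuation", 1.0)
        amp_b = g_b * cond.envelope_amplitude
        beh = bp["f0"] + amp_b * np.sin(2 * np.pi * f * t + bp["phase"]) + \
            rng.normal(0.0, bp["noise_fraction"] * amp_b, n)
        cid = cond.condition_id
        envelopes[cid] = env
        carriers[cid] = car
        spike_times[cid] = per_neuron
        behavior[cid] = beh

    frac = clipped / max(total, 1)
    if frac > 0.01:
        warnings.warn(f"{100 * frac:.1f}% of rate bins were clipped",
                      RuntimeWarning, stacklevel=2)
    return SessionData(population=pop, feedback_state=feedback_state,
                       conditions=list(conditions), envelopes=envelopes,
                       carriers=carriers, spike_times=spike_times,
                       behavior=behavior, behavior_params=bp, rng_seed=seed,
                       clipped_fraction=frac)
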