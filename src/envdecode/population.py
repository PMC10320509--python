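"""Model populations of electrosensory (ELL) pyramidal cells.

Each neuron carries a polarity (ON/OFF response to the fast carrier), a
baseline-rate class (low < 15 spk/s, high > 25 spk/s, medium otherwise,
mirroring the superficial/intermediate/deep morphological axis), an envelope
sensitivity with high-pass frequency tuning, and a preferred envelope phase.
Phase preferences are drawn per cell type from a von Mises distribution whose
concentration kappa is the population's heterogeneity knob: kappa = 0 gives
uniform (maximally heterogeneous) phases, large kappa homogenizes the type.
Feedback inactivation is modeled as a selective increase of kappa for one
cell type plus an attenuation of the behavioral envelope-following gain.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

POLARITIES = ("ON", "OFF")
RATE_CLASSES = ("low", "medium", "high")
CELL_TYPES = tuple((p, r) for p in POLARITIES for r in RATE_CLASSES)

#: Baseline-rate sampling ranges (spikes/s) per rate class.
BASELINE_RANGES = {"low": (4.0, 15.0), "medium": (15.0, 25.0), "high": (25.0, 65.0)}

#: Rate-class thresholds used for classification (spikes/s): low < 15,
#: high > 25, medium otherwise.
RATE_CLASS_LOW = 15.0
RATE_CLASS_HIGH = 25.0

#: Envelope sensitivity at 1 Hz (spikes/s per mV/cm) sampling range, and the
#: high-pass tuning exponent: gain(f) = gain_1Hz * f**exponent.
GAIN_RANGE_1HZ = (25.0, 100.0)
GAIN_EXPONENT = 0.4

#: Sensitivity sampling range at 1 Hz for ON low-rate (superficial) cells, the
#: type most strongly driven by envelope stimuli and targeted by descending
#: feedback.  A narrow high band keeps the targeted subpopulation's influence
#: on the population decoders comparable across sampled sessions.
ON_LOW_GAIN_RANGE_1HZ = (400.0, 480.0)

#: Carrier modulation depth sampling range (dimensionless).
CARRIER_DEPTH_RANGE = (0.2, 0.6)

#: Mean preferred envelope phase per cell type (radians).  Under control
#: conditions kappa = 0 makes these irrelevant; after feedback inactivation
#: the targeted type collapses onto its mean.  ON low-rate cells collapse in
#: phase with the envelope (pure feedforward drive).
TYPE_PHASE_MEANS = {
    ("ON", "low"): 0.0,
    ("ON", "medium"): np.pi / 3,
    ("ON", "high"): 2 * np.pi / 3,
    ("OFF", "low"): np.pi,
    ("OFF", "medium"): -2 * np.pi / 3,
    ("OFF", "high"): -np.pi / 3,
}

#: Six-type cell counts of the full recorded dataset (134 cells).
FULL_COUNTS = {
    ("ON", "low"): 29, ("OFF", "low"): 21,
    ("ON", "medium"): 25, ("OFF", "medium"): 24,
    ("ON", "high"): 15, ("OFF", "high"): 20,
}


@dataclass(frozen=True)
class NeuronSpec:
    """Generative parameters of one model pyramidal cell."""

    neuron_id: int
    polarity: str              # "ON" or "OFF"
    rate_class: str            # "low", "medium", "high"
    baseline_rate: float       # spikes/s
    envelope_gain_at_1hz: float  # spikes/s per mV/cm
    gain_exponent: float       # high-pass tuning exponent
    envelope_phase: float      # preferred envelope phase, radians
    carrier_modulation_depth: float  # in [0, 1]

    def __post_init__(self):
        if not 0 < self.baseline_rate < 2000:
            raise ValueError("baseline_rate must lie in (0, 2000) spk/s")
        if not 0 <= self.carrier_modulation_depth <= 1:
            raise ValueError("carrier_modulation_depth must lie in [0, 1]")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.rate_class != rate_class_of(self.baseline_rate):
            raise ValueError("rate_class inconsistent with baseline_rate")

    @property
    def cell_type(self) -> tuple:
        return (self.polarity, self.rate_class)

    def envelope_gain(self, frequency: float) -> float:
        """Envelope sensitivity at `frequency` Hz (high-pass tuning)."""
        return self.envelope_gain_at_1hz * frequency ** self.gain_exponent


def rate_class_of(baseline_rate: float) -> str:
    """Classify a baseline firing rate: low < 15, high > 25, else medium."""
    if baseline_rate < RATE_CLASS_LOW:
        return "low"
    if baseline_rate > RATE_CLASS_HIGH:
        return "high"
    return "medium"


@dataclass(frozen=True)
class PopulationSpec:
    """A recorded population: neurons plus per-type phase concentrations."""

    neurons: tuple
    phase_concentration_by_type: dict
    session_id: str = "session0"

    @property
    def size(self) -> int:
        return len(self.neurons)

    def type_indices(self, cell_type) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.neurons)
                         if n.cell_type == tuple(cell_type)], dtype=int)


def _draw_baseline(rng, rate_class, lo_hi):
    lo, hi = lo_hi
    # keep strictly inside the class interval so classification round-trips
    r = rng.uniform(lo, hi)
    eps = 1e-6
    return min(max(r, lo + eps), hi - eps)


def sample_population(counts_by_type: dict | None = None,
                      phase_concentration_by_type: dict | None = None,
                      seed: int = 0,
                      session_id: str = "session0",
                      gain_range_1hz=GAIN_RANGE_1HZ,
                      on_low_gain_range=ON_LOW_GAIN_RANGE_1HZ,
                      gain_exponent: float = GAIN_EXPONENT) -> PopulationSpec:
    """Draw a population of model neurons.

    Parameters
    ----------
    counts_by_type : mapping (polarity, rate_class) -> int
        Number of neurons per cell type; defaults to the full 134-cell counts.
    phase_concentration_by_type : mapping (polarity, rate_class) -> float
        Von Mises concentration of preferred envelope phases per type;
        kappa = 0 (default for every type) draws uniform phases.
    seed : int
        Seed; identical seeds give identical populations.

    Returns
    -------
    PopulationSpec
    """
    counts = dict(FULL_COUNTS if counts_by_type is None else counts_by_type)
    for key, cnt in counts.items():
        if tuple(key) not in CELL_TYPES:
            raise ValueError(f"unknown cell type {key!r}")
        if cnt < 0:
            raise ValueError("counts must be non-negative")
    kappa = {t: 0.0 for t in CELL_TYPES}
    if phase_concentration_by_type:
        for key, k in phase_concentration_by_type.items():
            if tuple(key) not in CELL_TYPES:
                raise ValueError(f"unknown cell type {key!r}")
            if k < 0:
                raise ValueError("kappa must be >= 0")
            kappa[tuple(key)] = float(k)

    rng = np.random.default_rng(seed)
    neurons = []
    nid = 0
    for cell_type in CELL_TYPES:          # fixed iteration order -> determinism
        n = counts.get(cell_type, 0)
        polarity, rate_class = cell_type
        for _ in range(n):
            baseline = _draw_baseline(rng, rate_class, BASELINE_RANGES[rate_class])
            rng_lo, rng_hi = (on_low_gain_range if cell_type == ("ON", "low")
                              else gain_range_1hz)
            gain = rng.uniform(rng_lo, rng_hi)
            phase = _draw_phase(rng, TYPE_PHASE_MEANS[cell_type], kappa[cell_type])
            depth = rng.uniform(*CARRIER_DEPTH_RANGE)
            neurons.append(NeuronSpec(
                neuron_id=nid, polarity=polarity, rate_class=rate_class,
                baseline_rate=baseline, envelope_gain_at_1hz=gain,
                gain_exponent=gain_exponent, envelope_phase=phase,
                carrier_modulation_depth=depth))
            nid += 1
    return PopulationSpec(neurons=tuple(neurons),
                          phase_concentration_by_type=kappa,
                          session_id=session_id)


def _draw_phase(rng, mu, kappa):
    if kappa == 0:
        return float(rng.uniform(0, 2 * np.pi))
    return float(np.mod(rng.vonmises(mu, kappa), 2 * np.pi))


def apply_feedback_inactivation(pop: PopulationSpec,
                                target_type=("ON", "low"),
                                kappa_new: float = 8.0,
                                behavior_attenuation: float = 0.5,
                                seed: int = 0) -> tuple[PopulationSpec, dict]:
    """Homogenize one cell type's phase preferences; attenuate behavior.

    Only the targeted type's preferred envelope phases are redrawn, from a
    von Mises with concentration `kappa_new` around the type's phase mean;
    every other field of every neuron is untouched.  The behavioral
    envelope-following gain is multiplied by `behavior_attenuation`.

    Returns
    -------
    (PopulationSpec, dict)
        The inactivated population and ``{"behavior_attenuation": ...}``.
    """
    target_type = tuple(target_type)
    if target_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {target_type!r}")
    kappa_old = pop.phase_concentration_by_type.get(target_type, 0.0)
    if kappa_new < kappa_old:
        raise ValueError("inactivation homogenizes: kappa_new must be >= current kappa")
    if not 0 < behavior_attenuation <= 1:
        raise ValueError("behavior_attenuation must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    mu = TYPE_PHASE_MEANS[target_type]
    neurons = []
    for n in pop.neurons:
        if n.cell_type == target_type:
            neurons.append(replace(n, envelope_phase=_draw_phase(rng, mu, kappa_new)))
        else:
            neurons.append(n)
    kappa = dict(pop.phase_concentration_by_type)
    kappa[target_type] = float(kappa_new)
    new_pop = PopulationSpec(neurons=tuple(neurons),
                             phase_concentration_by_type=kappa,
                             session_id=pop.session_id)
    return new_pop, {"behavior_attenuation": float(behavior_attenuation)}


def split_counts_across_sessions(total_counts: dict | None = None,
                                 n_sessions: int = 7) -> list[dict]:
    """Partition six-type cell counts into per-session subpopulations.

    The full dataset's cells were recorded over several sessions; this
    distributes each type's total as evenly as possible (round robin), so the
    per-session populations sum exactly to the totals.
    """
    totals = dict(FULL_COUNTS if total_counts is None else total_counts)
    out = [dict.fromkeys(CELL_TYPES, 0) for _ in range(n_sessions)]
    for t in CELL_TYPES:
        n = totals.get(t, 0)
        base, extra = divmod(n, n_sessions)
        for s in range(n_sessions):
            out[s][t] = base + (1 if s < extra else 0)
    return out
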