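"""Spike-train processing: binning, filtered rates, tuning, classification,
and response-heterogeneity quantification.

Spike times are converted to binary sequences on the 2 kHz grid (0.5 ms
bins).  Continuous firing rates come from a first-order Butterworth low-pass
applied forward and backward (zero phase), with cutoffs of 0.15, 0.3 and
1.5 Hz for the 0.1, 0.5 and 1 Hz envelope frequencies.  Envelope tuning
(gain and preferred phase) is estimated from a sinusoidal fit to the cycle
histogram; ON/OFF polarity from the slope of the spike-triggered average of
the carrier just before the spike; response heterogeneity from the
distribution of pairwise Pearson correlations between trial-averaged
filtered rates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, firwin, kaiserord

from .conditions import SAMPLE_RATE
from .population import rate_class_of

#: Verbatim cutoff map for the three canonical envelope frequencies (Hz).
BUTTERWORTH_CUTOFFS = {0.1: 0.15, 0.5: 0.3, 1.0: 1.5}

CLEAR_RESPONDER_THRESHOLD = 5.0   # spikes/s per mV/cm at 0.1 Hz, control


@dataclass(frozen=True)
class BinarySpikeTrain:
    values: np.ndarray        # 0/1 on the 2 kHz grid
    duration: float
    neuron_id: int = -1
    trial: int = -1

    def __post_init__(self):
        if self.values.size != int(round(self.duration * SAMPLE_RATE)):
            raise ValueError("length must equal round(duration * 2000)")


@dataclass(frozen=True)
class FilteredRate:
    rate: np.ndarray          # spikes/s on the 2 kHz grid
    filter_kind: str          # "butterworth" or "kaiser"
    cutoff: float             # Hz
    trial_scope: str = "single"


@dataclass(frozen=True)
class TuningEstimate:
    gain: float               # spikes/s per mV/cm
    preferred_phase: float    # radians in (-pi, pi]
    modulation_amplitude: float  # spikes/s
    fit_residual: float
    phase_defined: bool = True


def bin_spikes(spike_times, duration: float,
               sample_rate: float = SAMPLE_RATE,
               neuron_id: int = -1, trial: int = -1) -> BinarySpikeTrain:
    """Binary sequence: bin b is 1 iff at least one spike fell in it."""
    times = np.asarray(spike_times, dtype=float)
    n = int(round(duration * sample_rate))
    if times.size:
        if np.any(np.diff(times) < 0):
            raise ValueError("spike times must be sorted")
        if times[0] < 0 or times[-1] >= duration:
            raise ValueError("spike times must lie in [0, duration)")
    values = np.zeros(n, dtype=np.uint8)
    if times.size:
        idx = np.floor(times * sample_rate).astype(int)
        values[idx] = 1
    return BinarySpikeTrain(values=values, duration=duration,
                            neuron_id=neuron_id, trial=trial)


def _butter_cutoff(envelope_frequency: float) -> float:
    return BUTTERWORTH_CUTOFFS.get(float(envelope_frequency),
                                   1.5 * envelope_frequency)


def butterworth_rate(train, envelope_frequency: float,
                     sample_rate: float = SAMPLE_RATE,
                     trial_scope: str = "single") -> FilteredRate:
    """First-order Butterworth low-pass of the binary sequence, zero phase.

    `train` may be a BinarySpikeTrain or a raw array (binary sequence or a
    trial-averaged binary sequence); values are scaled to spikes/s first.
    """
    x = train.values if isinstance(train, BinarySpikeTrain) else np.asarray(train, float)
    cutoff = _butter_cutoff(envelope_frequency)
    if cutoff >= sample_rate / 2:
        raise ValueError("cutoff must lie below Nyquist")
    b, a = butter(1, cutoff / (sample_rate / 2))
    # scipy's default pad length (a few samples) is far shorter than the
    # filter's time constant at sub-Hz cutoffs and leaves large edge
    # transients; pad with about three time constants instead
    padlen = min(x.shape[-1] - 1, int(round(3 * sample_rate / cutoff)))
    rate = filtfilt(b, a, x.astype(float) * sample_rate, axis=-1,
                    padtype="even", padlen=padlen)
    return FilteredRate(rate=rate, filter_kind="butterworth", cutoff=cutoff,
                        trial_scope=trial_scope)


def kaiser_rate(train, stimulus_frequency: float,
                sample_rate: float = SAMPLE_RATE,
                trial_scope: str = "single") -> FilteredRate:
    """Kaiser-window FIR low-pass (cutoff 20% above the stimulus frequency).

    Used for visualization only; decoders always consume Butterworth rates.
    """
    x = train.values if isinstance(train, BinarySpikeTrain) else np.asarray(train, float)
    cutoff = 1.2 * stimulus_frequency
    if cutoff >= sample_rate / 2:
        raise ValueError("cutoff must lie below Nyquist")
    ntaps, beta = kaiserord(ripple=60.0, width=2 * cutoff / (sample_rate / 2))
    ntaps = min(ntaps | 1, 2 * x.shape[-1] // 2 - 1)
    taps = firwin(ntaps, cutoff / (sample_rate / 2), window=("kaiser", beta))
    padlen = min(x.shape[-1] - 1, 3 * ntaps)
    rate = filtfilt(taps, [1.0], x.astype(float) * sample_rate, axis=-1,
                    padtype="even", padlen=padlen)
    return FilteredRate(rate=rate, filter_kind="kaiser", cutoff=cutoff,
                        trial_scope=trial_scope)


def trial_averaged_rate(trial_trains, envelope_frequency: float,
                        sample_rate: float = SAMPLE_RATE) -> FilteredRate:
    """Butterworth-filtered rate of the across-trial mean binary sequence.

    Filtering is linear, so filtering the mean equals the mean of filtered
    single-trial rates.
    """
    mat = np.stack([t.values if isinstance(t, BinarySpikeTrain) else np.asarray(t)
                    for t in trial_trains]).astype(float)
    return butterworth_rate(mat.mean(axis=0), envelope_frequency, sample_rate,
                            trial_scope="trial_averaged")


def estimate_tuning(trial_spike_times, envelope_frequency: float,
                    envelope_amplitude: float, duration: float,
                    n_bins: int = 32,
                    sample_rate: float = SAMPLE_RATE) -> TuningEstimate:
    """Gain and preferred phase from a sinusoidal fit to the cycle histogram.

    Spikes from all trials are folded on the envelope period into `n_bins`
    phase bins, converted to spikes/s, and fit with
    r(theta) = a + b sin(theta + phi), b >= 0.  Gain is b divided by the
    envelope amplitude.
    """
    f = envelope_frequency
    period = 1.0 / f
    n_cycles_total = 0
    counts = np.zeros(n_bins)
    n_trials = 0
    for times in trial_spike_times:
        times = np.asarray(times, float)
        phases = np.mod(times, period) / period          # in [0, 1)
        idx = np.minimum((phases * n_bins).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1.0)
        n_trials += 1
        n_cycles_total += duration / period
    if counts.sum() == 0:
        return TuningEstimate(gain=0.0, preferred_phase=0.0,
                              modulation_amplitude=0.0, fit_residual=0.0,
                              phase_defined=False)
    bin_dt = period / n_bins
    hist_rate = counts / (n_cycles_total * bin_dt)        # spikes/s
    theta = (np.arange(n_bins) + 0.5) / n_bins * 2 * np.pi
    # least squares on r = a + c1 sin(theta) + c2 cos(theta)
    X = np.column_stack([np.ones(n_bins), np.sin(theta), np.cos(theta)])
    coef, *_ = np.linalg.lstsq(X, hist_rate, rcond=None)
    a, c1, c2 = coef
    b = float(np.hypot(c1, c2))
    phi = float(np.arctan2(c2, c1))       # r = a + b sin(theta + phi)
    resid = float(np.sqrt(np.mean((X @ coef - hist_rate) ** 2)))
    return TuningEstimate(gain=b / envelope_amplitude, preferred_phase=phi,
                          modulation_amplitude=b, fit_residual=resid,
                          phase_defined=True)


def is_clear_responder(tuning: TuningEstimate,
                       threshold: float = CLEAR_RESPONDER_THRESHOLD) -> bool:
    """Clear envelope responder: gain strictly greater than 5 spk/s/(mV/cm)
    at 0.1 Hz under control conditions."""
    return bool(tuning.gain > threshold)


def compute_sta(spike_times, carrier: np.ndarray, window: float = 0.05,
                slope_window: float = 0.01,
                sample_rate: float = SAMPLE_RATE) -> tuple[np.ndarray, float]:
    """Spike-triggered average of the carrier and its pre-spike slope.

    Averages carrier segments in [-window, +window] around every spike
    (spikes too close to the edges are dropped), then fits a least-squares
    line over [-slope_window, 0]; a positive slope marks an ON cell.
    """
    times = np.concatenate([np.asarray(t, float) for t in spike_times]) \
        if isinstance(spike_times, (list, tuple)) else np.asarray(spike_times, float)
    if times.size == 0:
        raise ValueError("cannot compute an STA without spikes")
    w = int(round(window * sample_rate))
    idx = np.round(times * sample_rate).astype(int)
    idx = idx[(idx >= w) & (idx < carrier.size - w)]
    if idx.size == 0:
        raise ValueError("no spikes far enough from the edges for the STA window")
    offsets = np.arange(-w, w + 1)
    sta = carrier[idx[:, None] + offsets[None, :]].mean(axis=0)
    sw = int(round(slope_window * sample_rate))
    tt = offsets[w - sw:w + 1] / sample_rate
    seg = sta[w - sw:w + 1]
    slope = float(np.polyfit(tt, seg, 1)[0])
    return sta, slope


def classify_polarity(sta_slope: float) -> str:
    """ON iff the pre-spike STA slope is positive."""
    return "ON" if sta_slope > 0 else "OFF"


def classify_rate_class(baseline_rate: float) -> str:
    """low < 15 spk/s, high > 25 spk/s, medium otherwise."""
    return rate_class_of(baseline_rate)


def pairwise_correlations(rates: np.ndarray, neuron_types=None,
                          condition_id: str = "", state: str = "") -> pd.DataFrame:
    """Pearson correlations between all unordered pairs of rate traces.

    Parameters
    ----------
    rates : (M, T) array
        Trial-averaged filtered rates on a common grid.
    neuron_types : optional sequence of hashables
        Per-neuron type labels; pairs are tagged same-type/different-type.

    Returns
    -------
    DataFrame with columns i, j, r, same_type, condition_id, state.
        Zero-variance traces are skipped.
    """
    rates = np.asarray(rates, float)
    if rates.ndim != 2 or rates.shape[0] < 2:
        raise ValueError("need at least two neurons on a common grid")
    sd = rates.std(axis=1)
    ok = sd > 0
    C = np.corrcoef(rates[ok])
    idx = np.flatnonzero(ok)
    rows = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = int(idx[a]), int(idx[b])
            same = (neuron_types is not None and
                    neuron_types[i] == neuron_types[j])
            rows.append((i, j, float(C[a, b]), bool(same)))
    df = pd.DataFrame(rows, columns=["i", "j", "r", "same_type"])
    df["condition_id"] = condition_id
    df["state"] = state
    return df


def correlation_summary(corr: pd.DataFrame, high: float = 0.9) -> dict:
    """Fraction of pairs above `high` plus basic distribution stats."""
    r = corr["r"].to_numpy()
    return {
        "n_pairs": int(r.size),
        "frac_above": float(np.mean(r > high)) if r.size else float("nan"),
        "mean": float(r.mean()) if r.size else float("nan"),
        "median": float(np.median(r)) if r.size else float("nan"),
    }
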