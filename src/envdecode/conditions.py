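"""Stimulus conditions: sinusoidal envelopes riding on a band-limited carrier.

The stimulus set crosses three envelope frequencies (0.1, 0.5 and 1 Hz) with
three contrast levels (weak, intermediate, strong).  Each condition lasts one
envelope period and is presented for a fixed number of trials, sampled on a
common 2 kHz grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

SAMPLE_RATE = 2000.0
"""Common sampling grid for spike binning, rates, stimuli and behavior (Hz)."""

ENVELOPE_FREQUENCIES = (0.1, 0.5, 1.0)
CONTRAST_LABELS = ("weak", "intermediate", "strong")

#: Mean measured contrasts (fraction of baseline carrier amplitude) for the
#: weak / intermediate / strong levels.
DEFAULT_CONTRAST_FRACTIONS = (0.091, 0.232, 0.497)

#: Carrier (amplitude-modulation) noise band in Hz.
CARRIER_BAND = (5.0, 15.0)


@dataclass(frozen=True)
class StimulusCondition:
    """One envelope frequency delivered at one contrast.

    Attributes
    ----------
    envelope_frequency : float
        Envelope frequency in Hz.
    contrast_level : str
        One of ``weak``, ``intermediate``, ``strong``.
    envelope_amplitude : float
        Envelope amplitude in mV/cm (base amplitude times contrast fraction).
    duration : float
        Stimulus duration in seconds; always one envelope period.
    carrier_band : tuple of float
        Carrier noise band (low, high) in Hz.
    n_trials : int
        Number of repeated presentations.
    sample_rate : float
        Sampling rate of all traces, Hz.
    """

    envelope_frequency: float
    contrast_level: str
    envelope_amplitude: float
    duration: float
    carrier_band: tuple = CARRIER_BAND
    n_trials: int = 20
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self):
        if self.envelope_amplitude <= 0:
            raise ValueError("envelope_amplitude must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2 for a train/test split")
        expected = 1.0 / self.envelope_frequency
        if abs(self.duration - expected) > 1e-9:
            raise ValueError("duration must equal one envelope period")

    @property
    def condition_id(self) -> str:
        return f"{self.envelope_frequency:g}Hz_{self.contrast_level}"

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


def make_conditions(base_amplitude: float = 1.0,
                    contrast_fractions=DEFAULT_CONTRAST_FRACTIONS,
                    n_trials: int = 20) -> list[StimulusCondition]:
    """Build the nine-condition stimulus set.

    Parameters
    ----------
    base_amplitude : float
        Nominal carrier amplitude in mV/cm; envelope amplitudes are
        ``base_amplitude * contrast_fraction``.
    contrast_fractions : sequence of three floats
        Strictly increasing contrasts in (0, 1] for weak/intermediate/strong.
    n_trials : int
        Trials per condition.

    Returns
    -------
    list of StimulusCondition
        Nine conditions, ordered frequency-major then contrast.
    """
    if base_amplitude <= 0:
        raise ValueError("base_amplitude must be positive")
    fr = tuple(float(x) for x in contrast_fractions)
    if len(fr) != 3:
        raise ValueError("exactly three contrast fractions required")
    if not all(0 < x <= 1 for x in fr):
        raise ValueError("contrast fractions must lie in (0, 1]")
    if not (fr[0] < fr[1] < fr[2]):
        raise ValueError("contrast fractions must be strictly increasing")
    out = []
    for f in ENVELOPE_FREQUENCIES:
        for label, frac in zip(CONTRAST_LABELS, fr):
            out.append(StimulusCondition(
                envelope_frequency=f,
                contrast_level=label,
                envelope_amplitude=base_amplitude * frac,
                duration=1.0 / f,
                n_trials=n_trials,
            ))
    return out
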