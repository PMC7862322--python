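"""Electrical stimulation pulse trains.

Synthesizes the tetanus-inducing burst signal a function generator would
produce — rectangular pulses repeated at a fixed rate for a burst
("duration time"), followed by a rest ("relaxation time") — and provides
the inverse measurements (pulse count, pulse width) used to verify a
synthesized or recorded trace.

The reference protocol is 40 Vpp, 40 Hz, 4 ms pulses, 1 s bursts with 4 s
rest: 40 rectangular waves per burst, driving complete tetanus in skeletal
muscle tissue.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

__all__ = [
    "PulseTrainSpec",
    "Waveform",
    "synthesize",
    "count_pulses",
    "measure_pulse_width",
    "write_waveform_csv",
]


@dataclasses.dataclass(frozen=True)
class PulseTrainSpec:
    """Parameters of a burst-mode rectangular pulse train.

    Attributes
    ----------
    amplitude_vpp : float
        Peak-to-peak voltage of the pulses, volts.
    frequency : float
        Pulse repetition rate within a burst, Hz.
    pulse_width : float
        Width of each rectangular pulse, seconds. Must be shorter than
        one repetition period.
    burst_duration : float
        Length of the stimulation burst ("duration time"), seconds.
    rest_duration : float
        Quiet interval after each burst ("relaxation time"), seconds.
    n_bursts : int
        Number of burst+rest cycles to synthesize.
    sample_rate : float
        Synthesis resolution, Hz. Must give at least 10 samples per pulse.
    polarity : str
        ``"bipolar"`` (default): two-level signal symmetric about 0 V,
        +Vpp/2 during a pulse and -Vpp/2 otherwise. ``"monopolar"``:
        0 V baseline, +Vpp during a pulse.
    """

    amplitude_vpp: float = 40.0
    frequency: float = 40.0
    pulse_width: float = 4e-3
    burst_duration: float = 1.0
    rest_duration: float = 4.0
    n_bursts: int = 1
    sample_rate: float = 10_000.0
    polarity: str = "bipolar"

    def __post_init__(self) -> None:
        if self.amplitude_vpp < 0:
            raise ValueError("amplitude_vpp must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be > 0")
        if self.pulse_width >= 1.0 / self.frequency:
            raise ValueError(
                f"pulse_width {self.pulse_width} s must be shorter than the "
                f"repetition period {1.0 / self.frequency} s (pulses overlap)"
            )
        if self.burst_duration < 0:
            raise ValueError("burst_duration must be >= 0")
        if self.rest_duration < 0:
            raise ValueError("rest_duration must be >= 0")
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.sample_rate < 10.0 / self.pulse_width:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz resolves a "
                f"{self.pulse_width} s pulse with fewer than 10 samples; "
                f"need >= {10.0 / self.pulse_width} Hz"
            )
        if self.polarity not in ("bipolar", "monopolar"):
            raise ValueError("polarity must be 'bipolar' or 'monopolar'")

    @property
    def pulses_per_burst(self) -> int:
        return int(math.floor(self.frequency * self.burst_duration + 1e-9))

    @property
    def levels(self) -> tuple[float, float]:
        """(baseline, high) voltage levels for this polarity dialect."""
        if self.polarity == "monopolar":
            return 0.0, self.amplitude_vpp
        return -self.amplitude_vpp / 2.0, self.amplitude_vpp / 2.0


@dataclasses.dataclass(frozen=True)
class Waveform:
    """A sampled voltage trace on a uniform time grid."""

    times: np.ndarray
    voltages: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must have equal length")

    @property
    def duration(self) -> float:
        return len(self.times) / self.sample_rate


def synthesize(spec: PulseTrainSpec) -> Waveform:
    """Sample the pulse train described by *spec* onto a uniform grid.

    Each burst carries ``floor(frequency * burst_duration)`` pulses, the
    first starting at the beginning of the burst; the signal sits at
    baseline during the rest interval. Pulse edges are placed by rounding
    to the nearest sample, so edge timing is accurate to half a sample
    period.
    """
    sr = spec.sample_rate
    cycle_samples = int(round((spec.burst_duration + spec.rest_duration) * sr))
    low, high = spec.levels
    one_cycle = np.full(cycle_samples, low, dtype=float)
    width_s = max(1, int(round(spec.pulse_width * sr)))
    burst_end = min(int(round(spec.burst_duration * sr)), cycle_samples)

    for k in range(spec.pulses_per_burst):
        start = int(round(k / spec.frequency * sr))
        # keep at least one baseline sample before the next pulse
        next_start = int(round((k + 1) / spec.frequency * sr))
        stop = min(start + width_s, next_start - 1, burst_end)
        if stop > start:
            one_cycle[start:stop] = high

    # tiling the sampled cycle makes burst periodicity exact by
    # construction (cumulative edge drift stays below half a sample)
    v = np.tile(one_cycle, spec.n_bursts)
    times = np.arange(len(v)) / sr
    return Waveform(times=times, voltages=v, sample_rate=sr)


def _high_mask(w: Waveform) -> np.ndarray:
    lo, hi = float(w.voltages.min()), float(w.voltages.max())
    if hi - lo < 1e-12:
        return np.zeros(len(w.voltages), dtype=bool)
    return w.voltages > (lo + hi) / 2.0


def count_pulses(w: Waveform) -> int:
    """Number of maximal contiguous high-level intervals (rising edges)."""
    if len(w.voltages) == 0:
        raise ValueError("cannot count pulses of an empty waveform")
    high = _high_mask(w)
    rising = np.flatnonzero(np.diff(high.astype(np.int8)) == 1)
    return int(len(rising) + (1 if high[0] else 0))


def measure_pulse_width(w: Waveform) -> float:
    """Median duration of the high-level intervals, seconds.

    Accurate to one sample period of the trace.
    """
    high = _high_mask(w)
    if not high.any():
        raise ValueError("waveform contains no pulses")
    edges = np.diff(np.concatenate(([0], high.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return float(np.median(stops - starts)) / w.sample_rate


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    """Two-column CSV export: time_s, voltage_v."""
    arr = np.column_stack([w.times, w.voltages])
    np.savetxt(path, arr, delimiter=",", header="time_s,voltage_v", comments="")
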