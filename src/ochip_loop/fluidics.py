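"""Fluidic subsystem twin: sampling state machine, circulation mixing,
metabolite plant, and virtual biosensor.

The sampling cycle mirrors the four-phase PC-controlled sequence —
circulating (homogenize the dish), sampling (capture the tube segment
between the circulating valves), drainage (return the remainder to the
dish), waiting — and stores each captured aliquot in a numbered
container. The aliquot volume is fixed by tube geometry: the default
1.6 mm inner diameter x 19.89 mm segment holds 40 uL.

The dish itself is an 8-compartment ring: circulation advects medium
around the ring and exchanges it between neighbours, homogenizing a dye
bolus (coefficient of variation < 5%) within the 180 s circulating step.

The metabolite plant produces lactate linearly in time; electrical
stimulation adds a multiplicative excess that grows as a power law of
stimulation time, anchored at +14% after 6 h and +26% after 24 h of
stimulation. Glucose declines linearly and is unaffected by stimulation.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "TubeGeometry",
    "Aliquot",
    "SamplerState",
    "PhaseDurations",
    "stored_volume",
    "run_sampling_cycle",
    "MixCompartments",
    "circulate_mix",
    "coefficient_of_variation",
    "time_to_uniform",
    "MetabolitePlant",
    "metabolite_concentrations",
    "biosensor_read",
    "aliquot_table",
]


class Phase(str, enum.Enum):
    CIRCULATING = "circulating"
    SAMPLING = "sampling"
    DRAINAGE = "drainage"
    WAITING = "waiting"
    IDLE = "idle"


@dataclasses.dataclass(frozen=True)
class TubeGeometry:
    """Valve-to-valve tube segment that defines the sample volume."""

    inner_diameter: float = 1.6  # mm
    segment_length: float = 19.89  # mm

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0 or self.segment_length <= 0:
            raise ValueError("tube dimensions must be > 0")


def stored_volume(g: TubeGeometry) -> float:
    """Aliquot volume captured by the tube segment, uL (= mm^3)."""
    return math.pi * (g.inner_diameter / 2.0) ** 2 * g.segment_length


@dataclasses.dataclass(frozen=True)
class Aliquot:
    volume: float  # uL
    time: float  # hours
    lactate: float  # mmol/L
    glucose: float  # mmol/L
    container_id: int = 0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("aliquot volume must be > 0")
        if self.lactate < 0 or self.glucose < 0:
            raise ValueError("concentrations must be >= 0")


@dataclasses.dataclass(frozen=True)
class PhaseDurations:
    """Seconds spent in each active phase of a sampling cycle."""

    circulating: float = 180.0
    sampling: float = 10.0
    drainage: float = 30.0


@dataclasses.dataclass(frozen=True)
class SamplerState:
    phase: Phase = Phase.IDLE
    phase_elapsed: float = 0.0
    containers: tuple[Aliquot, ...] = ()
    schedule: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0)
    max_containers: int = 24
    geometry: TubeGeometry = dataclasses.field(default_factory=TubeGeometry)
    phase_log: tuple[tuple[float, Phase], ...] = ()
    messages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if tuple(sorted(self.schedule)) != tuple(self.schedule):
            raise ValueError("sampling schedule must be sorted")


def run_sampling_cycle(
    state: SamplerState,
    now: float,
    concentrations: tuple[float, float],
    durations: PhaseDurations = PhaseDurations(),
    tolerance: float = 1e-6,
) -> SamplerState:
    """Execute one circulate -> sample -> drain -> wait cycle at ``now`` h.

    Captures one aliquot at the dish's current mixed ``(lactate,
    glucose)`` concentrations. Called at a time not on the schedule, the
    cycle is skipped with a log message (the PC only samples at
    programmed times); overfilling the container rack is an error.
    """
    if not any(abs(now - t) <= tolerance for t in state.schedule):
        return dataclasses.replace(
            state,
            messages=state.messages + (f"off-schedule call at t={now} h ignored",),
        )
    if len(state.containers) >= state.max_containers:
        raise RuntimeError(
            f"container capacity {state.max_containers} exceeded at t={now} h"
        )
    lactate, glucose = concentrations
    aliquot = Aliquot(
        volume=stored_volume(state.geometry),
        time=now,
        lactate=lactate,
        glucose=glucose,
        container_id=len(state.containers),
    )
    log = state.phase_log + (
        (now, Phase.CIRCULATING),
        (now + durations.circulating / 3600.0, Phase.SAMPLING),
        (now + (durations.circulating + durations.sampling) / 3600.0, Phase.DRAINAGE),
        (
            now
            + (durations.circulating + durations.sampling + durations.drainage)
            / 3600.0,
            Phase.WAITING,
        ),
    )
    return dataclasses.replace(
        state,
        phase=Phase.IDLE,
        phase_elapsed=0.0,
        containers=state.containers + (aliquot,),
        phase_log=log,
    )


@dataclasses.dataclass(frozen=True)
class MixCompartments:
    """Ring model of the circulated dish.

    ``dye`` holds per-compartment concentrations (arbitrary units);
    compartment volumes are equal (dish volume / n). Circulation advects
    one-way around the ring at ``circulation_rate``; ``exchange_fraction``
    is the additional per-second symmetric exchange between neighbours
    (the calibrated mixing constant: 0.05 /s homogenizes a bolus well
    inside the 180 s circulating step).
    """

    dye: np.ndarray
    dish_volume: float = 10.0  # mL
    circulation_rate: float = 2.0  # mL/min
    exchange_fraction: float = 0.05  # per second, per neighbour

    def __post_init__(self) -> None:
        if self.dish_volume <= 0:
            raise ValueError("dish_volume must be > 0")
        if self.circulation_rate < 0 or self.exchange_fraction < 0:
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "dye", np.asarray(self.dye, dtype=float))

    @property
    def n(self) -> int:
        return len(self.dye)

    @property
    def compartment_volume(self) -> float:
        return self.dish_volume / self.n

    def total_mass(self) -> float:
        return float(self.dye.sum() * self.compartment_volume)


def coefficient_of_variation(m: MixCompartments) -> float:
    mean = float(m.dye.mean())
    if mean == 0:
        return 0.0
    return float(m.dye.std() / mean)


def circulate_mix(m: MixCompartments, dt: float) -> MixCompartments:
    """Advance circulation mixing by ``dt`` seconds.

    Integrated in sub-steps of at most 1 s. Per sub-step each compartment
    passes fraction f = rate*dt_sub/volume of its contents to the next
    compartment around the ring and ``exchange_fraction*dt_sub`` to each
    neighbour. The update matrix is doubly stochastic, so dye mass is
    conserved exactly and the coefficient of variation never increases.
    Zero circulation rate and zero exchange is the identity.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = m.dye.copy()
    remaining = float(dt)
    while remaining > 1e-12:
        h = min(1.0, remaining)
        remaining -= h
        f = (m.circulation_rate / 60.0) * h / m.compartment_volume
        g = m.exchange_fraction * h
        if f + 2 * g > 1.0:
            raise ValueError(
                "mixing fractions exceed 1 per sub-step; reduce rates"
            )
        c = (
            (1.0 - f - 2.0 * g) * c
            + (f + g) * np.roll(c, 1)
            + g * np.roll(c, -1)
        )
    return dataclasses.replace(m, dye=c)


def time_to_uniform(
    m: MixCompartments, cv_target: float = 0.05, dt: float = 1.0, max_time: float = 3600.0
) -> float:
    """First time (s) at which the across-compartment CV drops below target."""
    t = 0.0
    while coefficient_of_variation(m) >= cv_target:
        if t >= max_time:
            raise RuntimeError(f"CV did not reach {cv_target} within {max_time} s")
        m = circulate_mix(m, dt)
        t += dt
    return t


@dataclasses.dataclass(frozen=True)
class MetabolitePlant:
    """Lactate/glucose time courses of the cultured tissue.

    Control lactate rises linearly; stimulation multiplies it by
    (1 + excess), where excess follows a power law of stimulation time
    fixed by the two anchors ``excess_at_6h`` and ``excess_at_24h``.
    ``excess_scale`` rescales the law for experiment variants (1.0 for
    the dedicated stimulation experiment). Absolute concentrations are
    arbitrary-scale; only ratios are anchored.
    """

    lactate_initial: float = 1.0  # mmol/L
    lactate_rate: float = 0.5  # mmol/L/h
    excess_at_6h: float = 0.14
    excess_at_24h: float = 0.26
    excess_scale: float = 1.0
    glucose_initial: float = 5.5  # mmol/L (1 g/L medium)
    glucose_uptake: float = 0.1  # mmol/L/h
    stim_window: tuple[float, float] = (0.0, float("inf"))  # hours

    @property
    def excess_exponent(self) -> float:
        """Power-law exponent fixed by the 6 h and 24 h anchors."""
        return math.log(self.excess_at_6h / self.excess_at_24h) / math.log(6.0 / 24.0)

    def excess(self, stim_hours: float) -> float:
        """Fractional lactate excess after ``stim_hours`` of stimulation."""
        if stim_hours <= 0:
            return 0.0
        return (
            self.excess_scale
            * self.excess_at_24h
            * (stim_hours / 24.0) ** self.excess_exponent
        )


def metabolite_concentrations(
    p: MetabolitePlant, t: float, stimulated: bool
) -> tuple[float, float]:
    """(lactate, glucose) in the dish at ``t`` hours, mmol/L."""
    if t < 0:
        raise ValueError("t must be >= 0")
    lactate = p.lactate_initial + p.lactate_rate * t
    if stimulated:
        start, end = p.stim_window
        stim_hours = max(0.0, min(t, end) - start)
        lactate *= 1.0 + p.excess(stim_hours)
    glucose = max(0.0, p.glucose_initial - p.glucose_uptake * t)
    return lactate, glucose


def biosensor_read(
    a: Aliquot,
    noise_sd: float = 0.0,
    seed: int | None = None,
    min_volume: float = 40.0,
) -> tuple[float, float]:
    """Virtual external biosensor: true concentration + relative noise.

    Requires the aliquot to meet the sensor's minimum volume (40 uL by
    default, with 0.1% relative tolerance so the default tube geometry's
    39.996 uL aliquot is accepted). Deterministic per seed.
    """
    if a.volume < min_volume * (1.0 - 1e-3):
        raise ValueError(
            f"aliquot volume {a.volume:.2f} uL below sensor minimum {min_volume} uL"
        )
    if noise_sd == 0.0:
        return a.lactate, a.glucose
    rng = np.random.default_rng(seed)
    lac = max(0.0, a.lactate * (1.0 + rng.normal(0.0, noise_sd)))
    glu = max(0.0, a.glucose * (1.0 + rng.normal(0.0, noise_sd)))
    return lac, glu


def aliquot_table(state: SamplerState) -> pd.DataFrame:
    """Dispensed-sample log (time_h, volume_ul, lactate_mM, glucose_mM, container_id)."""
    return pd.DataFrame(
        [
            {
                "time_h": a.time,
                "volume_ul": a.volume,
                "lactate_mM": a.lactate,
                "glucose_mM": a.glucose,
                "container_id": a.container_id,
            }
            for a in state.containers
        ],
        columns=["time_h", "volume_ul", "lactate_mM", "glucose_mM", "container_id"],
    )
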