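"""Bang-bang feedback controller for lipid-droplet size.

Compares the current white-pixel index against a stored reference. If the
index rises more than the threshold above the reference, the lipolytic
decelerator (adrenaline) is supplied; if it falls more than the threshold
below, the lipogenic accelerator (insulin) is supplied; otherwise the
active stimulant continues. On every switch the reference is replaced by
the index at the switch ("on_switch" mode, the default); an alternative
"previous_frame" mode re-references to the immediately preceding frame at
every step, which rejects slow imaging disturbances.

The default threshold is 0.3 percentage points of the index; a relative
dialect (threshold as percent of the reference) is selectable.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .monitor import LDIndex
from .stimulant import Stimulant

__all__ = [
    "ControllerState",
    "SwitchEvent",
    "initialize",
    "step",
    "events_table",
    "replay",
    "minimal_switching_deviation",
]


@dataclasses.dataclass(frozen=True)
class SwitchEvent:
    """One stimulant changeover, with the index that triggered it."""

    time: float
    from_stimulant: Stimulant
    to_stimulant: Stimulant
    index_at_switch: float

    def __post_init__(self) -> None:
        if self.from_stimulant == self.to_stimulant:
            raise ValueError("a switch event must change the stimulant")


@dataclasses.dataclass(frozen=True)
class ControllerState:
    reference_index: float | None
    active_stimulant: Stimulant = Stimulant.INSULIN
    threshold: float = 0.3
    threshold_mode: str = "absolute"  # or "relative" (percent of reference)
    reference_mode: str = "on_switch"  # or "previous_frame"
    events: tuple[SwitchEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.reference_index is not None and not 0.0 <= self.reference_index <= 100.0:
            raise ValueError("reference_index must lie in [0, 100]")
        if self.threshold_mode not in ("absolute", "relative"):
            raise ValueError("threshold_mode must be 'absolute' or 'relative'")
        if self.reference_mode not in ("on_switch", "previous_frame"):
            raise ValueError("reference_mode must be 'on_switch' or 'previous_frame'")


def initialize(
    first: LDIndex | float,
    initial_stimulant: Stimulant | str = Stimulant.INSULIN,
    threshold: float = 0.3,
    threshold_mode: str = "absolute",
    reference_mode: str = "on_switch",
) -> ControllerState:
    """Controller state referenced to the first observed index."""
    value = first.value if isinstance(first, LDIndex) else float(first)
    return ControllerState(
        reference_index=value,
        active_stimulant=Stimulant.parse(initial_stimulant),
        threshold=threshold,
        threshold_mode=threshold_mode,
        reference_mode=reference_mode,
    )


def step(
    state: ControllerState, current: LDIndex | float
) -> tuple[Stimulant, ControllerState]:
    """One control decision.

    Returns the stimulant to supply for the next interval and the updated
    state; appends a :class:`SwitchEvent` whenever the decision differs
    from the active stimulant. No switch is ever emitted for a deviation
    with magnitude <= threshold (strict crossing).
    """
    if state.reference_index is None:
        raise ValueError(
            "controller reference is uninitialized; call initialize() with the "
            "first index before stepping"
        )
    if isinstance(current, LDIndex):
        value, time = current.value, current.time
    else:
        value, time = float(current), float("nan")
    if not 0.0 <= value <= 100.0:
        raise ValueError("index must lie in [0, 100]")

    deviation = value - state.reference_index
    if state.threshold_mode == "relative":
        deviation = 100.0 * deviation / max(state.reference_index, 1e-12)

    if deviation > state.threshold:
        action = Stimulant.ADRENALINE
    elif -deviation > state.threshold:
        action = Stimulant.INSULIN
    else:
        action = state.active_stimulant

    if action != state.active_stimulant:
        event = SwitchEvent(
            time=time,
            from_stimulant=state.active_stimulant,
            to_stimulant=action,
            index_at_switch=value,
        )
        new_state = dataclasses.replace(
            state,
            reference_index=value,
            active_stimulant=action,
            events=state.events + (event,),
        )
    elif state.reference_mode == "previous_frame":
        new_state = dataclasses.replace(state, reference_index=value)
    else:
        new_state = state
    return action, new_state


def minimal_switching_deviation(
    reference: float = 10.0,
    direction: str = "up",
    tol: float = 1e-6,
    search_span: float = 1.0,
    **init_kwargs,
) -> float:
    """Empirically measure the controller's switching band edge.

    Bisects over the deviation magnitude (percentage points) applied to
    the reference index, returning the infimum deviation that makes the
    controller emit a switch — by construction this probes the configured
    threshold of an actual controller, not the constant itself.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1.0 if direction == "up" else -1.0
    initial = Stimulant.INSULIN if direction == "up" else Stimulant.ADRENALINE

    def switches(dev: float) -> bool:
        state = initialize(reference, initial, **init_kwargs)
        _, new = step(state, reference + sign * dev)
        return len(new.events) > 0

    lo, hi = 0.0, search_span
    if not switches(hi):
        raise ValueError(f"no switch within {search_span} pp of the reference")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if switches(mid):
            hi = mid
        else:
            lo = mid
    return hi


def events_table(state: ControllerState) -> pd.DataFrame:
    """Switch audit trail as a table (time_h, from, to, index_percent)."""
    return pd.DataFrame(
        [
            {
                "time_h": e.time,
                "from": e.from_stimulant.value,
                "to": e.to_stimulant.value,
                "index_percent": e.index_at_switch,
            }
            for e in state.events
        ],
        columns=["time_h", "from", "to", "index_percent"],
    )


def replay(
    index_trace: pd.DataFrame,
    initial_stimulant: Stimulant | str = Stimulant.INSULIN,
    threshold: float = 0.3,
    **init_kwargs,
) -> tuple[pd.DataFrame, ControllerState]:
    """Run the controller over a recorded index trace.

    Expects columns ``time_h`` and ``index_percent``; returns the
    per-frame action table and the final controller state.
    """
    rows = []
    state: ControllerState | None = None
    for _, row in index_trace.iterrows():
        idx = LDIndex(
            value=float(row["index_percent"]),
            frame_id=int(row.get("frame_id", 0)),
            time=float(row["time_h"]),
        )
        if state is None:
            state = initialize(idx, initial_stimulant, threshold=threshold, **init_kwargs)
            action = state.active_stimulant
        else:
            action, state = step(state, idx)
        rows.append(
            {"time_h": idx.time, "index_percent": idx.value, "action": action.value}
        )
    if state is None:
        raise ValueError("index trace is empty")
    return pd.DataFrame(rows, columns=["time_h", "index_percent", "action"]), state
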