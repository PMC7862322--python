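"""Biochemical stimulant identities shared across the plant and the controller."""

from __future__ import annotations

import enum


class Stimulant(str, enum.Enum):
    """Lipogenic / lipolytic agents acting on adipocyte lipid droplets.

    Insulin accelerates triglyceride storage (droplet radii grow);
    adrenaline drives lipolysis (radii shrink).
    """

    INSULIN = "insulin"
    ADRENALINE = "adrenaline"

    @classmethod
    def parse(cls, value: "Stimulant | str") -> "Stimulant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown stimulant {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None
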