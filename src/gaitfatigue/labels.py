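"""Fatigue labelling and physiological safety rules.

Perceived exertion is collected on the Borg CR10 scale (integers 0-10) at
the end of every walking bout and banded into four ordinal fatigue classes.
The banding follows the standard CR10 descriptor grouping: 0-2 ("no
exertion" to "easy") is Low, 3-5 ("somewhat moderate" to "somewhat hard")
is Moderate, 6-8 ("hard" to "very very hard") is High, and 9-10
("extremely hard", "maximum exertion") is Very High.

The module also provides the age-predicted maximal heart rate
(Tanaka: HRmax = 206.9 - 0.7 * age) and the treadmill stop rule: a bout is
terminated as soon as heart rate exceeds 90% of HRmax or a Borg value of 10
is reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class FatigueClass(enum.IntEnum):
    """The four ordinal fatigue states, Low < Moderate < High < VeryHigh."""

    Low = 0
    Moderate = 1
    High = 2
    VeryHigh = 3

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    FatigueClass.Low: "Low",
    FatigueClass.Moderate: "Moderate",
    FatigueClass.High: "High",
    FatigueClass.VeryHigh: "VeryHigh",
}

#: CR10 band upper edges (inclusive) for Low / Moderate / High / VeryHigh.
_BAND_UPPER = (2, 5, 8, 10)


def borg_to_class(value: int) -> FatigueClass:
    """Map an integer Borg CR10 reading (0-10) to a fatigue class.

    Bands: 0-2 -> Low, 3-5 -> Moderate, 6-8 -> High, 9-10 -> VeryHigh.
    """
    if isinstance(value, (bool, float)) and not float(value).is_integer():
        raise ValueError(f"Borg CR10 reading must be an integer, got {value!r}")
    v = int(value)
    if v != value or not 0 <= v <= 10:
        raise ValueError(f"Borg CR10 reading must be an integer in [0, 10], got {value!r}")
    for cls, upper in zip(FatigueClass, _BAND_UPPER):
        if v <= upper:
            return cls
    raise AssertionError("unreachable")  # pragma: no cover


def tanaka_hrmax(age: float) -> float:
    """Age-predicted maximal heart rate in bpm: 206.9 - 0.7 * age."""
    if age <= 0:
        raise ValueError("age must be positive")
    return 206.9 - 0.7 * age


@dataclass
class SafetyState:
    """Inputs to the stop rule for one bout."""

    hr: np.ndarray          # bpm samples at 1 Hz
    hrmax: float            # bpm
    borg: int               # CR10 reading for the bout

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        if self.hrmax <= 0:
            raise ValueError("hrmax must be positive")


def safety_stop(state: SafetyState) -> tuple[bool, str | None]:
    """Return (stop?, reason).

    Stops with reason ``"hr"`` if any heart-rate sample exceeds 90% of
    HRmax, with reason ``"borg"`` if the Borg reading is 10, else
    ``(False, None)``.  HR takes precedence as it is evaluated continuously
    during the bout while Borg is collected at the end.
    """
    if state.hr.size == 0:
        raise ValueError("empty heart-rate series")
    if np.any(state.hr > 0.9 * state.hrmax):
        return True, "hr"
    if int(state.borg) == 10:
        return True, "borg"
    return False, None
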