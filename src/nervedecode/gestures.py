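"""Finger-state gesture codebook.

A hand gesture is a binary activity state of the five fingers. The state
vector is always ordered (thumb, index, middle, ring, little); printed bit
strings are derived labels and their direction is configurable because the
two conventions found in the literature disagree (see ``GestureCode.code``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

FINGERS = ("thumb", "index", "middle", "ring", "little")
N_FINGERS = 5

#: Number of distinct binary activity combinations of five fingers.
N_STATE_COMBINATIONS = 2 ** N_FINGERS


@dataclass(frozen=True)
class GestureCode:
    """A named gesture with its 5-bit finger-activity vector.

    ``finger_state`` is ordered thumb-first: (thumb, index, middle, ring,
    little). 0 = finger at rest, 1 = finger flexing.
    """

    name: str
    finger_state: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.finger_state) != N_FINGERS:
            raise ValueError(f"finger_state must have {N_FINGERS} entries")
        if any(b not in (0, 1) for b in self.finger_state):
            raise ValueError("finger_state entries must be 0 or 1")

    def code(self, order: str = "thumb_first") -> str:
        """Render the state as a bit string under an explicit ordering."""
        bits = self.finger_state
        if order == "thumb_first":
            pass
        elif order == "little_first":
            bits = bits[::-1]
        else:
            raise ValueError(f"unknown bit order: {order!r}")
        return "".join(str(b) for b in bits)

    @property
    def active_fingers(self) -> tuple[int, ...]:
        """Indices (0-based, thumb=0) of active fingers."""
        return tuple(i for i, b in enumerate(self.finger_state) if b)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.finger_state, dtype=np.int8)


_CODEBOOK: tuple[GestureCode, ...] = (
    GestureCode("thumb", (1, 0, 0, 0, 0)),
    GestureCode("index", (0, 1, 0, 0, 0)),
    GestureCode("middle", (0, 0, 1, 0, 0)),
    GestureCode("ring", (0, 0, 0, 1, 0)),
    GestureCode("little", (0, 0, 0, 0, 1)),
    # Pinches involve the thumb plus the named finger(s); bit strings in
    # circulation render these little-first, so "index_pinch" prints as
    # "00011" under order="little_first".
    GestureCode("index_pinch", (1, 1, 0, 0, 0)),
    GestureCode("tripod_pinch", (1, 1, 1, 0, 0)),
    GestureCode("fist", (1, 1, 1, 1, 1)),
    GestureCode("rest", (0, 0, 0, 0, 0)),
)


def codebook() -> list[GestureCode]:
    """The nine gestures used by the decoding task.

    Five single-finger flexions, index pinch, tripod pinch, fist, and rest.
    """
    return list(_CODEBOOK)


def lookup(name: str) -> GestureCode:
    for g in _CODEBOOK:
        if g.name == name:
            return g
    raise KeyError(f"unknown gesture name: {name!r}")


def enumerate_finger_states() -> Iterator[tuple[int, ...]]:
    """All admissible binary 5-vectors (2^5 = 32 combinations)."""
    for k in range(N_STATE_COMBINATIONS):
        yield tuple((k >> (N_FINGERS - 1 - i)) & 1 for i in range(N_FINGERS))
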