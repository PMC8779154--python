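"""Gesture classes and their 3-bit output state vectors.

The classifier communicates with the prosthetic hand through a 3-bit state
vector ``(a, b, c)``.  Each of the eight supported hand poses — rest plus
seven finger-flexion combinations — maps one-to-one onto a code, so decoding
is a total function over all eight possible bit patterns.
"""

from __future__ import annotations

from enum import Enum

__all__ = ["GestureClass", "StateVector", "NON_REST_CLASSES"]

StateVector = tuple[int, int, int]


class GestureClass(Enum):
    """The eight gesture classes and their ``(a, b, c)`` state vectors.

    Bit ``c`` marks index involvement, bit ``b`` middle, bit ``a``
    ring/pinky; combined flexions OR the bits together, so All Fingers is
    ``(1, 1, 1)`` and Rest is ``(0, 0, 0)``.
    """

    Rest = (0, 0, 0)
    Index = (0, 0, 1)
    Middle = (0, 1, 0)
    RingPinky = (1, 0, 0)
    IndexMiddle = (0, 1, 1)
    MiddleRingPinky = (1, 1, 0)
    IndexRingPinky = (1, 0, 1)
    AllFingers = (1, 1, 1)

    @property
    def code(self) -> StateVector:
        """The 3-bit output state vector ``(a, b, c)``."""
        return self.value

    @classmethod
    def from_code(cls, code: StateVector) -> "GestureClass":
        """Decode a 3-bit state vector to its gesture class.

        Total over all eight bit patterns; raises ``ValueError`` only for
        inputs that are not 3-bit vectors.
        """
        key = tuple(int(b) for b in code)
        if len(key) != 3 or any(b not in (0, 1) for b in key):
            raise ValueError(f"not a 3-bit state vector: {code!r}")
        return cls(key)

    @classmethod
    def from_name(cls, name: str) -> "GestureClass":
        try:
            return cls[name]
        except KeyError:
            raise ValueError(
                f"unknown gesture label {name!r}; expected one of "
                f"{[g.name for g in cls]}"
            ) from None


#: The seven non-rest poses, in the order they are held during a session.
NON_REST_CLASSES: tuple[GestureClass, ...] = (
    GestureClass.Index,
    GestureClass.Middle,
    GestureClass.RingPinky,
    GestureClass.IndexMiddle,
    GestureClass.MiddleRingPinky,
    GestureClass.IndexRingPinky,
    GestureClass.AllFingers,
)
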