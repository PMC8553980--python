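"""Symbol label vocabulary shared by the generator and the classifier."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

__all__ = ["SymbolKind", "SymbolLabel", "LABEL_SPACE", "label_index"]


class SymbolKind(str, enum.Enum):
    CLOCK_FACE = "clock_face"
    DIGIT = "digit"
    HOUR_HAND = "hour_hand"
    MINUTE_HAND = "minute_hand"
    NOISE = "noise"
    CROSS_OUT = "cross_out"
    OVERWRITE = "overwrite"


@dataclass(frozen=True)
class SymbolLabel:
    """A resolved symbol label; ``value`` is set iff kind is DIGIT (1..12)."""

    kind: SymbolKind
    value: Optional[int] = None

    def __post_init__(self):
        if self.kind is SymbolKind.DIGIT:
            if self.value is None or not 1 <= self.value <= 12:
                raise ValueError("digit label needs value in 1..12")
        elif self.value is not None:
            raise ValueError(f"{self.kind.value} label takes no value")

    def __str__(self) -> str:
        return f"digit_{self.value}" if self.kind is SymbolKind.DIGIT else self.kind.value

    @classmethod
    def parse(cls, s: str) -> "SymbolLabel":
        if s.startswith("digit_"):
            return cls(SymbolKind.DIGIT, int(s.split("_")[1]))
        return cls(SymbolKind(s))


#: Fixed ordering of the 18 label classes used for probability vectors:
#: clock_face, digit_1..digit_12, hour_hand, minute_hand, noise, cross_out,
#: overwrite.
LABEL_SPACE: tuple[SymbolLabel, ...] = (
    (SymbolLabel(SymbolKind.CLOCK_FACE),)
    + tuple(SymbolLabel(SymbolKind.DIGIT, v) for v in range(1, 13))
    + (
        SymbolLabel(SymbolKind.HOUR_HAND),
        SymbolLabel(SymbolKind.MINUTE_HAND),
        SymbolLabel(SymbolKind.NOISE),
        SymbolLabel(SymbolKind.CROSS_OUT),
        SymbolLabel(SymbolKind.OVERWRITE),
    )
)

_INDEX = {lab: i for i, lab in enumerate(LABEL_SPACE)}


def label_index(label: SymbolLabel) -> int:
    return _INDEX[label]
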