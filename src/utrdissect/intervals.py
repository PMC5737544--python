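"""Half-open genomic intervals on the reference coordinate frame."""

from __future__ import annotations

from typing import NamedTuple


class Interval(NamedTuple):
    """A 0-based half-open interval ``[start, end)``."""

    start: int
    end: int

    def __len__(self) -> int:
        return max(0, self.end - self.start)

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.start}, {self.end})"
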