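"""Degenerate barcode templates.

A barcode template is a short DNA pattern over ``{A, C, G, T, N}`` in which
``N`` marks a randomized ("free") position and any other letter is fixed.
The default TARDIS barcode is a 15-mer, ``NNNCNNTNTNANNNN``, with 11 free
positions and four fixed bases (C, T, T, A at 1-based positions 4, 7, 9
and 11).  Its design space therefore holds ``4**11 = 4,194,304`` (about
4.2 million) distinct sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

BASES = "ACGT"
DEFAULT_PATTERN = "NNNCNNTNTNANNNN"


class InvalidTemplateError(ValueError):
    """Raised when a template pattern contains symbols outside A/C/G/T/N."""


@dataclass(frozen=True)
class BarcodeTemplate:
    """A degenerate barcode pattern with fixed and free positions."""

    pattern: str = DEFAULT_PATTERN

    def __post_init__(self) -> None:
        if not self.pattern:
            raise InvalidTemplateError("template pattern is empty")
        bad = set(self.pattern) - set("ACGTN")
        if bad:
            raise InvalidTemplateError(
                f"template pattern contains non-ACGTN symbols: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def free_positions(self) -> tuple[int, ...]:
        """0-based indices of randomized (N) positions, in order."""
        return tuple(i for i, b in enumerate(self.pattern) if b == "N")

    @property
    def fixed_positions(self) -> tuple[tuple[int, str], ...]:
        """(0-based index, base) pairs for the constant positions."""
        return tuple((i, b) for i, b in enumerate(self.pattern) if b != "N")

    @property
    def space_size(self) -> int:
        return 4 ** len(self.free_positions)

    def matches(self, sequence: str) -> bool:
        """True if ``sequence`` has the template length and fixed bases."""
        if len(sequence) != self.length:
            return False
        return all(sequence[i] == b for i, b in self.fixed_positions)

    def iterate_space(self, limit: int = 2**20) -> Iterator[str]:
        """Deterministically yield every sequence in the template space.

        Free positions are filled in A<C<G<T order, last position fastest.
        Guarded by ``limit`` so that the 4.2-million default space is not
        enumerated by accident.
        """
        if self.space_size > limit:
            raise ValueError(
                f"template space of {self.space_size} exceeds limit {limit}"
            )
        free = self.free_positions
        chars = list(self.pattern)
        for combo in product(BASES, repeat=len(free)):
            for i, b in zip(free, combo):
                chars[i] = b
            yield "".join(chars)


def enumerate_space(template: BarcodeTemplate | str) -> int:
    """Number of distinct sequences a template can encode (``4**n_free``)."""
    if isinstance(template, str):
        template = BarcodeTemplate(template)
    return template.space_size
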