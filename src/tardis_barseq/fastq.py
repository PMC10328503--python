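"""Streaming FASTQ input/output (Phred+33, plain or gzip).

Records are validated strictly: four lines per record, ``@``/``+`` markers,
sequence and quality of equal length, quality characters in the printable
Phred+33 range.  Parse errors carry the 1-based line number of the
offending record so malformed files can be located quickly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

PHRED_OFFSET = 33
MAX_QUAL = 60


class FastqParseError(ValueError):
    """Malformed FASTQ record (with file line number in the message)."""


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases and per-base Phred qualities."""

    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FastqParseError(
                f"read {self.read_id!r}: sequence length {len(self.bases)} "
                f"!= quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def trimmed(self, start: int = 0, stop: int | None = None) -> "ReadRecord":
        """A copy restricted to the half-open base interval [start, stop)."""
        return ReadRecord(self.read_id, self.bases[start:stop], self.quals[start:stop])


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily yield :class:`ReadRecord` from a plain or gzipped FASTQ file.

    The read id is the header token up to the first whitespace, without
    the leading ``@``.
    """
    with _open_text(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header, got {header[:30]!r}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(f"line {lineno}: truncated record {header[:30]!r}")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual)} != sequence "
                    f"length {len(seq)} for read {header[1:].split()[0]!r}"
                )
            quals = []
            for ch in qual:
                q = ord(ch) - PHRED_OFFSET
                if not (0 <= q <= 93) or ord(ch) > 126:
                    raise FastqParseError(
                        f"line {lineno}: non-Phred+33 quality character {ch!r}"
                    )
                quals.append(q)
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            yield ReadRecord(read_id, seq, quals)


def format_record(record: ReadRecord) -> str:
    qual = "".join(chr(q + PHRED_OFFSET) for q in record.quals)
    return f"@{record.read_id}\n{record.bases}\n+\n{qual}\n"


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as Phred+33 FASTQ (gzip if the path ends in .gz).

    Returns the number of records written.
    """
    n = 0
    with _open_text(path, "wt") as handle:
        for record in records:
            handle.write(format_record(record))
            n += 1
    return n
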