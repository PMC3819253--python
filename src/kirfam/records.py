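"""Basic sequence containers used throughout the package.

A :class:`Transcript` is a single cDNA record; an :class:`Alignment` is an
ordered, equal-length collection of them. Coordinates are 0-based half-open
internally; report writers convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

NUCLEOTIDE_ALPHABET = frozenset("ACGTN-")

#: Characters treated as missing data in a column.
MISSING = frozenset("N-")


class FormatError(ValueError):
    """Raised for malformed input files or records."""


@dataclass
class Transcript:
    """A cDNA record.

    Sequences are upper-cased on construction and restricted to the
    nucleotide alphabet {A, C, G, T, N, -}.
    """

    id: str
    sequence: str
    individual: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("transcript id must be non-empty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise FormatError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FormatError(
                f"transcript {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass
class Alignment:
    """An ordered collection of equal-length transcripts."""

    members: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError("alignment must have at least one member")
        lengths = {len(t) for t in self.members}
        if len(lengths) != 1:
            raise FormatError(f"unequal member lengths: {sorted(lengths)}")
        ids = [t.id for t in self.members]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ids in alignment")

    @property
    def length(self) -> int:
        return len(self.members[0])

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.members)

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.members]

    def to_matrix(self) -> np.ndarray:
        """Return an (n, L) array of single-byte characters ('S1')."""
        return np.array(
            [np.frombuffer(t.sequence.encode(), dtype="S1") for t in self.members]
        )

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, ids: Iterable[str]) -> "Alignment":
        members = [
            Transcript(id=i, sequence=row.tobytes().decode())
            for i, row in zip(ids, matrix, strict=True)
        ]
        return cls(members)

    def take_columns(self, columns: np.ndarray) -> "Alignment":
        return Alignment.from_matrix(self.to_matrix()[:, columns], self.ids)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        by_id = {t.id: t for t in self.members}
        return Alignment([by_id[i] for i in wanted])


def check_unique_ids(transcripts: Iterable[Transcript]) -> None:
    seen: set[str] = set()
    for t in transcripts:
        if t.id in seen:
            raise FormatError(f"duplicate transcript id {t.id!r}")
        seen.add(t.id)
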