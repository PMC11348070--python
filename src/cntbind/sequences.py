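"""Sequence primitives shared across the package.

The experimental construct is a 66-nt single strand: an 18-nt forward primer,
a random 30-nt insert, and an 18-nt reverse primer region.  All affinity
analysis operates on the 30-nt insert only.
"""

from __future__ import annotations

from dataclasses import dataclass

ALPHABET = "ACGT"
INSERT_LENGTH = 30

FORWARD_PRIMER = "AGCGTCGAATACCACTAC"
REVERSE_REGION = "GACCACGAGCTCCATTAG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for sequences violating alphabet/length constraints."""


@dataclass(frozen=True)
class SequenceRecord:
    """A read or insert sequence with a multiplicity count.

    Alphabet and count are validated at construction; the 30-nt insert
    constraint is enforced by :func:`require_insert` at the operations that
    need it, because raw sequencing reads (66-151 nt) flow through the same
    container before primer trimming.
    """

    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError("empty sequence")
        bad = set(self.sequence) - set(ALPHABET + "N")
        if bad:
            raise SequenceError(f"invalid characters in sequence: {sorted(bad)}")
        if self.count < 0:
            raise SequenceError(f"negative count: {self.count}")


def require_insert(seq: str) -> str:
    """Validate that *seq* is a 30-nt string over {A,C,G,T} and return it."""
    if len(seq) != INSERT_LENGTH:
        raise SequenceError(
            f"expected a {INSERT_LENGTH}-nt insert, got length {len(seq)}"
        )
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise SequenceError(f"invalid characters in insert: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def library_space_size(length: int = INSERT_LENGTH, alphabet_size: int = 4) -> int:
    """Number of distinct random inserts, computed in exact integer arithmetic.

    For the 30-nt random region this is 4**30 ~ 1.15e18 unique sequences.
    """
    if length < 0 or alphabet_size < 1:
        raise ValueError("length must be >= 0 and alphabet_size >= 1")
    return alphabet_size**length
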