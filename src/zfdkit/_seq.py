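"""Small sequence helpers shared across modules.

Coordinates are 0-based half-open everywhere inside the package; report
writers convert to 1-based inclusive at serialization time.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Dinucleotide contexts of an edited cytosine (5' neighbour + C).
CONTEXTS = ("TC", "AC", "GC", "CC")


class ZfdkitError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(ZfdkitError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class ConsistencyError(ZfdkitError):
    """Inputs that should describe the same object disagree."""


class InfeasibleDesignError(ZfdkitError):
    """A finger-plan rearrangement cannot satisfy its constraints."""


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval [start, end) on a reference sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise InvalidArgumentError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise InvalidArgumentError(f"{name} is empty")
    if set(seq) - set("ACGTN"):
        raise InvalidArgumentError(f"{name} contains non-ACGTN characters")
    if set(seq) == {"N"}:
        raise InvalidArgumentError(f"{name} is all N")
    return seq


def circular_slice(seq: str, start: int, end: int) -> str:
    """Substring of a circular sequence; indices may run past either end."""
    n = len(seq)
    length = end - start
    if length > n:
        raise InvalidArgumentError("slice longer than the circular sequence")
    start %= n
    stop = start + length
    if stop <= n:
        return seq[start:stop]
    return seq[start:] + seq[: stop - n]


def c_context(seq: str, pos: int, strand: str, circular: bool = False) -> str:
    """Dinucleotide context (5' neighbour + C) of the cytosine at ``pos``.

    On the plus strand the reference base must be C and the 5' neighbour is
    ``seq[pos-1]``; on the minus strand the reference base is G and the 5'
    neighbour is the complement of ``seq[pos+1]``.  Returns "n/a" when the
    neighbour falls off a linear sequence end.
    """
    n = len(seq)
    if strand == "+":
        if seq[pos] != "C":
            raise InvalidArgumentError(f"position {pos} is not C on + strand")
        j = pos - 1
        if j < 0:
            if not circular:
                return "n/a"
            j = n - 1
        five = seq[j]
    elif strand == "-":
        if seq[pos] != "G":
            raise InvalidArgumentError(f"position {pos} is not C on - strand")
        j = pos + 1
        if j >= n:
            if not circular:
                return "n/a"
            j = 0
        five = seq[j].translate(COMPLEMENT)
    else:
        raise InvalidArgumentError(f"strand must be '+' or '-', got {strand!r}")
    ctx = five + "C"
    return ctx if ctx in CONTEXTS else "n/a"
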