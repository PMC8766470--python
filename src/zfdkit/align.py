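"""Semi-global read alignment and pileup construction.

Reads are aligned globally (every read base is accounted for) against a
reference whose overhanging ends are free, under affine gap penalties — the
standard amplicon-sequencing geometry.  The dynamic programming engine is
Biopython's :class:`Bio.Align.PairwiseAligner`; this module wraps it into a
compact :class:`Alignment` (CIGAR-style operations) and accumulates aligned
reads into a :class:`PileupMatrix` of per-position base/deletion counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._seq import ConsistencyError, Interval, InvalidArgumentError, validate_dna
from .simulate import FastqRecord

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c
DEL = 4  # deletion column index in the pileup


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class Alignment:
    """A read aligned to [ref_start, ref_end) of the reference.

    ``cigar`` is a tuple of (op, length) with op in {"M", "I", "D"}; "M"
    covers both matches and mismatches.  The read is fully consumed by the
    M and I operations.
    """

    read_id: str
    read_seq: str
    ref_start: int
    ref_end: int
    cigar: tuple[tuple[str, int], ...]
    score: float

    def has_indel(self) -> bool:
        return any(op in "ID" for op, _ in self.cigar)


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring):
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    # free gaps at the ends of the read row = unaligned reference overhangs
    a.end_deletion_score = 0
    return a


def align_read(
    read: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
) -> Alignment:
    """Optimal semi-global alignment of ``read`` within ``reference``.

    Ties between co-optimal alignments are broken deterministically (the
    engine's canonical enumeration order), so identical inputs always yield
    the identical alignment.
    """
    read = validate_dna(read, "read")
    reference = validate_dna(reference, "reference")
    aln = _aligner(scoring).align(reference, read)
    best = aln[0]
    t_blocks, q_blocks = (np.asarray(b, dtype=int) for b in best.aligned)
    if len(t_blocks) == 0:
        # degenerate optimum: the whole read is one insertion (no base pairs
        # with the reference at these scores)
        return Alignment(
            read_id=read_id,
            read_seq=read,
            ref_start=0,
            ref_end=0,
            cigar=(("I", len(read)),),
            score=float(aln.score),
        )

    cigar: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    push("I", int(q_blocks[0][0]))  # read overhang before the reference
    for k in range(len(t_blocks)):
        if k > 0:
            push("D", int(t_blocks[k][0] - t_blocks[k - 1][1]))
            push("I", int(q_blocks[k][0] - q_blocks[k - 1][1]))
        push("M", int(t_blocks[k][1] - t_blocks[k][0]))
    push("I", int(len(read) - q_blocks[-1][1]))  # read overhang after

    return Alignment(
        read_id=read_id,
        read_seq=read,
        ref_start=int(t_blocks[0][0]),
        ref_end=int(t_blocks[-1][1]),
        cigar=tuple(cigar),
        score=float(aln.score),
    )


def align_records(
    records: list[FastqRecord],
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[Alignment]:
    return [align_read(r.seq, reference, scoring, read_id=r.id) for r in records]


class PileupMatrix:
    """Per-reference-position counts of A/C/G/T/deletion plus insertion anchors.

    ``counts[p]`` sums to the number of reads whose alignment overlaps
    position p (deletions keep the read in the depth); insertions do not
    consume reference positions and are counted at the preceding position.
    """

    def __init__(self, length: int, circular: bool = False):
        if length < 1:
            raise InvalidArgumentError("reference length must be >= 1")
        self.length = length
        self.circular = circular
        self.counts = np.zeros((length, 5), dtype=np.int64)
        self.insertions = np.zeros(length, dtype=np.int64)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add(self, aln: Alignment) -> None:
        n = self.length
        if not self.circular and (aln.ref_start < 0 or aln.ref_end > n):
            raise ConsistencyError(
                f"alignment [{aln.ref_start}, {aln.ref_end}) outside reference of length {n}"
            )
        ref_pos = aln.ref_start
        read_pos = 0
        for op, ln in aln.cigar:
            if op == "M":
                seg = np.frombuffer(
                    aln.read_seq[read_pos : read_pos + ln].encode(), dtype=np.uint8
                )
                cols = _LUT[seg]
                valid = cols != 255  # N bases contribute nothing
                idx = ref_pos + np.nonzero(valid)[0]
                if self.circular:
                    idx = idx % n
                # positions are unique within one alignment, so plain fancy
                # indexing (no add.at) is safe
                self.counts[idx, cols[valid]] += 1
                ref_pos += ln
                read_pos += ln
            elif op == "D":
                idx = ref_pos + np.arange(ln)
                if self.circular:
                    idx = idx % n
                self.counts[idx, DEL] += 1
                ref_pos += ln
            elif op == "I":
                anchor = max(ref_pos - 1, 0)
                self.insertions[anchor % n if self.circular else anchor] += 1
                read_pos += ln
            else:  # pragma: no cover
                raise ConsistencyError(f"unknown cigar op {op!r}")


def build_pileup(
    alignments: list[Alignment],
    reference: str,
    circular: bool = False,
) -> PileupMatrix:
    """Accumulate alignments into a pileup over ``reference``.

    With ``circular=True`` reference coordinates are taken modulo the genome
    length, so alignments spanning the origin of a circular genome fold back.
    """
    reference = validate_dna(reference, "reference")
    pile = PileupMatrix(len(reference), circular=circular)
    for aln in alignments:
        pile.add(aln)
    return pile


def shift_alignment(aln: Alignment, offset: int) -> Alignment:
    """Translate an alignment made against a local window to global coordinates."""
    return Alignment(
        read_id=aln.read_id,
        read_seq=aln.read_seq,
        ref_start=aln.ref_start + offset,
        ref_end=aln.ref_end + offset,
        cigar=aln.cigar,
        score=aln.score,
    )


def overlapping(alignments: list[Alignment], window: Interval) -> list[Alignment]:
    return [a for a in alignments if a.ref_start < window.end and a.ref_end > window.start]
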