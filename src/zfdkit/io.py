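"""Reading and writing the standard interchange formats.

FASTA/FASTQ go through Biopython, SAM through pysam, tables through pandas.
All coordinates are 1-based in TSV reports and 0-based half-open in BED,
matching the usual conventions for those formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import Interval, InvalidArgumentError
from .align import Alignment
from .simulate import FastqRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_single_fasta(path) -> str:
    seqs = read_fasta(path)
    if len(seqs) != 1:
        raise InvalidArgumentError(f"{path} must contain exactly one sequence")
    return next(iter(seqs.values()))


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path) -> list[FastqRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        records.append(FastqRecord(rec.id, str(rec.seq).upper(), qual))
    if not records:
        raise InvalidArgumentError(f"{path} contains no reads")
    return records


def write_fastq(path, records: list[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_fastq())


def read_sam(path) -> list[Alignment]:
    """Pre-aligned reads from a SAM file mapped to a single reference.

    CIGAR M/=/X become M; I/S become insertions (soft clips are read bases
    without reference placement); D/N become deletions; hard clips are
    ignored.
    """
    import pysam

    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            cigar = []
            for op, ln in rec.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X
                    sym = "M"
                elif op in (1, 4):  # I, S
                    sym = "I"
                elif op in (2, 3):  # D, N
                    sym = "D"
                elif op == 5:  # H
                    continue
                else:
                    raise InvalidArgumentError(f"unsupported CIGAR op {op}")
                if cigar and cigar[-1][0] == sym:
                    cigar[-1] = (sym, cigar[-1][1] + ln)
                else:
                    cigar.append((sym, ln))
            ref_len = sum(ln for sym, ln in cigar if sym in "MD")
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    read_seq=rec.query_sequence.upper(),
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_start + ref_len,
                    cigar=tuple(cigar),
                    score=float(rec.mapping_quality),
                )
            )
    if not alignments:
        raise InvalidArgumentError(f"{path} contains no mapped reads")
    return alignments


def read_bed_intervals(path) -> list[tuple[str, Interval, str]]:
    """(name, interval, strand) triples from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InvalidArgumentError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else parts[0]
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((name, Interval(int(parts[1]), int(parts[2])), strand))
    return out


def write_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
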