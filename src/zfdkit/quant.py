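"""Per-position substitution statistics, editing windows, alleles and clones.

This is the targeted-deep-sequencing quantification stage: from a pileup it
derives per-position substitution frequencies (count/depth), C-to-T editing
profiles across a spacer window with C_n labels and dinucleotide contexts,
window indel frequencies, allele tables with amino-acid consequences under a
selectable genetic code, and clone classification from measured heteroplasmy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._seq import Interval, InvalidArgumentError, c_context, validate_dna
from .align import DEL, Alignment, PileupMatrix

_BASE_COLS = ("A", "C", "G", "T")

#: NCBI translation table ids.
STANDARD_CODE = 1
VERTEBRATE_MITO_CODE = 2


def substitution_table(
    pileup: PileupMatrix,
    reference: str,
    min_depth: int = 10,
    circular: bool = False,
) -> pd.DataFrame:
    """Per-position substitution frequencies.

    Frequencies are count/depth where depth counts every read overlapping the
    position (deleted bases included).  Positions with depth below
    ``min_depth`` are flagged missing and their frequencies are NaN rather
    than zero, so sparse positions do not deflate averages.  The ``context``
    column gives the dinucleotide context of the C on its strand for
    reference C (plus) and G (minus) positions, "n/a" elsewhere.
    """
    reference = validate_dna(reference, "reference")
    if len(reference) != pileup.length:
        raise InvalidArgumentError("reference length does not match pileup")
    if min_depth < 1:
        raise InvalidArgumentError("min_depth must be >= 1")
    depth = pileup.depth
    missing = depth < min_depth
    safe = np.where(depth > 0, depth, 1)
    freqs = pileup.counts / safe[:, None]
    freqs[missing] = np.nan

    contexts = []
    for pos, base in enumerate(reference):
        if base == "C":
            contexts.append(c_context(reference, pos, "+", circular=circular))
        elif base == "G":
            contexts.append(c_context(reference, pos, "-", circular=circular))
        else:
            contexts.append("n/a")

    return pd.DataFrame(
        {
            "pos": np.arange(1, pileup.length + 1),
            "ref": list(reference),
            "depth": depth,
            **{f"freq_{b}": freqs[:, i] for i, b in enumerate(_BASE_COLS)},
            "freq_del": freqs[:, DEL],
            "context": contexts,
            "missing": missing,
        }
    )


def window_c2t(
    table: pd.DataFrame,
    spacer: Interval,
    strand_of_edit: str = "both",
) -> pd.DataFrame:
    """C-to-T editing profile across a spacer window.

    Returns one row per cytosine of the requested strand(s) inside the
    spacer: plus-strand Cs report the C-to-T frequency, minus-strand Cs
    (reference G) the G-to-A frequency in plus coordinates.  Each row carries
    the label C_n where n is the 1-based offset of the position from the
    spacer's 5' end on the displayed (plus) strand, matching the numbering
    used for editing-window figures.
    """
    if strand_of_edit not in ("+", "-", "both"):
        raise InvalidArgumentError("strand_of_edit must be '+', '-' or 'both'")
    n_ref = len(table)
    if spacer.end > n_ref:
        raise InvalidArgumentError("spacer extends past the reference")
    rows = []
    for pos in range(spacer.start, spacer.end):
        rec = table.iloc[pos]
        if rec["ref"] == "C" and strand_of_edit in ("+", "both"):
            strand, freq = "+", rec["freq_T"]
        elif rec["ref"] == "G" and strand_of_edit in ("-", "both"):
            strand, freq = "-", rec["freq_A"]
        else:
            continue
        rows.append(
            {
                "pos": pos + 1,
                "label": f"C_{pos - spacer.start + 1}",
                "strand": strand,
                "context": rec["context"],
                "freq": freq,
                "missing": bool(rec["missing"]),
            }
        )
    return pd.DataFrame(
        rows, columns=["pos", "label", "strand", "context", "freq", "missing"]
    )


def indel_frequency(alignments: list[Alignment], window: Interval) -> float:
    """Fraction of window-overlapping reads with an indel inside the window.

    A deletion overlaps the window if its reference span intersects it; an
    insertion counts if its insertion point lies strictly inside the window.
    """
    n_total = 0
    n_indel = 0
    for aln in alignments:
        if not (aln.ref_start < window.end and aln.ref_end > window.start):
            continue
        n_total += 1
        ref_pos = aln.ref_start
        hit = False
        for op, ln in aln.cigar:
            if op == "M":
                ref_pos += ln
            elif op == "D":
                if ref_pos < window.end and ref_pos + ln > window.start:
                    hit = True
                ref_pos += ln
            elif op == "I":
                if window.start < ref_pos < window.end:
                    hit = True
        if hit:
            n_indel += 1
    return n_indel / n_total if n_total else 0.0


# ---------------------------------------------------------------------------
# Allele tables and amino-acid consequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFrame:
    """Reading-frame anchor: 0-based plus coordinate of a codon first base.

    For a minus-strand gene, ``codon_start`` is the plus coordinate of the
    first base of a codon read on the minus strand (the 3'-most plus
    coordinate of that codon).
    """

    codon_start: int
    strand: str = "+"


def _window_read_string(aln: Alignment, window: Interval) -> tuple[str, bool]:
    """Read bases over the window ('-' for deletions) and an in-window indel flag."""
    out = ["."] * len(window)
    has_indel = False
    ref_pos = aln.ref_start
    read_pos = 0
    for op, ln in aln.cigar:
        if op == "M":
            for i in range(ln):
                p = ref_pos + i
                if p in window:
                    out[p - window.start] = aln.read_seq[read_pos + i]
            ref_pos += ln
            read_pos += ln
        elif op == "D":
            for i in range(ln):
                p = ref_pos + i
                if p in window:
                    out[p - window.start] = "-"
                    has_indel = True
            ref_pos += ln
        elif op == "I":
            if window.start < ref_pos < window.end:
                has_indel = True
            read_pos += ln
    return "".join(out), has_indel


def _aa_changes(
    ref_window: str,
    alt_window: str,
    frame: GeneFrame,
    window: Interval,
    table: int,
) -> tuple[list[str], bool]:
    if frame.strand == "+":
        aa_offset = (window.start - frame.codon_start) // 3
        ref_cds, alt_cds = ref_window, alt_window
    else:
        aa_offset = (frame.codon_start - window.end + 1) // 3
        ref_cds = str(Seq(ref_window).reverse_complement())
        alt_cds = str(Seq(alt_window).reverse_complement())
    ref_aa = str(Seq(ref_cds).translate(table=table))
    alt_aa = str(Seq(alt_cds).translate(table=table))
    changes = []
    stop = False
    for i, (r, a) in enumerate(zip(ref_aa, alt_aa)):
        if r != a:
            changes.append(f"{r}{aa_offset + i + 1}{a}")
            if a == "*":
                stop = True
    return changes, stop


def allele_table(
    alignments: list[Alignment],
    reference: str,
    window: Interval,
    gene_frame: GeneFrame | None = None,
    genetic_code: int = STANDARD_CODE,
) -> pd.DataFrame:
    """Group window-spanning reads by their exact window sequence.

    Each non-reference allele is annotated with amino-acid substitutions under
    the requested NCBI translation table (vertebrate mitochondrial, table 2,
    for mtDNA genes; standard, table 1, otherwise); stop gains are written
    with '*' and flagged.  Alleles containing an indel are flagged frameshift
    and not translated.  Fractions are over reads spanning the whole window,
    so they sum to 1.
    """
    reference = validate_dna(reference, "reference")
    if window.end > len(reference):
        raise InvalidArgumentError("window extends past the reference")
    if gene_frame is not None:
        if len(window) % 3 != 0:
            raise InvalidArgumentError("window length is not a multiple of 3")
        if gene_frame.strand == "+":
            ok = (window.start - gene_frame.codon_start) % 3 == 0
        else:
            ok = (gene_frame.codon_start - window.end + 1) % 3 == 0
        if not ok:
            raise InvalidArgumentError("window is not aligned to codon boundaries")

    ref_window = reference[window.start : window.end]
    counts: dict[tuple[str, bool], int] = {}
    n_spanning = 0
    for aln in alignments:
        if aln.ref_start > window.start or aln.ref_end < window.end:
            continue
        key = _window_read_string(aln, window)
        if "." in key[0]:
            continue
        n_spanning += 1
        counts[key] = counts.get(key, 0) + 1
    if n_spanning == 0:
        raise InvalidArgumentError("no reads span the window")

    rows = []
    for (seq, has_indel), n in sorted(
        counts.items(), key=lambda kv: (-kv[1], kv[0][0])
    ):
        is_ref = seq == ref_window and not has_indel
        changes: list[str] = []
        stop = False
        if gene_frame is not None and not has_indel and not is_ref and "-" not in seq:
            changes, stop = _aa_changes(ref_window, seq, gene_frame, window, genetic_code)
        rows.append(
            {
                "allele": seq,
                "n_reads": n,
                "fraction": n / n_spanning,
                "is_reference": is_ref,
                "frameshift": has_indel,
                "aa_changes": ",".join(changes),
                "stop_gained": stop,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clonal classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CloneCall:
    clone_id: str
    frequency: float
    label: str  # "edited" | "background" | "indeterminate"


def classify_clone(
    frequency: float,
    background_max: float = 0.02,
    edited_min: float = 0.05,
    clone_id: str = "clone",
) -> CloneCall:
    """Label a clone from its measured variant frequency.

    Frequencies at or below ``background_max`` are sequencing-error background
    (untreated clones sit around 0.4-1%); at or above ``edited_min`` the clone
    carries a real heteroplasmic edit.  The open interval between the two
    thresholds is labelled indeterminate rather than forced to a side.
    """
    if not (0.0 <= background_max < edited_min <= 1.0):
        raise InvalidArgumentError(
            "thresholds must satisfy 0 <= background_max < edited_min <= 1"
        )
    if not (0.0 <= frequency <= 1.0):
        raise InvalidArgumentError("frequency must be in [0, 1]")
    if frequency <= background_max:
        label = "background"
    elif frequency >= edited_min:
        label = "edited"
    else:
        label = "indeterminate"
    return CloneCall(clone_id, frequency, label)


def edit_frequency(
    table: pd.DataFrame, positions: list[tuple[int, str]]
) -> float:
    """Mean conversion frequency over (0-based position, strand) sites."""
    if not positions:
        raise InvalidArgumentError("positions list is empty")
    vals = []
    for pos, strand in positions:
        rec = table.iloc[pos]
        freq = rec["freq_T"] if strand == "+" else rec["freq_A"]
        if not np.isnan(freq):
            vals.append(freq)
    return float(np.mean(vals)) if vals else float("nan")
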