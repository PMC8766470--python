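"""Whole-mitochondrial-genome off-target analysis.

Implements the genome-wide specificity workflow for double-strand-DNA
deaminase editors: map reads over a circular genome, tabulate C-to-T (plus
strand) and G-to-A (minus-strand C) conversion rates at every C/G position,
mask cell-line SNVs (positions converted at >= 50% in all samples), exclude
the on-target spacer, call off-target sites above a 1% conversion rate,
summarize mean on-/off-target rates and their ratio (the specificity ratio),
extract the sequence context around calls, and aggregate a dose series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (
    ConsistencyError,
    Interval,
    InvalidArgumentError,
    c_context,
    circular_slice,
    revcomp,
    validate_dna,
)
from .align import (
    DEFAULT_SCORING,
    Alignment,
    PileupMatrix,
    Scoring,
    align_read,
    build_pileup,
    shift_alignment,
)
from .simulate import FastqRecord


# ---------------------------------------------------------------------------
# Seed-and-extend mapping over a circular genome
# ---------------------------------------------------------------------------


def _kmer_index(genome: str, k: int) -> dict[str, list[int]]:
    ext = genome + genome[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(len(genome)):
        index.setdefault(ext[i : i + k], []).append(i)
    return index


def map_records(
    records: list[FastqRecord],
    genome: str,
    k: int = 20,
    margin: int = 10,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[Alignment]:
    """Map reads to a circular genome by unique k-mer seeding plus local
    semi-global alignment; alignments carry global (unwrapped) coordinates.

    Reads whose every k-mer seed is absent or ambiguous are dropped — at
    amplicon-scale error rates this loses a negligible fraction of reads.
    """
    genome = validate_dna(genome, "genome")
    n = len(genome)
    if k < 8 or k > n:
        raise InvalidArgumentError("k must be in [8, len(genome)]")
    index = _kmer_index(genome, k)
    out: list[Alignment] = []
    for rec in records:
        read = rec.seq
        start = None
        offsets = list(range(0, max(len(read) - k, 0) + 1, k))
        for off in offsets:
            hits = index.get(read[off : off + k])
            if hits and len(hits) == 1:
                start = (hits[0] - off) % n
                break
        if start is None:
            continue
        w_start = start - margin
        window = circular_slice(genome, w_start, start + len(read) + margin)
        aln = align_read(read, window, scoring, read_id=rec.id)
        out.append(shift_alignment(aln, w_start))
    return out


def genome_pileup(
    records: list[FastqRecord],
    genome: str,
    k: int = 20,
    scoring: Scoring = DEFAULT_SCORING,
) -> PileupMatrix:
    alignments = map_records(records, genome, k=k, scoring=scoring)
    return build_pileup(alignments, genome, circular=True)


# ---------------------------------------------------------------------------
# Conversion table
# ---------------------------------------------------------------------------


def genome_conversion_table(
    pileup: PileupMatrix,
    genome: str,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Conversion rate at every C/G position of the circular genome.

    Plus-strand Cs are scored by T count / depth; reference Gs carry the C on
    the minus strand and are scored by A count / depth in plus coordinates.
    A/T reference positions are absent.  Positions below ``min_depth`` do not
    enter the table.
    """
    genome = validate_dna(genome, "genome")
    if len(genome) != pileup.length:
        raise ConsistencyError("genome length does not match pileup")
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    depth = pileup.depth
    rows = []
    for pos in np.nonzero((arr == ord("C")) | (arr == ord("G")))[0]:
        pos = int(pos)
        d = int(depth[pos])
        if d < min_depth:
            continue
        if genome[pos] == "C":
            strand, conv = "+", int(pileup.counts[pos, 3])  # T column
        else:
            strand, conv = "-", int(pileup.counts[pos, 0])  # A column
        rows.append(
            {
                "pos": pos,
                "strand": strand,
                "depth": d,
                "converted": conv,
                "rate": conv / d,
                "context": c_context(genome, pos, strand, circular=True),
            }
        )
    return pd.DataFrame(rows, columns=["pos", "strand", "depth", "converted", "rate", "context"])


# ---------------------------------------------------------------------------
# SNV masking, off-target calling, specificity
# ---------------------------------------------------------------------------


def mask_variants(
    tables: dict[str, pd.DataFrame],
    threshold: float = 0.5,
) -> set[int]:
    """Positions converted at >= ``threshold`` in *every* sample.

    Such positions behave as pre-existing single-nucleotide variants of the
    cell line, not editing, and are excluded from off-target calling.  The
    comparison is inclusive; a position absent from any sample (e.g. below
    the depth cutoff there) is not masked.
    """
    if not tables:
        raise InvalidArgumentError("no samples supplied")
    if not (0.0 < threshold <= 1.0):
        raise InvalidArgumentError("threshold must be in (0, 1]")
    masked: set[int] | None = None
    for table in tables.values():
        high = set(table.loc[table["rate"] >= threshold, "pos"].astype(int))
        masked = high if masked is None else masked & high
    return masked or set()


@dataclass
class OffTargetCallSet:
    calls: pd.DataFrame  # pos, strand, rate, context
    min_rate: float
    masked: set[int] = field(default_factory=set)
    on_target: Interval | None = None

    @property
    def n_calls(self) -> int:
        return len(self.calls)


def _on_target_positions(
    table: pd.DataFrame, on_target: Interval
) -> pd.DataFrame:
    return table[(table["pos"] >= on_target.start) & (table["pos"] < on_target.end)]


def call_offtargets(
    table: pd.DataFrame,
    masked: set[int],
    on_target: Interval,
    min_rate: float = 0.01,
    genome_length: int | None = None,
) -> OffTargetCallSet:
    """Off-target calls: rate >= min_rate, not masked, outside the on-target
    spacer.  All three rules are inclusive/exclusive exactly as stated; the
    rate threshold is inclusive (>=), matching the >= 1% candidate rule.
    """
    if not (0.0 < min_rate <= 1.0):
        raise InvalidArgumentError("min_rate must be in (0, 1]")
    if genome_length is not None and on_target.end > genome_length:
        raise InvalidArgumentError("on-target interval outside the genome")
    keep = table[
        (table["rate"] >= min_rate)
        & ~table["pos"].isin(list(masked))
        & ~((table["pos"] >= on_target.start) & (table["pos"] < on_target.end))
    ]
    calls = keep[["pos", "strand", "rate", "context"]].reset_index(drop=True)
    return OffTargetCallSet(calls=calls, min_rate=min_rate, masked=set(masked), on_target=on_target)


@dataclass
class SpecificityReport:
    """Mean rates and their ratio for one sample.

    ``mean_on`` averages all C/G positions inside the on-target spacer;
    ``mean_off`` averages the called off-target sites; ``mean_genome``
    averages every C/G position in the table.  The specificity ratio is
    mean_on / mean_off, reported as undefined (None) when there are no
    off-target calls — never serialized as infinity.
    """

    mean_on: float
    mean_off: float | None
    mean_genome: float
    n_offtargets: int
    ratio: float | None
    ratio_defined: bool
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mean_on_target_rate": self.mean_on,
            "mean_off_target_rate": self.mean_off,
            "mean_genome_rate": self.mean_genome,
            "n_offtargets": self.n_offtargets,
            "specificity_ratio": self.ratio if self.ratio_defined else None,
            "ratio_defined": self.ratio_defined,
        }


def specificity_report(
    table: pd.DataFrame,
    on_target: Interval,
    calls: OffTargetCallSet,
    label: str = "",
) -> SpecificityReport:
    on = _on_target_positions(table, on_target)
    if on.empty:
        raise InvalidArgumentError("on-target interval contains no C/G position")
    mean_on = float(on["rate"].mean())
    mean_genome = float(table["rate"].mean()) if len(table) else 0.0
    if calls.n_calls > 0:
        mean_off = float(calls.calls["rate"].mean())
        ratio = mean_on / mean_off if mean_off > 0 else None
    else:
        mean_off = None
        ratio = None
    return SpecificityReport(
        mean_on=mean_on,
        mean_off=mean_off,
        mean_genome=mean_genome,
        n_offtargets=calls.n_calls,
        ratio=ratio,
        ratio_defined=ratio is not None,
        label=label,
    )


# ---------------------------------------------------------------------------
# Context matrix (sequence-logo input)
# ---------------------------------------------------------------------------


def context_matrix(
    calls: OffTargetCallSet,
    genome: str,
    flank: int = 5,
) -> pd.DataFrame:
    """Base fractions at each offset around called off-target Cs.

    Sequences are extracted on the edited strand (minus-strand calls are
    reverse-complemented) with the C at offset 0, wrapping the circular
    origin; each row (offset) sums to 1.  The offset -1 row exposes the TC
    preference.  The output is a position-frequency matrix directly
    consumable by logo-plotting tools.
    """
    genome = validate_dna(genome, "genome")
    if flank < 1:
        raise InvalidArgumentError("flank must be >= 1")
    if calls.n_calls == 0:
        raise InvalidArgumentError("no off-target calls to summarize")
    counts = np.zeros((2 * flank + 1, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for _, row in calls.calls.iterrows():
        pos, strand = int(row["pos"]), row["strand"]
        window = circular_slice(genome, pos - flank, pos + flank + 1)
        if strand == "-":
            window = revcomp(window)
        for off, base in enumerate(window):
            if base in base_idx:
                counts[off, base_idx[base]] += 1
    fracs = counts / counts.sum(axis=1, keepdims=True)
    out = pd.DataFrame(fracs, columns=list("ACGT"))
    out.insert(0, "offset", np.arange(-flank, flank + 1))
    return out


# ---------------------------------------------------------------------------
# Dose-response aggregation
# ---------------------------------------------------------------------------


def dose_response_summary(
    samples: list[tuple[str, pd.DataFrame]],
    on_target: Interval,
    min_rate: float = 0.01,
    snv_threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[SpecificityReport]]:
    """One specificity report per dose, with SNV masking shared across all
    samples (the all-samples rule, including any untreated control present).
    """
    if not samples:
        raise InvalidArgumentError("no samples supplied")
    labels = [lab for lab, _ in samples]
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError("duplicate dose labels")
    masked = mask_variants({lab: tab for lab, tab in samples}, threshold=snv_threshold)
    reports = []
    for lab, tab in samples:
        calls = call_offtargets(tab, masked, on_target, min_rate=min_rate)
        reports.append(specificity_report(tab, on_target, calls, label=lab))
    frame = pd.DataFrame([r.to_dict() for r in reports])
    return frame, reports
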