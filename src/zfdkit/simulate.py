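"""Synthetic references, reporter constructs and sequencing reads.

This module produces the inputs every downstream stage consumes: pTarget-style
reporter constructs with TC-repeat spacers, amplicon reads carrying a planted
strand-specific C-to-T deamination signal, clonal read populations with known
heteroplasmy fractions, and whole-mitochondrial-genome samples with planted
off-target edits.  Every generator is seeded and byte-deterministic, and each
emits a :class:`SimTruth` record so that recovery can be checked against the
planted ground truth.  Analysis stages never read the truth.

The deamination model is strand-specific: a cytosine edited on the minus
strand appears in plus-strand read coordinates as a G-to-A change.  Context
preference (TC >> AC/GC/CC) is expressed through per-context default rates;
``dose_scale`` multiplies every rate, emulating titration of the editor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import (
    Interval,
    InvalidArgumentError,
    c_context,
    circular_slice,
    validate_dna,
)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# _OTHER[b, k] = k-th base different from b (substitution error channel)
_OTHER = np.array([[c for c in range(4) if c != b] for b in range(4)], dtype=np.uint8)

#: Default sequencing quality symbol (Phred+33 'I' = Q40).
QUALITY_CHAR = "I"


@dataclass(frozen=True)
class FastqRecord:
    id: str
    seq: str
    qual: str

    def to_fastq(self) -> str:
        return f"@{self.id}\n{self.seq}\n+\n{self.qual}\n"


@dataclass(frozen=True)
class PlantedEdit:
    pos: int  # 0-based reference coordinate of the edited C (plus-strand coords)
    strand: str  # strand carrying the C ('+' ref C, '-' ref G)
    true_rate: float  # effective (dose-scaled) conversion probability
    context: str  # dinucleotide context of the C on its strand


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated reads; never fed to analysis."""

    planted_edits: list[PlantedEdit] = field(default_factory=list)
    planted_snvs: list[tuple[int, str, float]] = field(default_factory=list)
    per_clone_fractions: list[float] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["pos\tstrand\ttrue_rate\tcontext"]
        for e in self.planted_edits:
            lines.append(f"{e.pos + 1}\t{e.strand}\t{e.true_rate:.6g}\t{e.context}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_edits": [
                    {"pos": e.pos + 1, "strand": e.strand,
                     "true_rate": e.true_rate, "context": e.context}
                    for e in self.planted_edits
                ],
                "planted_snvs": [
                    {"pos": p + 1, "alt": alt, "fraction": f}
                    for p, alt, f in self.planted_snvs
                ],
                "per_clone_fractions": self.per_clone_fractions,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# pTarget reporter constructs
# ---------------------------------------------------------------------------

#: Fixed flanks around the (left site, spacer, right site) cassette.
PTARGET_LEFT_FLANK = "GAATTCGCTAGC"
PTARGET_RIGHT_FLANK = "GGATCCTTAAGC"


@dataclass(frozen=True)
class PTargetConstruct:
    left_site: str
    spacer: str
    right_site: str
    full_sequence: str

    @property
    def spacer_interval(self) -> Interval:
        start = len(PTARGET_LEFT_FLANK) + len(self.left_site)
        return Interval(start, start + len(self.spacer))


def tc_repeat(length: int) -> str:
    """Prefix of the infinite repeat "TCTCTC..." (length 1 -> "T")."""
    if length <= 0:
        raise InvalidArgumentError(f"spacer length must be >= 1, got {length}")
    return ("TC" * ((length + 1) // 2))[:length]


def make_ptarget_library(
    left_site: str,
    right_site: str,
    spacer_lengths: Iterable[int],
) -> list[PTargetConstruct]:
    """One reporter construct per requested spacer length.

    The spacer is a TC-repeat prefix so that every other spacer position is a
    cytosine in TC context, the deaminase's preferred substrate.
    """
    left_site = validate_dna(left_site, "left_site")
    right_site = validate_dna(right_site, "right_site")
    lengths = list(spacer_lengths)
    if not lengths:
        raise InvalidArgumentError("spacer_lengths is empty")
    out = []
    for k in lengths:
        spacer = tc_repeat(k)
        full = PTARGET_LEFT_FLANK + left_site + spacer + right_site + PTARGET_RIGHT_FLANK
        out.append(PTargetConstruct(left_site, spacer, right_site, full))
    return out


# ---------------------------------------------------------------------------
# Editing model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditingModel:
    """Per-position, per-strand deamination probabilities plus noise channels.

    ``rates`` maps (position, strand) to the base conversion probability
    before dose scaling; every keyed position is a C on the stated strand.
    ``dose_scale`` multiplies all rates (editing and indel channels) and
    emulates the delivered editor dose; 0 yields an identity channel apart
    from sequencing error.
    """

    window: Interval
    rates: Mapping[tuple[int, str], float]
    contexts: Mapping[tuple[int, str], str]
    seq_error_rate: float = 0.0
    indel_rate: float = 0.0
    dose_scale: float = 1.0

    def effective_rate(self, pos: int, strand: str) -> float:
        return self.rates.get((pos, strand), 0.0) * self.dose_scale

    def effective_edits(self) -> list[tuple[int, str, float]]:
        return [
            (pos, strand, rate * self.dose_scale)
            for (pos, strand), rate in self.rates.items()
        ]

    def with_dose(self, dose_scale: float) -> "EditingModel":
        _check_prob(dose_scale, "dose_scale")
        return replace(self, dose_scale=dose_scale)


def _check_prob(p: float, name: str) -> float:
    if not (0.0 <= p <= 1.0):
        raise InvalidArgumentError(f"{name} must be in [0, 1], got {p}")
    return p


def make_editing_model(
    reference: str,
    window: Interval,
    explicit_rates: Mapping[tuple[int, str], float] | None = None,
    context_defaults: Mapping[str, float] | None = None,
    seq_error_rate: float = 0.0,
    indel_rate: float = 0.0,
    dose_scale: float = 1.0,
    circular: bool = False,
) -> EditingModel:
    """Resolve per-position rates over the editing window.

    Positions without an explicit rate inherit the default for their
    dinucleotide context (base 5' of the C on the edited strand); non-C
    positions get rate 0 and are omitted.  Reference C positions are edited
    on the plus strand, reference G positions on the minus strand (observed
    as G-to-A in plus coordinates).
    """
    reference = validate_dna(reference, "reference")
    if window.end > len(reference):
        raise InvalidArgumentError("window extends past the reference")
    explicit = dict(explicit_rates or {})
    defaults = dict(context_defaults or {})
    for name, p in defaults.items():
        _check_prob(p, f"context rate {name}")
    _check_prob(seq_error_rate, "seq_error_rate")
    _check_prob(indel_rate, "indel_rate")
    _check_prob(dose_scale, "dose_scale")

    rates: dict[tuple[int, str], float] = {}
    contexts: dict[tuple[int, str], str] = {}
    for pos in range(window.start, window.end):
        base = reference[pos]
        if base == "C":
            strand = "+"
        elif base == "G":
            strand = "-"
        else:
            continue
        ctx = c_context(reference, pos, strand, circular=circular)
        key = (pos, strand)
        if key in explicit:
            rate = _check_prob(explicit.pop(key), f"rate at {key}")
        else:
            rate = defaults.get(ctx, 0.0)
        if rate > 0.0:
            rates[key] = rate
            contexts[key] = ctx
    for (pos, strand), rate in explicit.items():
        # explicit rates outside the window, or on a non-C base, are errors
        _check_prob(rate, f"rate at ({pos}, {strand})")
        expected = "C" if strand == "+" else "G"
        if not (0 <= pos < len(reference)) or reference[pos] != expected:
            raise InvalidArgumentError(
                f"explicit rate at ({pos}, {strand}) is not on a C of that strand"
            )
        raise InvalidArgumentError(
            f"explicit rate at ({pos}, {strand}) lies outside the editing window"
        )
    return EditingModel(
        window=window,
        rates=rates,
        contexts=contexts,
        seq_error_rate=seq_error_rate,
        indel_rate=indel_rate,
        dose_scale=dose_scale,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for b, c in _CODE.items():
        lut[ord(b)] = c
    out = lut[codes]
    if (out == 255).any():
        raise InvalidArgumentError("sequence contains bases outside ACGT")
    return out


def _apply_seq_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Uniform substitution error: each base flips to one of the 3 others."""
    if rate <= 0.0:
        return
    mask = rng.random(mat.shape) < rate
    idx = np.nonzero(mask)
    if idx[0].size:
        k = rng.integers(0, 3, size=idx[0].size)
        mat[idx] = _OTHER[mat[idx], k]


def _truth_from_model(model: EditingModel) -> list[PlantedEdit]:
    return [
        PlantedEdit(pos, strand, rate * model.dose_scale,
                    model.contexts.get((pos, strand), "n/a"))
        for (pos, strand), rate in model.rates.items()
    ]


def simulate_reads(
    reference: str,
    model: EditingModel,
    n_reads: int,
    seed: int,
    read_prefix: str = "read",
) -> tuple[list[FastqRecord], SimTruth]:
    """Single-end reads fully covering the amplicon.

    Per-position conversions are sampled Bernoulli(rate * dose_scale); minus-
    strand edits are emitted as G-to-A in plus-strand coordinates.  Substitution
    sequencing errors are applied uniformly; the indel channel inserts or
    deletes one base inside the editing window in a Bernoulli(indel_rate *
    dose_scale) fraction of reads.  Identical (inputs, seed) give byte-identical
    records.
    """
    reference = validate_dna(reference, "reference")
    if n_reads < 1:
        raise InvalidArgumentError(f"n_reads must be >= 1, got {n_reads}")
    rng = np.random.default_rng(seed)
    codes = _encode(reference)
    mat = np.tile(codes, (n_reads, 1))

    for pos, strand, eff in model.effective_edits():
        if eff <= 0.0:
            continue
        hits = rng.random(n_reads) < eff
        mat[hits, pos] = _CODE["T"] if strand == "+" else _CODE["A"]

    _apply_seq_errors(mat, model.seq_error_rate, rng)

    indel_eff = model.indel_rate * model.dose_scale
    indel_reads = (
        np.nonzero(rng.random(n_reads) < indel_eff)[0] if indel_eff > 0 else []
    )
    seqs = [_BASES[row].tobytes().decode() for row in mat]
    for i in indel_reads:
        pos = int(rng.integers(model.window.start, model.window.end))
        if rng.random() < 0.5:  # 1-bp deletion
            seqs[i] = seqs[i][:pos] + seqs[i][pos + 1 :]
        else:  # 1-bp insertion
            ins = "ACGT"[rng.integers(0, 4)]
            seqs[i] = seqs[i][:pos] + ins + seqs[i][pos:]

    records = [
        FastqRecord(f"{read_prefix}_{i}", s, QUALITY_CHAR * len(s))
        for i, s in enumerate(seqs)
    ]
    return records, SimTruth(planted_edits=_truth_from_model(model))


def _edited_haplotype(codes: np.ndarray, model: EditingModel) -> np.ndarray:
    """The fully edited molecule: every positive-rate position converted."""
    hap = codes.copy()
    for pos, strand, eff in model.effective_edits():
        if eff > 0.0:
            hap[pos] = _CODE["T"] if strand == "+" else _CODE["A"]
    return hap


def simulate_clonal_populations(
    reference: str,
    model: EditingModel,
    fractions: Sequence[float],
    reads_per_clone: int,
    seed: int,
) -> tuple[list[tuple[str, list[FastqRecord]]], SimTruth]:
    """Per-clone read sets mixing edited and unedited mtDNA molecules.

    A clone with heteroplasmy fraction f draws each read from the fully
    edited haplotype with probability f and from the reference otherwise,
    then applies sequencing error; the measured conversion frequency at a
    planted position therefore estimates f directly.
    """
    reference = validate_dna(reference, "reference")
    if not list(fractions):
        raise InvalidArgumentError("fractions list is empty")
    for f in fractions:
        _check_prob(f, "heteroplasmy fraction")
    if reads_per_clone < 1:
        raise InvalidArgumentError("reads_per_clone must be >= 1")
    rng = np.random.default_rng(seed)
    codes = _encode(reference)
    hap = _edited_haplotype(codes, model)
    clones = []
    for ci, f in enumerate(fractions):
        edited = rng.random(reads_per_clone) < f
        mat = np.where(edited[:, None], hap[None, :], codes[None, :]).astype(np.uint8)
        _apply_seq_errors(mat, model.seq_error_rate, rng)
        recs = [
            FastqRecord(f"clone{ci}_{i}", _BASES[row].tobytes().decode(),
                        QUALITY_CHAR * len(reference))
            for i, row in enumerate(mat)
        ]
        clones.append((f"clone{ci}", recs))
    truth = SimTruth(
        planted_edits=_truth_from_model(model),
        per_clone_fractions=[float(f) for f in fractions],
    )
    return clones, truth


# ---------------------------------------------------------------------------
# Whole-mitochondrial-genome simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffTargetSpec:
    """Planted genome-wide off-target editing.

    ``n_sites`` C/G positions outside the on-target spacer receive rates drawn
    uniformly from ``rate_range``; at least ``tc_context_fraction`` of them sit
    in TC context, mirroring the deaminase's substrate preference.
    """

    n_sites: int
    rate_range: tuple[float, float] = (0.02, 0.10)
    tc_context_fraction: float = 0.8


def random_genome(length: int, seed: int, gc: float = 0.44) -> str:
    """Random circular-genome-like sequence with mtDNA-ish GC content."""
    if length < 1:
        raise InvalidArgumentError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def simulate_mtdna_sample(
    genome: str,
    on_model: EditingModel,
    offtarget_spec: OffTargetSpec,
    depth: int,
    seed: int,
    read_length: int = 150,
    snvs: Sequence[tuple[int, str, float]] = (),
) -> tuple[list[FastqRecord], SimTruth]:
    """Reads tiled over a circular genome with planted on- and off-target edits.

    Fixed-length reads start at uniform positions (wrapping the origin) to the
    requested mean depth.  Off-target sites are sampled from C/G positions
    outside the on-target window, honouring the TC-context fraction; their
    rates are scaled by the on-target model's ``dose_scale`` so that a dose
    series scales on- and off-target signal together.  ``snvs`` plants
    homoplasmic-like variants (pos, alt, fraction) shared across samples.
    """
    genome = validate_dna(genome, "genome")
    n = len(genome)
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    if read_length < 20 or read_length > n:
        raise InvalidArgumentError("read_length must be in [20, len(genome)]")
    spec = offtarget_spec
    if spec.n_sites < 0:
        raise InvalidArgumentError("n_sites must be >= 0")
    lo, hi = spec.rate_range
    _check_prob(lo, "rate_range low")
    _check_prob(hi, "rate_range high")
    if lo > hi:
        raise InvalidArgumentError("rate_range inverted")
    _check_prob(spec.tc_context_fraction, "tc_context_fraction")

    rng = np.random.default_rng(seed)

    # candidate off-target C/G positions, split by context
    tc_pool, other_pool = [], []
    for pos, base in enumerate(genome):
        if pos in on_model.window:
            continue
        if base == "C":
            strand = "+"
        elif base == "G":
            strand = "-"
        else:
            continue
        ctx = c_context(genome, pos, strand, circular=True)
        (tc_pool if ctx == "TC" else other_pool).append((pos, strand, ctx))
    n_tc = int(round(spec.tc_context_fraction * spec.n_sites))
    n_other = spec.n_sites - n_tc
    if n_tc > len(tc_pool) or n_other > len(other_pool):
        raise InvalidArgumentError(
            "n_sites exceeds available C/G positions in the requested contexts"
        )
    picked = [
        tc_pool[i] for i in sorted(rng.choice(len(tc_pool), n_tc, replace=False))
    ] + [
        other_pool[i] for i in sorted(rng.choice(len(other_pool), n_other, replace=False))
    ]
    off_rates = rng.uniform(lo, hi, size=len(picked))

    dose = on_model.dose_scale
    edits: list[PlantedEdit] = _truth_from_model(on_model)
    for (pos, strand, ctx), r in zip(picked, off_rates):
        edits.append(PlantedEdit(pos, strand, float(r) * dose, ctx))

    n_reads = max(1, int(round(depth * n / read_length)))
    starts = rng.integers(0, n, size=n_reads)
    codes = _encode(genome)
    ext = np.concatenate([codes, codes[: read_length - 1]])
    mat = ext[starts[:, None] + np.arange(read_length)[None, :]].copy()

    for e in edits:
        if e.true_rate <= 0.0:
            continue
        rel = (e.pos - starts) % n
        cov = np.nonzero(rel < read_length)[0]
        if cov.size == 0:
            continue
        hits = cov[rng.random(cov.size) < e.true_rate]
        mat[hits, rel[hits]] = _CODE["T"] if e.strand == "+" else _CODE["A"]

    snv_truth = []
    for pos, alt, frac in snvs:
        _check_prob(frac, "snv fraction")
        if alt not in "ACGT":
            raise InvalidArgumentError(f"snv alt must be a base, got {alt!r}")
        rel = (pos - starts) % n
        cov = np.nonzero(rel < read_length)[0]
        hits = cov[rng.random(cov.size) < frac]
        mat[hits, rel[hits]] = _CODE[alt]
        snv_truth.append((int(pos), alt, float(frac)))

    _apply_seq_errors(mat, on_model.seq_error_rate, rng)

    records = [
        FastqRecord(f"mt_{i}", _BASES[row].tobytes().decode(),
                    QUALITY_CHAR * read_length)
        for i, row in enumerate(mat)
    ]
    truth = SimTruth(planted_edits=edits, planted_snvs=snv_truth)
    return records, truth
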