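"""ZFD architecture enumeration, target-site scanning and finger planning.

A zinc finger deaminase (ZFD) pair is defined by an amino-acid linker length,
a DddA_tox split position (G1333 or G1397), which side carries the N-terminal
half, and the fusion configuration (CC or NC: which ZFP terminus carries the
deaminase half).  A candidate target site is a (left half-site, spacer, right
half-site) window whose spacer contains editable cytosines — preferentially
in TC context, the split deaminase's favoured substrate.  This module also
implements the ZFN-to-ZFD finger rearrangement (widen the spacer to >= 7 bp
by removing spacer-proximal fingers, then restore a minimum of four fingers)
and the R(-5)Q "QQ" high-specificity framework variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

from ._seq import (
    Interval,
    InfeasibleDesignError,
    InvalidArgumentError,
    circular_slice,
    revcomp,
    validate_dna,
)

LINKER_LENGTHS = (2, 5, 10, 16, 24, 32)
SPLIT_POSITIONS = ("G1333", "G1397")
FUSION_SIDES = ("left", "right")
CONFIGURATIONS = ("CC", "NC")


@dataclass(frozen=True)
class ZFDArchitecture:
    linker_length: int
    split_position: str
    n_half_side: str  # which monomer carries the N-terminal DddA_tox half
    configuration: str = "CC"

    def __post_init__(self) -> None:
        if self.linker_length not in LINKER_LENGTHS:
            raise InvalidArgumentError(f"linker_length must be one of {LINKER_LENGTHS}")
        if self.split_position not in SPLIT_POSITIONS:
            raise InvalidArgumentError(f"split_position must be one of {SPLIT_POSITIONS}")
        if self.n_half_side not in FUSION_SIDES:
            raise InvalidArgumentError(f"n_half_side must be one of {FUSION_SIDES}")
        if self.configuration not in CONFIGURATIONS:
            raise InvalidArgumentError(f"configuration must be one of {CONFIGURATIONS}")


def enumerate_architectures(
    linkers=LINKER_LENGTHS,
    splits=SPLIT_POSITIONS,
    orientations=FUSION_SIDES,
    configurations=("CC",),
) -> list[ZFDArchitecture]:
    """Cartesian product of the design variables, deterministically ordered.

    The default space is the 24-construct screen: 6 linker lengths x 2 split
    positions x 2 fusion orientations.
    """
    return [
        ZFDArchitecture(l, s, o, c)
        for l, s, o, c in product(linkers, splits, orientations, configurations)
    ]


# ---------------------------------------------------------------------------
# Target-site scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditableC:
    offset: int  # 1-based C_n offset from the spacer 5' end (displayed strand)
    strand: str  # spacer strand carrying the C, relative to the displayed site
    context: str


@dataclass(frozen=True)
class CandidateSite:
    """A (left half-site, spacer, right half-site) window on one strand.

    ``start`` is the 0-based plus-strand coordinate of the leftmost base of
    the site (on the displayed strand for '+', of the plus-strand projection
    for '-').  ``editable_cs`` lists every spacer cytosine on either spacer
    strand with its context; TC-context entries are the preferred substrates.
    """

    start: int
    strand: str
    left_site: str
    spacer: str
    right_site: str
    editable_cs: tuple[EditableC, ...] = ()

    @property
    def spacer_interval(self) -> Interval:
        # interval on the displayed strand's local coordinates
        return Interval(self.start + len(self.left_site),
                        self.start + len(self.left_site) + len(self.spacer))


def _spacer_cs(window: str, half_len: int, spacer_len: int) -> tuple[EditableC, ...]:
    """All cytosines in the spacer, on either strand, with contexts.

    The 5' neighbour may come from the flanking half-site.  A displayed-strand
    C at spacer offset i has context window[h+i-1] + 'C'; an opposite-strand C
    (displayed G) reads its 5' neighbour from the complement of the next base.
    """
    h = half_len
    out = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in range(spacer_len):
        base = window[h + i]
        if base == "C":
            out.append(EditableC(i + 1, "+", window[h + i - 1] + "C"))
        elif base == "G":
            out.append(EditableC(i + 1, "-", comp[window[h + i + 1]] + "C"))
    return tuple(out)


def scan_sites(
    sequence: str,
    half_len: int = 12,
    spacer_range: tuple[int, int] = (7, 15),
    require_editable_c: bool = False,
    circular: bool = False,
    both_strands: bool = True,
) -> list[CandidateSite]:
    """Enumerate candidate ZFD sites over a region or circular genome.

    Every placement of left half-site + spacer + right half-site, for every
    spacer length in ``spacer_range`` (inclusive) and on both strands, is a
    candidate.  With ``require_editable_c`` only sites whose spacer contains
    at least one TC-context cytosine (on either spacer strand) are kept;
    AC/GC/CC-context cytosines are still reported since they edit, albeit
    less efficiently.
    """
    sequence = validate_dna(sequence, "sequence")
    smin, smax = spacer_range
    if smin < 1 or smin > smax:
        raise InvalidArgumentError(f"invalid spacer_range {spacer_range}")
    if half_len < 1:
        raise InvalidArgumentError("half_len must be >= 1")
    n = len(sequence)
    if n < 2 * half_len + smin:
        raise InvalidArgumentError("sequence shorter than the smallest site")

    strands = ("+", "-") if both_strands else ("+",)
    sites = []
    for strand in strands:
        seq = sequence if strand == "+" else revcomp(sequence)
        for spacer_len in range(smin, smax + 1):
            total = 2 * half_len + spacer_len
            if total > n:
                continue
            n_starts = n if circular else n - total + 1
            for start in range(n_starts):
                window = circular_slice(seq, start, start + total) if circular else seq[start : start + total]
                cs = _spacer_cs(window, half_len, spacer_len)
                if require_editable_c and not any(c.context == "TC" for c in cs):
                    continue
                if strand == "+":
                    plus_start = start
                else:
                    plus_start = (n - start - total) % n if circular else n - start - total
                sites.append(
                    CandidateSite(
                        start=plus_start,
                        strand=strand,
                        left_site=window[:half_len],
                        spacer=window[half_len : half_len + spacer_len],
                        right_site=window[half_len + spacer_len :],
                        editable_cs=cs,
                    )
                )
    sites.sort(key=lambda s: (s.strand, len(s.spacer), s.start))
    return sites


# ---------------------------------------------------------------------------
# Zinc finger module tables and coverage
# ---------------------------------------------------------------------------


@dataclass
class ZFModuleTable:
    """Map from DNA triplet to available zinc finger module identifiers."""

    modules: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for trip in self.modules:
            if len(trip) != 3 or set(trip) - set("ACGT"):
                raise InvalidArgumentError(f"bad triplet key {trip!r}")

    @classmethod
    def from_tsv(cls, path) -> "ZFModuleTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if "triplet" not in df.columns or "finger_id" not in df.columns:
            raise InvalidArgumentError(
                "module table needs 'triplet' and 'finger_id' columns"
            )
        modules: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            modules.setdefault(row["triplet"].upper(), []).append(row["finger_id"])
        return cls({t: tuple(v) for t, v in modules.items()})


@dataclass
class CoverageResult:
    subsites: list[tuple[str, tuple[str, ...]]]  # (triplet 3'->5' order, fingers)
    designable: bool
    missing: list[str]


def module_coverage(
    half_site: str,
    table: ZFModuleTable,
    half: str = "left",
) -> CoverageResult:
    """Per-3-bp-subsite module availability for one half-site.

    Fingers listed N-to-C bind subsites 3'-to-5' on the displayed strand, so
    subsites are reported in that order.  The site is designable iff every
    subsite has at least one module.
    """
    half_site = validate_dna(half_site, "half_site")
    if half not in ("left", "right"):
        raise InvalidArgumentError("half must be 'left' or 'right'")
    if len(half_site) % 3 != 0:
        raise InvalidArgumentError("half-site length must be divisible by 3")
    triplets = [half_site[i : i + 3] for i in range(0, len(half_site), 3)]
    triplets.reverse()  # 3'->5' subsite order = N->C finger order
    subsites = [(t, table.modules.get(t, ())) for t in triplets]
    missing = [t for t, fingers in subsites if not fingers]
    return CoverageResult(subsites=subsites, designable=not missing, missing=missing)


# ---------------------------------------------------------------------------
# Finger plans: ZFN -> ZFD conversion and the QQ variant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finger:
    """One zinc finger with a framework annotation.

    ``framework`` maps positions relative to the recognition helix (e.g. -5)
    to amino-acid residues; the -5 residue makes the non-specific phosphate
    contact removed in the QQ variant.
    """

    name: str
    framework: dict[int, str] | None = None
    flags: tuple[str, ...] = ()

    def __hash__(self) -> int:  # framework dict is treated as identity-free
        return hash((self.name, self.flags))


@dataclass(frozen=True)
class FingerPlan:
    """An ordered finger array; ``fingers[0]`` is spacer-proximal.

    Fingers are listed from the spacer-proximal ("back") end to the spacer-
    distal ("front") end, so the ZFN-to-ZFD rearrangement removes from the
    head and appends to the tail.
    """

    fingers: tuple[Finger, ...]
    spacer_length: int
    removed: tuple[str, ...] = ()
    added: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.fingers) < 1:
            raise InvalidArgumentError("a finger plan needs at least one finger")


def zfn_to_zfd_conversion(
    plan: FingerPlan,
    min_spacer: int = 7,
    min_fingers: int = 4,
) -> FingerPlan:
    """Rearrange a nuclease-derived finger array for deaminase spacing.

    ZFNs cut in 5-6 bp spacers but the deaminase needs >= ``min_spacer`` bp,
    so spacer-proximal fingers are removed (each widens the spacer by its
    3-bp subsite) until the spacer is wide enough; if fewer than
    ``min_fingers`` remain, generic fingers are appended at the distal end to
    restore binding strength.  Raises when the spacer cannot be widened
    enough while keeping at least three fingers.
    """
    if len(plan.fingers) < 3:
        raise InvalidArgumentError("conversion needs a plan with >= 3 fingers")
    if min_spacer < 1 or min_fingers < 1:
        raise InvalidArgumentError("min_spacer and min_fingers must be >= 1")
    fingers = list(plan.fingers)
    spacer = plan.spacer_length
    removed = []
    while spacer < min_spacer:
        if len(fingers) <= 3:
            raise InfeasibleDesignError(
                f"cannot reach spacer {min_spacer} without dropping below 3 fingers"
            )
        removed.append(fingers.pop(0).name)
        spacer += 3
    added = []
    i = 1
    while len(fingers) < min_fingers:
        name = f"added_F{i}"
        fingers.append(Finger(name=name, framework={-5: "R"}, flags=("added",)))
        added.append(name)
        i += 1
    return FingerPlan(
        fingers=tuple(fingers),
        spacer_length=spacer,
        removed=plan.removed + tuple(removed),
        added=plan.added + tuple(added),
    )


#: Fallback search order around position -5 for the QQ substitution.
QQ_SEARCH_ORDER = (-4, -6, -3, -7)


def apply_qq_variant(plan: FingerPlan) -> FingerPlan:
    """R(-5)Q substitution in every finger framework.

    An arginine at framework position -5 becomes glutamine; if none is
    present, the nearest annotated K or R (searched at -4, -6, -3, -7, in
    that order) is converted instead; fingers with no candidate are left
    unchanged and flagged.  Already-converted fingers are skipped, making the
    transformation idempotent.
    """
    new_fingers = []
    for f in plan.fingers:
        if "qq" in f.flags or "qq_no_candidate" in f.flags:
            new_fingers.append(f)
            continue
        if f.framework is None:
            raise InvalidArgumentError(f"finger {f.name} lacks a framework annotation")
        fw = dict(f.framework)
        target = None
        if fw.get(-5) == "R":
            target = -5
        else:
            for p in QQ_SEARCH_ORDER:
                if fw.get(p) in ("K", "R"):
                    target = p
                    break
        if target is None:
            new_fingers.append(replace(f, flags=f.flags + ("qq_no_candidate",)))
        else:
            fw[target] = "Q"
            new_fingers.append(
                replace(f, framework=fw, flags=f.flags + ("qq", f"qq_at_{target}"))
            )
    return replace(plan, fingers=tuple(new_fingers))
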