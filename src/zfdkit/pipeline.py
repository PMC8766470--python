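"""End-to-end runs driven by a YAML manifest.

Four modes: ``simulate`` writes synthetic references and reads; ``amplicon``
quantifies targeted deep sequencing over an amplicon; ``mito`` runs the
whole-mitochondrial-genome off-target analysis; ``design`` scans for
candidate ZFD sites and checks module coverage.  Every run produces a
:class:`ReportBundle`: a directory with machine-readable JSON, the same
numbers in TSV tables, and a log echoing the fully resolved configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from ._seq import Interval, InvalidArgumentError
from . import io as zio
from .align import align_records
from .design import ZFModuleTable, enumerate_architectures, module_coverage, scan_sites
from .offtarget import (
    call_offtargets,
    context_matrix,
    genome_conversion_table,
    genome_pileup,
    mask_variants,
    specificity_report,
)
from .quant import (
    GeneFrame,
    allele_table,
    classify_clone,
    edit_frequency,
    indel_frequency,
    substitution_table,
    window_c2t,
)
from .simulate import make_editing_model, simulate_reads
from .align import build_pileup

log = logging.getLogger("zfdkit")


def _package_version() -> str:
    try:
        return version("zfdkit")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    mode: str
    params: dict
    seed: int = 0
    outdir: Path = Path("zfdkit_out")

    @classmethod
    def from_yaml(cls, path, mode: str, seed: int | None = None, outdir=None) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if mode not in doc:
            raise InvalidArgumentError(f"config has no '{mode}' section")
        params = doc[mode] or {}
        cfg_seed = seed if seed is not None else int(doc.get("seed", 0))
        cfg_out = Path(outdir) if outdir is not None else Path(doc.get("outdir", "zfdkit_out"))
        return cls(mode=mode, params=params, seed=cfg_seed, outdir=cfg_out)


@dataclass
class ReportBundle:
    outdir: Path
    results: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, config: RunConfig) -> None:
        self.outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables.items():
            zio.write_tsv(self.outdir / f"{name}.tsv", frame)
        payload = {
            "results": self.results,
            "config": {
                "mode": config.mode,
                "seed": config.seed,
                "params": config.params,
            },
            "version": _package_version(),
            "tables": sorted(self.tables),
        }
        zio.write_json(self.outdir / "results.json", payload)
        (self.outdir / "run.log").write_text(
            f"zfdkit {_package_version()} mode={config.mode} seed={config.seed}\n"
            f"resolved config: {json.dumps(config.params, sort_keys=True, default=str)}\n"
        )


def _interval_from(params: dict, key: str) -> Interval:
    """1-based inclusive [start, end] in the manifest -> half-open interval."""
    if key not in params:
        raise InvalidArgumentError(f"configuration is missing '{key}'")
    start, end = params[key]
    return Interval(int(start) - 1, int(end))


def _require(params: dict, *keys: str) -> None:
    for key in keys:
        if key not in params:
            raise InvalidArgumentError(f"configuration is missing '{key}'")


# ---------------------------------------------------------------------------
# amplicon mode
# ---------------------------------------------------------------------------


def run_amplicon(config: RunConfig) -> ReportBundle:
    p = config.params
    _require(p, "reference", "reads", "spacer")
    reference = zio.read_single_fasta(p["reference"])
    spacer = _interval_from(p, "spacer")
    min_depth = int(p.get("min_depth", 10))
    strand = p.get("strand_of_edit", "both")

    reads = zio.read_fastq(p["reads"])
    alignments = align_records(reads, reference)
    pileup = build_pileup(alignments, reference)
    table = substitution_table(pileup, reference, min_depth=min_depth)
    profile = window_c2t(table, spacer, strand_of_edit=strand)
    indel = indel_frequency(alignments, spacer)

    bundle = ReportBundle(config.outdir)
    bundle.tables["edit_table"] = table
    bundle.tables["c2t_profile"] = profile
    bundle.results["indel_frequency"] = indel
    bundle.results["n_reads"] = len(reads)

    if "gene_frame" in p:
        gf = p["gene_frame"]
        frame = GeneFrame(codon_start=int(gf["codon_start"]) - 1, strand=gf.get("strand", "+"))
        window = _interval_from(p, "allele_window") if "allele_window" in p else spacer
        code = int(p.get("genetic_code", 2))
        bundle.tables["allele_table"] = allele_table(
            alignments, reference, window, gene_frame=frame, genetic_code=code
        )

    if "clones" in p:
        background_max = float(p.get("clone_background_max", 0.02))
        edited_min = float(p.get("clone_edited_min", 0.05))
        positions = [(int(pos) - 1, s) for pos, s in p.get("clone_positions", [])]
        rows = []
        for clone in p["clones"]:
            recs = zio.read_fastq(clone["reads"])
            alns = align_records(recs, reference)
            tab = substitution_table(build_pileup(alns, reference), reference, min_depth=min_depth)
            freq = edit_frequency(tab, positions) if positions else float(
                window_c2t(tab, spacer, strand_of_edit=strand)["freq"].max()
            )
            call = classify_clone(freq, background_max, edited_min, clone_id=clone["label"])
            rows.append({"clone": call.clone_id, "frequency": call.frequency, "label": call.label})
        bundle.tables["clone_calls"] = pd.DataFrame(rows)

    bundle.write(config)
    return bundle


# ---------------------------------------------------------------------------
# mito mode
# ---------------------------------------------------------------------------


def run_mito(config: RunConfig) -> ReportBundle:
    p = config.params
    _require(p, "genome", "samples", "on_target")
    samples = p["samples"]
    labels = [s["label"] for s in samples]
    if len(samples) < 2 or not any(s.get("untreated") for s in samples):
        raise InvalidArgumentError(
            "mito mode needs >= 2 samples including an untreated control"
        )
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError("duplicate sample labels")

    genome = zio.read_single_fasta(p["genome"])
    on_target = _interval_from(p, "on_target")
    min_rate = float(p.get("min_rate", 0.01))
    snv_threshold = float(p.get("snv_threshold", 0.5))
    min_depth = int(p.get("min_depth", 10))
    flank = int(p.get("context_flank", 5))

    tables = {}
    for s in samples:
        reads = zio.read_fastq(s["reads"])
        pileup = genome_pileup(reads, genome)
        tables[s["label"]] = genome_conversion_table(pileup, genome, min_depth=min_depth)

    masked = mask_variants(tables, threshold=snv_threshold)
    bundle = ReportBundle(config.outdir)
    reports = []
    for s in samples:
        lab = s["label"]
        calls = call_offtargets(tables[lab], masked, on_target, min_rate=min_rate,
                                genome_length=len(genome))
        rep = specificity_report(tables[lab], on_target, calls, label=lab)
        if not rep.ratio_defined:
            log.warning("specificity ratio undefined for sample %s (no off-target calls)", lab)
        reports.append(rep)
        bundle.tables[f"conversion_{lab}"] = _conversion_report(tables[lab])
        bundle.tables[f"offtarget_calls_{lab}"] = _calls_report(calls.calls)
        if calls.n_calls > 0 and not s.get("untreated"):
            bundle.tables[f"context_{lab}"] = context_matrix(calls, genome, flank=flank)

    summary = pd.DataFrame([r.to_dict() for r in reports])
    bundle.tables["specificity"] = summary
    bundle.results["masked_positions"] = sorted(int(x) + 1 for x in masked)
    bundle.results["specificity"] = [r.to_dict() for r in reports]
    bundle.write(config)
    return bundle


def _conversion_report(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["pos"] = out["pos"] + 1  # 1-based in reports
    return out


def _calls_report(calls: pd.DataFrame) -> pd.DataFrame:
    out = calls.copy()
    out["pos"] = out["pos"] + 1
    return out


# ---------------------------------------------------------------------------
# design mode
# ---------------------------------------------------------------------------


def run_design(config: RunConfig) -> ReportBundle:
    p = config.params
    _require(p, "reference")
    reference = zio.read_single_fasta(p["reference"])
    half_len = int(p.get("half_len", 12))
    spacer_range = tuple(p.get("spacer_range", (7, 15)))
    circular = bool(p.get("circular", False))
    require_c = bool(p.get("require_editable_c", True))

    sites = scan_sites(
        reference,
        half_len=half_len,
        spacer_range=spacer_range,  # type: ignore[arg-type]
        require_editable_c=require_c,
        circular=circular,
    )
    table = None
    if "module_table" in p:
        try:
            table = ZFModuleTable.from_tsv(p["module_table"])
        except InvalidArgumentError:
            raise
        except Exception as exc:  # pragma: no cover
            raise InvalidArgumentError(f"malformed module table: {exc}") from exc

    rows = []
    for site in sites:
        row = {
            "start": site.start + 1,
            "strand": site.strand,
            "left_site": site.left_site,
            "spacer": site.spacer,
            "right_site": site.right_site,
            "n_tc_cs": sum(1 for c in site.editable_cs if c.context == "TC"),
        }
        if table is not None:
            left = module_coverage(site.left_site, table, "left")
            right = module_coverage(site.right_site, table, "right")
            row["designable"] = left.designable and right.designable
            row["missing_triplets"] = ",".join(left.missing + right.missing)
        rows.append(row)

    archs = enumerate_architectures()
    arch_frame = pd.DataFrame(
        [
            {
                "linker_length": a.linker_length,
                "split_position": a.split_position,
                "n_half_side": a.n_half_side,
                "configuration": a.configuration,
            }
            for a in archs
        ]
    )
    bundle = ReportBundle(config.outdir)
    bundle.tables["candidate_sites"] = pd.DataFrame(rows)
    bundle.tables["architectures"] = arch_frame
    bundle.results["n_sites"] = len(sites)
    bundle.results["n_architectures"] = len(archs)
    bundle.write(config)
    return bundle


# ---------------------------------------------------------------------------
# simulate mode
# ---------------------------------------------------------------------------


def run_simulate(config: RunConfig) -> ReportBundle:
    p = config.params
    _require(p, "reference", "window")
    reference = zio.read_single_fasta(p["reference"])
    window = _interval_from(p, "window")
    model = make_editing_model(
        reference,
        window,
        context_defaults=p.get("context_rates", {"TC": 0.3}),
        seq_error_rate=float(p.get("seq_error_rate", 0.001)),
        indel_rate=float(p.get("indel_rate", 0.0)),
        dose_scale=float(p.get("dose_scale", 1.0)),
    )
    n_reads = int(p.get("n_reads", 10000))
    records, truth = simulate_reads(reference, model, n_reads, seed=config.seed)

    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    zio.write_fastq(outdir / "reads.fastq", records)
    (outdir / "truth.tsv").write_text(truth.to_tsv())
    (outdir / "truth.json").write_text(truth.to_json())

    bundle = ReportBundle(outdir)
    bundle.results["n_reads"] = n_reads
    bundle.results["n_planted_edits"] = len(truth.planted_edits)
    bundle.write(config)
    return bundle


RUNNERS = {
    "amplicon": run_amplicon,
    "mito": run_mito,
    "design": run_design,
    "simulate": run_simulate,
}


def run(config: RunConfig) -> ReportBundle:
    if config.mode not in RUNNERS:
        raise InvalidArgumentError(f"unknown mode {config.mode!r}")
    return RUNNERS[config.mode](config)
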