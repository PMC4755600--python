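"""One-shot characterization pipeline: composition -> boxes -> capacity.

``run_report`` chains the sequence-level stages (composition summary,
MT-likeness screen, Cys-box decomposition, Cu capacity prediction) and,
when genomic inputs are supplied, the gene-model stages (spliced
alignment, coding check, promoter scan). The JSON report is the single
source of truth; the human-readable summary is rendered from it, never
computed separately. Any stage error is re-raised as
:class:`PipelineStageError` with the stage name attached, and no
partial report is written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cysbox, cucapacity, genemodel, seqstats
from .errors import ModmtError, PipelineStageError
from .records import ProteinRecord, read_fasta

logger = logging.getLogger("modmt")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    protein_fasta: str | Path | None = None
    protein: ProteinRecord | None = None
    cdna_fasta: str | Path | None = None
    genome_fasta: str | Path | None = None
    n_term_extension: str = ""
    thresholds: seqstats.MtThresholds = field(default_factory=seqstats.MtThresholds)
    profiles: tuple[cysbox.BoxProfile, ...] = cysbox.DEFAULT_PROFILES
    allow_degenerate: bool = True
    motifs: dict[str, str] = field(default_factory=lambda: dict(genemodel.DEFAULT_MOTIFS))
    promoter_window: int = 1500
    align_params: genemodel.SplicedAlignParams = field(
        default_factory=genemodel.SplicedAlignParams)
    observed_majors: tuple[int, ...] = ()
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        for path in (self.protein_fasta, self.cdna_fasta, self.genome_fasta):
            if path is not None and not Path(path).exists():
                raise ModmtError(f"input path does not exist: {path}")


def _read_single_nt(path: str | Path) -> tuple[str, str]:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def run_report(config: PipelineConfig) -> dict:
    """Run all configured stages and return one JSON-ready report bundle."""

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    if config.protein is not None:
        record = config.protein
    elif config.protein_fasta is not None:
        record = stage("read_protein", read_fasta, config.protein_fasta)[0]
    else:
        raise ModmtError("a protein record or FASTA is required")

    summary = stage("characterize", seqstats.summarize_composition, record)
    verdict = stage("mt_screen", seqstats.is_mt_like, summary, config.thresholds)
    arch = stage("decompose", cysbox.decompose, record, config.profiles,
                 config.allow_degenerate)
    capacity = stage("capacity", cucapacity.cu_capacity, arch)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "record_id": record.id,
        "composition": summary.to_dict(),
        "mt_like": verdict.to_dict(),
        "architecture": cysbox.architecture_report(arch),
        "capacity": capacity.to_dict(),
    }
    if config.observed_majors:
        entries = stage("consistency", cucapacity.capacity_consistency,
                        capacity, list(config.observed_majors))
        report["capacity_consistency"] = [
            {"observed": e.observed, "inside": e.inside,
             "offset_from_base": e.offset_from_base}
            for e in entries
        ]

    if config.cdna_fasta is not None and config.genome_fasta is not None:
        cdna_id, cdna = stage("read_cdna", _read_single_nt, config.cdna_fasta)
        scaffold_id, genome = stage("read_genome", _read_single_nt,
                                    config.genome_fasta)
        model = stage("spliced_align", genemodel.spliced_align, cdna, genome,
                      config.align_params, cdna_id, scaffold_id)
        coding = stage("check_coding", genemodel.check_coding, model, cdna)
        report["gene_model"] = {
            "scaffold_id": model.scaffold_id,
            "strand": model.strand,
            "n_exons": model.n_exons,
            "n_introns": model.n_introns,
            "exons": [[s, e] for s, e in model.exons],
            "introns": [[i.start, i.end, i.donor, i.acceptor]
                        for i in model.introns],
            "mismatches": model.mismatches,
            "coding": {
                "ok": coding.ok,
                "coding_length": coding.coding_length,
                "protein_length": coding.protein_length,
                "utr5_length": coding.utr5_length,
                "diagnostics": list(coding.diagnostics),
            },
        }
        report["gff3"] = genemodel.export_gff3(model)

        if model.strand == "+" and model.coding_span_on_cdna is not None:
            atg = _atg_genomic(model)
            upstream = genome[max(0, atg - config.promoter_window):atg]
            hits = stage("scan_promoter", genemodel.scan_promoter, upstream,
                         config.motifs)
            report["promoter_hits"] = [
                {"motif": h.motif_name, "offset": h.offset,
                 "matched_seq": h.matched_seq, "strand": h.strand}
                for h in hits
            ]

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        (outdir / "report.txt").write_text(render_summary(report))
        if "gff3" in report:
            (outdir / "model.gff3").write_text(report["gff3"])
    return report


def _atg_genomic(model) -> int:
    """Forward-axis genomic coordinate of the A of the ATG (plus strand)."""
    a = model.coding_span_on_cdna[0]
    offset = 0
    for s, e in model.exons:
        if a < offset + (e - s):
            return s + (a - offset)
        offset += e - s
    raise ModmtError("coding start outside exons")


def render_summary(report: dict) -> str:
    """Human-readable summary derived from the JSON report."""
    comp = report["composition"]
    lines = [
        f"modmt report (schema {report['schema_version']}) — {report['record_id']}",
        (f"  composition: {comp['length']} aa, {comp['cys_count']} Cys "
         f"({comp['cys_percent']}%), {comp['cys_in_cxc']} Cys in CXC, "
         f"{comp['his_count']} His, {comp['aromatic_count']} aromatics, "
         f"avg mass {comp['average_mass_da']} Da"),
        f"  MT-like: {report['mt_like']['is_mt_like']} "
        f"({'; '.join(report['mt_like']['reasons'])})",
        f"  architecture: {report['architecture']['summary']}",
        (f"  Cu capacity: base {report['capacity']['base_total']}, "
         f"max {report['capacity']['max_total']}"),
    ]
    if "capacity_consistency" in report:
        for e in report["capacity_consistency"]:
            verdict = "inside" if e["inside"] else "outside"
            lines.append(f"  observed Cu{e['observed']}: {verdict} "
                         f"(base{e['offset_from_base']:+d})")
    if "gene_model" in report:
        gm = report["gene_model"]
        lines.append(
            f"  gene model: {gm['n_exons']} exons / {gm['n_introns']} introns "
            f"on {gm['scaffold_id']} ({gm['strand']}), "
            f"coding {gm['coding']['coding_length']} bp -> "
            f"{gm['coding']['protein_length']} aa, "
            f"5'UTR {gm['coding']['utr5_length']} bp"
        )
    for hit in report.get("promoter_hits", []):
        lines.append(f"  promoter: {hit['motif']} at {hit['offset']} "
                     f"({hit['matched_seq']}, {hit['strand']})")
    return "\n".join(lines) + "\n"
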