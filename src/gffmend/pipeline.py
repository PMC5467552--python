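"""End-to-end import pipeline: summarize → repair → name → verify → export.

All outputs are written with fixed orderings and no timestamps, so two
runs on identical inputs and configuration produce byte-identical
artifact directories. A stage failure halts the run with a machine-
readable status report; artifacts produced so far are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from Bio import SeqIO

from . import export as ex
from .config import Config, ConfigError, ProvenanceRecord, fetch_inputs
from .model import FeatureGraph, TRANSCRIPT_TYPES
from .naming import assign_names
from .parser import parse_gff, summarize_attributes
from .rules import apply_all
from .verify import (
    VerificationError,
    assemble_cds,
    cds_children,
    gene_set_quality,
    read_domain_hits,
    translate,
    verify_translations,
)

EXIT_OK = 0
EXIT_USAGE = 1
EXIT_PARSE = 2
EXIT_VERIFICATION = 3


@dataclass
class PipelineResult:
    status: int
    stage: str
    artifacts: dict[str, str] = field(default_factory=dict)
    report: Optional[dict] = None

    @property
    def ok(self) -> bool:
        return self.status == EXIT_OK


def read_fasta(path: str) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def predicted_translations(
    graph: FeatureGraph, genome: Mapping[str, str]
) -> tuple[dict[str, str], dict[str, str]]:
    """(translation ID → protein, translation ID → raw CDS nt) for every
    coding transcript."""
    predicted: dict[str, str] = {}
    raw_cds: dict[str, str] = {}
    for t in sorted(
        (f for f in graph if f.feature_type in TRANSCRIPT_TYPES
         and cds_children(graph, f)),
        key=lambda t: (t.seq_id, t.start, t.stable_id or ""),
    ):
        pid = t.translation_stable_id or t.stable_id or t.feature_id
        if pid is None:
            continue
        try:
            raw = assemble_cds(t, graph, genome, apply_phase=False)
            trimmed = assemble_cds(t, graph, genome)
            predicted[pid] = translate(trimmed, graph=graph)
            raw_cds[pid] = raw
        except VerificationError as exc:
            graph.log("error", "cds_assembly_failed",
                      f"transcript {pid!r}: {exc}", feature_ids=(pid,))
    return predicted, raw_cds


def _issues_json(graph: FeatureGraph) -> list[dict]:
    return [
        {
            "severity": i.severity,
            "code": i.code,
            "message": i.message,
            "feature_ids": list(i.feature_ids),
            "action_taken": i.action_taken,
        }
        for i in graph.issues
    ]


def run_pipeline(
    cfg: Config,
    outdir: str,
    cache_dir: Optional[str] = None,
) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, text: str) -> None:
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        artifacts[name] = str(path)

    def finish(status: int, stage: str, report=None) -> PipelineResult:
        emit(
            "pipeline_status.json",
            json.dumps(
                {"status": status, "stage": stage,
                 "artifacts": sorted(artifacts)},
                indent=2, sort_keys=True,
            ) + "\n",
        )
        return PipelineResult(status, stage, artifacts, report)

    # -- inputs ---------------------------------------------------------
    try:
        inputs = fetch_inputs(cfg, cache_dir or str(out / ".cache"))
    except ConfigError as exc:
        emit("error.txt", f"input resolution failed: {exc}\n")
        return finish(EXIT_PARSE, "fetch_inputs")
    required = {"SCAFFOLDS", "GFF"}
    missing = required - set(inputs)
    if missing:
        emit("error.txt", f"missing [FILES] keys: {sorted(missing)}\n")
        return finish(EXIT_USAGE, "fetch_inputs")

    genome = read_fasta(inputs["SCAFFOLDS"]["path"])
    if not genome:
        emit("error.txt", "no scaffolds could be read\n")
        return finish(EXIT_PARSE, "read_genome")

    # -- summarize + parse ----------------------------------------------
    try:
        graph = parse_gff(inputs["GFF"]["path"])
    except OSError as exc:
        emit("error.txt", f"cannot read GFF: {exc}\n")
        return finish(EXIT_PARSE, "parse")
    emit("summary.tsv", summarize_attributes(graph).to_tsv())

    # -- repair + naming ------------------------------------------------
    rules = cfg.rules()
    apply_all(graph, rules)
    assign_names(graph, cfg)
    provenance = ProvenanceRecord(
        config=cfg.snapshot(),
        inputs=inputs,
        modifications=graph.provenance,
    )
    emit("provenance.json", provenance.to_json())

    # -- verification ----------------------------------------------------
    predicted, raw_cds = predicted_translations(graph, genome)
    domains = (
        read_domain_hits(inputs["DOMAINS"]["path"])
        if "DOMAINS" in inputs else {}
    )
    quality = gene_set_quality(graph, domains)
    verification: dict = {"gene_set_quality": quality.to_dict()}
    report = None
    if "PROTEINS" in inputs:
        expected = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(inputs["PROTEINS"]["path"], "fasta")
        }
        report = verify_translations(predicted, expected, raw_cds)
        verification["translations"] = report.to_dict()
    emit(
        "verification.json",
        json.dumps(verification, indent=2, sort_keys=True) + "\n",
    )
    if report is not None and not report.ok:
        emit(
            "issues.json",
            json.dumps(_issues_json(graph), indent=2, sort_keys=True) + "\n",
        )
        return finish(EXIT_VERIFICATION, "verify", verification)

    # -- export -----------------------------------------------------------
    emit("repaired.gff3", ex.write_gff3(graph))
    seqs = ex.export_sequences(graph, genome)
    emit("scaffolds.fa", ex.format_fasta(seqs.scaffolds))
    emit("cds.fa", ex.format_fasta(seqs.cds))
    emit("proteins.fa", ex.format_fasta(seqs.proteins))
    emit("assembly_stats.json", ex.stats_json(ex.assembly_stats(genome)))
    emit(
        "codon_usage.json",
        ex.codon_usage_json(ex.codon_usage([s for _, s in seqs.cds])),
    )
    meta_section = cfg.section("META")
    meta = ex.EmblMeta(
        organism=meta_section.get("ORGANISM", "unclassified organism"),
        taxonomy=tuple(
            t.strip()
            for t in meta_section.get("TAXONOMY", "Eukaryota").split(";")
            if t.strip()
        ),
        division=meta_section.get("DIVISION", "UNC"),
        data_class=meta_section.get("DATA_CLASS", "STD"),
    )
    embl = ex.write_embl(graph, genome, meta)
    emit("annotation.embl", "".join(embl[k] for k in sorted(embl)))
    emit(
        "issues.json",
        json.dumps(_issues_json(graph), indent=2, sort_keys=True) + "\n",
    )
    return finish(EXIT_OK, "done", verification)
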