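# gffmend

Tolerant GFF parsing, rule-based gene-model repair, translation
verification and INSDC export.

Anyone who has tried to load third-party genome annotation knows the
failure modes: CDS features split over lines that share an ID, CDS lines
with no ID at all, missing exon records, missing gene parents, GTF files
whose `gene_id`/`transcript_id` attributes never become actual parent
features, phase columns computed as reading frames, and protein FASTA
files that were hand-edited to stop at the first stop codon. gffmend is
for bioinformaticians who need to turn such files into a clean,
verified gene set: it parses *anything* line-splittable without
crashing, records every deviation as an issue, and repairs only what an
explicit, ordered rule list instructs — keeping a replayable provenance
record of every modification.

## What it does

* **Tolerant parser** — GFF3 and GTF-like dialects (plain or gzip,
  embedded `##FASTA` accepted). Malformed lines are quarantined with
  issues, never fatal. A pre-import summary reports attribute counts by
  feature type, flagging discrepancies that suggest repair is needed.
* **Repair rules** in an INI meta-syntax, applied in declaration order:

  ```ini
  [GFF]
  CONDITION_1 = [MULTILINE CDS]
  CONDITION_2 = [LACKS_ID CDS make]
  CONDITION_3 = [EXPECTATION cds hasSister exon force]
  CONDITION_4 = [EXPECTATION cds hasParent mrna force]
  CONDITION_5 = [EXPECTATION exon hasParent transcript|mrna|mirna|trna|ncrna|rrna force]
  CONDITION_6 = [EXPECTATION mrna hasParent gene force]
  ```

  These six defaults (shipped in `data/default.ini`, layered under your
  assembly-specific INI) rebuild a full `gene → mRNA → {exon, CDS}`
  hierarchy even from a CDS-only GTF file.
* **Naming patterns** — `[gene->id/(.+)/]`-style extraction with
  match-and-replace (`[SELF->ID/(.+)//-RA/-PA/]` derives a translation
  ID from a transcript ID), plus lookup tables from FASTA headers or
  text files.
* **Verification** — assembles each CDS (strand- and phase-aware,
  phase = bases to trim, the GFF3 reading), translates it, and compares
  with expected proteins; mismatches are classified `phase_shift`,
  `stop_truncation` or `other`. A gene-set quality summary counts
  single-exon genes (canonical transcript = longest CDS) and the subset
  without structural domain hits — e.g. compositions of
  5340/21 493 → 25% and 673/13 920 → 5%.
* **Exporters** — canonical GFF3, scaffold/CDS/protein FASTA, one EMBL
  flat-file record per scaffold (ENA conventions, `/codon_start` from
  phase, `/translation` recomputed and enforced), JSON assembly
  statistics (N50/N90/GC) and codon-usage tables.
* **Synthetic data** — a deterministic generator of genomes with
  known-true gene models and a corruptor that injects each of the
  defects above with a manifest, so the whole toolchain is testable
  offline.

## Worked example

```sh
$ gffmend fixtures --outdir demo/in --seed 7 --scaffolds 2 --genes-per-scaffold 5
wrote demo/in/annotation.gff3, demo/in/assembly.ini, demo/in/cds.fa, ...
$ gffmend run --config demo/in/assembly.ini --outdir demo/out
stage=done status=0
```

`demo/out/verification.json` then contains

```json
{
  "gene_set_quality": {
    "pct_single_exon": 30,
    "pct_single_exon_no_domain": 0,
    "single_exon_genes": 3,
    "single_exon_no_domain": 0,
    "total_genes": 10
  },
  "translations": {
    "identical": 10,
    "ids_only_expected": [],
    "ids_only_predicted": [],
    "mismatched": []
  }
}
```

— all 10 transcripts re-translate exactly to the expected proteins
(`identical: 10`, no mismatches), and 3 of the 10 genes (30%) are
single-exon, every one of them carrying a domain hit. The run also
writes `repaired.gff3`, `annotation.embl`, sequence FASTAs,
`assembly_stats.json` (here: 2 scaffolds, 8791 bp, N50 = 4490) and
`codon_usage.json`, plus `provenance.json` recording every repair. A
second `run` on the same inputs is byte-identical.

Exit codes: 0 ok, 1 usage, 2 parse/config error, 3 verification
failure.

## Library use

```python
from gffmend import parse_gff, apply_all, assign_names, write_gff3
from gffmend.config import Config, default_config_path

cfg = Config.load(str(default_config_path()), "assembly.ini")
graph = parse_gff("messy.gff")
apply_all(graph, cfg.rules())       # merge, mint IDs, synthesise parents
assign_names(graph, cfg)
print(write_gff3(graph))
for issue in graph.issues:
    print(issue.severity, issue.code, issue.message, issue.action_taken)
```

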