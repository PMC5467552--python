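"""Deterministic synthetic genomes with known-true gene models.

The generator emits internally consistent annotation: every CDS starts
with ATG, contains no internal stop, ends at a single stop codon, lies
inside its exons (exon coordinates coincide with CDS segments; UTRs are
not modelled so that structural repair can be checked for exact
coordinate recovery), and carries correctly computed per-segment phases.
The corruptor then injects the defects seen in real-world annotation
exchange — multiline CDS records, missing CDS IDs, missing exon lines,
missing gene parents, GTF-style files without parent links, phase columns
computed as strand-ignorant frames, and expected-protein files hand-
truncated at a stop codon — while recording a manifest that maps every
edit back to the truth, so repairs can be verified against an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .export import format_fasta, write_gff3
from .model import Feature, FeatureGraph, GenomicInterval, TRANSCRIPT_TYPES

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA") and a + b + c != "ATG"
]
STOP_CODONS = ["TAA", "TAG", "TGA"]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CORRUPTION_MODES = (
    "split_multiline_cds",
    "strip_cds_ids",
    "strip_exons",
    "strip_gene_parents",
    "gtf_dialect",
    "phase_as_frame",
    "truncate_expected_at_stop",
)


def _interleave(index: int, fraction: float) -> bool:
    """Deterministic allocation of exactly round(n * fraction) marks over
    n consecutive indices (no sampling noise)."""
    return int((index + 1) * fraction + 0.5) > int(index * fraction + 0.5)


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 0
    n_scaffolds: int = 5
    genes_per_scaffold: int = 20
    cds_codons: tuple[int, int] = (50, 200)
    max_exons: int = 5
    intron_length: tuple[int, int] = (40, 200)
    intergenic: tuple[int, int] = (60, 300)
    scaffold_tail: tuple[int, int] = (100, 2000)
    fraction_single_exon: float = 0.25
    minus_fraction: float = 0.5
    fraction_with_domain: float = 0.8
    n_run_fraction: float = 0.0  # fraction of intergenic gaps turned into N runs


@dataclass
class GeneModel:
    """Truth bookkeeping for one generated gene (one transcript each)."""

    gene_id: str
    transcript_id: str
    translation_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]  # ascending genomic order
    cds_parts_tx: list[int]  # part lengths in transcription order
    protein: str
    cds_nt: str  # transcription-order CDS

    @property
    def phases_tx(self) -> list[int]:
        phases, cum = [], 0
        for length in self.cds_parts_tx:
            phases.append((3 - cum % 3) % 3)
            cum += length
        return phases

    def phases_ascending(self) -> list[int]:
        ph = self.phases_tx
        return ph[::-1] if self.strand == "-" else ph


@dataclass
class Bundle:
    spec: GeneratorSpec
    genome: dict[str, str]
    graph: FeatureGraph
    gff3: str
    proteins: dict[str, str]
    cds: dict[str, str]
    domains: list[str]
    models: list[GeneModel]

    def domain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.domains:
            sid = row.split("\t", 1)[0]
            counts[sid] = counts.get(sid, 0) + 1
        return counts

    def write(self, outdir: str) -> dict[str, str]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gff": out / "annotation.gff3",
            "proteins": out / "proteins.fa",
            "cds": out / "cds.fa",
            "domains": out / "domains.tsv",
        }
        paths["genome"].write_text(
            format_fasta(sorted(self.genome.items()))
        )
        paths["gff"].write_text(self.gff3)
        paths["proteins"].write_text(
            format_fasta(sorted(self.proteins.items()))
        )
        paths["cds"].write_text(format_fasta(sorted(self.cds.items())))
        paths["domains"].write_text(
            "\n".join(self.domains) + ("\n" if self.domains else "")
        )
        paths["config"] = out / "assembly.ini"
        paths["config"].write_text(
            "[FILES]\n"
            f"SCAFFOLDS = {paths['genome']}\n"
            f"GFF = {paths['gff']}\n"
            f"PROTEINS = {paths['proteins']}\n"
            f"DOMAINS = {paths['domains']}\n"
            "\n[TRANSLATION_STABLE_IDS]\n"
            "GFF = [SELF->ID/(.+)//.t/.p/]\n"
        )
        return {k: str(v) for k, v in paths.items()}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, minimum: int = 3
) -> list[int]:
    extra = total - minimum * parts
    if extra < 0:
        raise ValueError("CDS too short to split")
    if parts == 1:
        return [total]
    weights = rng.random(parts)
    weights /= weights.sum()
    alloc = np.floor(weights * extra).astype(int)
    alloc[0] += extra - int(alloc.sum())
    return [minimum + int(a) for a in alloc]


def generate(spec: GeneratorSpec) -> Bundle:
    """Generate a genome, truth annotation graph/GFF3, protein and CDS
    sets, and a synthetic domain table. Same spec (same seed) gives
    byte-identical outputs."""
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    graph = FeatureGraph()
    proteins: dict[str, str] = {}
    cds_set: dict[str, str] = {}
    domains: list[str] = []
    models: list[GeneModel] = []
    gene_index = 0

    for s in range(spec.n_scaffolds):
        seq_id = f"scaffold_{s + 1:03d}"
        chunks: list[str] = []
        cursor = 0  # 0-based length so far

        for _ in range(spec.genes_per_scaffold):
            gap = int(rng.integers(*spec.intergenic))
            gap_seq = _random_dna(rng, gap)
            if spec.n_run_fraction and rng.random() < spec.n_run_fraction:
                run = min(gap - 2, max(5, gap // 2))
                start_at = 1
                gap_seq = (gap_seq[:start_at] + "N" * run
                           + gap_seq[start_at + run:])
            chunks.append(gap_seq)
            cursor += gap

            gid = f"g{gene_index + 1:05d}"
            tid = f"{gid}.t1"
            pid = f"{gid}.p1"
            single = _interleave(gene_index, spec.fraction_single_exon)
            minus = _interleave(gene_index, spec.minus_fraction)
            strand = "-" if minus else "+"
            n_codons = int(rng.integers(*spec.cds_codons))
            body = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
            codons = (
                ["ATG"]
                + [SENSE_CODONS[i] for i in body]
                + [STOP_CODONS[int(rng.integers(0, 3))]]
            )
            cds_nt = "".join(codons)
            protein = str(Seq(cds_nt).translate(table=1))[:-1]
            n_exons = 1 if single else int(rng.integers(2, spec.max_exons + 1))
            parts_tx = _split_lengths(rng, len(cds_nt), n_exons)
            introns = [
                int(rng.integers(*spec.intron_length))
                for _ in range(n_exons - 1)
            ]
            # genomic layout ascending; transcription order is reversed on '-'
            parts_asc = parts_tx[::-1] if minus else parts_tx
            exons: list[tuple[int, int]] = []
            offset = 0  # within-CDS offset in transcription order
            tx_bounds = []
            for L in parts_tx:
                tx_bounds.append((offset, offset + L))
                offset += L
            asc_index_to_tx = (
                list(range(n_exons - 1, -1, -1)) if minus
                else list(range(n_exons))
            )
            for j, L in enumerate(parts_asc):
                tx_i = asc_index_to_tx[j]
                lo, hi = tx_bounds[tx_i]
                piece = cds_nt[lo:hi]
                if minus:
                    piece = piece.translate(_COMPLEMENT)[::-1]
                start = cursor + 1  # 1-based
                chunks.append(piece)
                cursor += L
                exons.append((start, start + L - 1))
                if j < n_exons - 1:
                    ilen = introns[j]
                    chunks.append(_random_dna(rng, ilen))
                    cursor += ilen

            model = GeneModel(
                gene_id=gid, transcript_id=tid, translation_id=pid,
                seq_id=seq_id, strand=strand, exons=exons,
                cds_parts_tx=parts_tx, protein=protein, cds_nt=cds_nt,
            )
            models.append(model)
            proteins[pid] = protein
            cds_set[tid] = cds_nt
            if _interleave(gene_index, spec.fraction_with_domain):
                acc = f"PF{int(rng.integers(0, 99999)):05d}"
                end = min(50, len(protein))
                domains.append(
                    f"{pid}\t{len(protein)}\tPfam\t{acc}\t"
                    f"synthetic domain\t1\t{end}\t1e-10"
                )
            gene_index += 1

        tail = int(rng.integers(*spec.scaffold_tail))
        chunks.append(_random_dna(rng, tail))
        genome[seq_id] = "".join(chunks)

    # build the truth graph
    for model in models:
        span = GenomicInterval(
            model.seq_id, model.exons[0][0], model.exons[-1][1], model.strand
        )
        gene = Feature(
            feature_id=model.gene_id, feature_type="gene",
            type_as_read="gene", source="sim", segments=[span],
            attributes={"ID": [model.gene_id]},
        )
        mrna = Feature(
            feature_id=model.transcript_id, feature_type="mrna",
            type_as_read="mRNA", source="sim", segments=[span],
            attributes={"ID": [model.transcript_id],
                        "Parent": [model.gene_id]},
        )
        graph.add(gene)
        graph.add(mrna)
        graph.add_edge(mrna.uid, gene.uid)
        for j, (start, end) in enumerate(model.exons, 1):
            exon = Feature(
                feature_id=f"{model.transcript_id}.exon{j}",
                feature_type="exon", type_as_read="exon", source="sim",
                segments=[GenomicInterval(model.seq_id, start, end,
                                          model.strand)],
                attributes={"ID": [f"{model.transcript_id}.exon{j}"],
                            "Parent": [model.transcript_id]},
            )
            graph.add(exon)
            graph.add_edge(exon.uid, mrna.uid)
        cds = Feature(
            feature_id=f"{model.transcript_id}.cds", feature_type="cds",
            type_as_read="CDS", source="sim",
            segments=[
                GenomicInterval(model.seq_id, s, e, model.strand)
                for s, e in model.exons
            ],
            phases=[int(p) for p in model.phases_ascending()],
            attributes={"ID": [f"{model.transcript_id}.cds"],
                        "Parent": [model.transcript_id]},
        )
        graph.add(cds)
        graph.add_edge(cds.uid, mrna.uid)

    return Bundle(
        spec=spec, genome=genome, graph=graph, gff3=write_gff3(graph),
        proteins=proteins, cds=cds_set, domains=domains, models=models,
    )


# ---------------------------------------------------------------------------
# corruption


@dataclass(frozen=True)
class CorruptionSpec:
    modes: tuple[str, ...]
    probability: float = 1.0  # per-gene/transcript application probability
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.modes) - set(CORRUPTION_MODES)
        if unknown:
            raise ValueError(f"unknown corruption modes: {sorted(unknown)}")


@dataclass
class Corrupted:
    gff3: str
    genome: dict[str, str]
    proteins: dict[str, str]
    manifest: list[dict] = field(default_factory=list)

    def injected(self, mode: str) -> list[dict]:
        return [m for m in self.manifest if m["mode"] == mode]


def _gff_line(seq_id, src, ftype, start, end, strand, phase, attrs) -> str:
    return "\t".join(
        (seq_id, src, ftype, str(start), str(end), ".", strand,
         "." if phase is None else str(phase), attrs)
    )


def corrupt(bundle: Bundle, cspec: CorruptionSpec) -> Corrupted:
    """Inject the selected defect modes into a generated bundle.

    Structural modes rewrite the GFF text; ``phase_as_frame`` recomputes
    CDS phases cumulatively in ascending coordinate order as if strand
    were ignored (only minus-strand multi-exon transcripts actually
    change — unchanged candidates are not counted as injected);
    ``truncate_expected_at_stop`` rewrites one internal CDS codon of the
    genome copy to TAA and truncates the expected protein there. True
    gene coordinates are never altered. At most one of the two
    translation-level modes is applied per transcript so every injection
    has an unambiguous expected classification.
    """
    rng = np.random.default_rng(cspec.seed)
    modes = set(cspec.modes)
    genome = dict(bundle.genome)
    proteins = dict(bundle.proteins)
    manifest: list[dict] = []
    lines: list[str] = ["##gff-version 3"]
    gtf = "gtf_dialect" in modes

    for model in bundle.models:
        pick = {
            m: (m in modes and rng.random() < cspec.probability)
            for m in CORRUPTION_MODES
        }
        segs = [(s, e) for s, e in model.exons]
        parts_tx = list(model.cds_parts_tx)

        if pick["split_multiline_cds"]:
            # split the longest CDS segment at a point interior to it
            asc_lengths = [e - s + 1 for s, e in segs]
            j = int(np.argmax(asc_lengths))
            s, e = segs[j]
            if e - s + 1 >= 8:
                cut = int(rng.integers(s + 3, e - 3))
                segs = segs[:j] + [(s, cut), (cut + 1, e)] + segs[j + 1:]
                # recompute transcription-order part lengths
                asc = [e2 - s2 + 1 for s2, e2 in segs]
                parts_tx = asc[::-1] if model.strand == "-" else asc
                manifest.append(
                    {"mode": "split_multiline_cds",
                     "transcript": model.transcript_id, "at": cut}
                )
        phases_tx, cum = [], 0
        for L in parts_tx:
            phases_tx.append((3 - cum % 3) % 3)
            cum += L
        phases_asc = (
            phases_tx[::-1] if model.strand == "-" else list(phases_tx)
        )

        if pick["phase_as_frame"]:
            asc_lengths = [e - s + 1 for s, e in segs]
            wrong, cum = [], 0
            for L in asc_lengths:
                wrong.append((3 - cum % 3) % 3)
                cum += L
            # only the phase of the first segment in transcription order is
            # consumed during CDS assembly; an injection that leaves it
            # unchanged would be provably undetectable, so skip those
            first_tx = wrong[-1] if model.strand == "-" else wrong[0]
            truth_first = (
                phases_asc[-1] if model.strand == "-" else phases_asc[0]
            )
            if wrong != phases_asc and first_tx != truth_first:
                phases_asc = wrong
                manifest.append(
                    {"mode": "phase_as_frame",
                     "transcript": model.transcript_id}
                )
            else:
                pick["phase_as_frame"] = False

        if pick["truncate_expected_at_stop"] and not pick["phase_as_frame"]:
            k = _inject_internal_stop(genome, model, rng)
            if k is not None:
                proteins[model.translation_id] = model.protein[:k]
                manifest.append(
                    {"mode": "truncate_expected_at_stop",
                     "transcript": model.transcript_id, "residue": k}
                )

        # ---- emit lines ------------------------------------------------
        gid, tid = model.gene_id, model.transcript_id
        drop_gene = gtf or pick["strip_gene_parents"]
        drop_exons = pick["strip_exons"]
        strip_ids = gtf or pick["strip_cds_ids"]
        if gtf:
            gtf_attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            if not drop_exons:
                for s, e in model.exons:
                    lines.append(_gff_line(
                        model.seq_id, "sim", "exon", s, e, model.strand,
                        None, gtf_attrs,
                    ))
            for (s, e), ph in zip(segs, phases_asc):
                lines.append(_gff_line(
                    model.seq_id, "sim", "CDS", s, e, model.strand,
                    ph, gtf_attrs,
                ))
            if pick["strip_gene_parents"]:
                manifest.append({"mode": "strip_gene_parents", "gene": gid})
            if pick["strip_exons"]:
                manifest.append({"mode": "strip_exons", "transcript": tid})
            if pick["strip_cds_ids"]:
                manifest.append({"mode": "strip_cds_ids", "transcript": tid})
            manifest.append({"mode": "gtf_dialect", "transcript": tid})
            continue

        span = (model.exons[0][0], model.exons[-1][1])
        if not drop_gene:
            lines.append(_gff_line(
                model.seq_id, "sim", "gene", span[0], span[1],
                model.strand, None, f"ID={gid}",
            ))
            mrna_attrs = f"ID={tid};Parent={gid}"
        else:
            mrna_attrs = f"ID={tid}"
            manifest.append({"mode": "strip_gene_parents", "gene": gid})
        lines.append(_gff_line(
            model.seq_id, "sim", "mRNA", span[0], span[1], model.strand,
            None, mrna_attrs,
        ))
        if drop_exons:
            manifest.append({"mode": "strip_exons", "transcript": tid})
        else:
            for j, (s, e) in enumerate(model.exons, 1):
                lines.append(_gff_line(
                    model.seq_id, "sim", "exon", s, e, model.strand, None,
                    f"ID={tid}.exon{j};Parent={tid}",
                ))
        cds_attrs = (
            f"Parent={tid}" if strip_ids else f"ID={tid}.cds;Parent={tid}"
        )
        if strip_ids:
            manifest.append({"mode": "strip_cds_ids", "transcript": tid})
        for (s, e), ph in zip(segs, phases_asc):
            lines.append(_gff_line(
                model.seq_id, "sim", "CDS", s, e, model.strand, ph,
                cds_attrs,
            ))

    return Corrupted(
        gff3="\n".join(lines) + "\n",
        genome=genome,
        proteins=proteins,
        manifest=manifest,
    )


def _cds_genomic_positions(model: GeneModel,
                           segs: Optional[Sequence[tuple[int, int]]] = None
                           ) -> list[int]:
    """1-based genomic position of each CDS base, transcription order."""
    segs = list(segs if segs is not None else model.exons)
    if model.strand == "-":
        segs = segs[::-1]
    positions: list[int] = []
    for s, e in segs:
        if model.strand == "-":
            positions.extend(range(e, s - 1, -1))
        else:
            positions.extend(range(s, e + 1))
    return positions


def _inject_internal_stop(
    genome: dict[str, str], model: GeneModel, rng: np.random.Generator
) -> Optional[int]:
    """Rewrite one internal codon to TAA (strand-aware); returns the
    0-based residue index, or None when no suitable codon exists."""
    plen = len(model.protein)
    if plen < 5:
        return None
    positions = _cds_genomic_positions(model)
    candidates = []
    for k in range(2, plen - 1):
        codon_pos = positions[3 * k:3 * k + 3]
        if abs(codon_pos[2] - codon_pos[0]) == 2:  # within one segment
            candidates.append(k)
    if not candidates:
        return None
    k = int(rng.choice(candidates))
    codon_pos = positions[3 * k:3 * k + 3]
    seq = list(genome[model.seq_id])
    for p, base in zip(codon_pos, "TAA"):
        seq[p - 1] = base if model.strand == "+" else base.translate(
            _COMPLEMENT
        )
    genome[model.seq_id] = "".join(seq)
    return k


# ---------------------------------------------------------------------------
# recovery oracle


def coverage_signature(graph: FeatureGraph) -> dict:
    """Structure-insensitive coordinate summary used to compare a repaired
    graph against truth: per feature class, merged base coverage per
    (scaffold, strand), plus gene and transcript counts. Invariant under
    legitimate repair transformations that change feature granularity
    without touching annotated bases."""
    classes = {"gene": [], "transcript": [], "exon": [], "cds": []}
    n_genes = n_transcripts = 0
    for f in graph:
        if f.feature_type == "gene":
            cls = "gene"
            n_genes += 1
        elif f.feature_type in TRANSCRIPT_TYPES:
            cls = "transcript"
            n_transcripts += 1
        elif f.feature_type in ("exon", "cds"):
            cls = f.feature_type
        else:
            continue
        for seg in f.segments:
            classes[cls].append((seg.seq_id, seg.strand, seg.start, seg.end))
    sig: dict = {"n_genes": n_genes, "n_transcripts": n_transcripts}
    for cls, raw in classes.items():
        grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for seq_id, strand, start, end in raw:
            grouped.setdefault((seq_id, strand), []).append((start, end))
        merged: dict[tuple[str, str], tuple] = {}
        for key, ivs in grouped.items():
            ivs.sort()
            acc: list[list[int]] = []
            for start, end in ivs:
                if acc and start <= acc[-1][1] + 1:
                    acc[-1][1] = max(acc[-1][1], end)
                else:
                    acc.append([start, end])
            merged[key] = tuple(tuple(iv) for iv in acc)
        sig[cls] = tuple(sorted(merged.items()))
    return sig


def small_spec(seed: int = 0, genes: int = 12, scaffolds: int = 2,
               **overrides) -> GeneratorSpec:
    """Convenience spec for quick tests."""
    per = max(1, genes // scaffolds)
    return replace(
        GeneratorSpec(seed=seed, n_scaffolds=scaffolds,
                      genes_per_scaffold=per),
        **overrides,
    )
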