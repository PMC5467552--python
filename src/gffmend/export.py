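"""Canonical outputs: GFF3, FASTA sets, EMBL flat files and JSON statistics.

The repaired, named and verified gene-model graph is written back out as
clean GFF3 and as the sequence sets mirrored alongside an annotation
release (scaffolds, CDS, proteins). For INSDC submission an EMBL flat
file per scaffold is produced (ENA conventions: 80-column lines,
``join``/``complement`` location grammar, ``/codon_start`` derived from
the first CDS segment's phase). Assembly summary statistics (N50/N90, GC)
and a codon-usage table are exported as JSON documents whose schemas ship
with the package.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import Feature, FeatureGraph, TRANSCRIPT_TYPES
from .verify import VerificationError, assemble_cds, cds_children, translate


class ExportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFF3

_ESCAPES = [("%", "%25"), (";", "%3B"), ("=", "%3D"), (",", "%2C"),
            ("\t", "%09"), ("\n", "%0A")]


def escape_attribute(value: str) -> str:
    for char, code in _ESCAPES:
        value = value.replace(char, code)
    return value


def serialize_attributes(attrs: Mapping[str, Sequence[str]]) -> str:
    parts = []
    for key, vals in attrs.items():
        parts.append(f"{key}=" + ",".join(escape_attribute(v) for v in vals))
    return ";".join(parts) if parts else "."


_TYPE_RANK = {"gene": 0, "mrna": 1, "transcript": 1, "mirna": 1, "trna": 1,
              "ncrna": 1, "rrna": 1, "exon": 2, "cds": 3}


def write_gff3(graph: FeatureGraph, include_sequences: bool = False) -> str:
    """Serialise a graph as GFF3: features sorted by scaffold and start,
    parents before children, multiline features as one line per segment
    sharing their ID."""
    missing = [
        f"{f.feature_type}@{f.seq_id}:{f.start}" for f in graph
        if f.feature_id is None
    ]
    if missing:
        raise ExportError(
            "features lack IDs after repair: " + ", ".join(missing[:10])
        )
    lines = ["##gff-version 3"]
    emitted: set[int] = set()

    def feature_lines(f: Feature) -> None:
        if f.uid in emitted:
            return
        emitted.add(f.uid)
        attrs: dict[str, list[str]] = {"ID": [f.feature_id]}
        parent_ids = sorted(
            {p.feature_id for p in graph.parents_of(f) if p.feature_id}
        )
        if parent_ids:
            attrs["Parent"] = parent_ids
        for k, vals in f.attributes.items():
            if k.lower() in ("id", "parent") or k == "_bare":
                continue
            attrs[k] = list(vals)
        col9 = serialize_attributes(attrs)
        score = "." if f.score is None else f"{f.score:g}"
        for seg, phase in sorted(
            zip(f.segments, f.phases), key=lambda sp: sp[0].start
        ):
            lines.append(
                "\t".join(
                    (
                        seg.seq_id,
                        f.source or ".",
                        f.type_as_read,
                        str(seg.start),
                        str(seg.end),
                        score,
                        seg.strand,
                        "." if phase is None else str(phase),
                        col9,
                    )
                )
            )
        for child in sorted(
            graph.children_of(f),
            key=lambda c: (c.start, _TYPE_RANK.get(c.feature_type, 9),
                           c.feature_id or ""),
        ):
            feature_lines(child)

    for root in sorted(
        graph.roots(),
        key=lambda f: (f.seq_id, f.start, _TYPE_RANK.get(f.feature_type, 9),
                       f.feature_id or ""),
    ):
        feature_lines(root)
    # multi-parent stragglers (never expected, but stay lossless)
    for f in sorted(graph, key=lambda f: f.uid):
        feature_lines(f)
    text = "\n".join(lines) + "\n"
    if include_sequences and graph.sequences:
        text += "##FASTA\n"
        for name in sorted(graph.sequences):
            text += f">{name}\n"
            seq = graph.sequences[name]
            for i in range(0, len(seq), 60):
                text += seq[i:i + 60] + "\n"
    return text


# ---------------------------------------------------------------------------
# FASTA sequence sets


def format_fasta(records: Sequence[tuple[str, str]], width: int = 60) -> str:
    out = []
    for header, seq in records:
        out.append(f">{header}")
        for i in range(0, len(seq), width):
            out.append(seq[i:i + width])
    return "\n".join(out) + "\n" if records else ""


@dataclass
class SequenceSets:
    scaffolds: list[tuple[str, str]] = field(default_factory=list)
    cds: list[tuple[str, str]] = field(default_factory=list)
    proteins: list[tuple[str, str]] = field(default_factory=list)


def _sorted_transcripts(graph: FeatureGraph) -> list[Feature]:
    return sorted(
        (f for f in graph if f.feature_type in TRANSCRIPT_TYPES
         and cds_children(graph, f)),
        key=lambda t: (t.seq_id, t.start, t.stable_id or t.feature_id or ""),
    )


def export_sequences(
    graph: FeatureGraph, genome: Mapping[str, str]
) -> SequenceSets:
    """Scaffold, CDS and protein sequence sets for a verified graph.

    A transcript whose CDS cannot be assembled is skipped with an issue;
    the remaining records are still produced. Headers carry the stable ID
    and, when known, the description.
    """
    sets = SequenceSets()
    sets.scaffolds = [(name, genome[name]) for name in sorted(genome)]
    for t in _sorted_transcripts(graph):
        tid = t.stable_id or t.feature_id
        pid = t.translation_stable_id or tid
        desc = t.description
        if desc is None:
            parents = graph.parents_of(t)
            if parents and parents[0].description:
                desc = parents[0].description
        suffix = f" {desc}" if desc else ""
        try:
            nt = assemble_cds(t, graph, genome)
            protein = translate(nt, graph=graph)
        except VerificationError as exc:
            graph.log(
                "error", "cds_assembly_failed",
                f"transcript {tid!r}: {exc}",
                feature_ids=(tid,) if tid else (),
            )
            continue
        sets.cds.append((f"{tid}{suffix}", nt))
        sets.proteins.append((f"{pid}{suffix}", protein))
    return sets


# ---------------------------------------------------------------------------
# assembly statistics


@dataclass
class AssemblyStats:
    scaffold_count: int
    total_span: int
    longest: int
    n50: int
    n90: int
    gc_fraction: float
    n_fraction: float
    lengths: list[int]

    def to_dict(self) -> dict:
        return {
            "scaffold_count": self.scaffold_count,
            "total_span": self.total_span,
            "longest": self.longest,
            "N50": self.n50,
            "N90": self.n90,
            "GC_fraction": self.gc_fraction,
            "N_fraction": self.n_fraction,
            "lengths": self.lengths,
        }


def _nx(lengths_desc: list[int], total: int, fraction: float) -> int:
    threshold = total * fraction
    acc = 0
    for length in lengths_desc:
        acc += length
        if acc >= threshold:
            return length
    return lengths_desc[-1]  # pragma: no cover


def assembly_stats(genome: Mapping[str, str]) -> AssemblyStats:
    """N50/N90, GC (over unambiguous bases) and N content of an assembly.

    N50 is the length of the shortest sequence in the smallest prefix of
    the descending-sorted lengths whose sum reaches half the total span;
    N90 analogously at 90%.
    """
    if not genome:
        raise ExportError("cannot compute statistics of an empty assembly")
    lengths = sorted((len(s) for s in genome.values()), reverse=True)
    total = sum(lengths)
    gc = at = n = 0
    for seq in genome.values():
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
        n += up.count("N")
    acgt = gc + at
    return AssemblyStats(
        scaffold_count=len(lengths),
        total_span=total,
        longest=lengths[0],
        n50=_nx(lengths, total, 0.5),
        n90=_nx(lengths, total, 0.9),
        gc_fraction=gc / acgt if acgt else 0.0,
        n_fraction=n / total if total else 0.0,
        lengths=lengths,
    )


# ---------------------------------------------------------------------------
# codon usage

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]
_CODON_TO_AA = {
    c: ("*" if c in _STANDARD.stop_codons else _STANDARD.forward_table[c])
    for c in ALL_CODONS
}


@dataclass
class CodonUsage:
    counts: dict[str, int]
    frequencies: dict[str, float]
    per_aa_usage: dict[str, float]
    total_codons: int

    def to_dict(self) -> dict:
        return {
            "total_codons": self.total_codons,
            "counts": self.counts,
            "frequencies": self.frequencies,
            "per_aa_usage": self.per_aa_usage,
        }


def codon_usage(cds_sequences: Sequence[str]) -> CodonUsage:
    """Codon counts and frequencies over a CDS set, read in frame 0.

    Trailing partial codons are dropped; codons containing ambiguous
    bases are ignored. ``per_aa_usage`` is each codon's share within its
    synonymous family (stops form the ``*`` family).
    """
    counts = {c: 0 for c in ALL_CODONS}
    for seq in cds_sequences:
        up = seq.upper()
        for i in range(0, len(up) - len(up) % 3, 3):
            codon = up[i:i + 3]
            if codon in counts:
                counts[codon] += 1
    total = sum(counts.values())
    frequencies = {
        c: (n / total if total else 0.0) for c, n in counts.items()
    }
    family_totals: dict[str, int] = {}
    for c, n in counts.items():
        aa = _CODON_TO_AA[c]
        family_totals[aa] = family_totals.get(aa, 0) + n
    per_aa = {
        c: (counts[c] / family_totals[_CODON_TO_AA[c]]
            if family_totals[_CODON_TO_AA[c]] else 0.0)
        for c in ALL_CODONS
    }
    return CodonUsage(counts, frequencies, per_aa, total)


# ---------------------------------------------------------------------------
# EMBL flat files


@dataclass
class EmblMeta:
    organism: str = "unclassified organism"
    taxonomy: tuple[str, ...] = ("Eukaryota",)
    molecule_type: str = "genomic DNA"
    data_class: str = "STD"
    division: str = "UNC"
    topology: str = "linear"
    sequence_version: int = 1


def _location(segments, strand: str):
    parts = sorted(segments, key=lambda s: s.start, reverse=(strand == "-"))
    locs = [
        SimpleLocation(s.start - 1, s.end, -1 if strand == "-" else 1)
        for s in parts
    ]
    return locs[0] if len(locs) == 1 else CompoundLocation(locs)


def write_embl(
    graph: FeatureGraph,
    genome: Mapping[str, str],
    meta: Optional[EmblMeta] = None,
    expected: Optional[Mapping[str, str]] = None,
) -> dict[str, str]:
    """One EMBL flat-file record per scaffold carrying gene/mRNA/CDS
    features. Every ``/translation`` is recomputed from the graph; if
    ``expected`` is supplied and disagrees for any CDS, the whole
    scaffold's record is refused with an issue."""
    meta = meta or EmblMeta()
    records: dict[str, str] = {}
    genes_by_scaffold: dict[str, list[Feature]] = {}
    for g in graph.features_of_type("gene"):
        genes_by_scaffold.setdefault(g.seq_id, []).append(g)

    for seq_id in sorted(genome):
        seq = genome[seq_id]
        rec = SeqRecord(
            Seq(seq),
            id=f"{seq_id}.{meta.sequence_version}",
            name=seq_id,
            description=f"{meta.organism} genome assembly, {seq_id}",
        )
        rec.annotations = {
            "molecule_type": meta.molecule_type,
            "topology": meta.topology,
            "data_file_division": meta.division,
            "organism": meta.organism,
            "taxonomy": list(meta.taxonomy),
            "accession": seq_id,
        }
        feats = [
            SeqFeature(
                SimpleLocation(0, len(seq), 1),
                type="source",
                qualifiers={
                    "organism": [meta.organism],
                    "mol_type": [meta.molecule_type],
                },
            )
        ]
        refused = False
        for gene in sorted(genes_by_scaffold.get(seq_id, []),
                           key=lambda g: (g.start, g.stable_id or "")):
            gq = {"locus_tag": [gene.stable_id or gene.feature_id]}
            if gene.display_name:
                gq["gene"] = [gene.display_name]
            if gene.description:
                gq["note"] = [gene.description]
            feats.append(
                SeqFeature(_location(gene.segments, gene.strand),
                           type="gene", qualifiers=gq)
            )
            for t in sorted(
                (c for c in graph.children_of(gene)
                 if c.feature_type in TRANSCRIPT_TYPES),
                key=lambda t: (t.start, t.stable_id or ""),
            ):
                tid = t.stable_id or t.feature_id
                exon_segs = [
                    s for c in graph.children_of(t)
                    if c.feature_type == "exon" for s in c.segments
                ]
                if exon_segs:
                    feats.append(
                        SeqFeature(
                            _location(exon_segs, t.strand),
                            type="mRNA",
                            qualifiers={"locus_tag": [tid]},
                        )
                    )
                cds = cds_children(graph, t)
                if not cds:
                    continue
                seg_phase = [
                    (s, p) for c in cds for s, p in zip(c.segments, c.phases)
                ]
                seg_phase.sort(
                    key=lambda sp: sp[0].start, reverse=(t.strand == "-")
                )
                first_phase = seg_phase[0][1] or 0
                try:
                    protein = translate(assemble_cds(t, graph, genome))
                except VerificationError as exc:
                    graph.log("error", "cds_assembly_failed",
                              f"EMBL export, transcript {tid!r}: {exc}",
                              feature_ids=(tid,) if tid else ())
                    refused = True
                    break
                pid = t.translation_stable_id or tid
                if expected is not None and expected.get(pid) != protein:
                    graph.log(
                        "error", "translation_mismatch",
                        f"EMBL export refused for {seq_id}: translation of "
                        f"{pid!r} does not match the expected protein",
                        feature_ids=(pid,) if pid else (),
                    )
                    refused = True
                    break
                cq = {
                    "codon_start": [str(first_phase + 1)],
                    "locus_tag": [tid],
                    "translation": [protein],
                }
                desc = t.description or gene.description
                if desc:
                    cq["product"] = [desc]
                feats.append(
                    SeqFeature(
                        _location([sp[0] for sp in seg_phase], t.strand),
                        type="CDS",
                        qualifiers=cq,
                    )
                )
            if refused:
                break
        if refused:
            continue
        rec.features = feats
        buf = io.StringIO()
        SeqIO.write([rec], buf, "embl")
        text = buf.getvalue()
        # Biopython leaves the ID line's data-class slot empty; fill it.
        lines = text.split("\n")
        if lines[0].startswith("ID   "):
            lines[0] = lines[0].replace("; ; ", f"; {meta.data_class}; ", 1)
        records[seq_id] = "\n".join(lines)
    return records


# -- syntactic validator ----------------------------------------------------

_ID_RE = re.compile(
    r"^ID   \S+; SV \d+; (linear|circular); [^;]+; [A-Z]{3}; \w+; \d+ BP\.$"
)
_RANGE_RE = re.compile(r"^<?\d+\.\.>?\d+$|^\d+$")


def _check_location(loc: str) -> bool:
    loc = loc.strip()
    if loc.startswith("complement(") and loc.endswith(")"):
        return _check_location(loc[len("complement("):-1])
    if loc.startswith("join(") and loc.endswith(")"):
        inner = loc[len("join("):-1]
        depth = 0
        parts, cur = [], []
        for ch in inner:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if ch == "," and depth == 0:
                parts.append("".join(cur))
                cur = []
            else:
                cur.append(ch)
        parts.append("".join(cur))
        return len(parts) >= 1 and all(_check_location(p) for p in parts)
    return bool(_RANGE_RE.match(loc))


def validate_embl(text: str) -> list[str]:
    """Syntactic checks on EMBL flat-file text; returns a list of problems
    (empty when the record set is well formed). Checks line lengths, the
    ID line, feature-location grammar, ``/codon_start`` values and the SQ
    base count."""
    problems: list[str] = []
    chunks = [c for c in re.split(r"(?m)^//$", text) if c.strip()]
    if not chunks:
        return ["no records found"]
    if not re.search(r"(?m)^//$", text):
        problems.append("record not terminated by //")
    for idx, chunk in enumerate(chunks):
        lines = chunk.strip("\n").split("\n")
        label = f"record {idx + 1}"
        for ln in lines:
            if len(ln) > 80:
                problems.append(f"{label}: line exceeds 80 columns: {ln[:30]}...")
        if not _ID_RE.match(lines[0]):
            problems.append(f"{label}: malformed ID line: {lines[0]!r}")
        for prefix in ("AC   ", "OS   ", "OC   ", "FH   ", "SQ   "):
            if not any(ln.startswith(prefix) for ln in lines):
                problems.append(f"{label}: missing {prefix.strip()} line")
        # assemble FT features
        features: list[dict] = []
        for ln in lines:
            if not ln.startswith("FT "):
                continue
            body = ln[5:]
            if body[:16].strip():  # new feature key
                key = body[:16].strip()
                rest = body[16:].strip()
                features.append(
                    {"key": key, "location": rest, "qualifiers": [],
                     "in_qualifiers": False}
                )
            else:
                cont = body[16:].strip()
                if not features:
                    problems.append(f"{label}: FT continuation before key")
                    continue
                feat = features[-1]
                if cont.startswith("/"):
                    feat["in_qualifiers"] = True
                    feat["qualifiers"].append(cont)
                elif feat["in_qualifiers"]:
                    feat["qualifiers"][-1] += cont
                else:
                    feat["location"] += cont
        if not any(f["key"] == "source" for f in features):
            problems.append(f"{label}: no source feature")
        for feat in features:
            if not _check_location(feat["location"]):
                problems.append(
                    f"{label}: bad location for {feat['key']}: "
                    f"{feat['location']!r}"
                )
            for q in feat["qualifiers"]:
                if q.startswith("/codon_start="):
                    if q.split("=", 1)[1] not in ("1", "2", "3"):
                        problems.append(
                            f"{label}: invalid {q} (must be 1, 2 or 3)"
                        )
        # SQ length check
        sq = [ln for ln in lines if ln.startswith("SQ   ")]
        if sq:
            m = re.search(r"Sequence (\d+) BP", sq[0])
            declared = int(m.group(1)) if m else -1
            seq_len = 0
            past_sq = False
            for ln in lines:
                if ln.startswith("SQ   "):
                    past_sq = True
                    continue
                if past_sq:
                    seq_len += sum(
                        1 for ch in ln if ch.isalpha()
                    )
            if declared != seq_len:
                problems.append(
                    f"{label}: SQ declares {declared} BP but sequence "
                    f"block holds {seq_len}"
                )
    return problems


def parse_embl_translations(text: str) -> dict[str, str]:
    """Extract locus_tag → /translation pairs from EMBL CDS features
    (used to cross-check exports)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(text), "embl"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            tags = feat.qualifiers.get("locus_tag", [])
            trans = feat.qualifiers.get("translation", [])
            if tags and trans:
                out[tags[0]] = trans[0]
    return out


# ---------------------------------------------------------------------------
# JSON documents


def stats_json(stats: AssemblyStats) -> str:
    return json.dumps(stats.to_dict(), indent=2, sort_keys=True) + "\n"


def codon_usage_json(usage: CodonUsage) -> str:
    return json.dumps(usage.to_dict(), indent=2, sort_keys=True) + "\n"
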