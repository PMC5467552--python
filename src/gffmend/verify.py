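"""CDS assembly, translation and gene-set verification.

The decisive check after any annotation import is sequence-level: assemble
each transcript's CDS from the genome, translate it, and compare against
the provider's expected proteins. The two classic causes of disagreement
are providers interpreting the GFF phase column differently (``phase`` =
bases to remove from the 5' end of a CDS segment, *not* a reading frame)
and expected-protein files that were hand-edited to stop at the first stop
codon; mismatches are classified accordingly.

Also computed here is the gene-set quality summary used when triaging
draft annotations: the fraction of genes whose canonical (longest-CDS)
transcript is single-exon, and the subset of those with no structural
domain hit — an excess of which typically indicates spurious predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from Bio.Seq import Seq

from .model import Feature, FeatureGraph, TRANSCRIPT_TYPES


class VerificationError(ValueError):
    pass


def _segment_sequence(genome: Mapping[str, str], seq_id: str,
                      start: int, end: int) -> str:
    try:
        scaffold = genome[seq_id]
    except KeyError:
        raise VerificationError(f"scaffold {seq_id!r} not in genome") from None
    if end > len(scaffold):
        raise VerificationError(
            f"segment {seq_id}:{start}-{end} exceeds scaffold length "
            f"{len(scaffold)}"
        )
    return scaffold[start - 1:end]


def cds_children(graph: FeatureGraph, t: Feature) -> list[Feature]:
    return [c for c in graph.children_of(t) if c.feature_type == "cds"]


def assemble_cds(
    t: Feature,
    graph: FeatureGraph,
    genome: Mapping[str, str],
    apply_phase: bool = True,
) -> str:
    """Concatenate a transcript's CDS segments in transcription order.

    Minus-strand segments are reverse-complemented and taken in descending
    coordinate order. With ``apply_phase`` the first segment's phase p
    (transcription order) removes p leading bases; a missing phase is
    treated as 0 with an issue. With ``apply_phase=False`` the raw
    concatenation is returned (used by the mismatch classifier to re-try
    alternative phases).
    """
    seg_phase: list[tuple] = []
    for c in cds_children(graph, t):
        seg_phase.extend(zip(c.segments, c.phases))
    if not seg_phase:
        raise VerificationError(
            f"transcript {t.feature_id!r} has no CDS children"
        )
    minus = t.strand == "-" or seg_phase[0][0].strand == "-"
    seg_phase.sort(key=lambda sp: sp[0].start, reverse=minus)
    parts = []
    for seg, _ in seg_phase:
        s = _segment_sequence(genome, seg.seq_id, seg.start, seg.end)
        if minus:
            s = str(Seq(s).reverse_complement())
        parts.append(s)
    nt = "".join(parts)
    if not apply_phase:
        return nt
    first_phase = seg_phase[0][1]
    if first_phase is None:
        graph.log(
            "warning", "missing_phase",
            f"first CDS segment of {t.feature_id!r} lacks phase; assumed 0",
            feature_ids=(t.feature_id,) if t.feature_id else (),
        )
        first_phase = 0
    return nt[first_phase:]


def translate(
    nt: str,
    table: Union[int, str] = 1,
    graph: Optional[FeatureGraph] = None,
) -> str:
    """Translate in frame 0 with the given NCBI genetic code.

    Internal stops are rendered ``*``; a single terminal stop is stripped;
    trailing 1–2 bases are dropped (``partial_codon`` issue when a graph is
    supplied to log against).
    """
    if len(nt) < 3:
        raise VerificationError(
            f"sequence of length {len(nt)} is too short to translate"
        )
    overhang = len(nt) % 3
    if overhang:
        if graph is not None:
            graph.log(
                "warning", "partial_codon",
                f"{overhang} trailing base(s) ignored during translation",
            )
        nt = nt[: len(nt) - overhang]
    protein = str(Seq(nt).translate(table=table))
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


@dataclass
class Mismatch:
    seq_id: str
    classification: str  # phase_shift | stop_truncation | other
    detail: str = ""


@dataclass
class VerificationReport:
    ids_only_predicted: list[str] = field(default_factory=list)
    ids_only_expected: list[str] = field(default_factory=list)
    identical: int = 0
    mismatched: list[Mismatch] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.ids_only_predicted or self.ids_only_expected or self.mismatched
        )

    def to_dict(self) -> dict:
        return {
            "ids_only_predicted": self.ids_only_predicted,
            "ids_only_expected": self.ids_only_expected,
            "identical": self.identical,
            "mismatched": [
                {"id": m.seq_id, "class": m.classification, "detail": m.detail}
                for m in self.mismatched
            ],
        }


def classify_mismatch(
    predicted: str,
    expected: str,
    cds_nt: Optional[str] = None,
    table: Union[int, str] = 1,
) -> Mismatch:
    """Attribute a predicted/expected disagreement to its likely cause.

    stop_truncation: the expected protein equals the prediction truncated
    at its first internal stop (hand-edited expected file).
    phase_shift: re-translating the stored CDS with the first-segment
    phase forced to 0, 1 or 2 reproduces the expected protein (provider
    used a different phase interpretation).
    """
    if "*" in predicted and predicted.split("*", 1)[0] == expected:
        return Mismatch("", "stop_truncation",
                        "expected stops at prediction's first internal stop")
    if cds_nt is not None and len(cds_nt) >= 5:
        for p in (0, 1, 2):
            try:
                alt = translate(cds_nt[p:], table=table)
            except VerificationError:
                continue
            if alt == expected:
                return Mismatch(
                    "", "phase_shift",
                    f"expected matches translation at forced phase {p}",
                )
    return Mismatch("", "other", "no classification applies")


def verify_translations(
    predicted: Mapping[str, str],
    expected: Mapping[str, str],
    cds_nt: Optional[Mapping[str, str]] = None,
    table: Union[int, str] = 1,
) -> VerificationReport:
    """Compare predicted and expected proteins keyed on translation IDs.

    ``cds_nt`` optionally supplies the raw (phase-untrimmed) CDS
    nucleotide sequences so phase-shift mismatches can be recognised.
    """
    report = VerificationReport()
    report.ids_only_predicted = sorted(set(predicted) - set(expected))
    report.ids_only_expected = sorted(set(expected) - set(predicted))
    for sid in sorted(set(predicted) & set(expected)):
        if predicted[sid] == expected[sid]:
            report.identical += 1
            continue
        mm = classify_mismatch(
            predicted[sid],
            expected[sid],
            cds_nt.get(sid) if cds_nt else None,
            table=table,
        )
        mm.seq_id = sid
        report.mismatched.append(mm)
    return report


# ---------------------------------------------------------------------------
# gene-set quality


def _round_half_up_pct(count: int, total: int) -> int:
    if total == 0:
        return 0
    # floor(100*count/total + 1/2) in exact integer arithmetic
    return (200 * count + total) // (2 * total)


@dataclass
class GeneSetQuality:
    total_genes: int
    single_exon_genes: int
    single_exon_no_domain: int

    @property
    def pct_single_exon(self) -> int:
        return _round_half_up_pct(self.single_exon_genes, self.total_genes)

    @property
    def pct_single_exon_no_domain(self) -> int:
        return _round_half_up_pct(self.single_exon_no_domain, self.total_genes)

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "single_exon_genes": self.single_exon_genes,
            "single_exon_no_domain": self.single_exon_no_domain,
            "pct_single_exon": self.pct_single_exon,
            "pct_single_exon_no_domain": self.pct_single_exon_no_domain,
        }


def canonical_transcript(
    graph: FeatureGraph, gene: Feature
) -> Optional[Feature]:
    """Longest-summed-CDS transcript; ties broken by smallest stable ID."""
    best = None
    best_key = None
    for t in graph.children_of(gene):
        if t.feature_type not in TRANSCRIPT_TYPES:
            continue
        cds_len = sum(
            seg.length for c in cds_children(graph, t) for seg in c.segments
        )
        if cds_len == 0:
            continue
        tie = t.stable_id or t.feature_id or f"uid{t.uid}"
        key = (-cds_len, tie)
        if best_key is None or key < best_key:
            best, best_key = t, key
    return best


def exon_segment_count(graph: FeatureGraph, t: Feature) -> int:
    n = sum(
        len(c.segments) for c in graph.children_of(t)
        if c.feature_type == "exon"
    )
    if n == 0:
        # exon-less dialects: fall back to CDS segmentation
        n = sum(len(c.segments) for c in cds_children(graph, t))
    return n


def gene_set_quality(
    graph: FeatureGraph,
    domains: Union[Mapping[str, int], set, frozenset, None] = None,
) -> GeneSetQuality:
    """Summarise single-exon gene content of a protein-coding gene set.

    ``domains`` maps translation stable IDs to domain-hit counts (or is a
    set of IDs with at least one hit); only presence/absence is used.
    """
    domains = domains or {}

    def has_domain(tid: Optional[str]) -> bool:
        if tid is None:
            return False
        if isinstance(domains, (set, frozenset)):
            return tid in domains
        return domains.get(tid, 0) > 0

    total = single = single_nodom = 0
    for gene in graph.features_of_type("gene"):
        t = canonical_transcript(graph, gene)
        if t is None:
            graph.log(
                "info", "non_coding_gene",
                f"gene {gene.feature_id!r} has no coding transcript; "
                "excluded from gene-set quality",
                feature_ids=(gene.feature_id,) if gene.feature_id else (),
            )
            continue
        total += 1
        if exon_segment_count(graph, t) == 1:
            single += 1
            tid = t.translation_stable_id or t.stable_id or t.feature_id
            if not has_domain(tid):
                single_nodom += 1
    return GeneSetQuality(total, single, single_nodom)


def read_domain_hits(path: str) -> dict[str, int]:
    """Count tab-separated domain-annotation rows per sequence ID
    (InterProScan-style TSV: sequence ID in column 1)."""
    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid = line.split("\t", 1)[0].strip()
            if sid:
                counts[sid] = counts.get(sid, 0) + 1
    return counts
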