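import json

import numpy as np
import pytest

from gffmend.export import (
    EmblMeta,
    ExportError,
    assembly_stats,
    codon_usage,
    escape_attribute,
    export_sequences,
    format_fasta,
    parse_embl_translations,
    serialize_attributes,
    stats_json,
    validate_embl,
    write_embl,
    write_gff3,
)
from gffmend.model import Feature, FeatureGraph, GenomicInterval
from gffmend.parser import parse_attributes, parse_gff
from gffmend.simulate import coverage_signature
from gffmend.verify import translate, verify_translations


# ---------------------------------------------------------------------------
# GFF3


def test_gff3_round_trip_preserves_structure(bundle, truth_graph):
    text = write_gff3(truth_graph)
    reparsed = parse_gff(text.splitlines(True))
    from gffmend.rules import apply_all

    apply_all(reparsed, [])
    # multiline CDS re-split at parse; compare on coverage signature
    from gffmend.config import Config, default_config_path

    rules = Config.load(str(default_config_path())).rules()
    apply_all(reparsed, rules)
    assert coverage_signature(reparsed) == coverage_signature(truth_graph)


def test_attribute_escaping_round_trips():
    attrs = {"Note": ["a,b", "x;y"], "Key": ["50%=half"]}
    assert escape_attribute("a,b") == "a%2Cb"
    line = serialize_attributes(attrs)
    assert parse_attributes(line) == attrs


def test_empty_graph_writes_header_only():
    assert write_gff3(FeatureGraph()) == "##gff-version 3\n"


def test_write_refuses_idless_features():
    g = FeatureGraph()
    g.add(Feature(feature_id=None, feature_type="exon",
                  segments=[GenomicInterval("c", 1, 10, "+")]))
    with pytest.raises(ExportError):
        write_gff3(g)


def test_parents_written_before_children(truth_graph):
    text = write_gff3(truth_graph)
    seen = set()
    for line in text.splitlines():
        if line.startswith("#"):
            continue
        attrs = parse_attributes(line.split("\t")[8])
        for parent in attrs.get("Parent", []):
            assert parent in seen, f"child before parent {parent}"
        seen.update(attrs.get("ID", []))


# ---------------------------------------------------------------------------
# sequence sets


def test_export_sequences_round_trip_self_verifies(bundle, truth_graph):
    sets = export_sequences(truth_graph, bundle.genome)
    assert len(sets.cds) == len(bundle.proteins)
    proteins = {h.split()[0]: s for h, s in sets.proteins}
    report = verify_translations(proteins, dict(proteins))
    assert report.ok
    # emitted proteins equal the generator's
    expected = {k.replace(".p", ".t"): v for k, v in bundle.proteins.items()}
    assert proteins == expected


def test_export_isolates_failing_records(bundle, default_cfg):
    from gffmend.rules import apply_all

    graph = parse_gff(bundle.gff3.splitlines(True))
    apply_all(graph, default_cfg.rules())
    genome = {k: v for k, v in bundle.genome.items()}
    # truncate one scaffold so its transcripts fail
    victim = sorted(genome)[0]
    genome[victim] = genome[victim][:50]
    sets = export_sequences(graph, genome)
    assert 0 < len(sets.cds) < len(bundle.proteins)
    assert any(i.code == "cds_assembly_failed" for i in graph.issues)


# ---------------------------------------------------------------------------
# assembly stats


@pytest.mark.parametrize(
    "lengths,n50,n90",
    [
        ([10, 8, 6, 4, 2], 8, 4),
        ([7], 7, 7),
        ([5, 5, 5, 5], 5, 5),
    ],
)
def test_n50_n90_definitions(lengths, n50, n90):
    genome = {f"s{i}": "A" * n for i, n in enumerate(lengths)}
    stats = assembly_stats(genome)
    assert (stats.n50, stats.n90) == (n50, n90)
    assert stats.total_span == sum(lengths)
    assert stats.longest == max(lengths)


def brute_force_nx(lengths, fraction):
    """Independent oracle: scan every descending prefix explicitly."""
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    for i in range(len(desc)):
        if sum(desc[: i + 1]) >= total * fraction:
            return desc[i]
    raise AssertionError


def test_nx_matches_brute_force_oracle_on_random_lists():
    rng = np.random.default_rng(0)
    for _ in range(200):
        lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 40)))
        genome = {f"s{i}": "A" * n for i, n in enumerate(lengths)}
        stats = assembly_stats(genome)
        assert stats.n50 == brute_force_nx(lengths, 0.5)
        assert stats.n90 == brute_force_nx(lengths, 0.9)


def test_gc_and_n_fractions():
    stats = assembly_stats({"s": "GGCCAATTNN"})
    assert stats.gc_fraction == pytest.approx(0.5)
    assert stats.n_fraction == pytest.approx(0.2)
    assert stats.n50 == 10


def test_empty_assembly_is_an_error():
    with pytest.raises(ExportError):
        assembly_stats({})


def test_stats_json_is_schema_shaped():
    doc = json.loads(stats_json(assembly_stats({"s": "ACGT" * 100})))
    for key in ("scaffold_count", "total_span", "longest", "N50", "N90",
                "GC_fraction", "N_fraction", "lengths"):
        assert key in doc


# ---------------------------------------------------------------------------
# codon usage


def test_codon_usage_single_codon():
    usage = codon_usage(["ATGATG"])
    assert usage.counts["ATG"] == 2
    assert usage.frequencies["ATG"] == pytest.approx(1.0)


def test_codon_usage_three_codon_toy():
    usage = codon_usage(["ATGAAATAG"])
    for codon in ("ATG", "AAA", "TAG"):
        assert usage.counts[codon] == 1
        assert usage.frequencies[codon] == pytest.approx(1 / 3)
    assert usage.total_codons == 3


def test_codon_frequencies_sum_to_one(bundle):
    usage = codon_usage(list(bundle.cds.values()))
    assert sum(usage.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
    # per-amino-acid relative usage sums to 1 within each family
    from gffmend.export import _CODON_TO_AA

    fam: dict[str, float] = {}
    for codon, share in usage.per_aa_usage.items():
        fam[_CODON_TO_AA[codon]] = fam.get(_CODON_TO_AA[codon], 0.0) + share
    for aa, total in fam.items():
        assert total == pytest.approx(1.0, abs=1e-9), aa


def test_codon_usage_empty_input_flagged_zero():
    usage = codon_usage([])
    assert usage.total_codons == 0
    assert all(v == 0.0 for v in usage.frequencies.values())


# ---------------------------------------------------------------------------
# EMBL


def _embl_mini(strand="+", phase=0, segments=((1, 30), (61, 90))):
    g = FeatureGraph()
    lo, hi = segments[0][0], segments[-1][1]
    gene = Feature(feature_id="g1", feature_type="gene",
                   segments=[GenomicInterval("chr", lo, hi, strand)])
    t = Feature(feature_id="g1.t1", feature_type="mrna",
                segments=[GenomicInterval("chr", lo, hi, strand)])
    g.add(gene)
    g.add(t)
    g.add_edge(t.uid, gene.uid)
    phases = []
    cum = 0
    segs = list(segments) if strand == "+" else list(segments)[::-1]
    for s, e in segs:
        phases.append((3 - cum % 3) % 3 if cum else phase)
        cum += e - s + 1
    if strand == "-":
        phases = phases[::-1]
    for j, (s, e) in enumerate(segments, 1):
        exon = Feature(feature_id=f"e{j}", feature_type="exon",
                       segments=[GenomicInterval("chr", s, e, strand)])
        g.add(exon)
        g.add_edge(exon.uid, t.uid)
    cds = Feature(feature_id="g1.t1.cds", feature_type="cds",
                  segments=[GenomicInterval("chr", s, e, strand)
                            for s, e in segments],
                  phases=phases)
    g.add(cds)
    g.add_edge(cds.uid, t.uid)
    rng = np.random.default_rng(1)
    genome = {"chr": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])}
    return g, genome


def test_embl_plus_strand_join_location():
    g, genome = _embl_mini()
    text = write_embl(g, genome)["chr"]
    assert "join(1..30,61..90)" in text
    assert validate_embl(text) == []


def test_embl_minus_strand_complement_wrapping():
    g, genome = _embl_mini(strand="-", segments=((11, 100),))
    text = write_embl(g, genome)["chr"]
    assert "complement(11..100)" in text


def test_embl_codon_start_is_phase_plus_one():
    g, genome = _embl_mini(phase=2, segments=((1, 31),))
    text = write_embl(g, genome)["chr"]
    assert "/codon_start=3" in text
    assert validate_embl(text) == []


def test_embl_translation_qualifier_matches_recomputation(bundle, truth_graph):
    records = write_embl(truth_graph, bundle.genome)
    text = "".join(records[k] for k in sorted(records))
    assert validate_embl(text) == []
    from gffmend.verify import assemble_cds

    qualifiers = parse_embl_translations(text)
    assert len(qualifiers) == len(bundle.proteins)
    for t in truth_graph.features_of_type("mrna"):
        tid = t.stable_id or t.feature_id
        assert qualifiers[tid] == translate(
            assemble_cds(t, truth_graph, bundle.genome)
        )


def test_embl_refuses_record_on_translation_mismatch(bundle, default_cfg):
    from gffmend.rules import apply_all

    graph = parse_gff(bundle.gff3.splitlines(True))
    apply_all(graph, default_cfg.rules())
    expected = {
        (t.translation_stable_id or t.stable_id or t.feature_id): "WRONG"
        for t in graph.features_of_type("mrna")
    }
    records = write_embl(graph, bundle.genome, expected=expected)
    assert records == {} or all(
        "CDS" not in r for r in records.values()
    )
    assert any(
        i.code == "translation_mismatch" for i in graph.issues
    )


def test_embl_validator_reports_defects():
    g, genome = _embl_mini()
    text = write_embl(g, genome, EmblMeta(organism="Testus testus"))["chr"]
    assert validate_embl(text) == []
    broken = text.replace("join(1..30,61..90)", "join(1..30,,61..90)")
    assert any("location" in p for p in validate_embl(broken))
    broken = text.replace("/codon_start=1", "/codon_start=7")
    assert any("codon_start" in p for p in validate_embl(broken))
    long_line = text.replace(
        "FT   source", "FT   source" + " " * 80, 1
    )
    assert any("80 columns" in p for p in validate_embl(long_line))


def test_embl_line_lengths_within_80(bundle, truth_graph):
    records = write_embl(truth_graph, bundle.genome)
    for text in records.values():
        assert all(len(line) <= 80 for line in text.splitlines())


def test_format_fasta_wraps_at_60():
    text = format_fasta([("id desc", "A" * 130)])
    lines = text.splitlines()
    assert lines[0] == ">id desc"
    assert [len(x) for x in lines[1:]] == [60, 60, 10]
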