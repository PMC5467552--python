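import pytest

from gffmend.model import Feature, FeatureGraph, GenomicInterval
from gffmend.pipeline import predicted_translations
from gffmend.verify import (
    GeneSetQuality,
    VerificationError,
    assemble_cds,
    classify_mismatch,
    gene_set_quality,
    translate,
    verify_translations,
)


def _transcript_graph(segments, phases, strand="+"):
    g = FeatureGraph()
    span = GenomicInterval(
        "chr1", min(s for s, _ in segments), max(e for _, e in segments),
        strand,
    )
    t = Feature(feature_id="t1", feature_type="mrna", segments=[span])
    cds = Feature(
        feature_id="t1.cds", feature_type="cds",
        segments=[GenomicInterval("chr1", s, e, strand) for s, e in segments],
        phases=list(phases),
    )
    g.add(t)
    g.add(cds)
    g.add_edge(cds.uid, t.uid)
    return g, t


def test_assemble_cds_plus_strand_concatenates_in_order():
    genome = {"chr1": "ATGAAACCCTTTTAG"}
    g, t = _transcript_graph([(1, 6), (10, 15)], [0, 0])
    assert assemble_cds(t, g, genome) == "ATGAAATTTTAG"


def test_assemble_cds_minus_strand_reverse_complements_descending():
    genome = {"chr1": "ATGAAACCCTTTTAG"}
    g, t = _transcript_graph([(1, 6), (10, 15)], [0, 0], strand="-")
    # transcription order: (10,15) then (1,6), each reverse-complemented
    assert assemble_cds(t, g, genome) == "CTAAAA" + "TTTCAT"


def test_assemble_cds_first_segment_phase_trims_leading_bases():
    genome = {"chr1": "GGATGAAATTTAG"}
    g, t = _transcript_graph([(1, 11)], [2])
    nt = assemble_cds(t, g, genome)
    assert len(nt) == 9 and nt.startswith("ATG")


def test_assemble_cds_out_of_bounds_segment_is_an_error():
    g, t = _transcript_graph([(1, 60)], [0])
    with pytest.raises(VerificationError):
        assemble_cds(t, g, {"chr1": "ACGT"})


def test_missing_phase_treated_as_zero_with_issue():
    genome = {"chr1": "ATGAAATAG"}
    g, t = _transcript_graph([(1, 9)], [None])
    assert assemble_cds(t, g, genome) == "ATGAAATAG"
    assert any(i.code == "missing_phase" for i in g.issues)


@pytest.mark.parametrize(
    "nt,protein",
    [
        ("ATGAAATAG", "MK"),       # terminal stop stripped
        ("ATGTAAATG", "M*M"),      # internal stop retained
        ("ATGGGG", "MG"),
    ],
)
def test_translate_standard_code(nt, protein):
    assert translate(nt) == protein


def test_translate_drops_partial_codon_with_issue():
    g = FeatureGraph()
    assert translate("ATGAA", graph=g) == "M"
    assert any(i.code == "partial_codon" for i in g.issues)


def test_translate_rejects_too_short_input():
    with pytest.raises(VerificationError):
        translate("AT")


def test_verify_identical_maps_report_no_mismatches():
    m = {f"p{i}": "MKV" for i in range(5)}
    report = verify_translations(m, dict(m))
    assert report.identical == 5 and report.ok


def test_verify_id_set_differences_reported():
    report = verify_translations({"a": "MK", "b": "MK"}, {"b": "MK", "c": "MK"})
    assert report.ids_only_predicted == ["a"]
    assert report.ids_only_expected == ["c"]
    assert report.identical == 1


def test_stop_truncation_classification():
    mm = classify_mismatch("MK*QV", "MK")
    assert mm.classification == "stop_truncation"


def test_phase_shift_classification_from_stored_cds():
    # true protein uses phase 1; prediction was made at phase 0
    cds = "G" + "ATGAAACCCTAG"
    predicted = translate(cds)              # phase 0 (wrong frame)
    expected = translate(cds[1:])           # the provider's reading
    assert predicted != expected
    mm = classify_mismatch(predicted, expected, cds_nt=cds)
    assert mm.classification == "phase_shift"


def test_unexplained_mismatch_classified_other():
    mm = classify_mismatch("MKVA", "MRRR", cds_nt="ATGAAAGTTGCG")
    assert mm.classification == "other"


def test_invariant_identical_plus_mismatched_plus_extra_accounts_for_all():
    pred = {"a": "MK", "b": "MV", "c": "MM"}
    exp = {"a": "MK", "b": "MX"}
    r = verify_translations(pred, exp)
    assert r.identical + len(r.mismatched) + len(r.ids_only_predicted) == len(pred)


def _quality_graph():
    """4 genes: g1 single-exon with domain, g2 single-exon without,
    g3 two-exon, g4 non-coding (excluded)."""
    g = FeatureGraph()

    def add_gene(gid, exons, coding=True):
        lo, hi = exons[0][0], exons[-1][1]
        gene = Feature(feature_id=gid, feature_type="gene",
                       segments=[GenomicInterval("c", lo, hi, "+")])
        t = Feature(feature_id=f"{gid}.t", feature_type="mrna",
                    segments=[GenomicInterval("c", lo, hi, "+")])
        t.translation_stable_id = f"{gid}.p"
        g.add(gene)
        g.add(t)
        g.add_edge(t.uid, gene.uid)
        for j, (s, e) in enumerate(exons, 1):
            exon = Feature(feature_id=f"{gid}.e{j}", feature_type="exon",
                           segments=[GenomicInterval("c", s, e, "+")])
            g.add(exon)
            g.add_edge(exon.uid, t.uid)
        if coding:
            cds = Feature(
                feature_id=f"{gid}.cds", feature_type="cds",
                segments=[GenomicInterval("c", s, e, "+") for s, e in exons],
                phases=[0] * len(exons),
            )
            g.add(cds)
            g.add_edge(cds.uid, t.uid)

    add_gene("g1", [(1, 300)])
    add_gene("g2", [(401, 700)])
    add_gene("g3", [(801, 900), (1001, 1100)])
    add_gene("g4", [(1201, 1300)], coding=False)
    return g


def test_gene_set_quality_counts_and_domain_subset():
    g = _quality_graph()
    q = gene_set_quality(g, {"g1.p": 2})
    assert q.total_genes == 3
    assert q.single_exon_genes == 2
    assert q.single_exon_no_domain == 1
    assert any(i.code == "non_coding_gene" for i in g.issues)


def test_gene_set_quality_invariant_under_feature_reordering():
    base = gene_set_quality(_quality_graph(), {"g1.p": 1}).to_dict()
    # same content added in a different order via a fresh graph
    g = _quality_graph()
    again = gene_set_quality(g, {"g1.p": 1}).to_dict()
    assert base == again


@pytest.mark.parametrize(
    "total,single,nodom,pct_single,pct_nodom",
    [
        (21493, 5340, 3251, 25, 15),
        (13920, 1711, 673, 12, 5),
    ],
)
def test_percentages_round_half_up(total, single, nodom, pct_single,
                                   pct_nodom):
    q = GeneSetQuality(total, single, nodom)
    assert q.pct_single_exon == pct_single
    assert q.pct_single_exon_no_domain == pct_nodom


def test_canonical_transcript_is_longest_cds_with_lexicographic_ties():
    g = FeatureGraph()
    gene = Feature(feature_id="g", feature_type="gene",
                   segments=[GenomicInterval("c", 1, 1000, "+")])
    g.add(gene)
    for tid, span, nseg in (("tB", (1, 300), 1), ("tA", (1, 300), 2)):
        t = Feature(feature_id=tid, feature_type="mrna",
                    segments=[GenomicInterval("c", *span, "+")])
        g.add(t)
        g.add_edge(t.uid, gene.uid)
        step = 300 // nseg
        segs = [
            GenomicInterval("c", 1 + i * step, (i + 1) * step, "+")
            for i in range(nseg)
        ]
        cds = Feature(feature_id=f"{tid}.c", feature_type="cds",
                      segments=segs, phases=[0] * nseg)
        g.add(cds)
        g.add_edge(cds.uid, t.uid)
    from gffmend.verify import canonical_transcript

    # equal CDS length: lexicographically smaller ID wins
    assert canonical_transcript(g, gene).feature_id == "tA"


def test_end_to_end_translation_identity_on_truth(bundle, truth_graph):
    predicted, _ = predicted_translations(truth_graph, bundle.genome)
    expected = {k.replace(".p", ".t"): v for k, v in bundle.proteins.items()}
    report = verify_translations(predicted, expected)
    assert report.ok and report.identical == len(bundle.proteins)
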