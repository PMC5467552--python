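import pytest

from gffmend.parser import parse_gff
from gffmend.rules import RuleError, apply_all, apply_rule, parse_rule

SIX_RULES = [
    "[MULTILINE CDS]",
    "[LACKS_ID CDS make]",
    "[EXPECTATION cds hasSister exon force]",
    "[EXPECTATION cds hasParent mrna force]",
    "[EXPECTATION exon hasParent transcript|mrna|mirna|trna|ncrna|rrna force]",
    "[EXPECTATION mrna hasParent gene force]",
]


@pytest.mark.parametrize(
    "text,kind,subject,relation,n_objects,action",
    [
        ("[MULTILINE CDS]", "MULTILINE", "cds", None, 0, None),
        ("[LACKS_ID CDS make]", "LACKS_ID", "cds", None, 0, "make"),
        (
            "[EXPECTATION exon hasParent transcript|mrna|mirna|trna|ncrna|rrna force]",
            "EXPECTATION", "exon", "hasParent", 6, "force",
        ),
        (
            "[EXPECTATION cds hasSister exon force]",
            "EXPECTATION", "cds", "hasSister", 1, "force",
        ),
    ],
)
def test_parse_rule_grammar(text, kind, subject, relation, n_objects, action):
    rule = parse_rule(text)
    assert rule.kind == kind
    assert rule.subject_type == subject
    assert rule.relation == relation
    assert len(rule.object_types) == n_objects
    assert rule.action == action


@pytest.mark.parametrize(
    "text",
    [
        "MULTILINE CDS",              # unbracketed
        "[FROBNICATE CDS]",           # unknown kind
        "[LACKS_ID CDS force]",       # LACKS_ID only supports make
        "[EXPECTATION cds hasCousin exon force]",
        "[EXPECTATION cds hasParent exon maybe]",
        "[]",
    ],
)
def test_malformed_rules_rejected(text):
    with pytest.raises(RuleError):
        parse_rule(text)


def test_multiline_merges_same_id_segments_sorted_with_phases():
    text = (
        "chr1\ts\tCDS\t121\t150\t.\t+\t0\tID=c1\n"
        "chr1\ts\tCDS\t1\t30\t.\t+\t0\tID=c1\n"
        "chr1\ts\tCDS\t61\t90\t.\t+\t0\tID=c1\n"
    )
    g = parse_gff(text.splitlines(True))
    apply_rule(g, parse_rule("[MULTILINE CDS]"))
    (cds,) = g.by_id("c1")
    assert [(s.start, s.end) for s in cds.segments] == [
        (1, 30), (61, 90), (121, 150)
    ]
    assert cds.phases == [0, 0, 0]
    assert all(
        i.action_taken == "repaired"
        for i in g.issues if i.code == "repeated_id"
    )


def test_multiline_refuses_cross_scaffold_groups():
    text = (
        "chr1\ts\tCDS\t1\t30\t.\t+\t0\tID=c2\n"
        "chr2\ts\tCDS\t1\t30\t.\t+\t0\tID=c2\n"
    )
    g = parse_gff(text.splitlines(True))
    apply_rule(g, parse_rule("[MULTILINE CDS]"))
    assert len(g.by_id("c2")) == 2
    assert any(i.code == "unmergeable" for i in g.issues)


def test_multiline_is_opt_in_per_type():
    text = (
        "chr1\ts\texon\t1\t30\t.\t+\t.\tID=e1\n"
        "chr1\ts\texon\t61\t90\t.\t+\t.\tID=e1\n"
    )
    g = parse_gff(text.splitlines(True))
    apply_rule(g, parse_rule("[MULTILINE CDS]"))  # wrong type: no effect
    assert len(g.by_id("e1")) == 2
    assert any(
        i.code == "repeated_id" and i.action_taken == "none"
        for i in g.issues
    )


def test_lacks_id_numbers_siblings_in_transcription_direction():
    text = (
        "chr1\ts\tmRNA\t1\t200\t.\t-\t.\tID=t1\n"
        "chr1\ts\tCDS\t1\t50\t.\t-\t2\tParent=t1\n"
        "chr1\ts\tCDS\t101\t200\t.\t-\t0\tParent=t1\n"
    )
    g = parse_gff(text.splitlines(True))
    apply_rule(g, parse_rule("[LACKS_ID CDS make]"))
    # minus strand: the downstream-most (highest start) segment is first
    assert g.by_id("t1.cds.1")[0].start == 101
    assert g.by_id("t1.cds.2")[0].start == 1


def test_lacks_id_parentless_uses_type_scaffold_start():
    g = parse_gff(["chr2\ts\texon\t500\t600\t.\t+\t.\tNote=x\n"])
    apply_rule(g, parse_rule("[LACKS_ID exon make]"))
    assert len(g.by_id("exon.chr2.500")) == 1


def test_lacks_id_leaves_existing_ids_untouched():
    g = parse_gff(["chr1\ts\tCDS\t1\t30\t.\t+\t0\tID=have\n"])
    apply_rule(g, parse_rule("[LACKS_ID CDS make]"))
    assert g.by_id("have") and not g.provenance


def test_expectation_force_creates_exons_at_uncovered_cds_segments():
    text = (
        "chr1\ts\tmRNA\t1\t150\t.\t+\t.\tID=t1\n"
        "chr1\ts\tCDS\t1\t30\t.\t+\t0\tID=c1;Parent=t1\n"
        "chr1\ts\tCDS\t61\t90\t.\t+\t0\tID=c1;Parent=t1\n"
    )
    g = parse_gff(text.splitlines(True))
    apply_all(g, [parse_rule("[MULTILINE CDS]"),
                  parse_rule("[EXPECTATION cds hasSister exon force]")])
    mrna = g.by_id("t1")[0]
    exons = [c for c in g.children_of(mrna) if c.feature_type == "exon"]
    assert sorted((e.start, e.end) for e in exons) == [(1, 30), (61, 90)]


def test_expectation_force_synthesizes_gene_spanning_transcript():
    g = parse_gff(["chr1\ts\tmRNA\t11\t400\t.\t+\t.\tID=t1\n"])
    apply_rule(g, parse_rule("[EXPECTATION mrna hasParent gene force]"))
    (gene,) = g.by_id("t1.gene")
    assert (gene.start, gene.end, gene.feature_type) == (11, 400, "gene")
    mrna = g.by_id("t1")[0]
    assert g.parents_of(mrna) == [gene]


def test_expectation_satisfied_by_any_listed_alternative():
    text = (
        "chr1\ts\ttRNA\t1\t90\t.\t+\t.\tID=t1\n"
        "chr1\ts\texon\t1\t90\t.\t+\t.\tID=e1;Parent=t1\n"
    )
    g = parse_gff(text.splitlines(True))
    rule = parse_rule(
        "[EXPECTATION exon hasParent transcript|mrna|mirna|trna|ncrna|rrna force]"
    )
    apply_rule(g, rule)
    assert not g.provenance  # trna parent already satisfies the rule


def test_expectation_warn_logs_without_modifying():
    g = parse_gff(["chr1\ts\tmRNA\t1\t90\t.\t+\t.\tID=t1\n"])
    apply_rule(g, parse_rule("[EXPECTATION mrna hasParent gene warn]"))
    assert len(g) == 1
    assert any(i.code == "expectation_failed" for i in g.issues)


def test_expectation_ignore_does_nothing():
    g = parse_gff(["chr1\ts\tmRNA\t1\t90\t.\t+\t.\tID=t1\n"])
    n_issues = len(g.issues)
    apply_rule(g, parse_rule("[EXPECTATION mrna hasParent gene ignore]"))
    assert len(g) == 1 and len(g.issues) == n_issues


def test_gtf_derived_cds_only_file_rebuilt_to_full_topology():
    """CDS-only GTF lines are repaired into gene -> mRNA -> {exon, CDS}."""
    text = (
        'chr1\ts\tCDS\t1\t30\t.\t+\t0\tgene_id "gA"; transcript_id "tA";\n'
        'chr1\ts\tCDS\t61\t90\t.\t+\t0\tgene_id "gA"; transcript_id "tA";\n'
    )
    g = parse_gff(text.splitlines(True))
    apply_all(g, [parse_rule(r) for r in SIX_RULES])
    (mrna,) = g.by_id("tA")
    assert mrna.feature_type == "mrna"
    assert (mrna.start, mrna.end) == (1, 90)
    kids = g.children_of(mrna)
    assert sorted(c.feature_type for c in kids) == ["cds", "cds", "exon", "exon"]
    (gene,) = g.by_id("gA")
    assert g.parents_of(mrna) == [gene]


def test_apply_all_is_idempotent(bundle, default_cfg):
    g = parse_gff(bundle.gff3.splitlines(True))
    rules = default_cfg.rules()
    apply_all(g, rules)
    before = len(g.provenance)
    apply_all(g, rules)
    assert len(g.provenance) == before


def test_rules_never_delete_annotated_bases(bundle, default_cfg):
    from gffmend.simulate import coverage_signature

    g = parse_gff(bundle.gff3.splitlines(True))
    pre = coverage_signature(g)
    apply_all(g, default_cfg.rules())
    post = coverage_signature(g)
    for cls in ("gene", "transcript", "exon", "cds"):
        assert post[cls] == pre[cls]


def test_empty_rule_list_is_identity(bundle):
    g = parse_gff(bundle.gff3.splitlines(True))
    n = len(g)
    apply_all(g, [])
    assert len(g) == n and not g.provenance
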