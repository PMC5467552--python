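"""Declarative repair rules for gene-model graphs.

Rules are written in a bracketed meta-syntax embedded in INI files, e.g.::

    [GFF]
    CONDITION_1 = [MULTILINE CDS]
    CONDITION_2 = [LACKS_ID CDS make]
    CONDITION_3 = [EXPECTATION cds hasSister exon force]
    CONDITION_4 = [EXPECTATION cds hasParent mrna force]
    CONDITION_5 = [EXPECTATION exon hasParent transcript|mrna|mirna|trna|ncrna|rrna force]
    CONDITION_6 = [EXPECTATION mrna hasParent gene force]

Three rule kinds exist:

``MULTILINE <type>``
    merge provisional same-ID features of that type into one multi-segment
    feature.
``LACKS_ID <type> make``
    generate IDs for features of that type that have none.
``EXPECTATION <type> hasParent|hasSister <alt1|alt2|...> force|warn|ignore``
    check a structural relationship; ``force`` synthesises the missing
    feature, ``warn`` only logs, ``ignore`` does nothing.

Rules are applied strictly in declaration order and never delete input
features — repairs only add, merge or re-link. Every modification is
recorded in the graph's provenance list so the import is replayable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import Feature, FeatureGraph, GenomicInterval, ModelError, feature_span

KINDS = ("MULTILINE", "LACKS_ID", "EXPECTATION")
RELATIONS = ("hasparent", "hassister")
ACTIONS = ("force", "make", "warn", "ignore")


class RuleError(ValueError):
    """Malformed rule declaration."""


@dataclass(frozen=True)
class Rule:
    kind: str
    subject_type: str
    relation: Optional[str] = None  # hasParent | hasSister
    object_types: tuple[str, ...] = ()
    action: Optional[str] = None

    def __str__(self) -> str:
        parts = [self.kind, self.subject_type]
        if self.relation:
            parts.append(self.relation)
        if self.object_types:
            parts.append("|".join(self.object_types))
        if self.action:
            parts.append(self.action)
        return "[" + " ".join(parts) + "]"


def parse_rule(text: str) -> Rule:
    """Parse one bracketed rule declaration."""
    m = re.fullmatch(r"\s*\[(.*)\]\s*", text, flags=re.S)
    if not m:
        raise RuleError(f"rule must be bracketed: {text!r}")
    tokens = m.group(1).split()
    if not tokens:
        raise RuleError(f"empty rule: {text!r}")
    kind = tokens[0].upper()
    if kind == "MULTILINE":
        if len(tokens) != 2:
            raise RuleError(f"MULTILINE takes one type token: {text!r}")
        return Rule(kind="MULTILINE", subject_type=tokens[1].lower())
    if kind == "LACKS_ID":
        if len(tokens) != 3:
            raise RuleError(f"LACKS_ID takes type and action: {text!r}")
        action = tokens[2].lower()
        if action != "make":
            raise RuleError(
                f"LACKS_ID supports only the 'make' action, got {action!r}"
            )
        return Rule(kind="LACKS_ID", subject_type=tokens[1].lower(), action=action)
    if kind == "EXPECTATION":
        if len(tokens) != 5:
            raise RuleError(
                f"EXPECTATION takes subject, relation, alternatives, action: "
                f"{text!r}"
            )
        relation = tokens[2]
        if relation.lower() not in RELATIONS:
            raise RuleError(f"unknown relation {relation!r} in {text!r}")
        action = tokens[4].lower()
        if action not in ("force", "warn", "ignore"):
            raise RuleError(f"unknown action {action!r} in {text!r}")
        return Rule(
            kind="EXPECTATION",
            subject_type=tokens[1].lower(),
            relation="hasParent" if relation.lower() == "hasparent" else "hasSister",
            object_types=tuple(t.lower() for t in tokens[3].split("|") if t),
            action=action,
        )
    raise RuleError(f"unknown rule kind {tokens[0]!r} in {text!r}")


# ---------------------------------------------------------------------------
# rule application


def apply_multiline(graph: FeatureGraph, rule: Rule) -> FeatureGraph:
    """Merge same-ID provisional features of the rule's type.

    Segments are pooled and sorted by start with their phases; features on
    mixed scaffolds or strands are left unmerged with an ``unmergeable``
    issue. The matching ``repeated_id`` issues are marked repaired.
    """
    assert rule.kind == "MULTILINE"
    groups: dict[str, list[Feature]] = {}
    for f in graph.features_of_type(rule.subject_type):
        if f.feature_id is not None:
            groups.setdefault(f.feature_id, []).append(f)
    merged_ids = []
    for fid, members in groups.items():
        if len(members) < 2:
            continue
        members.sort(key=lambda f: f.uid)
        if len({m.seq_id for m in members}) > 1 or len(
            {m.strand for m in members}
        ) > 1:
            graph.log(
                "warning", "unmergeable",
                f"same-ID {rule.subject_type} features {fid!r} lie on "
                "different scaffolds or strands; left unmerged",
                feature_ids=(fid,),
            )
            continue
        keeper = members[0]
        seg_phase = []
        for m in members:
            seg_phase.extend(zip(m.segments, m.phases))
        seg_phase.sort(key=lambda sp: sp[0].start)
        keeper.segments = [sp[0] for sp in seg_phase]
        keeper.phases = [sp[1] for sp in seg_phase]
        keeper.origin = sorted(o for m in members for o in m.origin)
        for m in members[1:]:
            for p in list(graph.parents_of(m)):
                try:
                    graph.add_edge(keeper.uid, p.uid)
                except ModelError:
                    pass
            for ref in graph.deferred.get(m.uid, []):
                graph.add_deferred(keeper.uid, ref)
            graph.remove(m.uid)
        merged_ids.append(fid)
        graph.record(
            "merge_multiline",
            rule=str(rule),
            feature=fid,
            segments=[(s.start, s.end) for s in keeper.segments],
        )
    if merged_ids:
        wanted = set(merged_ids)
        for issue in graph.issues:
            if issue.code == "repeated_id" and set(issue.feature_ids) & wanted:
                issue.action_taken = "repaired"
    return graph


def _transcription_sort_key(f: Feature):
    return -f.start if f.strand == "-" else f.start


def apply_lacks_id(graph: FeatureGraph, rule: Rule) -> FeatureGraph:
    """Generate IDs for ID-less features of the rule's type.

    With a parent: ``<parentID>.<type>.<n>`` where n numbers the
    subject-type siblings in transcription direction. Parentless features
    get ``<type>.<seq_id>.<start>``.
    """
    assert rule.kind == "LACKS_ID" and rule.action == "make"
    for f in sorted(graph.features_of_type(rule.subject_type),
                    key=lambda f: f.uid):
        if f.feature_id is not None:
            continue
        parents = graph.parents_of(f)
        parent = next((p for p in parents if p.feature_id), None)
        if parent is not None:
            sibs = [
                c for c in graph.children_of(parent)
                if c.feature_type == f.feature_type
            ]
            sibs.sort(key=lambda c: (_transcription_sort_key(c), c.uid))
            n = sibs.index(f) + 1
            new_id = f"{parent.feature_id}.{f.feature_type}.{n}"
        else:
            new_id = f"{f.feature_type}.{f.seq_id}.{f.start}"
        base, k = new_id, 2
        while graph.by_id(new_id):
            new_id = f"{base}.{k}"
            k += 1
        graph.set_feature_id(f.uid, new_id)
        graph.record(
            "assign_id", rule=str(rule), feature=new_id,
            line=f.origin[0] if f.origin else None,
        )
    return graph


def _has_parent_of(graph: FeatureGraph, f: Feature,
                   types: Sequence[str]) -> bool:
    return any(p.feature_type in types for p in graph.parents_of(f))


def _covered(seg: GenomicInterval, sisters: list[Feature]) -> bool:
    return any(
        s.contains(seg) for sister in sisters for s in sister.segments
    )


def _force_parent(graph: FeatureGraph, rule: Rule,
                  failing: list[Feature]) -> None:
    ptype = rule.object_types[0]
    # group children referring to the same (unresolved) parent ID so that
    # e.g. all CDS lines of one GTF transcript obtain a single parent
    by_ref: dict[str, list[Feature]] = {}
    loners: list[Feature] = []
    for f in failing:
        refs = graph.deferred.get(f.uid, [])
        if refs:
            by_ref.setdefault(refs[0], []).append(f)
        else:
            loners.append(f)
    for ref_id, members in by_ref.items():
        if len({m.seq_id for m in members}) > 1 or len(
            {m.strand for m in members}
        ) > 1:
            graph.log(
                "warning", "unforceable",
                f"children of {ref_id!r} span scaffolds/strands; "
                "cannot synthesize parent",
                feature_ids=(ref_id,),
            )
            continue
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        parent = Feature(
            feature_id=ref_id,
            feature_type=ptype,
            segments=[GenomicInterval(members[0].seq_id, start, end,
                                      members[0].strand)],
            source="gffmend",
            attributes={"ID": [ref_id]},
        )
        graph.add(parent)
        # propagate a gene-level reference if the children agree on one
        gene_ids = {m.get_attr("gene_id") for m in members}
        gene_ids.discard(None)
        if ptype != "gene" and len(gene_ids) == 1:
            gid = gene_ids.pop()
            if gid != ref_id:
                parent.attributes.setdefault("gene_id", [gid])
                graph.add_deferred(parent.uid, gid)
        graph.record(
            "synthesize_parent", rule=str(rule), feature=ref_id,
            children=[m.feature_id or f"uid{m.uid}" for m in members],
        )
    for f in loners:
        if f.feature_id is None:
            graph.log(
                "warning", "unforceable",
                f"cannot synthesize {ptype} parent for ID-less "
                f"{f.feature_type}",
            )
            continue
        pid = f"{f.feature_id}.{ptype}"
        existing = graph.by_id(pid)
        if existing:
            try:
                graph.add_edge(f.uid, existing[0].uid)
            except ModelError:
                graph.log("warning", "cycle_refused",
                          f"attaching {f.feature_id} to {pid} would cycle",
                          feature_ids=(pid,))
            continue
        parent = Feature(
            feature_id=pid,
            feature_type=ptype,
            segments=[feature_span(f)],
            source="gffmend",
            attributes={"ID": [pid]},
        )
        graph.add(parent)
        try:
            graph.add_edge(f.uid, parent.uid)
        except ModelError:  # pragma: no cover
            graph.log("warning", "cycle_refused",
                      f"synthesized parent {pid} refused", feature_ids=(pid,))
            continue
        gid = f.get_attr("gene_id")
        if gid and ptype != "gene" and gid != pid:
            graph.add_deferred(parent.uid, gid)
        graph.record("synthesize_parent", rule=str(rule), feature=pid,
                     children=[f.feature_id])


def _force_sisters(graph: FeatureGraph, rule: Rule, f: Feature,
                   uncovered: list[GenomicInterval]) -> None:
    stype = rule.object_types[0]
    parents = graph.parents_of(f)
    refs = graph.deferred.get(f.uid, [])
    if not parents and not refs:
        graph.log(
            "warning", "unforceable",
            f"cannot create {stype} sister for parentless "
            f"{f.feature_id or f.feature_type}",
            feature_ids=(f.feature_id,) if f.feature_id else (),
        )
        return
    base = f.feature_id or f"{f.feature_type}.{f.seq_id}.{f.start}"
    for n, seg in enumerate(sorted(uncovered, key=lambda s: s.start), 1):
        sid = f"{base}.{stype}.{n}"
        k = 2
        while graph.by_id(sid):
            sid = f"{base}.{stype}.{n}.{k}"
            k += 1
        sister = Feature(
            feature_id=sid,
            feature_type=stype,
            segments=[seg],
            source="gffmend",
            attributes={"ID": [sid]},
        )
        graph.add(sister)
        for p in parents:
            try:
                graph.add_edge(sister.uid, p.uid)
            except ModelError:  # pragma: no cover
                pass
        for ref in refs:
            graph.add_deferred(sister.uid, ref)
        graph.record(
            "synthesize_sister", rule=str(rule), feature=sid,
            subject=f.feature_id, at=(seg.start, seg.end),
        )


def apply_expectation(graph: FeatureGraph, rule: Rule) -> FeatureGraph:
    """Check (and optionally repair) a hasParent/hasSister expectation.

    ``hasSister`` passes when every segment of the subject is contained in
    some segment of a sibling whose type is among the alternatives — for
    CDS/exon this is the biological containment of coding sequence within
    exons.
    """
    assert rule.kind == "EXPECTATION"
    subjects = sorted(graph.features_of_type(rule.subject_type),
                      key=lambda f: f.uid)
    if rule.relation == "hasParent":
        failing = [
            f for f in subjects if not _has_parent_of(graph, f, rule.object_types)
        ]
        if not failing or rule.action == "ignore":
            return graph
        if rule.action == "warn":
            for f in failing:
                graph.log(
                    "warning", "expectation_failed",
                    f"{rule.subject_type} "
                    f"{f.feature_id or f'uid{f.uid}'} lacks a parent of "
                    f"type {'|'.join(rule.object_types)}",
                    feature_ids=(f.feature_id,) if f.feature_id else (),
                )
            return graph
        _force_parent(graph, rule, failing)
        graph.resolve_deferred()
        return graph

    # hasSister
    for f in subjects:
        sisters = [
            s for s in graph.siblings_of(f)
            if s.feature_type in rule.object_types
        ]
        uncovered = [seg for seg in f.segments if not _covered(seg, sisters)]
        if not uncovered or rule.action == "ignore":
            continue
        if rule.action == "warn":
            graph.log(
                "warning", "expectation_failed",
                f"{rule.subject_type} {f.feature_id or f'uid{f.uid}'} has "
                f"{len(uncovered)} segment(s) uncovered by "
                f"{'|'.join(rule.object_types)} sisters",
                feature_ids=(f.feature_id,) if f.feature_id else (),
            )
            continue
        _force_sisters(graph, rule, f, uncovered)
    return graph


def apply_rule(graph: FeatureGraph, rule: Rule) -> FeatureGraph:
    if rule.kind == "MULTILINE":
        return apply_multiline(graph, rule)
    if rule.kind == "LACKS_ID":
        return apply_lacks_id(graph, rule)
    return apply_expectation(graph, rule)


def apply_all(graph: FeatureGraph, rules: Sequence[Rule]) -> FeatureGraph:
    """Apply rules in declaration order, re-resolving deferred parent
    references after each one. Idempotent: a second pass with the same
    rules performs no further modifications."""
    graph.resolve_deferred()
    for rule in rules:
        apply_rule(graph, rule)
        graph.resolve_deferred()
    return graph
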