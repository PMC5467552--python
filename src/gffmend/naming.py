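"""Stable-ID, name and description assignment.

IDs and names rarely live in the same attribute across annotation
providers, so they are pulled out with small extraction patterns written
in a match-and-replace mini-grammar embedded in INI values::

    [GENE_STABLE_IDS]        GFF = [gene->id/(.+)/]
    [GENE_NAMES]             GFF = [gene->symbol/(.+)/]
    [GENE_DESCRIPTIONS]      GFF = [1 DAUGHTER->product/(.+)/]
    [TRANSLATION_STABLE_IDS] GFF = [SELF->ID/(.+)//-RA/-PA/]

A pattern reads ``[selector->attribute/capture-regex/]`` with an optional
leading ordinal (for DAUGHTER lists) and an optional trailing
``/match/replacement/`` pair applied to the captured text. The selector is
``SELF``, ``PARENT``, ``DAUGHTER`` or a feature-type token meaning the
nearest ancestor-or-self of that type.

Names and descriptions can additionally be joined in from protein FASTA
headers or simple two-column text files via :class:`LookupTable`, keyed on
the extracted stable ID after the same match/replace normalisation, so
gene/transcript/protein ID variants can be matched across files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .model import Feature, FeatureGraph, TRANSCRIPT_TYPES


class PatternError(ValueError):
    """Malformed extraction pattern."""


_SLASH_SPLIT = re.compile(r"(?<!\\)/")


def _unescape(text: str) -> str:
    return text.replace("\\/", "/")


@dataclass(frozen=True)
class ExtractionPattern:
    selector: str  # SELF | PARENT | DAUGHTER | a feature-type token
    attribute: str
    capture: str
    ordinal: Optional[int] = None
    replace: Optional[tuple[str, str]] = None

    def compiled(self) -> re.Pattern:
        return re.compile(self.capture)


def parse_pattern(text: str) -> ExtractionPattern:
    """Parse ``[selector->attribute/capture/]`` with optional ordinal and
    optional ``/match/replacement/`` suffix."""
    stripped = text.strip()
    if not (stripped.startswith("[") and stripped.endswith("]")):
        raise PatternError(f"pattern must be bracketed: {text!r}")
    inner = stripped[1:-1].strip()
    m = re.match(r"(?:(\d+)\s+)?([^\s]+?)->(.*)$", inner, flags=re.S)
    if not m:
        raise PatternError(f"pattern lacks 'selector->attribute': {text!r}")
    ordinal = int(m.group(1)) if m.group(1) else None
    selector = m.group(2)
    rest = m.group(3)
    parts = _SLASH_SPLIT.split(rest)
    # rest = attribute/capture/            (3 parts, trailing empty)
    #      = attribute/capture//match/replacement/   (6 parts)
    if len(parts) == 3 and parts[2] == "":
        attribute, capture = parts[0], parts[1]
        replace = None
    elif len(parts) == 6 and parts[2] == "" and parts[5] == "":
        attribute, capture = parts[0], parts[1]
        replace = (_unescape(parts[3]), _unescape(parts[4]))
    else:
        raise PatternError(f"unbalanced '/' delimiters in {text!r}")
    if not attribute:
        raise PatternError(f"empty attribute in {text!r}")
    capture = _unescape(capture)
    try:
        re.compile(capture)
    except re.error as exc:
        raise PatternError(f"bad capture regex {capture!r}: {exc}") from exc
    sel_upper = selector.upper()
    if sel_upper in ("SELF", "PARENT", "DAUGHTER"):
        selector = sel_upper
    else:
        selector = selector.lower()
    if ordinal is not None and selector != "DAUGHTER":
        raise PatternError(
            f"ordinal only applies to DAUGHTER selectors: {text!r}"
        )
    return ExtractionPattern(
        selector=selector,
        attribute=attribute,
        capture=capture,
        ordinal=ordinal,
        replace=replace,
    )


def _resolve_selector(
    f: Feature, p: ExtractionPattern, graph: FeatureGraph
) -> Optional[Feature]:
    if p.selector == "SELF":
        return f
    if p.selector == "PARENT":
        parents = graph.parents_of(f)
        return parents[0] if parents else None
    if p.selector == "DAUGHTER":
        kids = sorted(
            graph.children_of(f),
            key=lambda c: (c.start, c.feature_id or "", c.uid),
        )
        idx = (p.ordinal or 1) - 1
        return kids[idx] if 0 <= idx < len(kids) else None
    # feature-type token: nearest ancestor-or-self of that type (BFS upward)
    level = [f]
    seen: set[int] = set()
    while level:
        hits = [x for x in level if x.feature_type == p.selector]
        if hits:
            if len(hits) > 1:
                graph.log(
                    "warning", "ambiguous_ancestor",
                    f"multiple {p.selector} ancestors at equal distance "
                    f"from {f.feature_id}; using first",
                    feature_ids=(f.feature_id,) if f.feature_id else (),
                )
            return hits[0]
        nxt: list[Feature] = []
        for x in level:
            for par in graph.parents_of(x):
                if par.uid not in seen:
                    seen.add(par.uid)
                    nxt.append(par)
        level = nxt
    return None


def extract_value(
    f: Feature, p: ExtractionPattern, graph: FeatureGraph
) -> Optional[str]:
    """Apply one extraction pattern to a feature; None signals a miss."""
    target = _resolve_selector(f, p, graph)
    if target is None:
        return None
    value = target.get_attr(p.attribute)
    if value is None and p.attribute.lower() == "id":
        value = target.feature_id
    if value is None:
        return None
    m = p.compiled().search(value)
    if not m:
        return None
    out = m.group(1) if m.groups() else m.group(0)
    if p.replace is not None:
        out = out.replace(p.replace[0], p.replace[1])
    return out if out else None


def first_match(
    f: Feature, patterns: list[ExtractionPattern], graph: FeatureGraph
) -> Optional[str]:
    """First pattern yielding a value wins."""
    for p in patterns:
        value = extract_value(f, p, graph)
        if value is not None:
            return value
    return None


class LookupTable:
    """Key → value mapping built from FASTA headers or a text table.

    Keys are normalised with ``match/replace`` pairs before joining so that
    e.g. protein IDs ``g1-PA`` can key descriptions onto genes ``g1``.
    Duplicate keys after normalisation are an ``ambiguous_lookup`` issue;
    the first entry wins.
    """

    def __init__(
        self,
        entries: dict[str, str],
        ambiguous: Optional[list[str]] = None,
    ) -> None:
        self.entries = entries
        self.ambiguous = ambiguous or []

    @staticmethod
    def _normalise(key: str, replace: Optional[tuple[str, str]]) -> str:
        if replace is not None:
            key = key.replace(replace[0], replace[1])
        return key

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[str, str]],
        replace: Optional[tuple[str, str]] = None,
    ) -> "LookupTable":
        entries: dict[str, str] = {}
        ambiguous: list[str] = []
        for key, value in pairs:
            key = cls._normalise(key, replace)
            if key in entries:
                ambiguous.append(key)
                continue
            entries[key] = value
        return cls(entries, ambiguous)

    @classmethod
    def from_fasta(
        cls, path: str, replace: Optional[tuple[str, str]] = None
    ) -> "LookupTable":
        """Key on FASTA record IDs, value = the rest of the header line."""
        from Bio import SeqIO

        pairs = []
        for rec in SeqIO.parse(path, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            pairs.append((rec.id, desc))
        return cls.from_pairs(pairs, replace)

    @classmethod
    def from_table(
        cls,
        path: str,
        key_column: int = 0,
        value_column: int = 1,
        sep: str = "\t",
        replace: Optional[tuple[str, str]] = None,
    ) -> "LookupTable":
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split(sep)
                if len(cols) <= max(key_column, value_column):
                    continue
                pairs.append((cols[key_column], cols[value_column]))
        return cls.from_pairs(pairs, replace)

    def get(self, key: str) -> Optional[str]:
        return self.entries.get(key)


# section name -> (target kind, attribute set on the feature)
_SECTIONS = {
    "GENE_STABLE_IDS": ("gene", "stable_id"),
    "GENE_NAMES": ("gene", "display_name"),
    "GENE_DESCRIPTIONS": ("gene", "description"),
    "TRANSCRIPT_STABLE_IDS": ("transcript", "stable_id"),
    "TRANSLATION_STABLE_IDS": ("transcript", "translation_stable_id"),
}


def _dedupe(graph: FeatureGraph, feats: list[Feature], attr: str) -> None:
    used: dict[str, int] = {}
    for f in feats:
        sid = getattr(f, attr)
        if sid is None:
            continue
        if sid not in used:
            used[sid] = 1
            continue
        used[sid] += 1
        new = f"{sid}_{used[sid]}"
        while new in used:
            used[sid] += 1
            new = f"{sid}_{used[sid]}"
        used[new] = 1
        graph.log(
            "warning", "duplicate_stable_id",
            f"stable ID {sid!r} assigned to multiple features; "
            f"renamed to {new!r}",
            feature_ids=(f.feature_id,) if f.feature_id else (),
        )
        setattr(f, attr, new)


def assign_names(
    graph: FeatureGraph,
    cfg,
    lookups: Optional[dict[str, LookupTable]] = None,
) -> FeatureGraph:
    """Assign stable IDs, display names and descriptions from config patterns.

    ``cfg`` must provide ``patterns(section)`` returning the ordered
    fallback list of :class:`ExtractionPattern` for each of the five
    naming sections. ``lookups`` optionally maps ``GENE_NAMES`` /
    ``GENE_DESCRIPTIONS`` to tables keyed on normalised gene stable IDs;
    lookup values fill in where no pattern matched.
    """
    lookups = lookups or {}
    genes = sorted(graph.features_of_type("gene"), key=lambda f: f.uid)
    transcripts = sorted(
        (f for f in graph if f.feature_type in TRANSCRIPT_TYPES),
        key=lambda f: f.uid,
    )
    for section, (kind, attr) in _SECTIONS.items():
        patterns = cfg.patterns(section)
        if not patterns:
            continue
        targets = genes if kind == "gene" else transcripts
        for f in targets:
            value = first_match(f, patterns, graph)
            if value is not None:
                setattr(f, attr, value)
                graph.record(
                    "assign_name", section=section,
                    feature=f.feature_id, value=value,
                )
    for section, attr in (
        ("GENE_NAMES", "display_name"),
        ("GENE_DESCRIPTIONS", "description"),
    ):
        table = lookups.get(section)
        if table is None:
            continue
        for issue_key in table.ambiguous:
            graph.log(
                "warning", "ambiguous_lookup",
                f"duplicate lookup key {issue_key!r} in {section} table",
            )
        for g in genes:
            if getattr(g, attr) is None and g.stable_id:
                value = table.get(g.stable_id)
                if value is not None:
                    setattr(g, attr, value)
                    graph.record(
                        "assign_name", section=section + ":lookup",
                        feature=g.feature_id, value=value,
                    )
    had_patterns = {
        "gene": bool(cfg.patterns("GENE_STABLE_IDS")),
        "transcript": bool(cfg.patterns("TRANSCRIPT_STABLE_IDS")),
    }
    for kind, feats in (("gene", genes), ("transcript", transcripts)):
        for f in feats:
            if f.stable_id is not None:
                continue
            if had_patterns[kind]:
                graph.log(
                    "warning", "unnamed",
                    f"no stable ID derivable for {f.feature_type} "
                    f"{f.feature_id or f'uid{f.uid}'}",
                    feature_ids=(f.feature_id,) if f.feature_id else (),
                )
            # fall back to the graph feature ID so downstream stages
            # still have a usable identifier
            if f.feature_id is not None:
                f.stable_id = f.feature_id
    _dedupe(graph, genes, "stable_id")
    _dedupe(graph, transcripts, "stable_id")
    _dedupe(graph, transcripts, "translation_stable_id")
    return graph
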