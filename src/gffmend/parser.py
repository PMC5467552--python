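"""Tolerant line-by-line GFF3/GTF reader.

The reader never rejects a file: every deviation from well-formed GFF3 is
recorded as an :class:`~gffmend.model.Issue` and the offending line is
either carried as a provisional feature or quarantined. Repairs (merging
multiline features, synthesising missing parents, ...) are deliberately
*not* performed here — they are opt-in rule-engine actions, so the parse
step stays a faithful record of the input.

Dialect notes
-------------
* GTF-style attribute columns (``key "value";`` pairs) are detected per
  line and re-parsed; ``transcript_id``/``gene_id`` become deferred parent
  references, since GTF does not model parent–child feature links.
* A trailing ``##FASTA`` section is accepted and exposed on the graph as an
  embedded sequence store.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

from .model import (
    Feature,
    FeatureGraph,
    GenomicInterval,
    ModelError,
    TRANSCRIPT_TYPES,
)

_PCT_DECODE = [
    ("%09", "\t"),
    ("%0A", "\n"),
    ("%3B", ";"),
    ("%3D", "="),
    ("%2C", ","),
]

_GTF_PAIR = re.compile(r'^\s*(\S+)\s+"([^"]*)"\s*$')


def _decode(value: str) -> str:
    for code, char in _PCT_DECODE:
        value = value.replace(code, char).replace(code.lower(), char)
    return value.replace("%25", "%")


def parse_attributes(
    column9: str,
    graph: Optional[FeatureGraph] = None,
    line_no: Optional[int] = None,
) -> dict[str, list[str]]:
    """Parse a GFF3 column-9 string into an ordered key → values multimap.

    Comma-separated values are split into lists and the GFF3 reserved
    percent-escapes decoded. Tokens lacking ``=`` are collected under the
    ``_bare`` key with a ``bare_attribute`` issue. An empty column (``.`` or
    ``""``) yields an empty map.
    """
    attrs: dict[str, list[str]] = {}
    column9 = column9.strip()
    if column9 in ("", "."):
        return attrs
    for token in column9.split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" not in token:
            attrs.setdefault("_bare", []).append(_decode(token))
            if graph is not None:
                graph.log(
                    "warning",
                    "bare_attribute",
                    f"attribute token without '=': {token!r}"
                    + (f" (line {line_no})" if line_no else ""),
                )
            continue
        key, _, raw = token.partition("=")
        values = [_decode(v) for v in raw.split(",")] if raw else [""]
        attrs.setdefault(key.strip(), []).extend(
            v.strip() for v in values
        )
    return attrs


def looks_like_gtf(column9: str) -> bool:
    """Heuristic GTF detection: ``key "value";`` pairs and no ``=``."""
    column9 = column9.strip()
    if not column9 or "=" in column9:
        return False
    tokens = [t for t in column9.split(";") if t.strip()]
    return bool(tokens) and all(_GTF_PAIR.match(t) for t in tokens)


def parse_gtf_attributes(column9: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for token in column9.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        m = _GTF_PAIR.match(token)
        if m:
            attrs.setdefault(m.group(1), []).append(m.group(2))
        else:
            attrs.setdefault("_bare", []).append(token)
    return attrs


def _open_source(source: Union[str, IO, Iterable[str]]) -> Iterable[str]:
    if isinstance(source, str):
        if source.endswith(".gz"):
            return io.TextIOWrapper(gzip.open(source, "rb"), encoding="utf-8")
        return open(source, "r", encoding="utf-8", errors="replace")
    return source


def parse_gff(source: Union[str, IO, Iterable[str]], cfg=None) -> FeatureGraph:
    """Read a GFF3/GTF-like stream into a :class:`FeatureGraph`.

    Every input line before any ``##FASTA`` directive becomes either one
    provisional feature or one quarantined line; repeated IDs of the same
    type are flagged as multiline candidates but never merged here.
    """
    graph = FeatureGraph()
    lines = _open_source(source)
    pending_parents: list[tuple[int, str]] = []  # (uid, parent_id)
    seen_ids: dict[tuple[str, str], int] = {}  # (id, type) -> count
    id_types: dict[str, set[str]] = {}
    gtf_logged = False
    in_fasta = False
    fasta_name: Optional[str] = None
    fasta_parts: list[str] = []

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if in_fasta:
            if line.startswith(">"):
                if fasta_name is not None:
                    graph.sequences[fasta_name] = "".join(fasta_parts)
                fasta_name = line[1:].split()[0] if len(line) > 1 else ""
                fasta_parts = []
            else:
                fasta_parts.append(line.strip())
            continue
        if line.startswith("#"):
            if line.upper().startswith("##FASTA"):
                in_fasta = True
            continue
        if not line.strip():
            continue

        cols = line.split("\t")
        if len(cols) < 8:
            graph.quarantined.append((line_no, "bad_columns", line))
            graph.log(
                "error", "bad_columns",
                f"line {line_no}: expected 8–9 tab-separated columns, "
                f"got {len(cols)}",
            )
            continue
        seq_id, src, ftype, start_s, end_s, score_s, strand, phase_s = cols[:8]
        col9 = cols[8] if len(cols) > 8 else ""

        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            graph.quarantined.append((line_no, "bad_coords", line))
            graph.log(
                "error", "bad_coords",
                f"line {line_no}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}",
            )
            continue
        if not seq_id or start < 1 or start > end:
            graph.quarantined.append((line_no, "bad_coords", line))
            graph.log(
                "error", "bad_coords",
                f"line {line_no}: invalid coordinates {start}-{end}",
            )
            continue
        if strand not in ("+", "-", "."):
            graph.quarantined.append((line_no, "bad_strand", line))
            graph.log(
                "error", "bad_strand",
                f"line {line_no}: invalid strand {strand!r}",
            )
            continue
        type_lower = ftype.lower()
        if strand == "." and (
            type_lower in TRANSCRIPT_TYPES or type_lower == "cds"
        ):
            graph.quarantined.append((line_no, "bad_strand", line))
            graph.log(
                "error", "bad_strand",
                f"line {line_no}: strand '.' not permitted on "
                f"{ftype} features",
            )
            continue

        gtf_mode = looks_like_gtf(col9)
        if gtf_mode:
            attrs = parse_gtf_attributes(col9)
            if not gtf_logged:
                graph.log(
                    "info", "gtf_dialect",
                    "GTF-style attribute column detected; gene_id/"
                    "transcript_id mapped to provisional parent relations",
                )
                gtf_logged = True
        else:
            attrs = parse_attributes(col9, graph, line_no)

        phase: Optional[int] = None
        if phase_s in ("0", "1", "2"):
            phase = int(phase_s)
        elif phase_s not in (".", ""):
            graph.log(
                "warning", "bad_phase",
                f"line {line_no}: unparseable phase {phase_s!r}, ignored",
            )

        score: Optional[float] = None
        if score_s not in (".", ""):
            try:
                score = float(score_s)
            except ValueError:
                graph.log(
                    "warning", "bad_score",
                    f"line {line_no}: unparseable score {score_s!r}",
                )

        feature_id: Optional[str] = None
        parent_ids: list[str] = []
        if gtf_mode:
            tid = attrs.get("transcript_id", [None])[0]
            gid = attrs.get("gene_id", [None])[0]
            if type_lower in TRANSCRIPT_TYPES:
                feature_id = tid
                if gid:
                    parent_ids = [gid]
            elif type_lower == "gene":
                feature_id = gid
            else:
                if tid:
                    parent_ids = [tid]
        else:
            for k, vals in attrs.items():
                if k.lower() == "id" and vals:
                    feature_id = vals[0]
                    break
            for k, vals in attrs.items():
                if k.lower() == "parent":
                    parent_ids.extend(v for v in vals if v)

        try:
            feat = Feature(
                feature_id=feature_id,
                feature_type=type_lower,
                type_as_read=ftype,
                source=src,
                segments=[GenomicInterval(seq_id, start, end, strand)],
                phases=[phase],
                score=score,
                attributes=attrs,
                origin=[line_no],
            )
        except ModelError as exc:  # pragma: no cover - guarded above
            graph.quarantined.append((line_no, "bad_feature", line))
            graph.log("error", "bad_feature", f"line {line_no}: {exc}")
            continue

        if feature_id is not None:
            key = (feature_id, type_lower)
            seen_ids[key] = seen_ids.get(key, 0) + 1
            if seen_ids[key] == 2:
                graph.log(
                    "warning", "repeated_id",
                    f"ID {feature_id!r} used by multiple {type_lower} "
                    "lines: candidate multiline feature",
                    feature_ids=(feature_id,),
                )
            types = id_types.setdefault(feature_id, set())
            if types and type_lower not in types:
                graph.log(
                    "warning", "id_collision",
                    f"ID {feature_id!r} reused across feature types "
                    f"{sorted(types | {type_lower})}",
                    feature_ids=(feature_id,),
                )
            types.add(type_lower)

        uid = graph.add(feat)
        for pid in parent_ids:
            pending_parents.append((uid, pid))

    if in_fasta and fasta_name is not None:
        graph.sequences[fasta_name] = "".join(fasta_parts)
    if hasattr(lines, "close") and not isinstance(source, (list, tuple)):
        try:
            lines.close()
        except Exception:
            pass

    # second pass: resolve Parent links (forward references allowed)
    for uid, pid in pending_parents:
        targets = graph.by_id(pid)
        if targets:
            try:
                graph.add_edge(uid, graph._pick_parent(uid, [t.uid for t in targets]))
            except ModelError:
                graph.log(
                    "warning", "cycle_refused",
                    f"Parent link to {pid!r} would create a cycle",
                    feature_ids=(pid,),
                )
        else:
            child = graph.get(uid)
            graph.log(
                "warning", "orphan",
                f"Parent {pid!r} of "
                f"{child.feature_id or child.feature_type} not found; "
                "edge deferred",
                feature_ids=(pid,),
            )
            graph.add_deferred(uid, pid)
    return graph


@dataclass
class TypeSummary:
    feature_count: int = 0
    attr_feature_counts: dict[str, int] = field(default_factory=dict)
    attr_value_counts: dict[str, int] = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        """Attribute keys not carried by every feature of this type."""
        return sorted(
            k for k, n in self.attr_feature_counts.items()
            if n != self.feature_count
        )


@dataclass
class AttributeSummary:
    """Per-feature-type attribute occurrence counts.

    Useful before import for spotting which attribute fields may hold IDs
    or descriptions, and whether count discrepancies suggest the file
    needs repair.
    """

    per_type: dict[str, TypeSummary] = field(default_factory=dict)

    def to_tsv(self) -> str:
        rows = ["feature_type\tfeatures\tattribute\tfeatures_with\tvalues\tflag"]
        for ftype in sorted(self.per_type):
            ts = self.per_type[ftype]
            if not ts.attr_feature_counts:
                rows.append(f"{ftype}\t{ts.feature_count}\t-\t0\t0\t")
            for key in sorted(ts.attr_feature_counts):
                flag = "DISCREPANT" if key in ts.flagged else ""
                rows.append(
                    f"{ftype}\t{ts.feature_count}\t{key}\t"
                    f"{ts.attr_feature_counts[key]}\t"
                    f"{ts.attr_value_counts[key]}\t{flag}"
                )
        return "\n".join(rows) + "\n"


def summarize_attributes(graph: FeatureGraph) -> AttributeSummary:
    """Count, per feature type, how many features carry each attribute key.

    Keys whose carrying-feature count differs from the type's feature count
    are flagged as discrepancies; total value counts (multi-valued keys)
    are reported separately.
    """
    summary = AttributeSummary()
    for f in graph:
        ts = summary.per_type.setdefault(f.feature_type, TypeSummary())
        ts.feature_count += 1
        for key, vals in f.attributes.items():
            ts.attr_feature_counts[key] = ts.attr_feature_counts.get(key, 0) + 1
            ts.attr_value_counts[key] = (
                ts.attr_value_counts.get(key, 0) + len(vals)
            )
    return summary
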