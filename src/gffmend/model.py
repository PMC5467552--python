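"""Shared gene-model data structures.

Coordinates are 1-based and closed throughout (the GFF3 and EMBL flat-file
convention); any conversion to 0-based half-open intervals happens only
inside exporters. Feature types are normalised to lower case for matching,
with the original casing retained for output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

VALID_STRANDS = ("+", "-", ".")

#: feature types treated as transcripts for strand checks, naming and CDS assembly
TRANSCRIPT_TYPES = frozenset(
    {"mrna", "transcript", "mirna", "trna", "ncrna", "rrna"}
)


class ModelError(ValueError):
    """Raised when a structural invariant of the gene model is violated."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based closed interval on a scaffold."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ModelError("interval requires a non-empty seq_id")
        if not (1 <= self.start <= self.end):
            raise ModelError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length of a 1-based closed interval (end - start + 1)."""
    return iv.length


@dataclass
class Issue:
    """One recorded deviation from expectations, and what was done about it."""

    severity: str  # info | warning | error
    code: str
    message: str
    feature_ids: tuple[str, ...] = ()
    action_taken: str = "none"  # none | repaired | ignored


@dataclass
class Feature:
    """One annotation feature, possibly spanning several GFF lines (segments).

    ``segments`` and ``phases`` run in parallel; multi-segment features arise
    only from multiline records (one biological feature written as several
    lines sharing an ID). All segments must share seq_id and strand.
    """

    feature_id: Optional[str]
    feature_type: str
    segments: list[GenomicInterval]
    phases: list[Optional[int]] = field(default_factory=list)
    type_as_read: str = ""
    source: str = "."
    score: Optional[float] = None
    attributes: dict[str, list[str]] = field(default_factory=dict)
    origin: list[int] = field(default_factory=list)
    # assigned by the naming stage
    stable_id: Optional[str] = None
    display_name: Optional[str] = None
    description: Optional[str] = None
    translation_stable_id: Optional[str] = None
    uid: int = -1  # set when added to a FeatureGraph

    def __post_init__(self) -> None:
        if not self.segments:
            raise ModelError("feature requires at least one segment")
        if not self.type_as_read:
            self.type_as_read = self.feature_type
        self.feature_type = self.feature_type.lower()
        if not self.phases:
            self.phases = [None] * len(self.segments)
        if len(self.phases) != len(self.segments):
            raise ModelError("phases and segments must align")
        seq_ids = {s.seq_id for s in self.segments}
        if len(seq_ids) > 1:
            raise ModelError(
                f"feature {self.feature_id!r} has segments on multiple "
                f"scaffolds: {sorted(seq_ids)}"
            )
        strands = {s.strand for s in self.segments}
        if len(strands) > 1:
            raise ModelError(
                f"feature {self.feature_id!r} has segments on mixed strands"
            )

    @property
    def seq_id(self) -> str:
        return self.segments[0].seq_id

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    @property
    def start(self) -> int:
        return min(s.start for s in self.segments)

    @property
    def end(self) -> int:
        return max(s.end for s in self.segments)

    def get_attr(self, key: str) -> Optional[str]:
        """First value stored under ``key``, matched case-insensitively."""
        vals = self.get_attr_list(key)
        return vals[0] if vals else None

    def get_attr_list(self, key: str) -> list[str]:
        kl = key.lower()
        for k, vals in self.attributes.items():
            if k.lower() == kl:
                return vals
        return []


def feature_span(f: Feature) -> GenomicInterval:
    """Envelope interval over all segments of a feature."""
    return GenomicInterval(f.seq_id, f.start, f.end, f.strand)


class FeatureGraph:
    """Parent–child graph of features grouped into gene models.

    Holds the features, the (acyclic) parent edges, unresolved "deferred"
    parent references by ID (forward references, orphans and GTF
    transcript_id links), an ordered issue log, and an append-only
    provenance list recording every modification.
    """

    def __init__(self) -> None:
        self._features: dict[int, Feature] = {}
        self._parents: dict[int, list[int]] = {}
        self._children: dict[int, list[int]] = {}
        self._by_id: dict[str, list[int]] = {}
        self.deferred: dict[int, list[str]] = {}
        self.issues: list[Issue] = []
        self.provenance: list[dict] = []
        self.quarantined: list[tuple[int, str, str]] = []  # (line_no, code, raw)
        self.sequences: dict[str, str] = {}  # embedded ##FASTA section
        self._next_uid = 0

    # -- bookkeeping ---------------------------------------------------
    def add(self, f: Feature) -> int:
        uid = self._next_uid
        self._next_uid += 1
        f.uid = uid
        self._features[uid] = f
        self._parents[uid] = []
        self._children[uid] = []
        if f.feature_id is not None:
            self._by_id.setdefault(f.feature_id, []).append(uid)
        return uid

    def remove(self, uid: int) -> Feature:
        """Remove a feature, dropping its edges. Used only when merging."""
        f = self._features.pop(uid)
        for p in self._parents.pop(uid, []):
            self._children[p].remove(uid)
        for c in self._children.pop(uid, []):
            self._parents[c].remove(uid)
        if f.feature_id is not None:
            ids = self._by_id.get(f.feature_id, [])
            if uid in ids:
                ids.remove(uid)
            if not ids:
                self._by_id.pop(f.feature_id, None)
        self.deferred.pop(uid, None)
        return f

    def set_feature_id(self, uid: int, new_id: str) -> None:
        f = self._features[uid]
        if f.feature_id is not None:
            ids = self._by_id.get(f.feature_id, [])
            if uid in ids:
                ids.remove(uid)
        f.feature_id = new_id
        self._by_id.setdefault(new_id, []).append(uid)

    def add_edge(self, child: int, parent: int) -> None:
        if child not in self._features or parent not in self._features:
            raise ModelError("edge endpoint not in graph")
        if child == parent or self.is_ancestor(child, parent):
            raise ModelError("edge would create a cycle")
        if parent not in self._parents[child]:
            self._parents[child].append(parent)
            self._children[parent].append(child)

    def add_deferred(self, child: int, parent_id: str) -> None:
        refs = self.deferred.setdefault(child, [])
        if parent_id not in refs:
            refs.append(parent_id)

    def resolve_deferred(self) -> int:
        """Attach deferred parent references whose target ID now exists."""
        resolved = 0
        for uid in list(self.deferred):
            remaining = []
            for pid in self.deferred[uid]:
                targets = self._by_id.get(pid)
                if targets:
                    try:
                        self.add_edge(uid, self._pick_parent(uid, targets))
                        resolved += 1
                    except ModelError:
                        self.log(
                            "warning", "cycle_refused",
                            f"deferred edge {pid} would create a cycle",
                            feature_ids=(pid,),
                        )
                else:
                    remaining.append(pid)
            if remaining:
                self.deferred[uid] = remaining
            else:
                del self.deferred[uid]
        return resolved

    def _pick_parent(self, child: int, candidates: list[int]) -> int:
        """Tie-break multiple same-ID parents: minimal containing span, then
        declaration order."""
        if len(candidates) == 1:
            return candidates[0]
        c = self._features[child]
        span = feature_span(c)
        containing = [
            u for u in candidates
            if feature_span(self._features[u]).contains(span)
        ]
        pool = containing or candidates
        best = min(
            pool,
            key=lambda u: (feature_span(self._features[u]).length, u),
        )
        self.log(
            "warning", "ambiguous_parent",
            f"multiple features share parent ID; attached to uid {best}",
            feature_ids=(c.feature_id or "?",),
        )
        return best

    # -- queries -------------------------------------------------------
    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self._features.values())

    def get(self, uid: int) -> Feature:
        return self._features[uid]

    def features_of_type(self, ftype: str) -> list[Feature]:
        tl = ftype.lower()
        return [f for f in self._features.values() if f.feature_type == tl]

    def by_id(self, feature_id: str) -> list[Feature]:
        return [self._features[u] for u in self._by_id.get(feature_id, [])]

    def parents_of(self, f: Feature) -> list[Feature]:
        return [self._features[u] for u in self._parents.get(f.uid, [])]

    def children_of(self, f: Feature) -> list[Feature]:
        return [self._features[u] for u in self._children.get(f.uid, [])]

    def roots(self) -> list[Feature]:
        return [
            f for u, f in self._features.items() if not self._parents.get(u)
        ]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if ``a`` is an ancestor of ``b`` along parent edges."""
        stack = list(self._parents.get(b, []))
        seen = set()
        while stack:
            u = stack.pop()
            if u == a:
                return True
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self._parents.get(u, []))
        return False

    def siblings_of(self, f: Feature) -> list[Feature]:
        """Features sharing an actual parent or a deferred parent reference."""
        sibs: dict[int, Feature] = {}
        for p in self._parents.get(f.uid, []):
            for c in self._children.get(p, []):
                if c != f.uid:
                    sibs[c] = self._features[c]
        refs = set(self.deferred.get(f.uid, []))
        if refs:
            for uid, other_refs in self.deferred.items():
                if uid != f.uid and refs.intersection(other_refs):
                    sibs[uid] = self._features[uid]
        return [sibs[u] for u in sorted(sibs)]

    # -- logging -------------------------------------------------------
    def log(
        self,
        severity: str,
        code: str,
        message: str,
        feature_ids: Iterable[str] = (),
        action: str = "none",
    ) -> Issue:
        issue = Issue(severity, code, message, tuple(feature_ids), action)
        self.issues.append(issue)
        return issue

    def record(self, op: str, **details) -> None:
        entry = {"op": op}
        entry.update(details)
        self.provenance.append(entry)

    def unresolved_issues(self) -> list[Issue]:
        return [
            i for i in self.issues
            if i.severity in ("warning", "error") and i.action_taken == "none"
        ]
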