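"""Evidence-backed literature knowledge graph: data model, I/O and filtering.

The graph is a typed entity set plus a multiset of subject-predicate-object
assertions, each carrying literature provenance (source document id, the
supporting sentence, and a publication date).  Publication dates drive the
time-split replays used for adjusted p-values, so parsing and boundary
semantics are defined here once.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace

__all__ = [
    "SEMANTIC_GROUPS",
    "ENTITY_TYPES",
    "RELATION_TYPES",
    "DEFAULT_GROUP_TO_TYPE",
    "Entity",
    "EvidenceTriple",
    "KnowledgeGraph",
    "HierarchyMap",
    "SchemaError",
    "RowError",
    "parse_date",
    "read_triples",
    "write_triples",
    "read_blocklist",
    "read_hierarchy",
    "read_category_map",
    "filter_graph",
    "map_entity_types",
    "subset_by_date",
    "remove_pairs",
    "expand_terms",
]

#: The eight coarse semantic groups retained after noise removal.
SEMANTIC_GROUPS = frozenset(
    {
        "Anatomy",
        "Chemicals & Drugs",
        "Devices",
        "Disorders",
        "Genes & Molecular Sequences",
        "Phenomena",
        "Physiology",
        "Procedures",
    }
)

#: The five entity types the groups are re-categorized into.
ENTITY_TYPES = frozenset(
    {"Drug/Chemical", "Gene/Protein", "Disease/Syndrome", "Pathway/Function", "Others"}
)

#: The ten positive relation types kept in the graph.  Negated counterparts
#: (``NEG_`` prefix) are excluded wholesale during filtering.
RELATION_TYPES = frozenset(
    {
        "ASSOCIATED_WITH",
        "CAUSES",
        "COEXIST_WITH",
        "COMPLICATES",
        "INHIBITS",
        "INTERACTS_WITH",
        "MANIFESTATION_OF",
        "PRODUCES",
        "STIMULATES",
        "TREATS",
    }
)

#: Default re-categorization of semantic groups into the five entity types.
#: Physiology and Phenomena hold molecular/biologic function concepts, hence
#: map to Pathway/Function; Anatomy, Devices and Procedures are Others.
DEFAULT_GROUP_TO_TYPE = {
    "Chemicals & Drugs": "Drug/Chemical",
    "Genes & Molecular Sequences": "Gene/Protein",
    "Disorders": "Disease/Syndrome",
    "Physiology": "Pathway/Function",
    "Phenomena": "Pathway/Function",
    "Anatomy": "Others",
    "Devices": "Others",
    "Procedures": "Others",
}

TRIPLES_HEADER = [
    "subject_id",
    "subject_name",
    "subject_group",
    "predicate",
    "object_id",
    "object_name",
    "object_group",
    "source_id",
    "sentence",
    "date",
]


class SchemaError(ValueError):
    """The file header does not match the documented TSV schema."""


class RowError(ValueError):
    """A data row is malformed; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def parse_date(text: str) -> dt.date:
    """Parse an ISO-8601 date, completing partial dates conservatively.

    ``YYYY`` becomes January 1st and ``YYYY-MM`` the first of the month, so
    partially dated evidence is treated as published at the earliest moment
    of its stated period (it is *included* by earlier cutoffs rather than
    silently dropped).
    """
    text = text.strip().replace("/", "-")
    parts = text.split("-")
    try:
        if len(parts) == 1:
            return dt.date(int(parts[0]), 1, 1)
        if len(parts) == 2:
            return dt.date(int(parts[0]), int(parts[1]), 1)
        if len(parts) == 3:
            return dt.date(int(parts[0]), int(parts[1]), int(parts[2]))
    except ValueError as exc:
        raise ValueError(f"invalid calendar date {text!r}: {exc}") from None
    raise ValueError(f"invalid calendar date {text!r}")


@dataclass(frozen=True)
class Entity:
    """A typed biomedical concept (CUI-style id with a preferred label)."""

    id: str
    name: str = ""
    semantic_group: str = ""
    entity_type: str = "Others"
    semantic_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.id:
            raise ValueError("entity id must be non-empty")


@dataclass(frozen=True)
class EvidenceTriple:
    """One subject-predicate-object assertion with literature provenance."""

    subject: str
    predicate: str
    object: str
    source_id: str = ""
    sentence: str = ""
    date: dt.date = dt.date(1900, 1, 1)

    def __post_init__(self):
        if self.subject == self.object:
            raise ValueError(
                f"self-loop triple {self.subject} {self.predicate} {self.object}"
            )

    @property
    def edge(self) -> tuple[str, str, str]:
        return (self.subject, self.predicate, self.object)


class KnowledgeGraph:
    """Typed entity set plus a multiset of evidence triples.

    ``distinct_edges`` deduplicates the triples by (subject, predicate,
    object), preserving first-occurrence order, with the evidence list
    attached; it is the substrate for embedding training.
    """

    def __init__(self, entities: dict[str, Entity], triples: list[EvidenceTriple]):
        missing = {t.subject for t in triples} | {t.object for t in triples}
        missing -= set(entities)
        if missing:
            raise ValueError(f"triples reference unknown entities: {sorted(missing)[:5]}")
        self.entities: dict[str, Entity] = dict(entities)
        self.triples: list[EvidenceTriple] = list(triples)
        self._distinct: dict[tuple[str, str, str], list[EvidenceTriple]] | None = None

    @property
    def distinct_edges(self) -> dict[tuple[str, str, str], list[EvidenceTriple]]:
        if self._distinct is None:
            edges: dict[tuple[str, str, str], list[EvidenceTriple]] = {}
            for t in self.triples:
                edges.setdefault(t.edge, []).append(t)
            self._distinct = edges
        return self._distinct

    @property
    def relations(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.triples:
            seen.setdefault(t.predicate)
        return list(seen)

    def entities_of_type(self, entity_type: str) -> list[str]:
        return [e.id for e in self.entities.values() if e.entity_type == entity_type]

    def neighbors(self, entity_id: str) -> set[str]:
        """Entities adjacent to ``entity_id`` via any edge, either direction."""
        out: set[str] = set()
        for s, _, o in self.distinct_edges:
            if s == entity_id:
                out.add(o)
            elif o == entity_id:
                out.add(s)
        return out

    def __len__(self) -> int:
        return len(self.triples)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KnowledgeGraph)
            and self.entities == other.entities
            and self.triples == other.triples
        )


@dataclass
class HierarchyMap:
    """Concept hierarchy (parent -> direct children) and drug categories."""

    parent_child: dict[str, set[str]] = field(default_factory=dict)
    category_of: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O


def read_triples(path, dedupe: bool = True) -> KnowledgeGraph:
    """Read the triples TSV into a knowledge graph.

    Entities are built from the endpoint columns, with entity types assigned
    from the default semantic-group mapping (re-mappable afterwards with
    :func:`map_entity_types`).  Identical (subject, predicate, object,
    source_id, sentence) rows are collapsed to one piece of evidence when
    ``dedupe`` is set, since abstract and full-text ingestion can repeat a
    sentence.
    """
    entities: dict[str, Entity] = {}
    triples: list[EvidenceTriple] = []
    seen: set[tuple] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != TRIPLES_HEADER:
            raise SchemaError(
                f"expected header {TRIPLES_HEADER}, got {header}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(TRIPLES_HEADER):
                raise RowError(row_no, f"expected {len(TRIPLES_HEADER)} columns, got {len(row)}")
            (s_id, s_name, s_group, pred, o_id, o_name, o_group,
             source_id, sentence, date_txt) = row
            try:
                date = parse_date(date_txt)
            except ValueError as exc:
                raise RowError(row_no, str(exc)) from None
            key = (s_id, pred, o_id, source_id, sentence)
            if dedupe and key in seen:
                continue
            seen.add(key)
            for eid, name, group in ((s_id, s_name, s_group), (o_id, o_name, o_group)):
                if eid not in entities:
                    try:
                        entities[eid] = Entity(
                            id=eid,
                            name=name,
                            semantic_group=group,
                            entity_type=DEFAULT_GROUP_TO_TYPE.get(group, "Others"),
                        )
                    except ValueError as exc:
                        raise RowError(row_no, str(exc)) from None
            try:
                triples.append(
                    EvidenceTriple(s_id, pred, o_id, source_id, sentence, date)
                )
            except ValueError as exc:
                raise RowError(row_no, str(exc)) from None
    return KnowledgeGraph(entities, triples)


def write_triples(kg: KnowledgeGraph, path) -> None:
    """Write the graph back to the triples TSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRIPLES_HEADER)
        for t in kg.triples:
            s = kg.entities[t.subject]
            o = kg.entities[t.object]
            writer.writerow(
                [
                    s.id, s.name, s.semantic_group,
                    t.predicate,
                    o.id, o.name, o.semantic_group,
                    t.source_id, t.sentence, t.date.isoformat(),
                ]
            )


def read_entities(path) -> dict[str, Entity]:
    """Read the entities TSV: id, name, semantic_group, semantic_types."""
    out: dict[str, Entity] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["id", "name", "semantic_group", "semantic_types"]:
            raise SchemaError(f"unexpected entities header: {header}")
        for row in reader:
            if not row:
                continue
            eid, name, group, stypes = row
            out[eid] = Entity(
                id=eid,
                name=name,
                semantic_group=group,
                entity_type=DEFAULT_GROUP_TO_TYPE.get(group, "Others"),
                semantic_types=frozenset(t for t in stypes.split("|") if t),
            )
    return out


def write_entities(entities: dict[str, Entity], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "name", "semantic_group", "semantic_types"])
        for e in entities.values():
            writer.writerow([e.id, e.name, e.semantic_group, "|".join(sorted(e.semantic_types))])


def read_blocklist(path) -> set[str]:
    """One concept id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def read_hierarchy(path) -> dict[str, set[str]]:
    """Hierarchy TSV (parent_id, child_id) -> parent -> direct children."""
    out: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["parent_id", "child_id"]:
            raise SchemaError(f"unexpected hierarchy header: {header}")
        for parent, child in reader:
            out.setdefault(parent, set()).add(child)
    return out


def read_category_map(path) -> dict[str, str]:
    """Category TSV (drug_id, category_id) -> drug -> category."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["drug_id", "category_id"]:
            raise SchemaError(f"unexpected category-map header: {header}")
        for drug, cat in reader:
            out[drug] = cat
    return out


# ---------------------------------------------------------------------------
# Filtering and subsetting


def filter_graph(
    kg: KnowledgeGraph,
    blocklist: set[str] | None = None,
    allowed_groups: frozenset[str] | set[str] = SEMANTIC_GROUPS,
    allowed_predicates: frozenset[str] | set[str] = RELATION_TYPES,
) -> KnowledgeGraph:
    """Apply the post-extraction noise-removal rules.

    Removes triples touching blocklisted generic concepts, entities outside
    the allowed semantic groups (and their triples), and triples whose
    predicate is negated (``NEG_`` prefix) or not in the whitelist.  The
    result contains only positive whitelisted relations; the operation is
    idempotent.
    """
    blocklist = blocklist or set()
    keep_entities = {
        eid: e for eid, e in kg.entities.items()
        if eid not in blocklist and e.semantic_group in allowed_groups
    }
    triples = [
        t for t in kg.triples
        if t.subject in keep_entities
        and t.object in keep_entities
        and not t.predicate.startswith("NEG_")
        and t.predicate in allowed_predicates
    ]
    return KnowledgeGraph(keep_entities, triples)


def map_entity_types(kg: KnowledgeGraph, group_to_type: dict[str, str] | None = None) -> KnowledgeGraph:
    """Re-categorize entities into the five entity types by semantic group."""
    mapping = DEFAULT_GROUP_TO_TYPE if group_to_type is None else group_to_type
    entities: dict[str, Entity] = {}
    for eid, e in kg.entities.items():
        if e.semantic_group not in mapping:
            raise KeyError(
                f"semantic group {e.semantic_group!r} has no entity-type mapping"
            )
        etype = mapping[e.semantic_group]
        if etype not in ENTITY_TYPES:
            raise ValueError(f"{etype!r} is not one of the five entity types")
        entities[eid] = replace(e, entity_type=etype)
    return KnowledgeGraph(entities, kg.triples)


def subset_by_date(
    kg: KnowledgeGraph, cutoff: dt.date, strict: bool = False
) -> KnowledgeGraph:
    """Keep only evidence published up to ``cutoff``.

    The boundary is inclusive (date <= cutoff) by default because partial
    publication dates are completed to the start of their period; ``strict``
    switches to a literal ``<`` comparison.  Entities left with no incident
    triple are dropped.
    """
    if strict:
        triples = [t for t in kg.triples if t.date < cutoff]
    else:
        triples = [t for t in kg.triples if t.date <= cutoff]
    used = {t.subject for t in triples} | {t.object for t in triples}
    entities = {eid: e for eid, e in kg.entities.items() if eid in used}
    return KnowledgeGraph(entities, triples)


def remove_pairs(
    kg: KnowledgeGraph, pairs: set[tuple[str, str]], predicate: str = "TREATS"
) -> KnowledgeGraph:
    """Drop all ``predicate`` edges between each listed (drug, disease) pair.

    Used to hold out known repurposing successes before embedding training so
    their scores are not read off memorized edges.  Entities are kept even if
    isolated (they must stay embeddable).
    """
    triples = [
        t for t in kg.triples
        if not (t.predicate == predicate and (t.subject, t.object) in pairs)
    ]
    return KnowledgeGraph(kg.entities, triples)


def expand_terms(seed_ids: set[str], hierarchy: HierarchyMap | dict[str, set[str]]) -> set[str]:
    """Seeds plus all hierarchy descendants (transitive closure).

    Raises on a cycle: a concept may not be its own descendant.
    """
    children = hierarchy.parent_child if isinstance(hierarchy, HierarchyMap) else hierarchy
    result: set[str] = set()
    for seed in seed_ids:
        stack = [(seed, frozenset({seed}))]
        result.add(seed)
        while stack:
            node, path = stack.pop()
            for child in children.get(node, ()):
                if child in path:
                    raise ValueError(f"hierarchy cycle involving {child!r}")
                result.add(child)
                stack.append((child, path | {child}))
    return result
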