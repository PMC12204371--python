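"""Evidence sub-graphs and citation-grounded explanation prompts.

For a nominated candidate drug, the evidence neighborhood linking it to the
target disease terms is extracted: the candidate, the disease terms, related
protein/symptom terms, and the molecular-function entities adjacent to both
the candidate and a disease term.  The candidate's own TREATS edges to the
disease terms are deliberately omitted, so any generated explanation must
argue from mechanism, not from the conclusion.  Supporting sentences are
indexed, capped (random subset beyond the cap), optionally mixed with an
equal number of unrelated control sentences and shuffled, and assembled into
one of four prompt variants.  A mechanical audit then parses the bracketed
citation indices out of a generated hypothesis and measures which fraction
point at supporting rather than control material.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from .kg import EvidenceTriple, KnowledgeGraph

__all__ = [
    "SubKnowledgeGraph",
    "SentenceItem",
    "PromptBundle",
    "CitationAudit",
    "LLMClient",
    "MockLLMClient",
    "DEFAULT_TEMPLATES",
    "DEFAULT_LLM_SETTINGS",
    "build_subkg",
    "select_sentences",
    "add_unrelated",
    "build_prompt",
    "audit_citations",
]

Edge = tuple[str, str, str]

#: Recorded LLM configuration for hypothesis generation (the shipped client
#: is a deterministic mock; live calls are out of scope).
DEFAULT_LLM_SETTINGS = {
    "system": "You are a neurologist and a professional scientific journal paper writer",
    "model": "gpt-4",
    "temperature": 0,
}


@dataclass
class SentenceItem:
    """One indexable prompt item: a sentence (or relation) with provenance."""

    edge: Edge
    source_id: str
    text: str
    supporting: bool = True


@dataclass
class SubKnowledgeGraph:
    """Candidate-drug evidence neighborhood feeding prompt construction."""

    candidate: str
    nodes: set[str]
    edges: dict[Edge, list[EvidenceTriple]]
    sentences: list[SentenceItem]
    disease_terms: set[str] = field(default_factory=set)


def build_subkg(
    kg: KnowledgeGraph,
    candidate: str,
    disease_terms: set[str],
    protein_symptom_terms: set[str] | None = None,
) -> SubKnowledgeGraph:
    """Extract the candidate <-> disease evidence neighborhood.

    Mutual function neighbors are Pathway/Function entities adjacent (any
    relation, either direction) to the candidate *and* to at least one
    disease term.  Edges are every graph edge among the node set except the
    candidate's TREATS edges into the disease terms; sentences are collected
    from the retained edges' evidence in provenance order.
    """
    if candidate not in kg.entities:
        raise KeyError(f"candidate {candidate!r} not in graph")
    protein_symptom_terms = protein_symptom_terms or set()
    cand_nb = kg.neighbors(candidate)
    disease_nb: set[str] = set()
    for term in disease_terms:
        if term in kg.entities:
            disease_nb |= kg.neighbors(term)
    mutual = {
        e for e in (cand_nb & disease_nb)
        if kg.entities[e].entity_type == "Pathway/Function"
    }
    nodes = (
        {candidate}
        | (disease_terms & set(kg.entities))
        | (protein_symptom_terms & set(kg.entities))
        | mutual
    )
    edges: dict[Edge, list[EvidenceTriple]] = {}
    for edge, evidence in kg.distinct_edges.items():
        s, p, o = edge
        if s not in nodes or o not in nodes:
            continue
        if p == "TREATS" and s == candidate and o in disease_terms:
            continue
        edges[edge] = list(evidence)
    sentences = [
        SentenceItem(edge=edge, source_id=t.source_id, text=t.sentence)
        for edge, evidence in edges.items()
        for t in evidence
    ]
    return SubKnowledgeGraph(candidate, nodes, edges, sentences, set(disease_terms))


def select_sentences(
    sub: SubKnowledgeGraph, cap: int = 50, seed: int = 0
) -> list[SentenceItem]:
    """All supporting sentences, or a seeded uniform sample of ``cap``."""
    items = sub.sentences
    if len(items) <= cap:
        return list(items)
    rng = np.random.default_rng(seed)
    pick = sorted(rng.choice(len(items), size=cap, replace=False).tolist())
    return [items[i] for i in pick]


def add_unrelated(
    sentences: list[SentenceItem],
    kg: KnowledgeGraph,
    candidate: str,
    disease_terms: set[str],
    seed: int = 0,
) -> list[SentenceItem]:
    """Mix in an equal number of unrelated control sentences and shuffle.

    A sentence is eligible as unrelated when its edge touches neither the
    candidate nor any disease term.  The merged supporting + control list is
    shuffled under ``seed``; the ``supporting`` flags travel with the items.
    """
    banned = {candidate} | set(disease_terms)
    pool = [
        SentenceItem(edge=t.edge, source_id=t.source_id, text=t.sentence, supporting=False)
        for t in kg.triples
        if t.subject not in banned and t.object not in banned
    ]
    need = len(sentences)
    if len(pool) < need:
        raise ValueError(
            f"only {len(pool)} unrelated sentences available, need {need}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool), size=need, replace=False)
    merged = list(sentences) + [pool[i] for i in pick]
    order = rng.permutation(len(merged))
    return [merged[i] for i in order]


#: Non-verbatim task templates; ``{items}`` receives the indexed material.
DEFAULT_TEMPLATES = {
    "litkg": (
        "Generate a hypothesis explaining how {drug} could treat {disease}, "
        "based on the following indexed supporting sentences from the "
        "biomedical literature. Cite the indices of the sentences you use in "
        "brackets.\n\n{items}"
    ),
    "litkg_prime": (
        "Generate a hypothesis explaining how {drug} could treat {disease}, "
        "based on the following indexed sentences from the biomedical "
        "literature. Cite the indices of the sentences you use in "
        "brackets.\n\n{items}"
    ),
    "kg": (
        "Generate a hypothesis explaining how {drug} could treat {disease}, "
        "based on the following indexed subject-relation-object statements. "
        "Cite the indices of the statements you use in brackets.\n\n{items}"
    ),
    "bare": (
        "Generate a hypothesis explaining how {drug} could treat {disease}."
    ),
}

_PLACEHOLDERS = {"litkg": ("{drug}", "{disease}", "{items}"),
                 "litkg_prime": ("{drug}", "{disease}", "{items}"),
                 "kg": ("{drug}", "{disease}", "{items}"),
                 "bare": ("{drug}", "{disease}")}


@dataclass
class PromptBundle:
    """Assembled prompt text plus the index -> provenance map."""

    task: str
    text: str
    index_map: dict[int, SentenceItem]
    seed: int = 0

    @property
    def supporting_indices(self) -> set[int]:
        return {i for i, item in self.index_map.items() if item.supporting}

    def to_json(self, path) -> None:
        payload = {
            "task": self.task,
            "text": self.text,
            "seed": self.seed,
            "index_map": {
                str(i): {
                    "edge": list(item.edge),
                    "source_id": item.source_id,
                    "text": item.text,
                    "supporting": item.supporting,
                }
                for i, item in self.index_map.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _relation_text(item: SentenceItem) -> str:
    s, p, o = item.edge
    return f"{s} {p} {o}"


def build_prompt(
    task: str,
    sub: SubKnowledgeGraph,
    items: list[SentenceItem] | None = None,
    template: str | None = None,
    drug_name: str | None = None,
    disease_name: str | None = None,
    seed: int = 0,
) -> PromptBundle:
    """Assemble one of the four prompt variants.

    ``litkg`` embeds indexed supporting sentences, ``litkg_prime`` the
    supporting + unrelated shuffled mix, ``kg`` only (subject, relation,
    object) statements, and ``bare`` just the drug and disease names.
    """
    if task not in DEFAULT_TEMPLATES:
        raise ValueError(f"unknown task {task!r}")
    template = template if template is not None else DEFAULT_TEMPLATES[task]
    for ph in _PLACEHOLDERS[task]:
        if ph not in template:
            raise ValueError(f"template for task {task!r} lacks placeholder {ph}")
    drug = drug_name or sub.candidate
    disease = disease_name or ",".join(sorted(sub.disease_terms))
    index_map: dict[int, SentenceItem] = {}
    if task == "bare":
        text = template.replace("{drug}", drug).replace("{disease}", disease)
        return PromptBundle(task, text, index_map, seed)
    if items is None:
        items = select_sentences(sub, seed=seed)
    lines = []
    for i, item in enumerate(items, start=1):
        index_map[i] = item
        body = _relation_text(item) if task == "kg" else item.text
        lines.append(f"[{i}] {body}")
    text = (
        template.replace("{drug}", drug)
        .replace("{disease}", disease)
        .replace("{items}", "\n".join(lines))
    )
    return PromptBundle(task, text, index_map, seed)


@dataclass
class CitationAudit:
    """Mechanical accounting of the indices a hypothesis cites."""

    cited_indices: list[int]
    valid: set[int]
    invalid: set[int]
    supported_fraction: float | None
    expanded_ranges: bool = False


_BRACKET = re.compile(r"\[([0-9][0-9,\s–-]*)\]")


def _parse_citations(text: str) -> tuple[list[int], bool]:
    cited: list[int] = []
    expanded = False
    for group in _BRACKET.findall(text):
        for token in group.split(","):
            token = token.strip()
            if not token:
                continue
            m = re.fullmatch(r"(\d+)\s*[–-]\s*(\d+)", token)
            if m:
                a, b = int(m.group(1)), int(m.group(2))
                cited.extend(range(a, b + 1))
                expanded = True
            elif token.isdigit():
                cited.append(int(token))
    return cited, expanded


def audit_citations(hypothesis: str, bundle: PromptBundle) -> CitationAudit:
    """Parse bracketed citation indices and measure their support.

    ``supported_fraction`` is |valid cited indices flagged supporting| /
    |valid cited indices|; None when the text cites nothing.
    """
    cited, expanded = _parse_citations(hypothesis)
    cited_unique = list(dict.fromkeys(cited))
    valid = {i for i in cited_unique if i in bundle.index_map}
    invalid = set(cited_unique) - valid
    if valid:
        supported = sum(1 for i in valid if bundle.index_map[i].supporting)
        fraction = supported / len(valid)
    else:
        fraction = None
    return CitationAudit(cited_unique, valid, invalid, fraction, expanded)


class LLMClient:
    """Abstract hypothesis generator: send a prompt, receive text."""

    settings = DEFAULT_LLM_SETTINGS

    def generate(self, prompt: str) -> str:  # pragma: no cover - interface
        raise NotImplementedError


class MockLLMClient(LLMClient):
    """Deterministic stand-in client that cites configured indices."""

    def __init__(self, cite_indices: list[int] | None = None):
        self.cite_indices = cite_indices

    def generate_from_bundle(self, bundle: PromptBundle) -> str:
        indices = self.cite_indices
        if indices is None:
            indices = sorted(bundle.supporting_indices)
        cites = ", ".join(str(i) for i in indices)
        return (
            f"The candidate may act through the mechanisms described in the "
            f"cited evidence [{cites}]." if indices else
            "No indexed evidence was provided."
        )

    def generate(self, prompt: str) -> str:
        return "No indexed evidence was provided."
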