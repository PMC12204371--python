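"""Synthetic literature-style knowledge graphs with planted mechanism structure.

The generator emulates the structure the scoring system assumes about real
pharmacological literature: drugs come in families sharing a mechanism (the
family's proteins and molecular functions), diseases are caused by a
family's proteins and associated with its functions, and TREATS edges link
family drugs to family diseases.  A configurable number of family-consistent
TREATS pairs is withheld from the graph ("held-out true repurposing pairs"):
their mechanism edges are dated before the pair's synthetic approval date, so
time-split replays can rediscover them from pre-approval literature alone.
Every edge carries at least one dated, templated evidence sentence, making
the generated graph usable end to end (I/O round trips, embedding, scoring,
significance replays and prompt construction).
"""

from __future__ import annotations

import datetime as dt
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .kg import Entity, EvidenceTriple, KnowledgeGraph, write_entities, write_triples
from .significance import EventDates, write_event_dates

__all__ = ["SynthConfig", "GroundTruth", "generate", "write_fixture"]

Edge = tuple[str, str, str]


@dataclass
class SynthConfig:
    """Generator settings; the defaults define the standard study conditions."""

    n_drugs: int = 200
    n_diseases: int = 50
    n_proteins: int = 40
    n_functions: int = 30
    n_families: int = 10
    treats_per_disease: float = 4.0
    noise_edge_rate: float = 0.05
    n_heldout: int = 20
    date_range: tuple[dt.date, dt.date] = (dt.date(1990, 1, 1), dt.date(2020, 12, 31))
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_diseases", "n_proteins", "n_functions", "n_families"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_families > min(self.n_drugs, self.n_diseases):
            raise ValueError("more families than drugs or diseases")
        if not (0.0 <= self.noise_edge_rate < 1.0):
            raise ValueError("noise_edge_rate must lie in [0, 1)")
        if self.treats_per_disease <= 0:
            raise ValueError("treats_per_disease must be positive")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("date_range start must precede end")


@dataclass
class GroundTruth:
    """What the generator planted and withheld."""

    heldout_pairs: dict[tuple[str, str], dt.date] = field(default_factory=dict)
    family_of: dict[str, int] = field(default_factory=dict)
    mechanism_of: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "heldout_pairs": [
                {"drug": d, "disease": s, "approval_date": a.isoformat()}
                for (d, s), a in self.heldout_pairs.items()
            ],
            "family_of": self.family_of,
            "mechanism_of": {k: sorted(v) for k, v in self.mechanism_of.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate(config: SynthConfig | None = None) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a planted-structure knowledge graph and its ground truth.

    Reproducible: the same config (including seed) yields an identical graph.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    start, end = cfg.date_range
    start_ord, end_ord = start.toordinal(), end.toordinal()

    drugs = _ids("DRUG", cfg.n_drugs)
    diseases = _ids("DIS", cfg.n_diseases)
    proteins = _ids("PROT", cfg.n_proteins)
    functions = _ids("FUNC", cfg.n_functions)

    entities: dict[str, Entity] = {}
    for i, d in enumerate(drugs):
        entities[d] = Entity(d, f"drug {i + 1}", "Chemicals & Drugs", "Drug/Chemical",
                             frozenset({"Pharmacologic Substance"}))
    for i, d in enumerate(diseases):
        entities[d] = Entity(d, f"disease {i + 1}", "Disorders", "Disease/Syndrome",
                             frozenset({"Disease or Syndrome"}))
    for i, p in enumerate(proteins):
        entities[p] = Entity(p, f"protein {i + 1}", "Genes & Molecular Sequences",
                             "Gene/Protein", frozenset({"Amino Acid, Peptide, or Protein"}))
    for i, g in enumerate(functions):
        entities[g] = Entity(g, f"function {i + 1}", "Physiology", "Pathway/Function",
                             frozenset({"Molecular Function"}))

    fam_of = {d: i % cfg.n_families for i, d in enumerate(drugs)}
    fam_of_disease = {d: i % cfg.n_families for i, d in enumerate(diseases)}
    fam_proteins: dict[int, list[str]] = {f: [] for f in range(cfg.n_families)}
    for i, p in enumerate(proteins):
        fam_proteins[i % cfg.n_families].append(p)
    fam_functions: dict[int, list[str]] = {f: [] for f in range(cfg.n_families)}
    for i, g in enumerate(functions):
        fam_functions[i % cfg.n_families].append(g)
    fam_drugs: dict[int, list[str]] = {f: [] for f in range(cfg.n_families)}
    for d in drugs:
        fam_drugs[fam_of[d]].append(d)
    fam_diseases: dict[int, list[str]] = {f: [] for f in range(cfg.n_families)}
    for d in diseases:
        fam_diseases[fam_of_disease[d]].append(d)

    edges: list[Edge] = []
    mech_edges_of_pair: dict[tuple[str, str], list[Edge]] = {}
    for f in range(cfg.n_families):
        for d in fam_drugs[f]:
            edges.extend((d, "INHIBITS", p) for p in fam_proteins[f])
            edges.extend((d, "STIMULATES", g) for g in fam_functions[f])
        for s in fam_diseases[f]:
            edges.extend((p, "CAUSES", s) for p in fam_proteins[f])
            edges.extend((g, "ASSOCIATED_WITH", s) for g in fam_functions[f])

    # planted TREATS: each disease treated by a few drugs of its family
    treats: set[tuple[str, str]] = set()
    for s in diseases:
        f = fam_of_disease[s]
        pool = fam_drugs[f]
        k = int(np.clip(rng.poisson(cfg.treats_per_disease), 1, len(pool)))
        chosen = rng.choice(len(pool), size=k, replace=False)
        for c in chosen:
            treats.add((pool[c], s))

    # held-out family-consistent pairs, withheld from the emitted TREATS set
    candidates = [
        (d, s)
        for f in range(cfg.n_families)
        for d in fam_drugs[f]
        for s in fam_diseases[f]
        if (d, s) not in treats
    ]
    if cfg.n_heldout > len(candidates):
        raise ValueError(
            f"n_heldout={cfg.n_heldout} exceeds the {len(candidates)} plausible pairs"
        )
    heldout_idx = rng.choice(len(candidates), size=cfg.n_heldout, replace=False)
    span = end_ord - start_ord
    heldout: dict[tuple[str, str], dt.date] = {}
    for i in sorted(heldout_idx.tolist()):
        d, s = candidates[i]
        approval = dt.date.fromordinal(int(rng.integers(start_ord + int(0.6 * span), end_ord + 1)))
        heldout[(d, s)] = approval
        f = fam_of[d]
        mech = (
            [(d, "INHIBITS", p) for p in fam_proteins[f]]
            + [(p, "CAUSES", s) for p in fam_proteins[f]]
            + [(d, "STIMULATES", g) for g in fam_functions[f]]
            + [(g, "ASSOCIATED_WITH", s) for g in fam_functions[f]]
        )
        mech_edges_of_pair[(d, s)] = mech

    edges.extend((d, "TREATS", s) for (d, s) in sorted(treats))

    # uniform random noise edges (target fraction of the final edge multiset)
    all_ids = drugs + diseases + proteins + functions
    from .kg import RELATION_TYPES

    rels = sorted(RELATION_TYPES)
    n_struct = len(edges)
    n_noise = int(round(cfg.noise_edge_rate * n_struct / (1.0 - cfg.noise_edge_rate)))
    existing = set(edges)
    made = 0
    while made < n_noise:
        a, b = rng.integers(0, len(all_ids), size=2)
        if a == b:
            continue
        p = rels[int(rng.integers(0, len(rels)))]
        e = (all_ids[int(a)], p, all_ids[int(b)])
        if e in existing:
            continue
        if p == "TREATS" and (e[0], e[2]) in heldout:
            continue
        existing.add(e)
        edges.append(e)
        made += 1

    # evidence dates: mechanism edges of held-out pairs must predate approval
    max_date_of: dict[Edge, int] = {}
    for (pair, mech) in mech_edges_of_pair.items():
        approval_ord = heldout[pair].toordinal()
        for e in mech:
            max_date_of[e] = min(max_date_of.get(e, end_ord), approval_ord - 1)

    triples: list[EvidenceTriple] = []
    pmid = 9_000_000
    for e in edges:
        s, p, o = e
        hi = max_date_of.get(e, end_ord)
        n_ev = 1 + int(rng.poisson(0.5))
        for k in range(n_ev):
            pmid += 1
            date = dt.date.fromordinal(int(rng.integers(start_ord, hi + 1)))
            suffix = "" if k == 0 else f" (report {k + 1})"
            sentence = f"{entities[s].name} {p} {entities[o].name}{suffix}."
            triples.append(EvidenceTriple(s, p, o, f"PMID{pmid}", sentence, date))

    kg = KnowledgeGraph(entities, triples)
    truth = GroundTruth(
        heldout_pairs=heldout,
        family_of=dict(fam_of),
        mechanism_of={
            s: set(fam_functions[fam_of_disease[s]]) for s in diseases
        },
    )
    return kg, truth


def write_fixture(kg: KnowledgeGraph, truth: GroundTruth, out_dir) -> None:
    """Emit triples.tsv, entities.tsv, event_dates.tsv and truth.json.

    Event dates for the held-out pairs use the synthetic approval date, a
    phase-3 start three years earlier and a first trial six years earlier
    (floored at the evidence range start), enabling time-split replays.
    """
    os.makedirs(out_dir, exist_ok=True)
    write_triples(kg, os.path.join(out_dir, "triples.tsv"))
    write_entities(kg.entities, os.path.join(out_dir, "entities.tsv"))
    dates: dict[tuple[str, str], EventDates] = {}
    floor = min((t.date for t in kg.triples), default=dt.date(1990, 1, 1))

    def _back(d: dt.date, years: int) -> dt.date:
        try:
            moved = d.replace(year=d.year - years)
        except ValueError:
            moved = d.replace(year=d.year - years, day=28)
        return max(moved, floor)

    for pair, approval in truth.heldout_pairs.items():
        dates[pair] = EventDates(
            approval_date=approval,
            phase_start_dates={3: _back(approval, 3)},
            first_trial_date=_back(approval, 6),
        )
    write_event_dates(dates, os.path.join(out_dir, "event_dates.tsv"))
    truth.to_json(os.path.join(out_dir, "truth.json"))
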