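"""Empirical significance of an R-score, plain and time-split adjusted.

The plain p-value of a pair's R-score is the fraction of the all-pairs
R-score population that strictly exceeds it.  The adjusted variants replay
history: the graph is truncated to evidence published up to a reference date
(approval, phase-n trial start, first trial, or approval minus four years),
embeddings are retrained on the truncated graph, every drug-disease R-score
is recomputed, and the pair's score is ranked against that historical
population.  Pairs whose drug or disease has not yet appeared in the
truncated literature are reported as not applicable.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from . import kg as kgmod
from .embedding import TrainConfig, train
from .kg import KnowledgeGraph
from .scoring import ScoreTable, ScoringContext, score_all

__all__ = [
    "EventDates",
    "PValueReport",
    "empirical_pvalue",
    "resolve_cutoff",
    "pair_pvalue",
    "adjusted_pvalue",
    "read_event_dates",
]


@dataclass
class EventDates:
    """Regulatory / trial milestones for one drug-disease pair."""

    approval_date: dt.date | None = None
    phase_start_dates: dict[int, dt.date] = field(default_factory=dict)
    first_trial_date: dt.date | None = None

    def __post_init__(self):
        import warnings

        if self.approval_date:
            for n, d in self.phase_start_dates.items():
                if d > self.approval_date:
                    warnings.warn(
                        f"phase-{n} start {d} is after approval {self.approval_date}",
                        stacklevel=2,
                    )


@dataclass
class PValueReport:
    """Outcome of a (possibly time-split) significance query."""

    pair: tuple[str, str]
    variant: str = "plain"
    cutoff_date: dt.date | None = None
    r_score: float | None = None
    p_value: float | None = None
    population_size: int = 0
    not_applicable: bool = False
    reason: str = ""
    score_table: ScoreTable | None = None

    def __str__(self) -> str:
        if self.not_applicable:
            return f"{self.pair}: NA ({self.reason})"
        p = self.p_value
        if p == 0.0:
            ptxt = f"< {1.0 / self.population_size:.3g}"
        else:
            ptxt = f"{p:.4g}"
        return f"{self.pair}: R-score {self.r_score:.4f}, p {ptxt} [{self.variant}]"


def empirical_pvalue(r: float, population, gte: bool = False) -> float:
    """Fraction of the population exceeding ``r`` (strictly, by default)."""
    pop = np.asarray(population, dtype=float)
    if pop.size == 0:
        raise ValueError("reference population is empty")
    if gte:
        return float((pop >= r).sum() / pop.size)
    return float((pop > r).sum() / pop.size)


def _minus_years(date: dt.date, years: int) -> dt.date:
    try:
        return date.replace(year=date.year - years)
    except ValueError:  # Feb 29 -> Feb 28
        return date.replace(year=date.year - years, day=28)


def resolve_cutoff(variant: str, dates: EventDates) -> dt.date | None:
    """Reference date for an adjusted-p-value variant; None when missing.

    ``adj_a`` uses the approval date, ``adj_<n>`` the phase-n trial start,
    ``adj_0`` the first trial of any phase, and ``adj_a_minus_4`` the approval
    date minus four calendar years (the typical phase-3 duration, the fallback
    when trial registry dates predate the registry itself).
    """
    if variant == "adj_a":
        return dates.approval_date
    if variant == "adj_0":
        return dates.first_trial_date
    if variant == "adj_a_minus_4":
        if dates.approval_date is None:
            return None
        return _minus_years(dates.approval_date, 4)
    if variant.startswith("adj_") and variant[4:].isdigit():
        return dates.phase_start_dates.get(int(variant[4:]))
    raise ValueError(f"unknown p-value variant {variant!r}")


def pair_pvalue(
    kg: KnowledgeGraph,
    pair: tuple[str, str],
    train_config: TrainConfig,
    cutoff: dt.date | None = None,
    variant: str = "plain",
    drugs: list[str] | None = None,
    diseases: list[str] | None = None,
    remove_pair_edges: bool = True,
    gte: bool = False,
) -> PValueReport:
    """Retrain, rescore all drug-disease pairs, and rank the queried pair.

    With ``cutoff`` set, the graph is first truncated to evidence up to that
    date; the queried pair's TREATS edges are removed before training (so the
    score is a genuine prediction, not edge recall) unless
    ``remove_pair_edges`` is False.  A cutoff at or beyond the latest evidence
    date reproduces the plain p-value exactly.
    """
    theta, lam = pair
    sub = kgmod.subset_by_date(kg, cutoff) if cutoff is not None else kg
    if theta not in sub.entities or lam not in sub.entities:
        missing = [e for e in pair if e not in sub.entities]
        return PValueReport(
            pair=pair,
            variant=variant,
            cutoff_date=cutoff,
            not_applicable=True,
            reason=f"absent after time split: {', '.join(missing)}",
        )
    if remove_pair_edges:
        sub = kgmod.remove_pairs(sub, {pair})
    if drugs is None:
        drugs = sub.entities_of_type("Drug/Chemical")
    else:
        drugs = [d for d in drugs if d in sub.entities]
    if diseases is None:
        diseases = sub.entities_of_type("Disease/Syndrome")
    else:
        diseases = [d for d in diseases if d in sub.entities]
    try:
        model = train(list(sub.distinct_edges), train_config, entities=list(sub.entities))
    except Exception as exc:
        raise RuntimeError(f"training failed under cutoff {cutoff}: {exc}") from exc
    ctx = ScoringContext.from_graph(sub, model, drugs=drugs, diseases=diseases)
    table = score_all(ctx)
    r = float(table.pair(theta, lam)["r_score"])
    population = table.r_scores()
    p = empirical_pvalue(r, population, gte=gte)
    return PValueReport(
        pair=pair,
        variant=variant,
        cutoff_date=cutoff,
        r_score=r,
        p_value=p,
        population_size=int(population.size),
        score_table=table,
    )


def adjusted_pvalue(
    kg: KnowledgeGraph,
    pair: tuple[str, str],
    cutoff: dt.date,
    train_config: TrainConfig,
    **kwargs,
) -> PValueReport:
    """Time-split p-value: truncate at ``cutoff``, retrain, rescore, rank."""
    if cutoff is None:
        raise ValueError("adjusted p-value requires a cutoff date")
    kwargs.setdefault("variant", "adjusted")
    return pair_pvalue(kg, pair, train_config, cutoff=cutoff, **kwargs)


def read_event_dates(path) -> dict[tuple[str, str], EventDates]:
    """EventDates TSV: drug_id, disease_id, approval_date, phase1..4, first_trial."""
    header = [
        "drug_id", "disease_id", "approval_date",
        "phase1_date", "phase2_date", "phase3_date", "phase4_date",
        "first_trial_date",
    ]
    out: dict[tuple[str, str], EventDates] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        got = next(reader, None)
        if got != header:
            raise kgmod.SchemaError(f"unexpected event-dates header: {got}")
        for row in reader:
            if not row:
                continue
            drug, disease, approval, p1, p2, p3, p4, first = row
            phases = {
                n: kgmod.parse_date(v)
                for n, v in zip((1, 2, 3, 4), (p1, p2, p3, p4))
                if v.strip()
            }
            out[(drug, disease)] = EventDates(
                approval_date=kgmod.parse_date(approval) if approval.strip() else None,
                phase_start_dates=phases,
                first_trial_date=kgmod.parse_date(first) if first.strip() else None,
            )
    return out


def write_event_dates(dates: dict[tuple[str, str], EventDates], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["drug_id", "disease_id", "approval_date", "phase1_date",
             "phase2_date", "phase3_date", "phase4_date", "first_trial_date"]
        )
        for (drug, disease), ev in dates.items():
            row = [drug, disease,
                   ev.approval_date.isoformat() if ev.approval_date else ""]
            for n in (1, 2, 3, 4):
                d = ev.phase_start_dates.get(n)
                row.append(d.isoformat() if d else "")
            row.append(ev.first_trial_date.isoformat() if ev.first_trial_date else "")
            writer.writerow(row)
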