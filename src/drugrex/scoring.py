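"""Composite repurposing score: link prediction + drug and disease similarity.

For a drug theta and a target lambda the three raw components are

* ``LPS``  — the embedding model's plausibility of (theta, predicate, lambda);
* ``DrSS`` — the mean normalized similarity between theta and every *other*
  drug already known to hold the target's relation to lambda
  (``sum_i T_il * S_it / sum_i T_il`` over ``i != theta``); undefined when
  no other drug treats lambda;
* ``DiSS`` — the mean normalized similarity between lambda and every *other*
  disease theta is known to treat (``sum_j T_tj * S_lj / sum_j T_tj`` over
  ``j != lambda``); undefined when theta treats nothing else.

Each raw population is Box-Cox transformed (maximum-likelihood exponent) and
min-max scaled to [0, 1], giving the primed scores; the R-score is the mean
of whichever primed components are defined.  Similarities are cosines of the
entity vectors mapped affinely from [-1, 1] to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .embedding import EmbeddingModel
from .kg import KnowledgeGraph

__all__ = [
    "TransformSpec",
    "ScoringContext",
    "ScoreTable",
    "DegenerateTransformWarning",
    "boxcox_normalize",
    "normalized_similarity",
    "raw_lps",
    "drss",
    "diss",
    "r_score",
    "score_all",
]

_SHIFT_EPS = 1e-6


class DegenerateTransformWarning(UserWarning):
    """The score population is constant; all normalized values are 0.5."""


@dataclass
class TransformSpec:
    """Frozen Box-Cox + min-max parameters, reusable on new values."""

    shift: float
    lmbda: float
    min: float
    max: float
    degenerate: bool = False


def boxcox_normalize(
    values, spec: TransformSpec | None = None
) -> tuple[np.ndarray, TransformSpec]:
    """Box-Cox transform then min-max scale a score population to [0, 1].

    Fitting shifts the values by ``-min + 1e-6`` when any is non-positive
    (translation-distance scores are <= 0), estimates the Box-Cox exponent by
    profile maximum likelihood, and records shift/exponent/bounds in the
    returned :class:`TransformSpec`.  Passing a fitted ``spec`` reapplies the
    stored parameters to new values (clipped to [0, 1]).  The map is strictly
    increasing, so rank order is preserved.  A constant population normalizes
    to 0.5 everywhere with a :class:`DegenerateTransformWarning`.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.isfinite(x).all():
        raise ValueError("need at least one finite value")
    if spec is not None:
        if spec.degenerate:
            return np.full_like(x, 0.5), spec
        y = stats.boxcox(x + spec.shift, lmbda=spec.lmbda)
        out = (y - spec.min) / (spec.max - spec.min)
        return np.clip(out, 0.0, 1.0), spec
    if np.ptp(x) == 0.0:
        warnings.warn(
            "constant score population; normalized values set to 0.5",
            DegenerateTransformWarning,
            stacklevel=2,
        )
        spec = TransformSpec(0.0, 1.0, float(x[0]), float(x[0]), degenerate=True)
        return np.full_like(x, 0.5), spec
    shift = 0.0 if x.min() > 0 else float(-x.min() + _SHIFT_EPS)
    y, lmbda = stats.boxcox(x + shift)
    if not np.isfinite(y).all() or np.ptp(y) == 0.0:
        # an extreme MLE exponent can collapse a barely varying population to
        # numerically identical values; fall back to the identity exponent
        warnings.warn(
            f"Box-Cox exponent {lmbda:.3g} degenerates numerically; "
            "falling back to lambda = 1 (plain min-max)",
            DegenerateTransformWarning,
            stacklevel=2,
        )
        lmbda = 1.0
        y = stats.boxcox(x + shift, lmbda=1.0)
    lo, hi = float(y.min()), float(y.max())
    spec = TransformSpec(shift=shift, lmbda=float(lmbda), min=lo, max=hi)
    return (y - lo) / (hi - lo), spec


def normalized_similarity(cosine: float) -> float:
    """Map a cosine in [-1, 1] affinely onto [0, 1]."""
    return (cosine + 1.0) / 2.0


@dataclass
class ScoringContext:
    """Everything needed to score drug-target pairs.

    ``known`` holds, per predicate, the set of (drug, target) pairs asserted
    in the graph: the TREATS set drives Eq.-style similarity indicators and
    the INHIBITS set its protein-target analog.  ``drugs`` and ``diseases``
    fix the scoring universes (ordered).
    """

    model: EmbeddingModel
    drugs: list[str]
    diseases: list[str]
    known: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    sim_normalization: str = "affine"

    def __post_init__(self):
        if not self.drugs or not self.diseases:
            raise ValueError("drug and disease universes must be nonempty")

    @property
    def treats(self) -> set[tuple[str, str]]:
        return self.known.get("TREATS", set())

    @classmethod
    def from_graph(
        cls,
        kg: KnowledgeGraph,
        model: EmbeddingModel,
        drugs: list[str] | None = None,
        diseases: list[str] | None = None,
        predicates: tuple[str, ...] = ("TREATS", "INHIBITS"),
    ) -> "ScoringContext":
        if drugs is None:
            drugs = [e for e in kg.entities_of_type("Drug/Chemical") if e in model.entity_index]
        if diseases is None:
            diseases = [e for e in kg.entities_of_type("Disease/Syndrome") if e in model.entity_index]
        known: dict[str, set[tuple[str, str]]] = {p: set() for p in predicates}
        for s, p, o in kg.distinct_edges:
            if p in known:
                known[p].add((s, o))
        return cls(model=model, drugs=drugs, diseases=diseases, known=known)

    def similarity(self, a: str, b: str) -> float:
        return normalized_similarity(self.model.cosine(a, b))


def raw_lps(ctx: ScoringContext, theta: str, lam: str, predicate: str = "TREATS") -> float:
    """Raw link-prediction score of (theta, predicate, lambda)."""
    if predicate not in ("TREATS", "INHIBITS"):
        raise ValueError("predicate must be TREATS or INHIBITS")
    return ctx.model.score(theta, predicate, lam)


def drss(ctx: ScoringContext, theta: str, lam: str, predicate: str = "TREATS") -> float | None:
    """Drug-similarity score; None when no other drug treats the target."""
    others = [i for i in ctx.drugs if i != theta and (i, lam) in ctx.known.get(predicate, ())]
    if not others:
        return None
    return float(np.mean([ctx.similarity(i, theta) for i in others]))


def diss(ctx: ScoringContext, theta: str, lam: str) -> float | None:
    """Disease-similarity score; None when theta treats no other disease."""
    others = [j for j in ctx.diseases if j != lam and (theta, j) in ctx.treats]
    if not others:
        return None
    return float(np.mean([ctx.similarity(lam, j) for j in others]))


def r_score(lps_prime: float, drss_prime: float | None, diss_prime: float | None) -> float:
    """Mean of the defined primed components (undefined ones are omitted)."""
    if lps_prime is None or (isinstance(lps_prime, float) and math.isnan(lps_prime)):
        raise ValueError("LPS' is required for an R-score")
    parts = [lps_prime]
    for v in (drss_prime, diss_prime):
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            parts.append(v)
    return float(np.mean(parts))


@dataclass
class ScoreTable:
    """Per-pair score table with the fitted transform specs.

    ``frame`` columns: drug_id, target_id, predicate, lps_raw, lps_prime,
    drss_raw, drss_prime, diss_raw, diss_prime, r_score; undefined similarity
    components are NaN in memory and the literal ``NA`` on disk.
    """

    frame: pd.DataFrame
    transforms: dict[tuple[str, str], TransformSpec] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")

    @staticmethod
    def from_tsv(path) -> "ScoreTable":
        return ScoreTable(pd.read_csv(path, sep="\t", na_values=["NA"]))

    def pair(self, drug: str, target: str) -> pd.Series:
        rows = self.frame[(self.frame.drug_id == drug) & (self.frame.target_id == target)]
        if rows.empty:
            raise KeyError(f"pair ({drug}, {target}) not in score table")
        return rows.iloc[0]

    def r_scores(self) -> np.ndarray:
        return self.frame["r_score"].to_numpy()


def _normalized_sim_matrix(model: EmbeddingModel, rows: list[str], cols: list[str]) -> np.ndarray:
    A = np.stack([model.vector(e) for e in rows])
    B = np.stack([model.vector(e) for e in cols])
    return (_sk_cosine(A, B) + 1.0) / 2.0


def score_all(
    ctx: ScoringContext,
    targets: list[tuple[str, str]] | None = None,
) -> ScoreTable:
    """Score every drug against every target and assemble the R-scores.

    ``targets`` is a list of (target id, predicate); by default every disease
    in the context via TREATS.  One transform is fitted per score type per
    predicate over that run's population, then applied uniformly, so scores
    are comparable within a run.  The vectorized computation is exactly the
    pairwise composition of :func:`raw_lps`, :func:`drss`, :func:`diss`,
    :func:`boxcox_normalize` and :func:`r_score`.
    """
    if targets is None:
        targets = [(d, "TREATS") for d in ctx.diseases]
    if not targets or not ctx.drugs:
        raise ValueError("empty drug or target list")
    model = ctx.model
    drugs = ctx.drugs
    n_d = len(drugs)
    drug_pos = {d: i for i, d in enumerate(drugs)}
    disease_pos = {d: j for j, d in enumerate(ctx.diseases)}

    by_pred: dict[str, list[str]] = {}
    for tid, pred in targets:
        by_pred.setdefault(pred, []).append(tid)

    S_dd = _normalized_sim_matrix(model, drugs, drugs)
    # TREATS indicator over the disease universe, for DiSS
    Td = np.zeros((n_d, len(ctx.diseases)))
    for (i, j) in ctx.treats:
        if i in drug_pos and j in disease_pos:
            Td[drug_pos[i], disease_pos[j]] = 1.0
    treats_per_drug = Td.sum(axis=1)

    records: list[dict] = []
    transforms: dict[tuple[str, str], TransformSpec] = {}
    for pred, tids in by_pred.items():
        n_t = len(tids)
        t_pos = {t: k for k, t in enumerate(tids)}
        # LPS: score theta-pred-target for all pairs
        lps = np.empty((n_d, n_t))
        for k, tid in enumerate(tids):
            scores = model.score_candidates(None, pred, tid)
            lps[:, k] = scores[[model.entity_index[d] for d in drugs]]
        # DrSS: mean similarity to the other drugs holding pred to the target
        Tp = np.zeros((n_d, n_t))
        for (i, lam) in ctx.known.get(pred, ()):
            if i in drug_pos and lam in t_pos:
                Tp[drug_pos[i], t_pos[lam]] = 1.0
        num = S_dd @ Tp - Tp * np.diag(S_dd)[:, None]
        den = Tp.sum(axis=0)[None, :] - Tp
        with np.errstate(invalid="ignore", divide="ignore"):
            drss_raw = np.where(den > 0, num / den, np.nan)
        # DiSS: mean similarity between the target and the other diseases
        # the drug treats
        S_tt = _normalized_sim_matrix(model, tids, ctx.diseases)
        self_term = np.zeros((n_d, n_t))
        self_count = np.zeros((n_d, n_t))
        for k, tid in enumerate(tids):
            j = disease_pos.get(tid)
            if j is not None:
                self_term[:, k] = Td[:, j] * S_tt[k, j]
                self_count[:, k] = Td[:, j]
        num2 = (Td @ S_tt.T) - self_term
        den2 = treats_per_drug[:, None] - self_count
        with np.errstate(invalid="ignore", divide="ignore"):
            diss_raw = np.where(den2 > 0, num2 / den2, np.nan)

        with warnings.catch_warnings():
            warnings.simplefilter("always", DegenerateTransformWarning)
            lps_prime, transforms[("lps", pred)] = boxcox_normalize(lps.ravel())
        lps_prime = lps_prime.reshape(lps.shape)
        drss_prime = np.full_like(drss_raw, np.nan)
        mask = ~np.isnan(drss_raw)
        if mask.any():
            vals, transforms[("drss", pred)] = boxcox_normalize(drss_raw[mask])
            drss_prime[mask] = vals
        diss_prime = np.full_like(diss_raw, np.nan)
        mask2 = ~np.isnan(diss_raw)
        if mask2.any():
            vals2, transforms[("diss", pred)] = boxcox_normalize(diss_raw[mask2])
            diss_prime[mask2] = vals2

        comp = np.stack([lps_prime, drss_prime, diss_prime])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.nanmean(comp, axis=0)

        for i, d in enumerate(drugs):
            for k, tid in enumerate(tids):
                records.append(
                    {
                        "drug_id": d,
                        "target_id": tid,
                        "predicate": pred,
                        "lps_raw": lps[i, k],
                        "lps_prime": lps_prime[i, k],
                        "drss_raw": drss_raw[i, k],
                        "drss_prime": drss_prime[i, k],
                        "diss_raw": diss_raw[i, k],
                        "diss_prime": diss_prime[i, k],
                        "r_score": r[i, k],
                    }
                )
    return ScoreTable(pd.DataFrame.from_records(records), transforms)
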