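"""Multi-target scoring profiles, Ward clustering and candidate nomination.

A scoring profile is a drugs x targets matrix of R-scores (diseases and
symptoms via TREATS, protein targets via INHIBITS).  Drugs are first reduced
to one representative per category (the category's best scorer for the focal
target), profiles are clustered with Ward's minimum-variance linkage on
Euclidean distances, the smallest clade containing all seed drugs (e.g., the
approved drugs for the focal disease) is extracted, and each candidate in
that clade is ranked by the Pearson correlation of its profile with its
closest seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "ScoringProfile",
    "Dendrogram",
    "build_profile",
    "representatives_per_category",
    "ward_cluster",
    "extract_clade",
    "closest_seed",
    "candidate_report",
]


@dataclass
class ScoringProfile:
    """Drugs x targets R-score matrix with imputation bookkeeping."""

    frame: pd.DataFrame                      # rows: drugs, columns: targets
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def drugs(self) -> list[str]:
        return list(self.frame.index)

    def row(self, drug: str) -> np.ndarray:
        return self.frame.loc[drug].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="drug_id", float_format="%.10g")

    @staticmethod
    def from_tsv(path) -> "ScoringProfile":
        return ScoringProfile(pd.read_csv(path, sep="\t", index_col="drug_id"))


def build_profile(score_frames: list[pd.DataFrame] | pd.DataFrame, impute: bool = True) -> ScoringProfile:
    """Pivot score-table rows into a drugs x targets R-score matrix.

    Missing R-scores (pairs never scored) are imputed with the column median
    when ``impute`` is set, since Ward clustering needs complete vectors;
    imputed cells are recorded.
    """
    if isinstance(score_frames, list):
        frame = pd.concat(score_frames, ignore_index=True)
    else:
        frame = score_frames
    mat = frame.pivot_table(index="drug_id", columns="target_id", values="r_score", aggfunc="first")
    imputed: list[tuple[str, str]] = []
    if impute:
        for col in mat.columns:
            missing = mat.index[mat[col].isna()]
            if len(missing):
                med = mat[col].median()
                imputed.extend((d, col) for d in missing)
                mat.loc[missing, col] = med
    return ScoringProfile(mat, imputed)


def representatives_per_category(
    scores: pd.DataFrame,
    category_map: dict[str, str],
    focal_target: str,
) -> list[str]:
    """One drug per category: the category's top R-score for the focal target.

    Ties break lexicographically by drug id; drugs without a category entry
    form their own singleton categories (and therefore survive).
    """
    focal = scores[scores["target_id"] == focal_target]
    if focal.empty:
        raise ValueError(f"no scores for focal target {focal_target!r}")
    best: dict[str, tuple[float, str]] = {}
    for drug, r in zip(focal["drug_id"], focal["r_score"]):
        cat = category_map.get(drug, f"__singleton__{drug}")
        r = float(r) if not pd.isna(r) else -np.inf
        cur = best.get(cat)
        if cur is None or r > cur[0] or (r == cur[0] and drug < cur[1]):
            best[cat] = (r, drug)
    return sorted(d for _, d in best.values())


@dataclass
class Dendrogram:
    """Agglomerative merge tree over profile rows (scipy linkage encoding)."""

    linkage_matrix: np.ndarray   # (n-1, 4): left, right, height, size
    leaves: list[str]
    method: str = "ward"

    def __post_init__(self):
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be nondecreasing (ultrametric)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cluster_members(self) -> list[set[int]]:
        """Leaf-index membership of every internal node, in merge order."""
        n = self.n_leaves
        members: list[set[int]] = []
        for a, b, _, _ in self.linkage_matrix:
            a, b = int(a), int(b)
            sa = {a} if a < n else members[a - n]
            sb = {b} if b < n else members[b - n]
            members.append(sa | sb)
        return members

    def to_newick(self) -> str:
        """Newick string with merge heights as node heights (branch lengths
        are the height differences between a node and its parent)."""
        n = self.n_leaves
        heights = [0.0] * n + [float(h) for h in self.linkage_matrix[:, 2]]

        def render(node: int, parent_h: float) -> str:
            bl = max(parent_h - heights[node], 0.0)
            if node < n:
                return f"{self.leaves[node]}:{bl:.10g}"
            a, b = int(self.linkage_matrix[node - n, 0]), int(self.linkage_matrix[node - n, 1])
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        root = n + len(self.linkage_matrix) - 1
        return render(root, heights[root]) + ";"


def ward_cluster(profile: ScoringProfile) -> Dendrogram:
    """Ward's minimum-variance agglomeration on Euclidean row distances."""
    X = profile.frame.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least two profile rows")
    if np.isnan(X).any():
        raise ValueError("profile has missing entries; impute before clustering")
    Z = linkage(X, method="ward")
    return Dendrogram(Z, list(profile.frame.index))


def extract_clade(tree: Dendrogram, seeds: set[str]) -> set[str]:
    """Leaves of the smallest subtree containing every seed.

    A single seed yields just that seed; seeds spanning the root yield the
    whole leaf set.  Candidates are the returned set minus the seeds.
    """
    leaf_pos = {name: i for i, name in enumerate(tree.leaves)}
    missing = [s for s in seeds if s not in leaf_pos]
    if missing:
        raise KeyError(f"seeds not among dendrogram leaves: {missing}")
    if not seeds:
        raise ValueError("need at least one seed")
    want = {leaf_pos[s] for s in seeds}
    if len(want) == 1:
        return set(seeds)
    for members in tree.cluster_members():   # merge order = increasing height
        if want <= members:
            return {tree.leaves[i] for i in members}
    raise AssertionError("root must contain all seeds")  # pragma: no cover


def closest_seed(
    profile: ScoringProfile, candidate: str, seeds: set[str]
) -> tuple[str, float]:
    """Seed whose profile row best Pearson-correlates with the candidate's."""
    if not seeds:
        raise ValueError("need at least one seed")
    x = profile.row(candidate)
    best: tuple[str, float] | None = None
    for seed in sorted(seeds):
        y = profile.row(seed)
        r = float(np.corrcoef(x, y)[0, 1])
        if best is None or r > best[1]:
            best = (seed, r)
    return best


def candidate_report(
    profile: ScoringProfile,
    candidates: list[str],
    seeds: set[str],
    focal_scores: dict[str, float] | None = None,
    p_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-candidate closest seed, correlation, focal R-score and p-value."""
    rows = []
    for cand in candidates:
        seed, r = closest_seed(profile, cand, seeds)
        rows.append(
            {
                "drug_id": cand,
                "closest_seed": seed,
                "pearson_r": r,
                "r_score_focal": (focal_scores or {}).get(cand, np.nan),
                "p_value": (p_values or {}).get(cand, np.nan),
            }
        )
    out = pd.DataFrame.from_records(rows)
    return out.sort_values("r_score_focal", ascending=False, ignore_index=True)
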