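"""Shared fixtures: small and default-scale synthetic graphs and fitted models.

The expensive artifacts (default-scale generation + training) are
session-scoped so the signal-recovery, significance and profiling tests share
one pipeline run per seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from drugrex import embedding, scoring, synthetic


@pytest.fixture(scope="session")
def small_kg():
    """A compact planted graph: 30 drugs, 10 diseases, 3 families."""
    cfg = synthetic.SynthConfig(
        n_drugs=30, n_diseases=10, n_proteins=9, n_functions=6,
        n_families=3, n_heldout=3, seed=7,
    )
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def small_model(small_kg):
    """A quickly trained TransE model over the small graph (all edges)."""
    kg, _ = small_kg
    cfg = embedding.desk_scale_config(seed=7, dim=32, max_steps=600, batch_size=128)
    return embedding.train(list(kg.distinct_edges), cfg, entities=list(kg.entities))


@pytest.fixture(scope="session")
def small_context(small_kg, small_model):
    kg, _ = small_kg
    return scoring.ScoringContext.from_graph(kg, small_model)


@pytest.fixture(scope="session")
def default_runs():
    """Full pipeline (generate, train on all edges, score all pairs) for the
    default study conditions, over three generator/training seeds."""
    runs = []
    for seed in (1, 2, 3):
        kg, truth = synthetic.generate(synthetic.SynthConfig(seed=seed))
        cfg = embedding.desk_scale_config(seed=seed)
        model = embedding.train(list(kg.distinct_edges), cfg, entities=list(kg.entities))
        ctx = scoring.ScoringContext.from_graph(kg, model)
        table = scoring.score_all(ctx)
        runs.append({"kg": kg, "truth": truth, "model": model, "ctx": ctx, "table": table, "seed": seed})
    return runs


def random_model(rng: np.random.Generator, n_entities: int = 15, dim: int = 8,
                 relations: tuple[str, ...] = ("TREATS", "INHIBITS")) -> embedding.EmbeddingModel:
    """An arbitrary (untrained) model for oracle comparisons."""
    ents = [f"E{i}" for i in range(n_entities)]
    E = rng.normal(size=(n_entities, dim))
    R = rng.normal(size=(len(relations), dim))
    return embedding.EmbeddingModel(E, R, ents, list(relations), "TransE", "l2")
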