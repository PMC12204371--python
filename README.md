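# drugrex

Computational drug repurposing over an evidence-backed literature knowledge
graph, with explainability plumbing.

Biomedical literature mining yields millions of subject–predicate–object
assertions ("drug *inhibits* protein", "protein *causes* disease"), each
backed by a source document, a supporting sentence and a publication date.
`drugrex` turns such a corpus into repurposing hypotheses in four stages:

1. **Knowledge graph** (`drugrex.kg`) — typed entities (Drug/Chemical,
   Gene/Protein, Disease/Syndrome, Pathway/Function, Others) connected by ten
   positive relation types (TREATS, INHIBITS, CAUSES, STIMULATES,
   ASSOCIATED_WITH, COEXIST_WITH, COMPLICATES, INTERACTS_WITH,
   MANIFESTATION_OF, PRODUCES). Negated assertions (`NEG_*`), generic
   concepts and out-of-scope semantic groups are filtered out. Every edge
   keeps its dated evidence, so the whole graph can be replayed as it stood
   at any past date.

2. **Embedding** (`drugrex.embedding`) — knowledge-graph embeddings
   (TransE, DistMult, ComplEx, RotatE) trained by SGD with negative
   sampling, evaluated by mean rank, mean reciprocal rank and Hits@k under
   the raw or filtered ranking protocol.

3. **Scoring** (`drugrex.scoring`, `drugrex.significance`) — for a drug θ
   and a disease λ the composite Repurposing Score is the mean of up to
   three [0, 1]-normalized components:

   - **LPS′**: the embedding model's plausibility of (θ, TREATS, λ)
     (for protein targets, (θ, INHIBITS, λ));
   - **DrSS′**: mean similarity of θ to the other drugs known to treat λ,
     `DrSS_θλ = Σᵢ T_iλ · S_iθ / Σᵢ T_iλ` over i ≠ θ, where `T_iλ` indicates
     a known TREATS edge and `S` is the normalized cosine similarity of
     entity vectors;
   - **DiSS′**: mean similarity of λ to the other diseases θ treats,
     `DiSS_θλ = Σⱼ T_θj · S_λj / Σⱼ T_θj` over j ≠ λ.

   Each raw population is Box-Cox transformed and min-max scaled; undefined
   components (zero denominators) are omitted from the mean. Significance is
   the empirical p-value of the R-score against the all-pairs distribution,
   and *adjusted* p-values replay history: truncate the graph at a reference
   date (approval, phase-n trial start, first trial, or approval − 4 years),
   retrain, rescore everything, re-rank.

4. **Profiling and explanation** (`drugrex.profiling`, `drugrex.explain`) —
   drugs are profiled by their R-scores across a target panel, reduced to one
   representative per category, clustered with Ward's method; candidates are
   the members of the smallest clade containing the approved seed drugs,
   ranked by Pearson correlation to their closest seed. For each candidate an
   evidence sub-graph is extracted (with the candidate's own TREATS edges to
   the target disease deliberately withheld), its sentences are indexed and
   capped at 50, and prompt bundles are assembled for an LLM client (a
   deterministic mock ships); a citation audit measures which cited indices
   point at supporting rather than control material.

A synthetic-data generator (`drugrex.synthetic`) emits literature-style
graphs with planted drug families, dated mechanism edges and withheld
true repurposing pairs, so the entire pipeline is testable offline.

## Worked example

```python
import numpy as np
from drugrex import embedding, scoring, significance, synthetic

# a literature-style graph with 10 drug families and 20 withheld true pairs
kg, truth = synthetic.generate(synthetic.SynthConfig(seed=1))
print(f"{len(kg.entities)} entities, {len(kg.distinct_edges)} distinct edges, "
      f"{len(kg.triples)} evidence sentences")

train, valid, test = embedding.split_triples(kg, (0.8, 0.1, 0.1), seed=1)
results = embedding.KGEmbedding(train, embedding.desk_scale_config(seed=1),
                                entities=list(kg.entities)).fit()
report = results.evaluate(test, list(kg.distinct_edges), protocol="filtered")
print(f"filtered MR {report.mr:.2f}, MRR {report.mrr:.3f}, "
      f"Hits@10 {report.hits_at[10]:.3f}")

full = embedding.KGEmbedding.from_graph(kg, embedding.desk_scale_config(seed=1)).fit()
ctx = scoring.ScoringContext.from_graph(kg, full.model)
table = scoring.score_all(ctx)
drug, disease = next(iter(truth.heldout_pairs))
row = table.pair(drug, disease)
print(f"withheld pair ({drug}, {disease}): "
      f"LPS' {row.lps_prime:.3f}, DrSS' {row.drss_prime:.3f}, "
      f"DiSS' {row.diss_prime:.3f}, R-score {row.r_score:.3f}")
p = significance.empirical_pvalue(row.r_score, table.r_scores())
print(f"empirical p against {len(table.frame)} drug-disease pairs: {p:.4f}")
```

prints

```
320 entities, 2062 distinct edges, 3080 evidence sentences
filtered MR 7.91, MRR 0.860, Hits@10 0.927
withheld pair (DRUG0002, DIS0042): LPS' 0.983, DrSS' 0.953, DiSS' 0.976, R-score 0.970
empirical p against 10000 drug-disease pairs: 0.0386
```

The withheld pair was never seen as a TREATS edge — the model recovers it
from the shared family mechanism: its R-score of 0.970 is exceeded by under
4% of all 10,000 drug–disease pairs, most of which are themselves known
treatments or family-consistent candidates.

The same stages are exposed as a CLI (`drugrex synth | build | embed | eval |
score | pvalue | profile | explain`); see `drugrex --help`.

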