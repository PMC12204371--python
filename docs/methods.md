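# Methods

## The model

`drugrex` scores the hypothesis "drug θ treats disease λ" by combining three
signals computed from a single trained knowledge-graph embedding:

- **Link prediction (LPS).** Entities and relations are embedded in a shared
  d-dimensional space; a scoring function assigns each (head, relation, tail)
  triple a real plausibility, higher = more plausible. The default model is
  TransE with the L1 distance — the relation is a translation vector and the
  score is `−‖h + r − t‖₁`. DistMult (trilinear product), ComplEx (real part
  of the Hermitian product over paired real/imaginary coordinates) and RotatE
  (element-wise rotation in the complex plane, score `−Σ|h∘e^{iφ} − t|`) are
  selectable alternatives with identical training plumbing. LPS is the score
  of (θ, TREATS, λ); protein targets use (θ, INHIBITS, λ).

- **Drug similarity (DrSS).** The mean normalized cosine similarity between θ
  and every *other* drug already known to treat λ. If no other drug treats λ
  the quantity is undefined (zero denominator) and recorded as not
  applicable, not as zero: absence of prior treatments is missing evidence,
  not negative evidence.

- **Disease similarity (DiSS).** Symmetrically, the mean normalized
  similarity between λ and every other disease θ is known to treat;
  undefined when θ treats nothing else. Cosines are mapped to [0, 1] by the
  affine rule S = (cos + 1)/2 (an order-preserving, invertible choice; a
  population min-max alternative is configurable).

Each raw score population is Box-Cox transformed (exponent fitted by profile
maximum likelihood per score type per predicate per run) and min-max scaled
to [0, 1]; the fitted shift/exponent/bounds are stored so the same transform
can be reapplied to held-out values. The **R-score** is the arithmetic mean of
the primed components that exist. Normalization is population-relative by
construction: an R-score is only meaningful against the population it was
normalized with, which is why significance is empirical.

### Significance

The p-value of a pair's R-score is the fraction of all drug × disease
R-scores strictly exceeding it ("exceedance count"); a `gte` flag switches to
a ≥ count for users who prefer p > 0 always. No multiple-testing correction
is applied across candidates — callers comparing many pairs should apply
their own. **Adjusted** p-values replay history: the graph is truncated to
evidence published up to a reference date (drug approval `adj_a`, phase-n
trial start `adj_n`, first trial `adj_0`, or approval minus four calendar
years `adj_a_minus_4`, the typical phase-3 duration used when registry dates
are unavailable), embeddings are retrained from scratch on the truncated
graph, every pair is rescored, and the query is ranked against that
historical population. Pairs whose drug or disease has not yet appeared in
the literature are reported as not applicable. The queried pair's own TREATS
edges are removed before training in both plain and adjusted modes (so the
score is a prediction, not edge recall); this is toggleable.

### Candidate nomination

Scoring profiles (drugs × target panel R-score matrices) are reduced to one
representative drug per category (the category's best scorer for the focal
target, ties broken lexicographically; uncategorized drugs survive as
singletons), then clustered with Ward's minimum-variance linkage on Euclidean
row distances — the linkage Ward's criterion is actually defined for.
Candidates are the leaves of the smallest dendrogram clade containing all
seed drugs (e.g., the approved drugs for the focal disease), minus the seeds;
a fixed-k cut is available as an alternative clade rule. Each candidate is
ranked by the Pearson correlation between its profile row and its closest
seed's row.

### Explanation prompts

For a nominated candidate, the evidence sub-graph contains the candidate, the
disease terms, user-supplied protein/symptom terms, and the Pathway/Function
entities directly adjacent (any relation, either direction) to both the
candidate and a disease term ("mutual function neighbors"; multi-hop
neighborhoods are deliberately not explored). The candidate's own TREATS
edges into the disease terms are withheld so a generated explanation must
argue from mechanism rather than restate the conclusion. Supporting sentences
are indexed in provenance order and capped at 50 (uniform random subset
beyond the cap, seeded). Four prompt variants exist: indexed sentences;
indexed sentences mixed with an equal number of unrelated control sentences,
shuffled; relation triples only; and names only. "Unrelated" means the
sentence's edge touches neither the candidate nor any disease term. The
citation audit parses bracketed indices (`[3]`, `[3, 5]`, and defensively
`[3-5]` ranges, flagged when expanded) and reports the fraction of valid
cited indices that are supporting. The LLM itself is an abstract client
(recorded default configuration: a neurologist/scientific-writer system role,
temperature 0); only a deterministic mock ships — live calls, hypothesis
quality scoring and expert comparison are out of scope.

## Training

The loss is the negative-sampling logistic loss
`softplus(−(γ + s⁺)) + (1/K) Σₖ softplus(γ + s⁻ₖ)` with uniform corruption of
head or tail (equal probability), optimized by plain SGD — a single fixed
learning rate, no schedule. Entity vectors are initialized
uniformly in ±6/√d and L2-renormalized each step for TransE (the original
TransE recipe, which keeps the default learning rate of 0.1 stable); RotatE
relation phases are initialized uniformly on the circle. "L1 regularization"
for TransE is interpreted as the L1 distance norm in the scoring function,
with an optional explicit L1/L2 embedding-norm penalty exposed separately.
Gradients of all four scoring functions are analytic and verified against
central differences. Training aborts with a diagnostic on a non-finite loss.
Runs are exactly reproducible given the config seed.

Default hyperparameters are the full-scale settings: batch 2,070, 30
negatives per positive, dimension 400, learning rate 0.1, 10,000 steps.
These are sized for graphs with millions of edges. For generator-scale
graphs the package ships `desk_scale_config()` — TransE-L1, d = 64, batch
512, 8 negatives, margin 4, 2,000 steps — which recovers the planted
structure (filtered Hits@10 ≥ 0.9) in well under a minute. The margin
matters per model family: translational scores are bounded distances and
tolerate larger margins, while the bilinear models (DistMult/ComplEx) have
unbounded scores and train reliably only with small margins (≈1).

Evaluation ranks each test edge's true head and tail against all entity
corruptions; the filtered protocol (default) excludes corruptions that form
other known true edges; ties receive the average rank, avoiding optimistic
bias from exact-tie artifacts. MR, MRR and Hits@k aggregate over both
corruption directions. MRR is the mean of reciprocal ranks.

## Dates and replays

Publication dates may be partial; `YYYY` and `YYYY-MM` are completed to the
first day of the period, so earlier cutoffs *include* partially dated
evidence rather than silently dropping it. The time-split boundary is
inclusive (date ≤ cutoff) at day resolution for the same reason; a strict-<
flag is available. Identical (subject, predicate, object, source, sentence)
rows are collapsed at read time, since abstract plus full-text ingestion can
duplicate a sentence. Each distinct edge counts once for embedding training;
evidence multiplicity does not weight the loss (whether it should is an open
modeling question — it is simply not done here). Generic-concept removal is
by identifier blocklist only; name matching is ambiguous. The calendar
arithmetic for "approval minus four years" clamps Feb 29 to Feb 28 when the
target year is not a leap year.

## The synthetic generator

The generator emulates the structural assumption the scoring system relies
on: *drugs that treat similar diseases share mechanisms.* Drugs belong to
families; family members INHIBIT the same proteins and STIMULATE the same
molecular functions; each disease is CAUSED by its family's proteins and
ASSOCIATED_WITH its functions; TREATS edges connect family drugs to family
diseases. Defaults: 200 drugs, 50 diseases, 40 proteins, 30 functions, 10
families, a mean of 4 known treatments per disease (Poisson, at least one),
5% uniformly random noise edges, evidence dates uniform over 1990–2020, and
20 family-consistent TREATS pairs withheld from the graph as ground-truth
repurposing targets. Withheld pairs receive synthetic approval dates in the
later part of the date range, and their mechanism edges are dated strictly
before approval, so time-split replays at the approval date still see the
mechanism. Every edge carries one or more templated evidence sentences with
synthetic PMID-style identifiers.

What the generator does *not* emulate — and hence what passing tests do not
show about real literature graphs: scale (hundreds of entities versus
hundreds of thousands), degree heterogeneity (real graphs are heavy-tailed;
families here are near-uniform), reporting biases and citation dynamics,
negation errors and extraction noise beyond uniform random edges, and any
linguistic content in sentences. Results on the generator demonstrate
correctness and signal recovery under the assumed structure, not real-world
effect sizes.

## Numerical choices and degenerate inputs

- Box-Cox requires positive inputs; non-positive populations are shifted by
  −min + 10⁻⁶ before transforming (translation scores are ≤ 0).
- A constant score population cannot be min-max scaled; it normalizes to 0.5
  everywhere with an explicit warning, keeping downstream R-scores defined
  and the degeneracy auditable.
- On small populations the Box-Cox maximum-likelihood exponent can diverge
  and collapse all transformed values to numerically identical floats; the
  transform then falls back to the identity exponent (plain min-max), with a
  warning. Reapplying a stored transform to new values clips to [0, 1].
- Split proportions use largest-remainder rounding (leftover edges to the
  earlier splits), so a 10-edge 8:1:1 split is exactly (8, 1, 1).
- Ward clustering delegates to `scipy.cluster.hierarchy.linkage`; its
  nearest-neighbor-chain algorithm is deterministic for a given row order,
  and profile rows are continuous so exact merge ties are measure-zero.
  Missing profile entries are imputed with the column median before
  clustering (Ward requires complete vectors); every imputed cell is logged.
- Empirical p-values use the strict exceedance count, so the top score gets
  p = 0; text output renders it as `< 1/population_size`.

## Known limitations

- Exact computation only: the all-pairs scoring is meant for desk-scale
  universes (10⁴–10⁶ pairs), not the billions implied by a full literature
  graph; there is no approximate nearest-neighbor shortcut.
- The NLP upstream (entity/relation extraction, negation detection, relation
  filtering) is consumed as TSV, never executed.
- Adjusted p-values retrain one model per (pair, cutoff); replaying many
  pairs is linear in training cost.
- The plain p-value population includes pairs whose similarity components are
  undefined (their R-score is the reduced mean); excluding them is a caller
  decision.
- Clade extraction is a declared convention (smallest subtree spanning the
  seeds), not a claim about how any particular published candidate list was
  cut.
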