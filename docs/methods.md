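# Methods

This note documents the model behind the package, the choices made
where a design was genuinely open, the synthetic study conditions the
tests run under, and what those tests do and do not establish about
real data.

## Data model and assumptions

The target PPI network is an undirected simple graph G = (V, E, w)
with w(e) ∈ (0, 1] read as the probability that interaction e is real.
The method assumes (i) functional modules induce dense, high-confidence
regions, and (ii) members of one module tend to be co-expressed. Both
assumptions are what the synthetic generator plants and what the
detection stages exploit; neither is verified on input data.

Identifiers are opaque case-sensitive strings. A duplicated edge keeps
the maximum score with a warning: scores are probabilities, and the
maximum is the conservative choice for the connectivity probabilities
computed downstream. Proteins with expression but no network vertex
are retained in the expression matrix and ignored downstream.

## Correlation threshold selection

With r profiled genes, the complete correlation graph K_r carries the
pairwise Pearson correlations. For each cutoff on the grid
d_j = 0.6 + 0.01·j, j ∈ [0, 39], H(d) keeps edges with correlation
strictly above d, and we compare C(H) — the mean local clustering
coefficient, vertices of degree < 2 contributing 0 (Watts–Strogatz
convention; a flag excludes them) — against C₀(H), its mean over
degree-preserving double-edge-swap randomizations (default 5
replicates of 10·|E| swaps, seeded). The chosen threshold is

    t = argmax_j [ C(K_r, d_j) − C₀(K_r, d_j) ],

ties toward the smaller d_j. The rationale: at the cutoff where the
correlation graph is most non-randomly clustered, its edges are most
informative about shared regulation. Whether the criterion should be
this argmax or a first-crossing rule is one of the genuinely open
design points; argmax of the gap is what we implement and test, and
the scan report exposes both curves so users can inspect the
alternative. Averaging C₀ over replicates (rather than one
realization) is likewise our choice, made for variance reduction.

Zero-variance profiles get correlation 0 with a warning, so they can
never pass a cutoff ≥ 0.6. Edge filtering removes (a, b) iff both
endpoints are profiled and corr(a, b) ≤ t — the same "at or below t"
convention the seed-cleaning index uses — and never touches edges with
an unprofiled endpoint.

## Seed generation

BMSI(S, u) counts profiled partners of u within S correlating at or
below t; unprofiled pairs contribute 0, because the expression graph
is defined only over profiled genes. Cleaning removes the max-BMSI
vertex one at a time, recomputing after each removal (the sequential
reading of "keep removing the maximum"), ties broken by lexicographic
id for determinism.

q-connectivity of S (default q = 0.95, an error probability of 0.05):
every bipartition (U, S−U) must be bridged with probability
1 − Π(1−w(e)) ≥ q over its crossing edges. Taking −log(1−w) as edge
capacity turns the worst bipartition into the global minimum cut, so
the decision is a single Stoer–Wagner cut compared against −log(1−q);
the test suite verifies the equivalence against exhaustive enumeration
of all 2^(|S|−1)−1 bipartitions. Numerical choices: w = 1 edges get
capacity 745 (≈ −log of the smallest positive normal double), so any
cut containing one passes every q < 1; the cut comparison carries a
1e−9 slack so "at least q" boundaries do not flip on rounding. In an
unweighted network (all w = 1) every connected set is q-connected and
the seed stage degenerates to connected-neighbourhood extraction —
documented, not an error.

When a component is not q-connected it is split at its minimum cut and
both sides are searched recursively; "maximal" is read as
maximum-cardinality (ties: lexicographically smallest member set), and
q-connectivity is evaluated on the component's own induced subgraph,
not component ∪ {v}. Among the cleaned components, MQC(v) is the
largest result; MS(v) = MQC(v) ∪ {v} when |MQC(v)| > 1, else empty, so
every non-empty seed has ≥ 3 members and is connected.

## Growth, screening, merging

Growth joins all u with 2·|N(u) ∩ M| > |M| simultaneously against the
current member set, then iterates; the batch semantics matter (two
candidates can join together when sequential joining would exclude the
second) and are pinned by test. The membership bar is strict majority,
so a candidate touching exactly half of an even-sized module stays
out.

The weak-community screen keeps a grown module iff its total internal
degree exceeds its total external degree (Radicchi's weak criterion)
on the unweighted topology; a weighted variant is available behind a
flag. The screen runs after growth completes, and failing modules are
dropped, not reverted to their seeds; dropped seeds are not recycled.

Merging collapses identical member sets (pooling seed provenance),
then repeatedly merges the pair with the largest overlap ratio
|U_i ∩ U_j| / min(|U_i|, |U_j|) among pairs satisfying
2·|U_i ∩ U_j| > min(|U_i|, |U_j|), ties toward the earliest pair in
the current ordering, until no pair qualifies. The order rule exists
only to make runs reproducible. Final modules of size < 3 are dropped
by default (the usual size > 2 reporting convention for complex
prediction); overlap between final modules is allowed and expected.

## Evaluation suite

Enrichment uses the hypergeometric upper tail P(X ≥ x) for a cluster
of n proteins containing x of the M term-annotated proteins in an
N-protein background. The background defaults to every annotated
protein in the aspect and can be restricted (e.g. to network
proteins); which universe the original evaluation protocol used is not
recoverable, so the choice is explicit in the API. Sensitivity is the
fraction of terms enriched in ≥ 1 cluster at p < 10⁻⁴ (no
multiple-testing correction, matching the protocol; a Bonferroni flag
exists, default off), specificity the fraction of clusters enriched
for ≥ 1 term, and F their harmonic mean — the natural reading of an
"F-measure" over the two rates. Terms annotating the entire background
(the aspect roots, p(a) = 1) are excluded from the sensitivity
universe: their tail p-value is identically 1, so counting them would
make sensitivity = 1 structurally unattainable while conveying no
information.

Term similarity is Schlicker's relevance measure
max_c [2·ln p(c) / (ln p(a₁) + ln p(a₂))] · (1 − p(c)) over common
ancestors c (including the terms themselves) after upward propagation
along is_a/part_of; p(a) is the annotated fraction of the aspect.
Protein pairs are scored by best-match averaging over their direct
annotation sets (max-over-pairs behind a flag); the cluster score is
the mean over annotated pairs, the clustering score the cluster-size
weighted mean (unweighted behind a flag), and co-annotation the
geometric mean of the BP and MF clustering scores. Co-localization is
Σ_j max_k |C_j ∩ O_k| / Σ_j |C_j| — proteins absent from every
location stay in the denominator, so the score is the fraction of
clustered proteins co-located with their cluster's plurality
compartment. Average similarity of a collection of vertex sets pools
all within-set annotated pairs (pair-count weighting). Gold-standard
matching treats each catalogued complex as a term over a protein
universe and applies the same hypergeometric screen; the
complex-matching criterion behind published "matched to known
complexes" counts is not stated anywhere recoverable, and the
hypergeometric screen is our defensible choice.

## Synthetic study conditions

The generator plants what the model assumes. Defaults: 3 modules of
8–12 proteins at within-block density 0.9 with confidences in
[0.9, 0.99]; 30 background proteins at density 0.02 with confidences
in [0.1, 0.5]; expression as a per-module latent profile over 20
conditions plus Gaussian noise calibrated (sd = √(1/ρ − 1)) to a
within-module Pearson correlation of ρ = 0.9. The `easy` preset plants
disjoint modules for exact-recovery checks; `overlap` shares 10% of
consecutive modules' vertices to exercise merging; `hard` lowers
densities and coherence. Optional decoy vertices are wired to a module
with within-range confidences but anticorrelated profiles — removable
only by the expression filter. Optional attachment vertices connect to
a strict majority of a module's core with low confidences (0.25–0.4):
growth adopts them, the q-connected core excludes them, and their
annotations sit one ontology level above the core's leaf term. That
two-level ("nested coherence") annotation is what makes the
seed ≥ module ≥ network similarity ordering a structural property
rather than an accident of weighting.

Problem sizes throughout the tests and the acceptance script (tens of
vertices, hundreds of edges, 500-graph oracle sweeps, backgrounds up
to N = 25 for exact enrichment sums) are chosen so the whole suite
re-runs from scratch in well under a minute on one CPU while still
exercising every stage at full strength.

What passing these tests shows: the implementation agrees with its
exact combinatorial and cut-enumeration oracles, and the pipeline
behaves as designed when its assumptions hold cleanly. What it does
not show: performance on real interactomes, whose confidence scores
are not independent probabilities, whose modules are not
density-separated blocks, and whose annotation corpora are vastly
deeper and biased; absolute evaluation scores are also sensitive to
the ontology release used.

## Known limitations

- Pearson correlation only; no rank or information-theoretic
  alternatives.
- Exact global min-cut on every candidate component: fine for
  neighbourhood-sized subgraphs, not tuned for dense seeds with
  thousands of vertices.
- The correlation scan materialises the r × r correlation matrix;
  with many profiled genes and 40 grid points the null randomizations
  dominate runtime.
- Merging is greedy under a fixed priority rule; other tie-break
  orders can yield different (equally valid) fixpoints on ties.
- The evaluator reads OBO 1.2 via obonet and propagates only
  is_a/part_of; regulates-style relations are ignored.
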