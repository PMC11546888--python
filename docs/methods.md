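# Methods

## Model

The pipeline treats disease-gene discovery as network propagation. Genes
associated with one etiological mechanism cluster in protein–protein
interaction (PPI) networks, so a walk that repeatedly restarts from a set of
trusted seed genes assigns high stationary probability to genes embedded in
the seeds' neighborhood — including genes several hops away that a plain
differential-expression cut would miss.

Seeds are, by default, the intersection of the differentially expressed
genes (DEGs) and the targets of the differentially expressed miRNAs (DERs),
restricted to the network. Intersection is the conservative reading: a seed
is supported by both the transcriptomic change and the miRNA regulatory
evidence. When only one list is supplied the seed set degrades to that list
(union with an empty set), which is logged.

Random Walk with Restart iterates

    u ← (1 − p) A u + p u₀

with *A* the column-normalized adjacency (column j is the step distribution
out of node j), *p* the restart probability and *u₀* the restart
distribution. The restart distribution is uniform over seeds: marking every
seed with weight 1 and leaving the vector un-normalized does not converge to
a probability distribution, so normalization by the seed count is forced;
uniformity encodes no preference among seeds. The fixed point equals
u\* = p (I − (1 − p)A)⁻¹ u₀, which the test suite uses as an independent
oracle for the power iteration.

**Isolated nodes.** A node that lost all edges in confidence filtering has a
zero column; a walker standing there has nowhere to step. The mass that
would vanish is redirected to the restart distribution each iteration
(teleporting from dangling nodes, as in PageRank practice), so every iterate
sums to exactly 1. The closed form above is adjusted the same way in the
oracle (zero columns replaced by u₀).

**Boosted sets.** Nodes are ranked by stationary score, descending, with
ties broken by ascending Entrez ID so every cut is deterministic. The
boosting level q ∈ [0, 1] is interpreted as a fraction of the *non-seed*
pool: the boosted set is the seeds plus the top ⌈q · (N − |seeds|)⌉
non-seeds. Defining the denominator over non-seeds keeps the added-gene
count proportional to q regardless of seed-set size and makes level 0 the
seeds and level 1 the whole network. Non-seed members are classified
*direct* (≥ 1 edge to a seed) or *indirect*.

## Enrichment and the permutation null

Enrichment uses the one-sided hypergeometric upper tail P(X ≥ k) with
universe N, term size K, query size n and overlap k — exact tail summation,
not a normal approximation. Multiplicity control is Benjamini–Hochberg over
all tested terms (via statsmodels); cross-level enriched-pathway *counts*
use the raw p < 0.01 criterion, because raw counts are what the permutation
null calibrates.

The null redraws gene sets of exactly the boosted-set size uniformly from
the universe, without replacement, and recounts enriched terms per draw.
The empirical p-value is the add-one estimator (r + 1)/(n_perm + 1) with
r = #{null counts ≥ observed}; it is never zero and is floored at
1/(n_perm + 1). Internally the per-draw counting is vectorized (term
membership indicators plus one batched tail evaluation per draw); a test
asserts draw-for-draw equality with the literal enrich-then-count route
under the same RNG stream. The universe defaults to the union of collection
members and can be overridden (e.g. to the PPI node set); both backgrounds
are defensible and the choice is recorded in the run manifest.

## Network ingestion

Confidence filtering keeps the top ⌈fraction · |E|⌉ edges *by count*
(default fraction 0.01); all edges tied at the cutoff score are kept so the
result does not depend on input order. The transition matrix uses binary
weights by default — the confidence score has already been spent on the
filter — with score weighting available as an option.

## Graph metrics

Eigenvector centrality is the principal eigenvector of the binary
adjacency, nonnegative, unit Euclidean norm, computed by shifted power
iteration (A + I) from the uniform vector: the shift leaves the principal
eigenvector unchanged while suppressing the ±λ oscillation of bipartite
graphs (stars, paths) under plain power iteration. On disconnected graphs
the vector concentrates on the dominant component; the report flags
disconnectedness instead of splitting components. Hub calling is
configurable: top-k by degree (default k = 3) or a mean + c·SD outlier
rule (strict inequality, so regular graphs have no outliers); no single hub
criterion is canonical in this setting.

## Synthetic fixtures

The generator emulates the five input kinds the pipeline reads: a
STRING-dialect scored edge list, a miRNA–target TSV, DEG/DER lists, a GMT
collection and a symbol↔Entrez map. The PPI model is preferential
attachment (heavy-tailed degrees, so hubs exist) started from a connected
seed pair with m = 3 edges per arrival, giving exactly 1 + m(n − 2) edges;
an Erdős–Rényi option exists for contrast. Edge confidences are uniform
integers in 150–999, mirroring the familiar combined-score range so
top-fraction filtering is meaningful.

A *case* plants a module: a gene subset wired as a dense community (a
connectivity ring plus each pair with probability 1/2 — modules in PPI
networks are dense subgraphs, and a sparse "module" would not be
recoverable by any propagation method). The first half of the module is
placed on the DEG list and made a target of every DER, so the intersection
seeds fall inside the module; the second half is reachable only through
propagation. The first GMT term equals the module; additional "discoverable"
terms, when requested, are *disjoint slices* of the module. Disjointness
matters: nested sub-terms of one module are pathologically correlated under
a size-matched null (a single module-rich random draw passes many of them
at once), which would corrupt the permutation calibration the fixtures are
meant to exercise. Background terms are uniform random draws. With planting
disabled, the seed overlap is still guaranteed (so the pipeline runs) but no
module edges or aligned terms exist — a negative control under which the
observed enriched count should be unremarkable against its null.

What the fixtures do **not** emulate: expression values and
differential-expression testing (lists are taken as given), miRNA-family
sequence structure, database-specific evidence codes, STRING sub-channel
scores, and the degree-dependent annotation bias of real gene-set
collections. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure, not performance on any
real disease dataset.

## Defaults and numerical choices

| parameter | default | rationale |
|---|---|---|
| restart probability p | 0.7 | convention in network-propagation work; exposed |
| RWR tolerance | 1e−10 (L1) | far below any ranking-relevant difference |
| max iterations | 1000 | spectral radius ≤ 1 − p ⇒ geometric convergence |
| PPI top fraction | 0.01 | high-confidence core of a scored interactome |
| boosting levels | 0.01, 0.10, 0.20 | the standard coarse-to-permissive sweep |
| enrichment threshold | 0.01 raw | the count statistic the null calibrates |
| permutations | 10,000 | p-floor ≈ 1e−4; scaled down in tests for runtime |
| hub k | 3 | small interpretable hub panel; configurable |

Tie-breaking is by ascending Entrez ID everywhere a ranking is cut, and all
randomness flows through explicit seeds, so identical config + seed gives
byte-identical tabular outputs.

Test and acceptance problem sizes (300–500 genes, 20–80-gene modules,
99–10,000 permutations) were chosen so each property is measured at the
smallest scale at which it is meaningful: oracle equivalences on ≤ 50-node
graphs where dense solves are exact, recovery on 500-gene networks where a
module is a small minority of nodes, and the permutation floor at the full
10,000 draws since the floor value itself depends on n_perm.

## Known limitations

- The walk runs on the gene–gene network only; miRNAs are overlaid for
  visualization, not walked on (no heterogeneous multilayer propagation).
- Dense matrix algebra throughout: comfortable to a few thousand network
  nodes, not for a full unfiltered interactome.
- No GO-DAG ancestor propagation; GMT terms are taken as flat sets.
- Target-prediction scores in target tables are ignored (database choice is
  the filter); score thresholding is a noted extension point.
- The empirical-p estimator is conservative at small n_perm; counts near
  the floor should be reported together with n_perm.
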