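# mirboost

Integrated miRNA/mRNA network analysis by gene boosting. Given a list of
differentially expressed miRNAs (DERs), a list of differentially expressed
genes (DEGs), one or more miRNA–target interaction tables and a scored
protein–protein interaction (PPI) network, `mirboost` builds a seed gene set,
propagates it over the network with Random Walk with Restart (RWR), extracts
*boosted* gene sets, and tests them for pathway enrichment against a
size-matched permutation null. It is aimed at systems-biology analysts who
have differential-expression results in hand and want the indirect,
network-mediated disease mechanisms that a plain DEG list misses.

## Method

1. **Preprocessing.** Mature miRNA names are canonicalized (arm suffixes
   `-5p`/`-3p`; legacy `*` names expand to both arms) and gene symbols are
   mapped to Entrez IDs. Target databases in several export dialects
   (miRTarBase-, TarBase-, TargetScan-, miRDB-like) are combined at the
   (miRNA, gene)-pair level by intersection (conservative), union, or used
   singly. The PPI network keeps the top fraction of edges by confidence
   score (default: top 1%, ties at the cutoff retained).

2. **Boosting.** Seed genes are the DEGs ∩ DER-targets present in the
   network (degrading to whichever list is supplied). With *A* the
   column-normalized adjacency, *p* the restart probability and *u₀* uniform
   on the seeds, the walk

       u ← (1 − p) A u + p u₀

   is iterated to its fixed point, u\* = p (I − (1 − p)A)⁻¹ u₀. Nodes are
   ranked by their stationary score; the boosted set at level *q* is the
   seeds plus the top ⌈q · (N − |seeds|)⌉ non-seeds, each classified
   *direct* (one hop from a seed) or *indirect*.

3. **Pathway analysis.** Each gene set is tested against a GMT collection
   with the one-sided hypergeometric upper tail, Benjamini–Hochberg
   adjusted. The number of terms with raw p < 0.01 is compared with a null
   of size-matched uniform gene sets; the empirical p-value is the add-one
   estimator (r + 1)/(n_perm + 1), so with 10,000 permutations its floor is
   1/10001 ≈ 9.999 × 10⁻⁵. Hub genes (degree, eigenvector centrality) and a
   miRNA–gene overlay network (GraphML / JSON) round out the report.

A synthetic-fixture module generates all five input kinds with a planted,
densely wired gene module and a matching "discoverable" pathway term, so the
entire pipeline is testable offline with known ground truth.

## Worked example

Generate a 300-gene case with a planted 15-gene module and run the pipeline:

```sh
mirboost simulate --out demo/case --n-genes 300 --module-size 15 --seed 7
mirboost run --config demo/config.yaml   # paths to the bundle, rng_seed: 7
```

with `demo/config.yaml` pointing at the generated bundle
(`db_mode: single`, `ppi_top_fraction: 1.0` since the fixture network is
already high-confidence, `n_perm: 1000`). The run log prints:

```
INFO preprocessing: 540 target interactions, 5 DERs, 47 DEGs
INFO network: kept 947/947 edges over 300 nodes (top fraction 1)
INFO propagation: 19 seeds, converged=True in 15 iterations (p=0.7)
INFO enrichment at level 0.1: 1 terms below p=0.01
```

19 seed genes (DEG ∩ DER-target, all on the network) were boosted to 48
genes at the 10% level — 29 of them one hop from a seed. The top of
`results/enrichment_10pct.tsv`:

```
term_id         description        overlap  term_size  query_size  p_value
PLANTED:0000    planted pathway 0  14       15         48          3.14e-11
RAND:0010       background ...      5       15         48          8.63e-02
```

The planted pathway is recovered with 14 of its 15 genes and is the only
term below p = 0.01; every background term is flat. The permutation summary
(`permutation_10pct.tsv`) puts the observed count of 1 enriched pathway at
empirical p = 0.16 against 1000 random 48-gene draws — one planted term is
real but not an unusual *count*, which is exactly what the null is for.

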