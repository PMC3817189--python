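# cgsa — Correlated Gene Set Analysis

Unsupervised extraction of disjoint, positively co-expressed gene sets from
an expression matrix, and the downstream machinery to use them: per-sample
summary scores, sample ordering on the principal plane, cross-platform
mapping, PAM subgrouping with silhouette model selection, level-controlled
association testing, fold-change density decomposition, and gene set
enrichment statistics.

The intended users are analysts of bulk (or pseudobulked single-cell)
transcriptomes — originally tumour expression cohorts such as diffuse large
B-cell lymphoma — who want a hypothesis-free, interpretable dimension
reduction: instead of abstract principal components, the cohort is described
by a small number of *correlated gene sets* (CGSs), each anchored at a real
"centre" gene, that can be tested against phenotypes without inflating the
false-positive rate.

## The method

Given a genes × samples matrix X on a variance-stabilised (generalised-log)
scale, every gene c seeds a candidate set

&nbsp;&nbsp;&nbsp;&nbsp;M(c) = { j : r<sub>cj</sub> ≥ r<sub>min</sub> }

of genes positively correlated with it (Pearson, across all samples).
Candidates are ranked by the score

&nbsp;&nbsp;&nbsp;&nbsp;score(c) = s²<sub>c</sub> · Σ<sub>j∈M(c)</sub> r²<sub>cj</sub>

— centre variance times summed squared centre correlations, so the score
grows with set size, centre variance and correlation tightness — and a
greedy scan accepts the best-scoring candidates that share no gene with any
previously accepted set, stopping after K acceptances (default K = 50).
Each accepted set is summarised per sample by the weighted sum
Σ<sub>j</sub> x<sub>ji</sub>/s<sub>j</sub>, oriented to correlate positively
with its centre gene, and standardised.

The crucial design property is that every statistic used — variances,
covariances, correlations — is **invariant under permutation of the
samples**. The extracted collection therefore carries no information about
any sample grouping, and testing the summaries against phenotypes with a
single-step max-T permutation adjustment (Westfall–Young, B = 999) keeps the
family-wise error at its nominal level *despite* the data-dependent
construction of the sets. The smallest attainable adjusted p is
1/(B+1) = 0.001.

Downstream, samples are projected onto two principal axes of the summary
matrix and ordered by their counterclockwise angle from a reference vector;
discrete subgroups come from partitioning around medoids (PAM) on Euclidean
distances over standardised summaries, with the number of clusters chosen
to maximise the average silhouette width. Group contrasts are quantified by
gene-wise generalised log-ratios, Welch tests with Benjamini–Hochberg FDR,
class-partitioned kernel densities of the log-ratios (e.g. by
highly/lowly-expressed gene classes), hypergeometric term enrichment and
PAGE z-statistics.

A synthetic-cohort generator with planted latent-factor modules, sample
clusters and factor-linked phenotypes makes the whole pipeline testable
without external data: a gene in module m follows
x<sub>gi</sub> = μ<sub>g</sub> + λ·f<sub>mi</sub> + ε<sub>gi</sub>, giving a
known within-module correlation λ²/(λ²+σ²) and a recoverable ground truth.

## Worked example

```python
import cgsa

design = cgsa.default_design()                       # 2000 genes, 10 planted modules,
X, phenotypes, truth = cgsa.simulate_cohort(design, seed=1)   # 150 samples, 3 clusters

collection = cgsa.extract_cgs_collection(X, n_sets=10, r_min=0.6)
S = cgsa.summarize_cgs(X, collection)
clusters = cgsa.choose_k(S, (2, 10))
report = cgsa.recovery_metrics(collection, truth, cluster_labels=clusters.labels)
assoc = cgsa.associate(S, phenotypes, B=999, seed=1)
```

This prints (via the obvious `print` statements):

```
10 disjoint sets covering 145 of 2000 genes
  rank 1: center G00550, 18 genes, score 125.3
  rank 2: center G00972, 16 genes, score 88.2
  rank 3: center G01910, 17 genes, score 84.3
silhouette-selected k = 3 (ASW = 0.227)
mean planted-module Jaccard = 1.000, cluster ARI = 0.863
strongest association: CGS10 vs proliferation_index: R2 = 0.63, adjusted P = 0.001
best subtype discriminator: CGS09: R2 = 0.44, AUC = 0.90, adjusted P = 0.001
```

Reading: the extraction recovered all ten planted modules exactly
(Jaccard 1.0) as disjoint sets; the silhouette criterion chose the planted
three sample clusters; the summary most driven by the phenotype-linked
factor explains 63% of the quantitative phenotype's variance, and the
binary subtype is discriminated with AUC 0.90 — with the max-T adjusted
p-values bottoming out at the 0.001 floor that B = 999 permutations allow.

The same pipeline is scriptable from the shell:

```sh
cgsa simulate --seed 1 --out-prefix cohort
cgsa extract --expr cohort.expr.tsv --r-min 0.6 --n-sets 10 --out sets.gmt
cgsa summarize --expr cohort.expr.tsv --sets sets.gmt --out summary.tsv
cgsa cluster --summary summary.tsv --out clusters.tsv
```

Real cohorts enter the same way: a tab-delimited expression table (genes in
rows, VSN/glog scale), a phenotype TSV with a declared column schema, and
GMT files for annotation catalogs.

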