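# Methods

## Model and assumptions

The package operates on a complete genes × samples matrix of
variance-stabilised expression values (a generalised-log / VSN-type scale).
Three assumptions matter:

1. **Co-expression is the signal.** Biological programmes manifest as groups
   of genes positively correlated across samples; a group can be anchored at
   the gene most representative of it (its *centre*).
2. **The scale is additive.** Differences of group means per gene are
   generalised log-ratios (estimated log fold changes); means and variances
   are meaningful on this scale.
3. **Permutation invariance buys valid inference.** Because set construction
   uses only total (phenotype-blind) variances and covariances, the sets are
   statistically independent of any sample labelling under the null, so
   permutation-based multiplicity adjustment of downstream association tests
   retains its exact level even though the tested features were learned from
   the same data.

## Extraction

For centre gene c with sample variance s²_c and correlations r_cj:

    members(c) = { j : r_cj >= r_min },     score(c) = s²_c · Σ_{j ∈ members} r²_cj

Candidates are scanned in decreasing score order (ties broken by centre gene
identifier for determinism); a candidate is accepted iff it overlaps no
previously accepted set and has at least `min_size` members; the scan stops
at `n_sets` acceptances. Negatively correlated genes are never members —
they are rare in practice and excluding them keeps each set a coherent
"activation" signature.

Parameters (defaults): `n_sets = 50` (enough to capture a cohort's main
factors while keeping the collection readable; analyses here use 10 on
synthetic cohorts with 10 planted modules), `r_min = 0.7` (0.6 in the
synthetic analyses; higher values give smaller, tighter sets),
`min_size = 2` (a singleton represents no co-expression). The score formula
identifier is recorded in every output so alternative scores can be plugged
in behind the same contract.

**Summaries.** Each set's per-sample summary is Σ_j x_ji / s_j — inverse
total-standard-deviation weights, again permutation-invariant — oriented to
correlate positively with the centre gene and standardised to mean 0 /
variance 1 across samples. Equal weights are available as an option.

**Canonical sample order.** All moments are accumulated with samples sorted
by identifier, which makes extraction *bitwise* invariant to the column
order of the input file — floating-point summation order can no longer leak
into scores. Outputs are emitted in the original column order.

## Sample structure

The sets × samples summary matrix is decomposed by SVD over samples;
samples are projected on two chosen principal axes (default 1 and 2 —
weaker contrasts, e.g. axes (1, 5), are exposed through the same argument)
with loadings sign-fixed so the largest-magnitude loading per axis is
positive. The angular ordering assigns each sample its counterclockwise
angle from a reference vector (default: the direction of the first sample;
arbitrary, recorded in the output) — a circular layout along the cohort's
dominant expression gradient. External cohorts are summarised with the
reference weights restricted to the shared genes, centred and scaled by the
reference per-set statistics, and projected with the reference loadings; a
set missing more than half its members on the target platform is dropped
(neutralised at the plane mean), and a sample missing more than 20% of sets
is rejected.

**PAM.** Partitioning around medoids on Euclidean distances over per-set
standardised summaries. Instances with fewer than 1000 candidate medoid
subsets are solved by exhaustive enumeration; larger ones by the
deterministic BUILD + SWAP procedure (single best cost-decreasing swap per
iteration until a local optimum). The hybrid exists because best-improvement
SWAP demonstrably stalls in local optima on a noticeable fraction of tiny
instances, where exactness is cheap. No randomness, no seed. The number of
clusters is chosen by maximising the average silhouette width over
k = 2..10, ties toward smaller k; a best ASW below 0.25 triggers a warning
that the cohort shows no convincing cluster structure.

## Association testing

Effect sizes: squared Pearson correlation for quantitative phenotypes,
eta² (between-group over total sum of squares) for categorical ones, AUC
(rank form, ties 1/2) for binary ones. Raw p-values come from the
corresponding F distributions. Family-wise adjustment is single-step max-T:
B = 999 phenotype permutations, recomputing all per-set statistics (squared
correlation or one-way F, so one procedure covers both phenotype types) and
comparing each observed statistic with the permutation distribution of the
maximum; adjusted p = (1 + #{max_b ≥ T_s})/(B + 1), floored at 0.001.
Missing phenotype entries are dropped pairwise per phenotype with the used
n reported. The two-way signature ANOVA regresses a signature's first
principal component (sign-oriented with the mean signature profile) on two
categorical factors, main effects only (type II) — the use case is
contrasting two sample groupings, not modelling their interaction.

## Differential expression and densities

Welch's t per gene with Benjamini–Hochberg adjustment across all tested
genes; up/down calls at the stated FDR. Constant, equal groups yield p = 1
(no evidence), not an error. Moderated-variance tests are intentionally out
of scope — the surface here is simulation-validated, and the Welch test's
level is what the simulations check.

Partitioned densities use Gaussian kernels with **one** Silverman bandwidth
computed on the pooled classified genes and shared across classes, each
class scaled by its share of classified genes. With a shared absolute
bandwidth the scaled class densities sum pointwise to the density of all
classified genes *by construction* (each data point contributes one kernel
divided by the total count, whichever class it sits in); this is why the
kernels are evaluated directly rather than through a per-dataset bandwidth
parameterisation. Grid: 512 points spanning the data range ± 3 bandwidths.
Genes not mapped to a class ("unclassified") are excluded.

## Enrichment

Hypergeometric over-representation is one-sided (upper tail), computed per
term after intersecting term and query with the universe; only terms with
more than `min_term_size = 10` universe genes are tested, and p-values are
reported unadjusted (a BH option exists but is off by default in the
characterisation report; the conventional report filters are GO/band 0.001,
KEGG 0.01). PAGE computes z = (S_m − μ)·√m/δ from the global score mean and
SD, with a two-sided normal p and a signed −log10 p for heat-map style
matrices; the conventional report threshold is 0.005, but the statistic is
always emitted. Catalogs are user-supplied GMT files — results never depend
on a live database version.

## Synthetic cohorts

The generator emulates exactly what the method assumes: gene g in module m
follows x_gi = μ_g + λ f_mi + ε_gi with standard-normal factors and
ε ~ N(0, σ²); background genes are μ_g + ε; per-gene baselines are
N(8, 0.5²) (an optional bimodal mixture mimics the global low/high
expression split); sample clusters shift factor means; phenotypes derive
from factors (linear plus unit noise for quantitative, quantile-thresholded
latent for categorical). Within-module correlation is λ²/(λ²+σ²)
conditional on cluster.

Default (acceptance-scale) design: 2000 genes, 10 modules of 10–19 genes,
λ = √3 and σ = 1 (conditional within-module r = 0.75), n = 150 samples,
3 equal clusters, two phenotypes at effect 1.2. Cluster shifts put δ = 2 on
three factors per cluster. The magnitude is a deliberate compromise: shifts
shared by same-cluster factors correlate those factors, hence their modules
(expected cross-module gene correlation ≈ 0.4 at δ = 2), so larger shifts
would merge planted modules at extraction (r_min = 0.6), while smaller ones
leave the clusters undetectable by the silhouette criterion. δ = 2 keeps
module recovery essentially perfect and cluster-number recovery reliable.

What the generator does **not** emulate: probe/batch effects, heteroscedastic
per-gene noise, correlated backgrounds, non-Gaussian factors, survival
outcomes. Passing tests therefore demonstrate correctness of the algorithms
under the factor model, not robustness to array artefacts.

Simulation sizes in the test-suite and acceptance script are the package's
choices: 100 replicates for module recovery and cluster-number recovery at
the full 2000 × 150 scale; 500 replicates for the family-wise error check on
20-module cohorts of 500 genes × 60 samples (the error-control property is
scale-free, and K = 20 extractable sets require 20 planted modules); 50
replicates for split-half ordering stability on a 330-gene, two-factor
cohort with tight modules (loadings 5 and 4) so that both random gene halves
estimate essentially the same principal plane — the regime in which the
original split-half analysis reported Spearman correlations of 0.94–0.99.
Angular orderings are compared by the best Spearman correlation over all
rotations and reflections of the circular ranks, since the origin and
direction of travel of the ordering are arbitrary.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1]; zero-variance genes get correlation 0
  with a warning, are never accepted as members, and cannot seed sets
  (degenerate-centre error).
- Score ties break by centre gene identifier; angle ties and zero-length
  coordinate vectors break by sample identifier.
- Standardisation tolerances: summary rows are mean 0 / variance 1 to 1e-8;
  density additivity holds to 1e-6 on the evaluation grid.
- Missing expression values are rejected at load (correlations assume
  complete data); an optional pre-step drops incomplete genes and an
  optional collapse keeps the highest-variance row per duplicated gene id
  (both off by default).
- All permutation draws come from numpy's PCG64 generator with an explicit
  seed; the seed and generator are recorded in outputs.

## Known limitations

- The score formula and r_min are declared package defaults; the original
  procedure's exact constants were specified in supplementary material that
  is not part of this implementation's inputs. Both are recorded in output
  metadata and swappable.
- Candidate set sizes are uncapped; a cohort with one overwhelming factor
  will spend its first set on it.
- max-T assumes exchangeability of samples under the null; strong known
  batch structure should be removed upstream.
- PAM above the enumeration threshold is a deterministic local optimiser;
  its cost is non-increasing but global optimality is not guaranteed.
- The enrichment stage performs no GO-graph propagation; terms are taken as
  given in the supplied GMT.
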