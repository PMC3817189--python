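"""Synthetic expression cohorts with planted co-expression structure.

The generator emulates exactly the statistical structure the extraction
method assumes: blocks of genes driven by shared latent factors (modules), a
large background of uncorrelated genes, discrete sample clusters expressed
as mean shifts of chosen factors, and phenotypes tied to factors. A gene g
in module m with loading lambda follows

    x_gi = mu_g + lambda * f_mi + eps_gi,   eps ~ N(0, sigma^2)

with f_m standard normal within a cluster (cluster shifts move the factor
mean), giving a within-cluster pairwise module correlation of
lambda^2 / (lambda^2 + sigma^2). Background genes are mu_g + eps. Every run
is reproducible from its seed, and the ground truth (gene -> module,
sample -> cluster, factor values) is returned alongside the data so that
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .exprio import ExpressionMatrix, PhenotypeTable
from .extract import CGSCollection
from .exprio import GeneSetFile

GENERATOR_ID = "numpy-PCG64"


@dataclass
class ModuleSpec:
    size: int
    loading: float
    factor: int  # index into the factor vector


@dataclass
class ClusterSpec:
    k: int
    shifts: np.ndarray  # (k, n_factors) per-cluster factor-mean shifts
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.shape[0] != self.k:
            raise ValueError("one shift row per cluster required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")


@dataclass
class PhenotypeSpec:
    name: str
    kind: str  # "categorical" | "quantitative"
    factor: int
    effect: float
    levels: tuple[str, ...] = ("A", "B")


@dataclass
class SyntheticDesign:
    """Full specification of a synthetic cohort; the defaults are the
    acceptance-scale study conditions (2000 genes, 10 modules, n = 150,
    3 planted sample clusters)."""

    n_samples: int = 150
    n_background_genes: int = 1855
    modules: list[ModuleSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    clusters: ClusterSpec | None = None
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)
    baseline_mean: float = 8.0
    baseline_sd: float = 0.5
    he_le_mixture: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        if self.n_samples < 4 or self.n_background_genes < 0:
            raise ValueError("infeasible design sizes")
        for m in self.modules:
            if m.size < 1:
                raise ValueError("module sizes must be positive")
        if self.clusters is not None and self.clusters.k > self.n_samples:
            raise ValueError("more clusters than samples")

    @property
    def n_factors(self) -> int:
        return max((m.factor for m in self.modules), default=-1) + 1

    @property
    def n_genes(self) -> int:
        return self.n_background_genes + sum(m.size for m in self.modules)


def default_design(
    n_samples: int = 150,
    n_genes: int = 2000,
    n_modules: int = 10,
    loading: float = np.sqrt(3.0),
    cluster_shift: float = 2.0,
    seed: int | None = None,
) -> SyntheticDesign:
    """The acceptance-scale design: within-cluster module correlation
    lambda^2/(lambda^2+1) = 0.75, three equal clusters shifting three
    factors each by ``cluster_shift``, and two factor-linked phenotypes
    (one binary, one quantitative) at effect 1.2.

    The shift magnitude balances two requirements: shifts shared by
    same-cluster factors induce positive cross-module correlation
    (lambda^2 * 2 delta^2/9 over the product of total SDs), which must stay
    well below the membership threshold so planted modules remain disjoint
    at extraction, while the cluster separation must be strong enough for
    the silhouette criterion to recover k = 3. delta = 2 keeps the expected
    cross-module gene correlation near 0.4 (sampling noise rarely lifts it
    past 0.6 at n = 150) with clearly separated clusters."""
    sizes = [10 + (i % 10) for i in range(n_modules)]
    modules = [ModuleSpec(sizes[i], loading, i) for i in range(n_modules)]
    n_factors = n_modules
    shifts = np.zeros((3, n_factors))
    for c in range(3):
        lo = c * 3
        cols = [f for f in range(lo, min(lo + 3, n_factors))]
        shifts[c, cols] = cluster_shift
    clusters = ClusterSpec(k=3, shifts=shifts, proportions=(1 / 3, 1 / 3, 1 / 3))
    phenos = [
        PhenotypeSpec("subtype", "categorical", factor=0, effect=1.2),
        PhenotypeSpec("proliferation_index", "quantitative", factor=1, effect=1.2),
    ]
    return SyntheticDesign(
        n_samples=n_samples,
        n_background_genes=n_genes - sum(sizes),
        modules=modules,
        clusters=clusters,
        phenotypes=phenos,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    gene_module: dict[str, str]  # gene id -> module id ("background" if none)
    sample_cluster: dict[str, int]
    factors: pd.DataFrame  # samples x factors
    phenotypes: pd.DataFrame
    module_members: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None
    generator: str = GENERATOR_ID


def simulate_cohort(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Draw one cohort from the latent-factor model; reproducible from seed."""
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    n, p = design.n_samples, design.n_genes
    n_factors = design.n_factors

    sample_ids = [f"S{j + 1:04d}" for j in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(p)]

    if design.clusters is not None:
        k = design.clusters.k
        labels = rng.choice(k, size=n, p=design.clusters.proportions)
        shifts = design.clusters.shifts
    else:
        labels = np.zeros(n, dtype=int)
        shifts = np.zeros((1, max(n_factors, 1)))

    F = rng.standard_normal((n_factors, n)) if n_factors else np.zeros((0, n))
    for f in range(n_factors):
        F[f] += shifts[labels, f]

    if design.he_le_mixture:
        # bimodal global baseline: low/high expression classes
        is_high = rng.random(p) < 0.65
        mu = np.where(
            is_high,
            rng.normal(design.baseline_mean + 1.0, design.baseline_sd, p),
            rng.normal(design.baseline_mean - 2.0, design.baseline_sd, p),
        )
    else:
        mu = rng.normal(design.baseline_mean, design.baseline_sd, p)

    # scatter module genes across random row positions so file order carries
    # no information about the planted structure
    perm = rng.permutation(p)
    values = mu[:, None] + rng.normal(0.0, design.noise_sd, (p, n))
    gene_module = {g: "background" for g in gene_ids}
    module_members: dict[str, list[str]] = {}
    cursor = 0
    for mi, mod in enumerate(design.modules):
        mid = f"M{mi + 1:02d}"
        rows = perm[cursor : cursor + mod.size]
        cursor += mod.size
        values[rows] += mod.loading * F[mod.factor]
        members = [gene_ids[r] for r in rows]
        module_members[mid] = sorted(members)
        for g in members:
            gene_module[g] = mid

    X = ExpressionMatrix(gene_ids, sample_ids, values)

    pheno_data: dict[str, object] = {}
    schema: dict[str, str] = {}
    for spec in design.phenotypes:
        f = F[spec.factor]
        latent = spec.effect * (f - f.mean()) / f.std(ddof=1) + rng.standard_normal(n)
        if spec.kind == "quantitative":
            pheno_data[spec.name] = latent
            schema[spec.name] = "quantitative"
        else:
            g = len(spec.levels)
            cuts = np.quantile(latent, np.linspace(0, 1, g + 1)[1:-1])
            codes = np.searchsorted(cuts, latent)
            pheno_data[spec.name] = [spec.levels[c] for c in codes]
            schema[spec.name] = "categorical"
    pheno_df = pd.DataFrame(pheno_data, index=sample_ids)
    phenotypes = PhenotypeTable(pheno_df, schema) if schema else PhenotypeTable(
        pd.DataFrame(index=sample_ids), {}
    )

    truth = SyntheticTruth(
        gene_module=gene_module,
        sample_cluster={s: int(c) for s, c in zip(sample_ids, labels)},
        factors=pd.DataFrame(F.T, index=sample_ids, columns=[f"F{i + 1}" for i in range(n_factors)]),
        phenotypes=pheno_df,
        module_members=module_members,
        seed=seed,
    )
    return X, phenotypes, truth


# ---------------------------------------------------------------------------
# truth-recovery metrics


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass
class RecoveryReport:
    module_jaccard: dict[str, float]
    matching: dict[str, str | None]  # module id -> matched set id
    mean_jaccard: float
    cluster_agreement: float | None = None
    confusion: pd.DataFrame | None = None


def recovery_metrics(
    found: CGSCollection | GeneSetFile | dict,
    truth: SyntheticTruth,
    cluster_labels: np.ndarray | None = None,
) -> RecoveryReport:
    """Score found sets against planted modules by greedy one-to-one Jaccard.

    All (module, set) Jaccard indices are sorted and assigned greedily so
    each planted module matches at most one found set; unmatched modules
    score 0. If cluster labels are given, agreement with the planted sample
    clusters is the adjusted Rand index and a confusion table is attached.
    """
    if isinstance(found, CGSCollection):
        found_sets = {sid: set(s.members) for sid, s in zip(found.set_ids(), found)}
    elif isinstance(found, GeneSetFile):
        found_sets = {r.set_id: set(r.members) for r in found}
    else:
        found_sets = {k: set(v) for k, v in found.items()}

    modules = truth.module_members
    pairs = []
    for mid, members in modules.items():
        mset = set(members)
        for sid, fset in found_sets.items():
            j = _jaccard(mset, fset)
            if j > 0:
                pairs.append((j, mid, sid))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_m: dict[str, str | None] = {m: None for m in modules}
    used_sets: set[str] = set()
    jaccard = {m: 0.0 for m in modules}
    for j, mid, sid in pairs:
        if matched_m[mid] is None and sid not in used_sets:
            matched_m[mid] = sid
            used_sets.add(sid)
            jaccard[mid] = j
    mean_j = float(np.mean(list(jaccard.values()))) if jaccard else 0.0

    agreement = None
    confusion = None
    if cluster_labels is not None:
        true_labels = np.array([truth.sample_cluster[s] for s in truth.factors.index])
        agreement = float(adjusted_rand_score(true_labels, cluster_labels))
        confusion = pd.crosstab(
            pd.Series(true_labels, name="planted"), pd.Series(cluster_labels, name="found")
        )
    return RecoveryReport(jaccard, matched_m, mean_j, agreement, confusion)


def exhaustive_best_matching(
    modules: dict[str, set[str]], found: dict[str, set[str]]
) -> float:
    """Mean Jaccard of the best one-to-one assignment by exhaustive search.

    Reference oracle for small instances (<= ~6 modules); enumerates every
    injective assignment of modules to found sets.
    """
    mids = sorted(modules)
    sids = sorted(found)
    best = 0.0
    k = min(len(mids), len(sids))
    for perm in permutations(sids, k):
        total = sum(_jaccard(modules[m], found[s]) for m, s in zip(mids, perm))
        best = max(best, total / len(mids))
    return best
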