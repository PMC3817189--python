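"""Unsupervised sample structure on top of the gene-set summary matrix.

Samples are projected onto a plane spanned by two principal axes of the
(sets x samples) summary matrix and ordered by their counterclockwise angle
from a reference vector — the circular ordering used to lay tumours out along
their dominant expression gradient. External cohorts are put on the same
plane by summarising them with the reference weights and reference
location/scale. Discrete subgroups come from classical PAM (partitioning
around medoids, deterministic BUILD+SWAP) on Euclidean distances over
standardised summaries, with the number of clusters chosen to maximise the
average silhouette width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import check_is_fitted, validate_data

from .exprio import ExpressionMatrix
from .extract import CGSCollection, SummaryMatrix


# ---------------------------------------------------------------------------
# principal plane and angular ordering


@dataclass
class PlaneProjection:
    """Coordinates of samples on two principal axes, plus the set loadings."""

    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, 2)
    loadings: np.ndarray  # (n_sets, 2)
    axes: tuple[int, int]  # 1-based component indices
    mean_: np.ndarray  # per-set means removed before the eigendecomposition
    set_ids: list[str] = field(default_factory=list)
    explained_variance: np.ndarray | None = None


def principal_plane(S: SummaryMatrix, axes: tuple[int, int] = (1, 2)) -> PlaneProjection:
    """Project samples onto two principal axes of the summary matrix.

    ``axes`` are 1-based component indices (the default plane is spanned by
    components 1 and 2; other pairs, e.g. (1, 5), expose weaker contrasts).
    Loadings are sign-fixed so the largest-magnitude loading on each axis is
    positive, making the orientation reproducible across runs and platforms.
    """
    D = S.values.T  # samples x sets
    n, p = D.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 samples and 2 sets")
    mean = D.mean(axis=0)
    Dc = D - mean
    U, sv, Vt = np.linalg.svd(Dc, full_matrices=False)
    for a in axes:
        if not 1 <= a <= len(sv):
            raise ValueError(
                f"axis {a} exceeds the available components ({len(sv)}) of the summary matrix"
            )
    cols = [a - 1 for a in axes]
    loadings = Vt[cols].T  # (n_sets, 2)
    scores = Dc @ loadings
    for j in range(2):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    ev = (sv**2) / (n - 1)
    return PlaneProjection(
        sample_ids=list(S.sample_ids),
        coords=scores,
        loadings=loadings,
        axes=tuple(axes),
        mean_=mean,
        set_ids=list(S.set_ids),
        explained_variance=ev[cols],
    )


@dataclass
class SampleOrdering:
    """Circular ordering of samples by angle from a reference vector."""

    sample_ids: list[str]
    angles: np.ndarray  # in [0, 2*pi), aligned with sample_ids
    order: list[str]  # sample ids sorted by increasing angle
    ranks: np.ndarray  # rank of each sample (1..n), aligned with sample_ids
    reference: tuple[float, float]
    axes: tuple[int, int]
    coords: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "angle": self.angles,
                "rank": self.ranks,
                "coord1": self.coords[:, 0],
                "coord2": self.coords[:, 1],
            }
        )


def angular_order(
    plane: PlaneProjection, reference: tuple[float, float] | None = None
) -> SampleOrdering:
    """Order samples by counterclockwise angle from ``reference`` on the plane.

    The reference defaults to the coordinate direction of the first sample
    (the choice is arbitrary and only rotates the circular ordering; it is
    recorded in the output). Zero-length coordinate vectors have no angle and
    are placed last, ordered by sample id; angle ties also break by sample id.
    """
    coords = plane.coords
    if reference is None:
        reference = tuple(coords[0])
    ref = np.asarray(reference, dtype=float)
    if np.allclose(ref, 0):
        raise ValueError("reference vector must be nonzero")
    ref_angle = np.arctan2(ref[1], ref[0])
    raw = np.arctan2(coords[:, 1], coords[:, 0]) - ref_angle
    angles = np.mod(raw, 2 * np.pi)
    zero = np.hypot(coords[:, 0], coords[:, 1]) == 0
    angles[zero] = np.nan
    ids = plane.sample_ids
    finite = [(angles[i], ids[i]) for i in range(len(ids)) if not zero[i]]
    degenerate = sorted(ids[i] for i in range(len(ids)) if zero[i])
    order = [s for _, s in sorted(finite)] + degenerate
    pos = {s: r + 1 for r, s in enumerate(order)}
    ranks = np.array([pos[s] for s in ids])
    return SampleOrdering(
        sample_ids=list(ids),
        angles=angles,
        order=order,
        ranks=ranks,
        reference=(float(ref[0]), float(ref[1])),
        axes=plane.axes,
        coords=coords,
    )


def circular_rank_agreement(order_a: list[str], order_b: list[str]) -> float:
    """Best Spearman correlation of two circular orderings over rotation/reflection.

    Both orderings must enumerate the same samples. Used to compare orderings
    derived from independent gene halves, where the circular origin and the
    direction of travel are arbitrary. Returns the signed rho of largest
    magnitude.
    """
    if set(order_a) != set(order_b):
        raise ValueError("orderings must cover the same samples")
    n = len(order_a)
    pos_b = {s: i for i, s in enumerate(order_b)}
    b = np.array([pos_b[s] for s in order_a])
    base = np.arange(n)
    best = 0.0
    for seq in (b, (n - 1) - b):  # original and reflected
        for shift in range(n):
            rho = spearmanr(base, (seq + shift) % n).statistic
            if abs(rho) > abs(best):
                best = float(rho)
    return best


# ---------------------------------------------------------------------------
# external projection and cross-dataset mapping


def project_external(
    S_ref: SummaryMatrix,
    X_ext: ExpressionMatrix,
    collection: CGSCollection,
    axes: tuple[int, int] = (1, 2),
    plane: PlaneProjection | None = None,
    max_missing_members: float = 0.5,
    max_missing_sets: float = 0.2,
) -> PlaneProjection:
    """Place external samples on the reference principal plane.

    External samples are summarised with the reference weights restricted to
    the genes present on the external platform, centred/scaled by the
    reference per-set statistics, and projected with the reference loadings.
    A set missing more than half of its members is marked missing (its
    coordinate contribution is dropped via a zero, and samples are dropped
    entirely if more than 20% of sets are missing).
    """
    if plane is None:
        plane = principal_plane(S_ref, axes=axes)
    ext_idx = X_ext.gene_index()
    n_sets = len(S_ref.set_ids)
    Z = np.zeros((n_sets, X_ext.n_samples))
    set_missing = np.zeros(n_sets, dtype=bool)
    for k, wlist in enumerate(S_ref.weights):
        present = [(g, w) for g, w in wlist if g in ext_idx]
        if len(present) < len(wlist) * (1 - max_missing_members):
            set_missing[k] = True
            continue
        rows = [ext_idx[g] for g, _ in present]
        w = np.array([wv for _, wv in present])
        summary = S_ref.signs[k] * (w @ X_ext.values[rows])
        if S_ref.standardized:
            summary = (summary - S_ref.means[k]) / S_ref.sds[k]
        Z[k] = summary
    if set_missing.mean() > max_missing_sets:
        raise ValueError(
            f"{int(set_missing.sum())}/{n_sets} sets unmappable on the external platform"
        )
    if set_missing.any():
        warnings.warn(f"{int(set_missing.sum())} sets missing on the external platform")
        Z[set_missing] = plane.mean_[set_missing][:, None]  # neutral contribution
    coords = (Z.T - plane.mean_) @ plane.loadings
    return PlaneProjection(
        sample_ids=list(X_ext.sample_ids),
        coords=coords,
        loadings=plane.loadings,
        axes=plane.axes,
        mean_=plane.mean_,
        set_ids=list(S_ref.set_ids),
    )


@dataclass
class MappedSet:
    set_id: str
    center_gene: str
    retained_members: list[str]
    retained_fraction: float
    mapped: bool


@dataclass
class MappedCollection:
    original: CGSCollection
    sets: list[MappedSet]
    min_fraction: float

    def mapped_ids(self) -> list[str]:
        return [s.set_id for s in self.sets if s.mapped]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": [s.set_id for s in self.sets],
                "center": [s.center_gene for s in self.sets],
                "retained": [len(s.retained_members) for s in self.sets],
                "original_size": [len(o.members) for o in self.original],
                "retained_fraction": [s.retained_fraction for s in self.sets],
                "mapped": [s.mapped for s in self.sets],
            }
        )


def map_gene_sets(
    collection: CGSCollection, target_genes: list[str], min_fraction: float = 0.5
) -> MappedCollection:
    """Intersect each set with a target platform's gene list.

    Sets retaining less than ``min_fraction`` of their members are flagged
    unmapped and excluded from downstream summaries. Mapping is idempotent.
    """
    target = set(target_genes)
    if not target:
        raise ValueError("target gene list is empty")
    mapped = []
    for sid, cset in zip(collection.set_ids(), collection):
        retained = [m for m in cset.members if m in target]
        frac = len(retained) / len(cset.members)
        mapped.append(MappedSet(sid, cset.center_gene, retained, frac, frac >= min_fraction))
    return MappedCollection(collection, mapped, min_fraction)


# ---------------------------------------------------------------------------
# PAM clustering with silhouette-based model selection


@dataclass
class ClusterResult:
    k: int
    sample_ids: list[str]
    labels: np.ndarray
    medoid_ids: list[str]
    silhouette: np.ndarray
    asw: float
    asw_by_k: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "label": self.labels, "silhouette": self.silhouette}
        )


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, D[c])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        Dm = D[medoids]  # (k, n)
        order = np.argsort(Dm, axis=0)
        d1 = Dm[order[0], np.arange(n)]
        d2 = Dm[order[1], np.arange(n)] if len(medoids) > 1 else np.full(n, np.inf)
        assign = order[0]
        best_delta, best_pair = -1e-12, None
        for mi in range(len(medoids)):
            mine = assign == mi
            # cost change of swapping medoid mi for each candidate h (vectorised over h)
            delta = (np.minimum(D[mine], d2[mine, None]) - d1[mine, None]).sum(axis=0)
            delta += np.minimum(0.0, D[~mine] - d1[~mine, None]).sum(axis=0)
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_pair = float(delta[h]), (mi, h)
        if best_pair is None:
            break
        medoids[best_pair[0]] = best_pair[1]
    return medoids


def _pam_exact(D: np.ndarray, k: int) -> list[int]:
    from itertools import combinations

    best_cost, best = np.inf, None
    for medoids in combinations(range(D.shape[0]), k):
        cost = D[list(medoids)].min(axis=0).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, list(medoids)
    return best


# enumerate all medoid subsets when the search space is this small; the
# BUILD+SWAP heuristic can stall in local optima on tiny instances
_EXACT_SUBSET_LIMIT = 1000


class PAM(ClusterMixin, BaseEstimator):
    """Partitioning around medoids (deterministic BUILD + SWAP).

    Fit on an (n_samples, n_features) array; Euclidean distances unless a
    precomputed square distance matrix is passed (``metric="precomputed"``).
    The SWAP phase applies the single best cost-decreasing swap per iteration
    until a local optimum, so results are deterministic given the input order
    — no random initialisation, no seed. Instances small enough to enumerate
    (fewer than 1000 candidate medoid subsets) are solved exactly instead,
    so tiny problems always reach the global minimum-cost medoid set.
    """

    def __init__(self, n_clusters: int = 3, metric: str = "euclidean"):
        self.n_clusters = n_clusters
        self.metric = metric

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if not 2 <= k < n:
            raise ValueError(f"n_clusters must satisfy 2 <= k < n (k={k}, n={n})")
        if self.metric == "precomputed":
            D = np.asarray(X, dtype=float)
        else:
            from scipy.spatial.distance import squareform, pdist

            D = squareform(pdist(X, metric=self.metric))
        from math import comb

        if comb(n, k) <= _EXACT_SUBSET_LIMIT:
            medoids = _pam_exact(D, k)
        else:
            medoids = _pam_swap(D, _pam_build(D, k))
        labels = np.argmin(D[medoids], axis=0)
        if len(np.unique(labels)) < k:
            raise ValueError("duplicate samples make the requested k infeasible")
        self.medoid_indices_ = np.array(medoids)
        self.labels_ = labels
        self.inertia_ = float(D[medoids, :][labels, np.arange(n)].sum())
        self._distances = D
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _standardized_samples(S: SummaryMatrix) -> np.ndarray:
    V = S.values
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ((V - mu) / sd).T  # samples x sets


def pam_cluster(S: SummaryMatrix, k: int) -> ClusterResult:
    """PAM on Euclidean distances over per-set standardised summaries."""
    Xs = _standardized_samples(S)
    est = PAM(n_clusters=k).fit(Xs)
    sil = silhouette_samples(est._distances, est.labels_, metric="precomputed")
    return ClusterResult(
        k=k,
        sample_ids=list(S.sample_ids),
        labels=est.labels_,
        medoid_ids=[S.sample_ids[i] for i in est.medoid_indices_],
        silhouette=sil,
        asw=float(sil.mean()),
    )


def choose_k(S: SummaryMatrix, k_range: range | tuple[int, int] = (2, 10)) -> ClusterResult:
    """Run PAM over a range of k and keep the silhouette-maximising solution.

    Ties break toward smaller k; every (k, ASW) pair is reported so the
    profile can be inspected. A warning is raised when even the best average
    silhouette width is weak (< 0.25), i.e. no convincing cluster structure.
    """
    if isinstance(k_range, tuple):
        ks = range(k_range[0], k_range[1] + 1)
    else:
        ks = k_range
    n = len(S.sample_ids)
    ks = [k for k in ks if 2 <= k < n]
    if not ks:
        raise ValueError("empty k range")
    results = {k: pam_cluster(S, k) for k in ks}
    asw_by_k = {k: r.asw for k, r in results.items()}
    best_k = min(ks, key=lambda k: (-asw_by_k[k], k))
    best = results[best_k]
    best.asw_by_k = asw_by_k
    if best.asw < 0.25:
        warnings.warn(f"weak cluster structure: best ASW {best.asw:.3f} < 0.25")
    return best


def cluster_centroids(S: SummaryMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster mean summary profile; rows = set ids, columns = cluster labels."""
    out = {}
    for lab in np.unique(labels):
        out[lab] = S.values[:, labels == lab].mean(axis=1)
    return pd.DataFrame(out, index=S.set_ids)


def centroid_correlation(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every centroid of A and of B over shared sets."""
    shared = A.index.intersection(B.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sets; need >= 3 for correlations")
    Av = A.loc[shared].to_numpy()
    Bv = B.loc[shared].to_numpy()
    Ac = Av - Av.mean(axis=0)
    Bc = Bv - Bv.mean(axis=0)
    num = Ac.T @ Bc
    den = np.outer(np.sqrt((Ac**2).sum(axis=0)), np.sqrt((Bc**2).sum(axis=0)))
    return pd.DataFrame(num / den, index=A.columns, columns=B.columns)
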