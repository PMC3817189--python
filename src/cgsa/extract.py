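"""Extraction of disjoint, positively co-expressed gene sets (CGSs).

Every gene is treated as the centre of a candidate set containing all genes
positively correlated with it at or above ``r_min``. Candidates are scored by

    score(c) = s2_c * sum_{j in members} r_cj^2

(the centre's sample variance times the summed squared centre correlations,
so the score grows with set size, centre variance and tightness), then a
greedy scan accepts the highest-scoring candidates whose members do not
overlap any previously accepted set, stopping after ``n_sets`` acceptances.
Each accepted set is summarised per sample by a weighted sum of its member
genes with permutation-invariant weights 1/s_j.

Because every statistic used (variances, covariances) is invariant under
permutation of the samples, the extracted collection carries no information
about any sample grouping — the property that lets downstream association
tests keep their nominal level despite the data-dependent set construction.
All moments are accumulated with samples in a canonical (sorted-identifier)
order, making the output bitwise invariant to the column order of the input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .exprio import ExpressionMatrix, GeneSetFile, GeneSetRecord

logger = logging.getLogger("cgsa")

SCORE_FORMULA_ID = "center_var_times_sum_r2"


class DegenerateGeneError(ValueError):
    """A centre gene with zero variance cannot seed a candidate set."""


@dataclass
class CorrelatedGeneSet:
    """One extracted gene set: a centre gene plus its correlated members."""

    center_gene: str
    members: list[str]  # centre first, remaining members in input row order
    score: float
    rank: int = 0

    def __post_init__(self) -> None:
        if self.center_gene not in self.members:
            raise ValueError(f"center {self.center_gene!r} not among members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in set centred on {self.center_gene!r}")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CGSCollection:
    """Ranked, pairwise-disjoint collection of correlated gene sets."""

    sets: list[CorrelatedGeneSet]
    parameters: dict = field(default_factory=dict)
    source_fingerprint: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.sets:
            overlap = seen.intersection(s.members)
            if overlap:
                raise ValueError(f"sets are not disjoint: {sorted(overlap)[:3]} shared")
            seen.update(s.members)
        ranks = [s.rank for s in self.sets]
        if ranks != list(range(1, len(self.sets) + 1)):
            raise ValueError("ranks must be 1..n in order")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def set_ids(self) -> list[str]:
        width = max(2, len(str(len(self.sets))))
        return [f"CGS{s.rank:0{width}d}" for s in self.sets]

    def member_union(self) -> set[str]:
        return set().union(*(s.members for s in self.sets)) if self.sets else set()

    def to_gene_set_file(self) -> GeneSetFile:
        """GMT carrier: centre gene first member, score in the description."""
        records = []
        for sid, s in zip(self.set_ids(), self.sets):
            members = [s.center_gene] + [m for m in s.members if m != s.center_gene]
            records.append(
                GeneSetRecord(sid, f"score={s.score:.12g};center={s.center_gene}", members)
            )
        return GeneSetFile(records)


@dataclass
class SummaryMatrix:
    """Per-set, per-sample summary scores plus the statistics that built them.

    ``weights`` holds, per set, the (gene, weight) pairs actually used;
    ``signs`` the orientation flags; ``means``/``sds`` the pre-standardisation
    location/scale of each oriented summary, retained so external samples can
    be summarised on the reference scale.
    """

    set_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_sets, n_samples)
    weights: list[list[tuple[str, float]]]
    signs: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    standardized: bool = True
    centers: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.set_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# moment computation in canonical sample order


def _canonical_values(X: ExpressionMatrix) -> np.ndarray:
    order = np.argsort(np.asarray(X.sample_ids, dtype=object))
    return X.values[:, order]


def correlation_with_center(X: ExpressionMatrix, center: str) -> np.ndarray:
    """Pearson correlation of every gene with the centre gene, across samples.

    Zero-variance genes other than the centre get correlation 0 (warned);
    a zero-variance centre raises :class:`DegenerateGeneError`.
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    V = _canonical_values(X)
    ci = X.gene_index()[center]
    c = V[ci]
    c_sd = c.std(ddof=1)
    if c_sd == 0:
        raise DegenerateGeneError(f"center gene {center!r} has zero variance")
    Vc = V - V.mean(axis=1, keepdims=True)
    sds = V.std(axis=1, ddof=1)
    zero = sds == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance genes: correlation set to 0")
    denom = np.where(zero, 1.0, sds) * c_sd * (X.n_samples - 1)
    r = (Vc @ (c - c.mean())) / denom
    r[zero] = 0.0
    r[ci] = 1.0
    return np.clip(r, -1.0, 1.0)


def build_candidate_set(X: ExpressionMatrix, center: str, r_min: float) -> CorrelatedGeneSet:
    """Candidate set around ``center``: genes with r >= r_min (centre included)."""
    if not 0 < r_min < 1:
        raise ValueError("r_min must lie in (0, 1)")
    r = correlation_with_center(X, center)
    keep = np.flatnonzero(r >= r_min)
    members = [X.gene_ids[i] for i in keep]
    members = [center] + [m for m in members if m != center]
    return CorrelatedGeneSet(center, members, score=0.0)


def score_candidate_set(X: ExpressionMatrix, cset: CorrelatedGeneSet) -> float:
    """Default score: centre variance times summed squared centre correlations."""
    idx = X.gene_index()
    for m in cset.members:
        if m not in idx:
            raise ValueError(f"member {m!r} not present in the expression matrix")
    r = correlation_with_center(X, cset.center_gene)
    V = _canonical_values(X)
    s2c = V[idx[cset.center_gene]].var(ddof=1)
    rows = [idx[m] for m in cset.members]
    return float(s2c * np.sum(r[rows] ** 2))


def select_disjoint_top_k(
    candidates: Sequence[CorrelatedGeneSet], K: int, min_size: int = 2
) -> list[CorrelatedGeneSet]:
    """Greedy disjoint selection: scan by descending score, accept non-overlapping.

    Ties in score break by centre gene identifier (ascending) for determinism.
    Returns fewer than K sets (with a warning) if the candidates run out.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    order = sorted(candidates, key=lambda s: (-s.score, s.center_gene))
    taken: set[str] = set()
    accepted: list[CorrelatedGeneSet] = []
    for cand in order:
        if len(accepted) >= K:
            break
        if cand.size < min_size:
            continue
        if taken.intersection(cand.members):
            continue
        accepted.append(
            CorrelatedGeneSet(cand.center_gene, list(cand.members), cand.score, rank=len(accepted) + 1)
        )
        taken.update(cand.members)
    if len(accepted) < K:
        warnings.warn(f"only {len(accepted)} disjoint sets available (requested {K})")
    return accepted


def extract_cgs_collection(
    X: ExpressionMatrix,
    n_sets: int = 50,
    r_min: float = 0.7,
    min_size: int = 2,
) -> CGSCollection:
    """Full extraction: candidates around every gene, score, greedy top-K.

    Vectorised over the gene-gene correlation matrix; equivalent to calling
    :func:`build_candidate_set` / :func:`score_candidate_set` per gene and
    :func:`select_disjoint_top_k` on the result.
    """
    if not 0 < r_min < 1:
        raise ValueError("r_min must lie in (0, 1)")
    V = _canonical_values(X)
    n_genes, n_samples = V.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    var = V.var(axis=1, ddof=1)
    live = var > 0
    if not live.all():
        warnings.warn(f"{int((~live).sum())} zero-variance genes excluded as centres")
    Vc = V - V.mean(axis=1, keepdims=True)
    sd = np.sqrt(var * (n_samples - 1))
    sd_safe = np.where(live, sd, 1.0)
    R = (Vc / sd_safe[:, None]) @ (Vc / sd_safe[:, None]).T
    np.clip(R, -1.0, 1.0, out=R)
    R[~live, :] = 0.0
    R[:, ~live] = 0.0
    np.fill_diagonal(R, np.where(live, 1.0, 0.0))

    member_mask = R >= r_min  # row c: candidate membership around centre c
    member_mask[~live, :] = False
    scores = var * np.where(member_mask, R * R, 0.0).sum(axis=1)
    sizes = member_mask.sum(axis=1)

    gene_arr = np.asarray(X.gene_ids, dtype=object)
    cand_order = sorted(
        np.flatnonzero(live), key=lambda i: (-scores[i], X.gene_ids[i])
    )
    taken = np.zeros(n_genes, dtype=bool)
    accepted: list[CorrelatedGeneSet] = []
    for i in cand_order:
        if len(accepted) >= n_sets:
            break
        if sizes[i] < min_size:
            continue
        mask = member_mask[i]
        if np.any(mask & taken):
            continue
        center = X.gene_ids[i]
        members = [center] + [g for g in gene_arr[mask] if g != center]
        accepted.append(CorrelatedGeneSet(center, members, float(scores[i]), rank=len(accepted) + 1))
        taken |= mask
    if len(accepted) < n_sets:
        warnings.warn(f"only {len(accepted)} disjoint sets available (requested {n_sets})")
    return CGSCollection(
        accepted,
        parameters={
            "n_sets": n_sets,
            "r_min": r_min,
            "min_size": min_size,
            "score_formula": SCORE_FORMULA_ID,
        },
        source_fingerprint=X.fingerprint(),
    )


def summarize_cgs(
    X: ExpressionMatrix,
    collection: CGSCollection,
    standardize: bool = True,
    weight_scheme: str = "inverse_sd",
) -> SummaryMatrix:
    """Per-set, per-sample summary scores.

    summary_i = sum_j w_j x_ji with w_j = 1/s_j (total standard deviation of
    gene j) — a weight depending only on permutation-invariant moments — then
    oriented to correlate positively with the centre gene and, if requested,
    standardised to mean 0 / variance 1 across samples. Zero-variance members
    are excluded from the sum with a warning.
    """
    if weight_scheme not in ("inverse_sd", "equal"):
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    idx = X.gene_index()
    order = np.argsort(np.asarray(X.sample_ids, dtype=object))
    V = X.values[:, order]
    sds = V.std(axis=1, ddof=1)

    n_sets = len(collection)
    values = np.empty((n_sets, X.n_samples))
    weights: list[list[tuple[str, float]]] = []
    signs = np.ones(n_sets)
    means = np.zeros(n_sets)
    scales = np.ones(n_sets)
    for k, cset in enumerate(collection):
        rows, wlist = [], []
        for m in cset.members:
            i = idx[m]
            if sds[i] == 0:
                warnings.warn(f"zero-variance member {m!r} excluded from summary")
                continue
            rows.append(i)
            wlist.append((m, 1.0 / sds[i] if weight_scheme == "inverse_sd" else 1.0))
        if not rows:
            raise DegenerateGeneError(f"set {cset.center_gene!r} has no usable members")
        w = np.array([wv for _, wv in wlist])
        summary = w @ V[rows]
        center_prof = V[idx[cset.center_gene]]
        cov = np.cov(summary, center_prof, ddof=1)[0, 1]
        sign = -1.0 if cov < 0 else 1.0
        summary = sign * summary
        mu = summary.mean()
        sd = summary.std(ddof=1)
        if standardize:
            if sd == 0:
                raise DegenerateGeneError(f"summary of {cset.center_gene!r} is constant")
            summary = (summary - mu) / sd
        values[k] = summary
        weights.append(wlist)
        signs[k], means[k], scales[k] = sign, mu, sd if sd > 0 else 1.0

    inv = np.argsort(order)  # back to input column order
    return SummaryMatrix(
        set_ids=collection.set_ids(),
        sample_ids=list(X.sample_ids),
        values=values[:, inv],
        weights=weights,
        signs=signs,
        means=means,
        sds=scales,
        standardized=standardize,
        centers=[s.center_gene for s in collection],
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator surface


class CorrelatedGeneSets(TransformerMixin, BaseEstimator):
    """Dimension reduction by disjoint correlated-gene-set extraction.

    Fit on an (n_samples, n_genes) array or DataFrame; ``transform`` returns
    per-sample summary scores of the fitted sets, (n_samples, n_sets_). New
    samples are summarised with the training weights and put on the training
    location/scale, so transforming external cohorts reproduces the reference
    frame.

    Parameters
    ----------
    n_sets : int, default 50
        Maximum number of disjoint sets to keep (the paper-scale default).
    r_min : float, default 0.7
        Minimum centre correlation for candidate membership.
    min_size : int, default 2
        Smallest acceptable set; singletons carry no co-expression signal.
    standardize : bool, default True
        Standardise each summary row over the training samples.
    weight_scheme : {"inverse_sd", "equal"}, default "inverse_sd"
        Member weights in the summary: inverse total SD or unweighted.
    """

    def __init__(
        self,
        n_sets: int = 50,
        r_min: float = 0.7,
        min_size: int = 2,
        standardize: bool = True,
        weight_scheme: str = "inverse_sd",
    ):
        self.n_sets = n_sets
        self.r_min = r_min
        self.min_size = min_size
        self.standardize = standardize
        self.weight_scheme = weight_scheme

    def _as_expression(self, X, *, reset: bool) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            if reset:
                self.feature_names_in_ = np.asarray(X.gene_ids, dtype=object)
                self.n_features_in_ = X.n_genes
            return X
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            sample_ids = [str(s) for s in X.index]
        else:
            sample_ids = None
        arr = validate_data(
            self, X, reset=reset, dtype=float, ensure_min_samples=3 if reset else 1
        )
        if sample_ids is None:
            sample_ids = [f"S{j + 1:04d}" for j in range(arr.shape[0])]
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"G{i + 1:05d}" for i in range(arr.shape[1])]
        return ExpressionMatrix(list(names), sample_ids, arr.T)

    def fit(self, X, y=None):
        Xm = self._as_expression(X, reset=True)
        self.collection_ = extract_cgs_collection(
            Xm, n_sets=self.n_sets, r_min=self.r_min, min_size=self.min_size
        )
        self.summary_ = summarize_cgs(
            Xm, self.collection_, standardize=self.standardize, weight_scheme=self.weight_scheme
        )
        self.set_ids_ = list(self.summary_.set_ids)
        self.n_sets_ = len(self.collection_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "collection_")
        Xm = self._as_expression(X, reset=False)
        ref = self.summary_
        idx = Xm.gene_index()
        out = np.empty((len(ref.set_ids), Xm.n_samples))
        for k, wlist in enumerate(ref.weights):
            rows = [idx[g] for g, _ in wlist]
            w = np.array([wv for _, wv in wlist])
            summary = ref.signs[k] * (w @ Xm.values[rows])
            if ref.standardized:
                summary = (summary - ref.means[k]) / ref.sds[k]
            out[k] = summary
        return out.T

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "set_ids_")
        return np.asarray(self.set_ids_, dtype=object)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = False
        return tags
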