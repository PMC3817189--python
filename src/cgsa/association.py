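"""Association testing of gene-set summaries against sample phenotypes.

Effect sizes are reported as R-squared — the squared Pearson correlation for
quantitative phenotypes, or the between-group share of the total sum of
squares (eta-squared) for categorical ones — together with the AUC for binary
phenotypes. Family-wise error over the whole collection of sets is controlled
by single-step max-T permutation adjustment (Westfall-Young): the phenotype
labels are permuted, all per-set statistics recomputed, and each observed
statistic compared with the permutation distribution of the maximum. Because
the sets themselves were built from permutation-invariant statistics only,
permuting the phenotype is a valid group action and the adjusted level holds
despite the data-dependent construction of the sets. With B permutations the
smallest attainable adjusted p is 1/(B+1) — 0.001 at the default B = 999.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import ExpressionMatrix, PhenotypeTable
from .extract import SummaryMatrix


class UndefinedEffectError(ValueError):
    """Effect size undefined (constant summary or constant phenotype)."""


def _clean_pairs(z: np.ndarray, y: pd.Series | np.ndarray):
    z = np.asarray(z, dtype=float)
    y = pd.Series(y) if not isinstance(y, pd.Series) else y
    ok = ~(pd.isna(y).to_numpy() | ~np.isfinite(z))
    return z[ok], y[ok].reset_index(drop=True)


def beta_r_squared(z, y, kind: str = "auto") -> tuple[float, float, int]:
    """R-squared of a per-sample summary against one phenotype, with raw p.

    Quantitative phenotype: squared Pearson correlation, p from the F test of
    the simple regression. Categorical: eta-squared from a one-way
    decomposition of z by the phenotype levels, p from the one-way F.
    Missing phenotype entries are excluded pairwise. Returns (r2, p, n).
    """
    z, y = _clean_pairs(z, y)
    n = len(z)
    if n < 3:
        raise UndefinedEffectError("fewer than 3 non-missing pairs")
    if kind == "auto":
        kind = "quantitative" if pd.api.types.is_numeric_dtype(y) else "categorical"
    if np.std(z) == 0:
        raise UndefinedEffectError("summary is constant")
    if kind == "quantitative":
        yv = y.to_numpy(dtype=float)
        if np.std(yv) == 0:
            raise UndefinedEffectError("phenotype is constant")
        r = float(np.corrcoef(z, yv)[0, 1])
        r2 = r * r
        df2 = n - 2
        F = r2 / max(1 - r2, 1e-300) * df2
        p = float(stats.f.sf(F, 1, df2))
        return r2, p, n
    codes, levels = pd.factorize(y)
    g = len(levels)
    if g < 2:
        raise UndefinedEffectError("categorical phenotype has fewer than 2 levels")
    grand = z.mean()
    ssb = sum(
        (z[codes == i]).size * (z[codes == i].mean() - grand) ** 2 for i in range(g)
    )
    sst = float(((z - grand) ** 2).sum())
    if sst == 0:
        raise UndefinedEffectError("summary is constant")
    r2 = float(ssb / sst)
    ssw = sst - ssb
    df1, df2 = g - 1, n - g
    if df2 <= 0:
        raise UndefinedEffectError("no residual degrees of freedom")
    F = (ssb / df1) / max(ssw / df2, 1e-300)
    p = float(stats.f.sf(F, df1, df2))
    return r2, p, n


def auc_binary(z, y, positive=None) -> tuple[float, float]:
    """AUC of a summary for a binary phenotype (rank form, ties count 1/2).

    Returns (auc, auc_raw): ``auc_raw`` is the probability that a random
    sample of the declared positive level scores higher than a random
    negative; ``auc`` is the orientation-fixed value max(raw, 1 - raw).
    """
    z, y = _clean_pairs(z, y)
    levels = pd.unique(y)
    if len(levels) != 2:
        raise ValueError(f"phenotype has {len(levels)} levels; AUC needs exactly 2")
    if positive is None:
        positive = sorted(map(str, levels))[-1]
    pos = (y.astype(str) == str(positive)).to_numpy()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one phenotype class is empty")
    ranks = stats.rankdata(z)
    auc_raw = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return max(auc_raw, 1 - auc_raw), auc_raw


def _set_statistics(Z: np.ndarray, y, kind: str) -> np.ndarray:
    """Per-set association statistic: squared correlation (quantitative) or F."""
    n = Z.shape[1]
    if kind == "quantitative":
        yv = np.asarray(y, dtype=float)
        yc = yv - yv.mean()
        ss_y = (yc**2).sum()
        Zc = Z - Z.mean(axis=1, keepdims=True)
        ss_z = (Zc**2).sum(axis=1)
        ss_z[ss_z == 0] = np.inf
        r = (Zc @ yc) / np.sqrt(ss_z * ss_y)
        return r**2
    codes = np.asarray(y, dtype=int)
    g = codes.max() + 1
    ind = np.zeros((g, n))
    ind[codes, np.arange(n)] = 1.0
    counts = ind.sum(axis=1)
    sums = Z @ ind.T  # (K, g)
    grand = Z.mean(axis=1, keepdims=True)
    ssb = ((sums / counts - grand) ** 2 * counts).sum(axis=1)
    sst = ((Z - grand) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    df1, df2 = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    return np.where(np.isfinite(F), F, np.inf)


def adjust_maxT(
    T_obs: np.ndarray,
    Z: np.ndarray,
    y,
    B: int = 999,
    seed: int | np.random.Generator = 0,
    kind: str = "quantitative",
) -> np.ndarray:
    """Single-step max-T adjusted p-values for per-set statistics.

    For each of B phenotype permutations all per-set statistics are
    recomputed and their maximum recorded; the adjusted p of set s is
    (1 + #{b: max_b >= T_s}) / (B + 1). Monotone in T_s, floored at 1/(B+1).
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    if B < 999:
        import warnings

        warnings.warn(f"B={B} limits adjusted-p resolution to {1 / (B + 1):.4g}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[1]
    if kind == "categorical":
        y_codes = pd.factorize(pd.Series(y))[0]
        maxes = np.empty(B)
        for b in range(B):
            maxes[b] = _set_statistics(Z, y_codes[rng.permutation(n)], "categorical").max()
    else:
        yv = np.asarray(y, dtype=float)
        yc = yv - yv.mean()
        ss_y = (yc**2).sum()
        Zc = Z - Z.mean(axis=1, keepdims=True)
        ss_z = (Zc**2).sum(axis=1)
        ss_z[ss_z == 0] = np.inf
        P = np.empty((B, n))
        for b in range(B):
            P[b] = yc[rng.permutation(n)]
        R = (Zc @ P.T) / np.sqrt(ss_z[:, None] * ss_y)  # (K, B)
        maxes = (R**2).max(axis=0)
    T_obs = np.asarray(T_obs, dtype=float)
    counts = (maxes[None, :] >= T_obs[:, None]).sum(axis=1)
    return (1.0 + counts) / (B + 1.0)


def associate(
    S: SummaryMatrix,
    phenotypes: PhenotypeTable,
    B: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every set against every declared phenotype, max-T adjusted.

    Returns a long-form frame: set_id, phenotype, n, r_squared, auc, p_raw,
    p_adjusted. Missing phenotype entries are dropped pairwise per phenotype;
    the permutation statistic is the squared correlation (quantitative) or
    the one-way F (categorical), so one procedure covers both.
    """
    rng = np.random.default_rng(seed)
    sample_pos = {s: j for j, s in enumerate(S.sample_ids)}
    rows = []
    for pheno, kind in phenotypes.schema.items():
        y_full = phenotypes.column(pheno)
        shared = [s for s in S.sample_ids if s in y_full.index]
        y = y_full.loc[shared]
        ok = ~pd.isna(y)
        used = [s for s, o in zip(shared, ok) if o]
        if len(used) < 3:
            continue
        Z = S.values[:, [sample_pos[s] for s in used]]
        y_used = y[ok.to_numpy()]
        if kind == "categorical":
            codes = pd.factorize(y_used)[0]
            T = _set_statistics(Z, codes, "categorical")
            adj = adjust_maxT(T, Z, codes, B=B, seed=rng, kind="categorical")
        else:
            yv = y_used.to_numpy(dtype=float)
            T = _set_statistics(Z, yv, "quantitative")
            adj = adjust_maxT(T, Z, yv, B=B, seed=rng, kind="quantitative")
        binary = kind == "categorical" and y_used.nunique() == 2
        for k, sid in enumerate(S.set_ids):
            r2, p_raw, n_used = beta_r_squared(Z[k], y_used, kind=kind)
            auc = auc_binary(Z[k], y_used)[0] if binary else np.nan
            rows.append(
                {
                    "set_id": sid,
                    "phenotype": pheno,
                    "n": n_used,
                    "r_squared": r2,
                    "auc": auc,
                    "p_raw": p_raw,
                    "p_adjusted": float(adj[k]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    signature_id: str
    p_factor_a: float
    p_factor_b: float
    n: int


def signature_pc1(X: ExpressionMatrix, signature_genes: list[str]) -> np.ndarray:
    """First principal component of a signature's genes, one score per sample.

    Sign-oriented to correlate positively with the mean signature profile, so
    higher scores mean higher signature expression. A single-gene signature
    reduces to that gene's standardised profile.
    """
    present = [g for g in signature_genes if g in set(X.gene_ids)]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    sub = X.subset_genes(present).values  # genes x samples
    if sub.shape[0] == 1:
        v = sub[0]
        return (v - v.mean()) / v.std(ddof=1)
    M = (sub - sub.mean(axis=1, keepdims=True)).T  # samples x genes
    U, sv, Vt = np.linalg.svd(M, full_matrices=False)
    pc1 = U[:, 0] * sv[0]
    mean_prof = sub.mean(axis=0)
    if np.corrcoef(pc1, mean_prof - mean_prof.mean())[0, 1] < 0:
        pc1 = -pc1
    return pc1


def signature_anova(
    X: ExpressionMatrix,
    signature_genes: list[str],
    factor_a: pd.Series,
    factor_b: pd.Series,
    signature_id: str = "signature",
) -> AnovaResult:
    """Two-way main-effects ANOVA of a signature's PC1 on two groupings.

    The dependent variable is the signature's first principal component;
    main effects only (type II), matching the use of contrasting two sample
    groupings without modelling their interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    present = [g for g in signature_genes if g in set(X.gene_ids)]
    if len(present) < 1:
        raise ValueError("no signature genes present")
    pc1 = signature_pc1(X, signature_genes)
    df = pd.DataFrame(
        {
            "pc1": pc1,
            "fa": factor_a.reindex(X.sample_ids).to_numpy(),
            "fb": factor_b.reindex(X.sample_ids).to_numpy(),
        }
    ).dropna()
    for col in ("fa", "fb"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 observed levels")
    model = smf.ols("pc1 ~ C(fa) + C(fb)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("design is not estimable: empty factor cell pattern")
    tab = anova_lm(model, typ=2)
    return AnovaResult(
        signature_id=signature_id,
        p_factor_a=float(tab.loc["C(fa)", "PR(>F)"]),
        p_factor_b=float(tab.loc["C(fb)", "PR(>F)"]),
        n=len(df),
    )
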