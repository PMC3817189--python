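"""Gene-wise generalized log-ratios, differential expression, and
class-partitioned fold-change densities.

Because the expression values are on a variance-stabilised (generalized-log)
scale, the difference of group means per gene is a generalized log-ratio —
an estimated log fold change. Two-group differential expression uses the
Welch t-test with Benjamini-Hochberg FDR control. The density machinery
decomposes the distribution of log-ratios by an external gene classification
(e.g. highly/lowly expressed, HE/LE): each class density is scaled by the
class's share of classified genes so the scaled class curves sum pointwise
to the density of all classified genes, which makes the visual decomposition
additive by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exprio import ExpressionMatrix


def group_log_ratios(
    X: ExpressionMatrix, group_a: list[str], group_b: list[str], label: str | None = None
) -> pd.DataFrame:
    """Per-gene difference of group means (A minus B) on the glog scale."""
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    pos = {s: j for j, s in enumerate(X.sample_ids)}
    ia = [pos[s] for s in group_a]
    ib = [pos[s] for s in group_b]
    lr = X.values[:, ia].mean(axis=1) - X.values[:, ib].mean(axis=1)
    return pd.DataFrame(
        {"gene_id": X.gene_ids, "log_ratio": lr, "contrast": label or "A-B"}
    ).set_index("gene_id")


def de_test(
    X: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    fdr: float = 0.05,
    label: str | None = None,
) -> pd.DataFrame:
    """Welch two-sample t-test per gene with BH adjustment across all genes.

    Returns a frame indexed by gene with log_ratio, t, p, q and an
    ``up``/``down`` call at the requested FDR. Genes constant and equal in
    both groups get p = 1 (no evidence), not an error.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 samples for the test")
    lr = group_log_ratios(X, group_a, group_b, label=label)
    pos = {s: j for j, s in enumerate(X.sample_ids)}
    A = X.values[:, [pos[s] for s in group_a]]
    B = X.values[:, [pos[s] for s in group_b]]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    diff = lr["log_ratio"].to_numpy()
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero within-group variance in both groups: p=1 when means agree,
        # effectively certain difference otherwise
        p = np.where(degenerate & (diff == 0), 1.0, p)
        p = np.where(degenerate & (diff != 0), 0.0, p)
        t = np.where(np.isfinite(t), t, np.sign(diff) * np.inf)
    q = multipletests(p, method="fdr_bh")[1]
    out = lr.copy()
    out["t"] = t
    out["p"] = p
    out["q"] = q
    out["up"] = (q <= fdr) & (diff > 0)
    out["down"] = (q <= fdr) & (diff < 0)
    return out


def de_counts(result: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) at the FDR used by :func:`de_test`."""
    return int(result["up"].sum()), int(result["down"].sum())


@dataclass
class PartitionedDensity:
    grid: np.ndarray
    class_density: dict[str, np.ndarray]  # scaled: sums pointwise to `total`
    total: np.ndarray
    bandwidth: float
    class_share: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"grid": self.grid, "total": self.total})
        for cls, dens in self.class_density.items():
            df[cls] = dens
        return df


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        raise ValueError("degenerate data: zero spread")
    return 0.9 * scale * n ** (-0.2)


def partitioned_density(
    ratios: pd.DataFrame | pd.Series,
    classes: Mapping[str, str],
    grid: np.ndarray | None = None,
    n_grid: int = 512,
    min_class_size: int = 10,
) -> PartitionedDensity:
    """Gaussian-kernel densities of log-ratios split by gene class.

    ``classes`` maps gene id to a class label; genes mapped to
    ``"unclassified"`` (or absent) are excluded. One Silverman bandwidth is
    computed on the pooled classified genes and shared across classes, and
    each class density is weighted by its share of classified genes — so the
    scaled class densities sum pointwise to the density of all classified
    genes exactly (up to numerical evaluation error).
    """
    if isinstance(ratios, pd.DataFrame):
        ratios = ratios["log_ratio"]
    values: dict[str, np.ndarray] = {}
    for cls in sorted(set(classes.values()) - {"unclassified"}):
        genes = [g for g, c in classes.items() if c == cls and g in ratios.index]
        if not genes:
            warnings.warn(f"class {cls!r} has no genes with log-ratios; omitted")
            continue
        if len(genes) < min_class_size:
            raise ValueError(f"class {cls!r} has {len(genes)} genes; need >= {min_class_size}")
        values[cls] = ratios.loc[genes].to_numpy(dtype=float)
    if not values:
        raise ValueError("no classified genes")
    pooled = np.concatenate(list(values.values()))
    h = _silverman_bandwidth(pooled)
    if grid is None:
        grid = np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, n_grid)
    grid = np.asarray(grid, dtype=float)
    n_total = len(pooled)
    class_density = {}
    total = np.zeros_like(grid)
    for cls, x in values.items():
        # shared absolute bandwidth; dividing by n_total (not len(x)) applies
        # the class-share scaling directly
        dens = stats.norm.pdf((grid[:, None] - x[None, :]) / h).sum(axis=1) / (n_total * h)
        class_density[cls] = dens
        total += dens
    share = {cls: len(x) / n_total for cls, x in values.items()}
    return PartitionedDensity(grid, class_density, total, h, share)


def venn_partition(up_lists: Mapping[str, set[str] | list[str]]) -> dict[tuple[str, ...], set[str]]:
    """Partition genes by which of the up-lists they belong to.

    Returns every non-empty combination as a tuple key of sorted list names
    mapping to the genes found in exactly those lists — the regions of the
    Venn diagram over (typically three) overexpressed-gene lists.
    """
    sets = {name: set(genes) for name, genes in up_lists.items()}
    universe = set().union(*sets.values()) if sets else set()
    out: dict[tuple[str, ...], set[str]] = {}
    for g in universe:
        key = tuple(sorted(name for name, s in sets.items() if g in s))
        out.setdefault(key, set()).add(g)
    return out
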