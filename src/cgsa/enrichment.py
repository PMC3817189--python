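"""Annotation-term enrichment: hypergeometric over-representation and
PAGE-style parametric enrichment.

Hypergeometric enrichment asks whether a query gene set shares more genes
with an annotation term than expected when drawing the query at random from
the universe (one-sided upper tail). PAGE compares the mean per-gene score
(e.g. a log fold change, or a membership indicator) of a gene subset with
the global score distribution via z = (S_m - mu) * sqrt(m) / delta and a
two-sided normal p — positive z means enrichment, negative depletion.
Reported p-values are unadjusted by default; per-category report thresholds
(GO 0.001, KEGG 0.01, chromosomal band 0.001, PAGE 0.005) are filters on the
report, not on the emitted statistics.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import GeneSetFile

REPORT_THRESHOLDS = {"GO": 0.001, "KEGG": 0.01, "band": 0.001, "PAGE": 0.005}


def _catalog_dict(catalog) -> dict[str, list[str]]:
    if isinstance(catalog, GeneSetFile):
        return catalog.as_dict()
    return {k: list(v) for k, v in catalog.items()}


def hypergeom_enrich(
    query: Sequence[str],
    catalog,
    universe: Sequence[str],
    min_term_size: int = 10,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of catalog terms in a query.

    Query and terms are intersected with the universe first; terms must have
    more than ``min_term_size`` genes in the universe to be tested. Returns a
    frame (term, term_size, overlap, p) sorted by p; p-values are unadjusted.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    rows = []
    for term, genes in _catalog_dict(catalog).items():
        tset = set(genes) & uni
        K = len(tset)
        if K <= min_term_size:
            continue
        k = len(q & tset)
        p = float(stats.hypergeom.sf(k - 1, len(uni), K, len(q)))
        rows.append({"term": term, "term_size": K, "overlap": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def page_enrich(
    scores: pd.Series | Mapping[str, float],
    subsets: Mapping[str, Sequence[str]],
    min_subset_size: int = 10,
) -> pd.DataFrame:
    """PAGE z and p per gene subset against the global score distribution.

    ``scores`` holds one value per gene (the global population, >= 30 genes);
    each subset's mean S_m is standardised by the global mean and SD:
    z = (S_m - mu) * sqrt(m) / delta, with a two-sided normal p and a signed
    -log10 p for heat-map style reporting.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 30:
        raise ValueError("need at least 30 genes in the global score vector")
    mu = float(s.mean())
    delta = float(s.std(ddof=1))
    if delta == 0:
        raise ValueError("global score SD is zero")
    rows = []
    for name, genes in subsets.items():
        present = [g for g in genes if g in s.index]
        m = len(present)
        if m < min_subset_size:
            continue
        S_m = float(s.loc[present].mean())
        z = (S_m - mu) * np.sqrt(m) / delta
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append(
            {
                "subset": name,
                "m": m,
                "mean": S_m,
                "z": z,
                "p": p,
                "direction": int(np.sign(z)) if z != 0 else 0,
                "signed_log10_p": -np.sign(z) * np.log10(p) if z != 0 else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["subset", "m", "mean", "z", "p", "direction", "signed_log10_p"]
    )


def page_matrix(
    regions: Mapping[str, Sequence[str]],
    catalog,
    universe: Sequence[str],
    min_term_size: int = 10,
) -> pd.DataFrame:
    """Signed -log10 p matrix of term enrichment within each gene region.

    For each region (e.g. a Venn partition of overexpressed genes) the score
    vector is the 0/1 indicator of region membership over the universe and
    each catalog term is a PAGE subset — positive entries mean the term's
    genes are over-represented in that region, negative depleted.
    """
    uni = list(dict.fromkeys(universe))
    cat = {
        t: [g for g in genes if g in set(uni)]
        for t, genes in _catalog_dict(catalog).items()
    }
    cat = {t: g for t, g in cat.items() if len(g) > min_term_size}
    out = pd.DataFrame(index=sorted(cat), columns=list(regions), dtype=float)
    for rname, rgenes in regions.items():
        rset = set(rgenes)
        ind = pd.Series([1.0 if g in rset else 0.0 for g in uni], index=uni)
        res = page_enrich(ind, cat, min_subset_size=min_term_size)
        for _, row in res.iterrows():
            out.loc[row["subset"], rname] = row["signed_log10_p"]
    return out
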