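"""Rank-based category enrichment of locus–phenotype correlations.

Instead of dichotomizing loci into significant/background, every locus keeps
its signed correlation coefficient with the residual bleaching phenotype and
each annotation category is tested by a one-sided Mann–Whitney U test of
member ranks against non-member ranks (direction of interest: members
enriched for *high* correlations, i.e. bleaching-associated).  Ties are
handled by midranks; Benjamini–Hochberg adjustment is applied within each GO
namespace.  Categories are tested flat — no GO-hierarchy propagation or
category clustering.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import EnrichConfig


def filter_annotations(
    annot: pd.DataFrame,
    universe: Sequence[str],
    cfg: EnrichConfig,
) -> pd.DataFrame:
    """Restrict annotations to the screened universe and usable categories.

    Categories smaller than ``min_category_size`` or covering more than
    ``max_category_fraction`` of the universe are dropped (a category spanning
    most of the universe cannot be enriched against it).
    """
    cfg.validate()
    universe = set(universe)
    a = annot[annot["locus_id"].isin(universe)].drop_duplicates(["locus_id", "category"])
    sizes = a.groupby("category", observed=True)["locus_id"].nunique()
    max_n = cfg.max_category_fraction * len(universe)
    keep = sizes[(sizes >= cfg.min_category_size) & (sizes <= max_n)].index
    return a[a["category"].isin(keep)]


def mwu_enrichment(
    r_by_locus: Mapping[str, float],
    annot: pd.DataFrame,
    cfg: EnrichConfig = EnrichConfig(),
    fdr_levels: Tuple[float, float] = (0.05, 0.10),
) -> pd.DataFrame:
    """One-sided rank-sum enrichment per category with BH adjustment.

    ``r_by_locus`` maps every locus in the screened universe to its signed
    correlation coefficient; ``annot`` is a long table with columns
    (locus_id, category[, namespace, name]).  Returns one row per tested
    category: n_loci, U statistic, one-sided p toward high r, the opposite
    tail, BH-adjusted p (within namespace), direction, and significance flags
    at each FDR level.
    """
    r = pd.Series(dict(r_by_locus), dtype=float)
    if not np.isfinite(r.to_numpy()).all():
        raise ValueError("correlation coefficients must be finite")
    a = annot.copy()
    if "namespace" not in a.columns:
        a["namespace"] = "all"
    if "name" not in a.columns:
        a["name"] = ""
    a = filter_annotations(a, r.index, cfg)
    if a["category"].nunique() < 2:
        raise ValueError("need >=2 categories after size filtering")

    rows = []
    for (cat, ns), members in a.groupby(["category", "namespace"], observed=True):
        ids = members["locus_id"].unique()
        in_r = r.reindex(ids).to_numpy()
        out_r = r.drop(index=ids).to_numpy()
        u_hi, p_hi = stats.mannwhitneyu(in_r, out_r, alternative="greater")
        _, p_lo = stats.mannwhitneyu(in_r, out_r, alternative="less")
        rows.append(
            {
                "category": cat,
                "namespace": ns,
                "name": members["name"].iloc[0],
                "n_loci": len(ids),
                "U": float(u_hi),
                "p_high": float(p_hi),
                "p_low": float(p_lo),
                "direction": "high" if p_hi <= p_lo else "low",
            }
        )
    result = pd.DataFrame(rows).set_index("category")

    result["p_adj"] = np.nan
    for ns, sub in result.groupby("namespace", observed=True):
        adj = multipletests(sub["p_high"].to_numpy(), method="fdr_bh")[1]
        result.loc[sub.index, "p_adj"] = adj
    for level in fdr_levels:
        result[f"sig_fdr_{level:g}"] = result["p_adj"] < level
    return result.sort_values("p_adj")
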