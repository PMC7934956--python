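"""Fragment phenotypes, site-corrected residuals, and the G×E ANOVAs.

The core phenotype is the *residual bleaching score*: a fragment's mean
ordinal bleaching score over the season minus the mean score of all fragments
at its site.  Subtracting the site mean removes environmental differences, so
the residual isolates how a genotype performed *relative to its neighbours* —
high values mean more bleaching than average at that site.  Averaged over all
of a genotype's sites it is a multi-site integrative measure of relative heat
tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass
class PhenotypeTable:
    """Per-fragment phenotypes plus the per-genotype mean residual."""

    fragments: pd.DataFrame  # fragment_id, genotype_id, site_id, mean_score, transformed_score, site_mean, residual
    genotype_residuals: pd.Series  # genotype_id -> mean residual


@dataclass
class MortalityReport:
    """Bleaching–mortality relationships.

    ``wilcox_p`` compares mean bleaching score between fragments that died
    and fragments that survived; the regression relates per-combination
    mortality fraction to mean bleaching score among genotype×site
    combinations without complete mortality.
    """

    wilcox_stat: Optional[float]
    wilcox_p: Optional[float]
    n_died: int
    n_survived: int
    regression_r2: Optional[float]
    regression_p: Optional[float]
    n_combinations: int
    n_regression: int
    frac_full_mortality: float
    notes: list


def compute_phenotypes(surveys: pd.DataFrame, drop_early_mortality: bool = True) -> PhenotypeTable:
    """Fragment mean scores, √-transform, site means and residuals.

    The √ transform is kept alongside the raw mean because the two-way ANOVA
    runs on the transformed scale while residuals are defined on the raw mean
    scale.  Site means pool every retained fragment at the site.
    """
    df = surveys.copy()
    if drop_early_mortality and "early_mortality" in df.columns:
        df = df[~df["early_mortality"].astype(bool)]
    if df.empty:
        raise ValueError("no fragments remain after filtering")
    if df["score"].isna().any():
        bad = df.loc[df["score"].isna(), "fragment_id"].unique().tolist()
        raise ValueError(f"fragments with missing scores: {bad}")

    per_frag = (
        df.groupby(["fragment_id", "genotype_id", "site_id"], sort=True, observed=True)["score"]
        .mean()
        .rename("mean_score")
        .reset_index()
    )
    per_frag["transformed_score"] = np.sqrt(per_frag["mean_score"])
    site_mean = per_frag.groupby("site_id", observed=True)["mean_score"].transform("mean")
    per_frag["site_mean"] = site_mean
    per_frag["residual"] = per_frag["mean_score"] - per_frag["site_mean"]

    small = per_frag.groupby("site_id", observed=True).size()
    for site, n in small.items():
        if n < 2:
            warnings.warn(f"site {site} has {n} fragment(s); residuals are defined but degenerate")

    genotype_residuals = per_frag.groupby("genotype_id", observed=True)["residual"].mean()
    genotype_residuals.name = "mean_residual"
    return PhenotypeTable(fragments=per_frag, genotype_residuals=genotype_residuals)


def gxe_anova(phenos: PhenotypeTable) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of √-transformed scores.

    Terms enter sequentially (Type-I sums of squares) in the order genotype,
    site, genotype:site — on the near-balanced design the ordering is
    immaterial, and sequential SS keep the decomposition additive with the one
    missing genotype×site cell.
    """
    df = phenos.fragments
    for col in ("genotype_id", "site_id"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} has a single level")
    if np.isclose(df["transformed_score"].var(ddof=0), 0.0):
        raise ValueError("response is constant; F statistics undefined")
    model = smf.ols("transformed_score ~ C(genotype_id) + C(site_id) + C(genotype_id):C(site_id)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = ["genotype", "site", "genotype:site", "residual"]
    table.index.name = "term"
    return table.rename(columns={"PR(>F)": "p"})[["df", "sum_sq", "F", "p"]]


def genotype_effect_anova(phenos: PhenotypeTable) -> pd.DataFrame:
    """One-way ANOVA of residual bleaching score on genotype."""
    df = phenos.fragments
    if df["genotype_id"].nunique() < 2:
        raise ValueError("need >=2 genotypes for a one-way ANOVA")
    if np.isclose(df["residual"].var(ddof=0), 0.0):
        raise ValueError("residuals are constant; F statistic undefined")
    model = smf.ols("residual ~ C(genotype_id)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = ["genotype", "residual"]
    table.index.name = "term"
    return table.rename(columns={"PR(>F)": "p"})[["df", "sum_sq", "F", "p"]]


def bleaching_mortality(phenos: PhenotypeTable, surveys: pd.DataFrame) -> MortalityReport:
    """Bleaching severity vs end-of-season mortality.

    (i) Two-sided rank-sum test of fragment mean score, died vs survived;
    (ii) among genotype×site combinations without 100% mortality, regression
    of mortality fraction on mean bleaching score; (iii) fraction of
    combinations with complete mortality.
    """
    notes: list = []
    surv = (
        surveys.drop_duplicates("fragment_id")
        .set_index("fragment_id")["survived_december"]
        .astype(bool)
    )
    frag = phenos.fragments.set_index("fragment_id")
    frag = frag.join(surv, how="inner")

    died = frag.loc[~frag["survived_december"], "mean_score"]
    alive = frag.loc[frag["survived_december"], "mean_score"]
    if len(died) == 0 or len(alive) == 0:
        notes.append("one survival class empty; rank-sum test skipped")
        w_stat = w_p = None
    else:
        w_stat, w_p = stats.mannwhitneyu(died, alive, alternative="two-sided", use_continuity=True)

    combo = frag.groupby(["genotype_id", "site_id"], observed=True).agg(
        mortality=("survived_december", lambda s: 1.0 - s.mean()),
        mean_score=("mean_score", "mean"),
    )
    full = combo["mortality"] >= 1.0
    partial = combo[~full]
    if len(partial) >= 3 and partial["mean_score"].nunique() > 1:
        reg = stats.linregress(partial["mean_score"], partial["mortality"])
        r2, rp = reg.rvalue**2, reg.pvalue
    else:
        notes.append("too few partial-mortality combinations; regression skipped")
        r2 = rp = None

    return MortalityReport(
        wilcox_stat=None if w_stat is None else float(w_stat),
        wilcox_p=None if w_p is None else float(w_p),
        n_died=int(len(died)),
        n_survived=int(len(alive)),
        regression_r2=None if r2 is None else float(r2),
        regression_p=None if rp is None else float(rp),
        n_combinations=int(len(combo)),
        n_regression=int(len(partial)),
        frac_full_mortality=float(full.mean()) if len(combo) else float("nan"),
        notes=notes,
    )
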