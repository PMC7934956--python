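"""Ensemble prediction of residual bleaching phenotypes from locus dosages.

A random-forest regression with one candidate predictor per split (mtry = 1)
keeps the model close to additive locus effects, appropriate for a small
sample of genotypes with many moderately correlated predictors.  Predictive
skill is quantified by repeated 2-fold cross-validation; R² throughout is the
squared Pearson correlation between held-out predictions and observations,
which is well defined for non-nested out-of-fold predictions (the 1 − SSE/SST
convention is not used).

The missing-data robustness procedure replaces a random subset of loci, for
all samples, with the *no-information dosage* — the dosage implied by the
genotype prior alone (2 × secondary-allele frequency under the default
frequency prior, or 1.0 under a flat prior) — and measures how much variance
the degraded predictions still explain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from numpy.random import SeedSequence, default_rng
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .config import ModelConfig
from .dosage import DosageMatrix

ARCHIVE_VERSION = 1


def _corr_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


@dataclass
class ModelFit:
    """A fitted forest with its resampled cross-validation record."""

    locus_ids: List[str]
    model: RandomForestRegressor
    cv_r2: np.ndarray  # n_folds × n_repeats values
    cv_constant_folds: int  # held-out folds with constant predictions (scored 0)
    final_r2: float
    importances: pd.Series  # sorted descending
    noinfo_dosage: pd.Series  # per-locus fallback dosage
    locus_freq: pd.Series
    training_residuals: pd.Series
    config: ModelConfig
    seed: int


def _sample_matrix(X: DosageMatrix, loci: Sequence[str]) -> pd.DataFrame:
    """Samples × loci design matrix restricted to the given loci."""
    sub = X.values.loc[list(loci)]
    return sub.T


def fit_and_crossvalidate(
    X: DosageMatrix,
    y: pd.Series,
    cfg: ModelConfig,
    loci: Optional[Sequence[str]] = None,
) -> ModelFit:
    """Train the forest and estimate skill by repeated k-fold cross-validation.

    Each repeat draws a fresh random partition of the samples into
    ``cfg.n_folds`` near-equal folds; each fold is predicted by a forest
    trained on its complement and scored by squared correlation.  A held-out
    fold with constant predictions scores 0 and is counted in
    ``cv_constant_folds``.  The final model is trained on all samples.
    """
    cfg.validate()
    loci = list(loci) if loci is not None else list(X.locus_ids)
    design = _sample_matrix(X, loci)
    common = [s for s in design.index if s in y.index]
    design = design.loc[common]
    yv = y.reindex(common).to_numpy(dtype=float)
    if design.isna().any().any():
        raise ValueError("missing dosages in the training matrix; impute or drop loci first")
    n = len(common)
    if n < 2 * cfg.n_folds:
        raise ValueError(f"need >= {2 * cfg.n_folds} samples for {cfg.n_folds}-fold CV")

    Xv = design.to_numpy(dtype=float)
    ss = SeedSequence(cfg.seed, spawn_key=(0,))
    rng = default_rng(ss)
    tree_seeds = default_rng(SeedSequence(cfg.seed, spawn_key=(1,))).integers(0, 2**31 - 1, cfg.n_repeats * cfg.n_folds + 1)

    r2s: List[float] = []
    constant = 0
    k = 0
    for rep in range(cfg.n_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, cfg.n_folds)
        for i in range(cfg.n_folds):
            test = folds[i]
            train = np.concatenate([folds[j] for j in range(cfg.n_folds) if j != i])
            rf = RandomForestRegressor(
                n_estimators=cfg.trees,
                max_features=cfg.predictors_per_split,
                random_state=int(tree_seeds[k]),
            )
            k += 1
            rf.fit(Xv[train], yv[train])
            pred = rf.predict(Xv[test])
            if np.std(pred) == 0:
                constant += 1
                r2s.append(0.0)
            else:
                r2s.append(_corr_r2(pred, yv[test]))

    final = RandomForestRegressor(
        n_estimators=cfg.trees,
        max_features=cfg.predictors_per_split,
        random_state=int(tree_seeds[-1]),
    )
    final.fit(Xv, yv)
    final_r2 = _corr_r2(final.predict(Xv), yv)
    importances = pd.Series(final.feature_importances_, index=loci, name="importance").sort_values(ascending=False)

    freq = X.freq.reindex(loci)
    if cfg.noinfo_mode == "frequency":
        noinfo = 2.0 * freq
    else:
        noinfo = pd.Series(1.0, index=loci)
    noinfo.name = "noinfo_dosage"

    return ModelFit(
        locus_ids=loci,
        model=final,
        cv_r2=np.asarray(r2s),
        cv_constant_folds=constant,
        final_r2=final_r2,
        importances=importances,
        noinfo_dosage=noinfo,
        locus_freq=freq,
        training_residuals=y.reindex(common),
        config=cfg,
        seed=cfg.seed,
    )


def missing_data_robustness(
    fit: ModelFit,
    X: DosageMatrix,
    y: pd.Series,
    fractions: Sequence[float] = (0.1, 0.25, 0.5),
    n_replicates: int = 100,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Variance explained when random subsets of loci carry no information.

    For each fraction f and replicate, round(f·L) of the model's loci are
    replaced — for *all* samples — by the no-information dosage; the fitted
    forest predicts and the squared correlation with ``y`` is recorded.
    Returns a DataFrame with one row per fraction: mean, sd, n_replicates.
    """
    rng = default_rng(SeedSequence(fit.seed if seed is None else seed, spawn_key=(2,)))
    design = _sample_matrix(X, fit.locus_ids)
    common = [s for s in design.index if s in y.index]
    base = design.loc[common].to_numpy(dtype=float)
    yv = y.reindex(common).to_numpy(dtype=float)
    L = len(fit.locus_ids)
    noinfo = fit.noinfo_dosage.to_numpy(dtype=float)

    rows = []
    for f in fractions:
        if not 0 <= f <= 1:
            raise ValueError("missing fractions must lie in [0, 1]")
        n_mask = int(round(f * L))
        ves = []
        for _ in range(n_replicates):
            Xm = base.copy()
            if n_mask:
                idx = rng.choice(L, size=n_mask, replace=False)
                Xm[:, idx] = noinfo[idx]
            ves.append(_corr_r2(fit.model.predict(Xm), yv))
        ves = np.asarray(ves)
        rows.append({"fraction": f, "mean": ves.mean(), "sd": ves.std(ddof=1) if len(ves) > 1 else 0.0, "n_replicates": n_replicates})
    return pd.DataFrame(rows)


def predict_novel(
    fit: ModelFit,
    newX: DosageMatrix,
    min_called: int = 30,
    one_per_reef: bool = False,
    reef_map: Optional[pd.Series] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Predict residual phenotypes for samples outside the training set.

    Samples with fewer than ``min_called`` informative model loci are dropped;
    remaining missing cells are imputed with the no-information dosage.  With
    ``one_per_reef`` a single sample per reef is kept by seeded uniform
    choice (reducing sampling bias toward heavily sampled reefs).  Returns a
    DataFrame (sample_id, predicted_residual, n_called_loci[, reef]).
    """
    absent = [l for l in fit.locus_ids if l not in newX.values.index]
    if absent:
        raise ValueError(f"novel dosage matrix is missing model loci: {absent}")
    design = _sample_matrix(newX, fit.locus_ids)  # samples × loci, NaN = missing
    n_called = design.notna().sum(axis=1)
    keep = design.index[n_called >= min_called]
    dropped = len(design) - len(keep)
    design = design.loc[keep]

    if one_per_reef:
        if reef_map is None:
            raise ValueError("one_per_reef requires a reef_map")
        rng = default_rng(SeedSequence(seed, spawn_key=(3,)))
        chosen = []
        reefs = reef_map.reindex(design.index)
        for reef in sorted(reefs.dropna().unique()):
            members = sorted(reefs.index[reefs == reef])
            chosen.append(members[rng.integers(len(members))])
        design = design.loc[chosen]

    filled = design.fillna(fit.noinfo_dosage)
    preds = fit.model.predict(filled.to_numpy(dtype=float)) if len(filled) else np.array([])
    out = pd.DataFrame(
        {
            "sample_id": filled.index,
            "predicted_residual": preds,
            "n_called_loci": n_called.reindex(filled.index).astype(int),
        }
    ).reset_index(drop=True)
    if reef_map is not None:
        out["reef"] = reef_map.reindex(out["sample_id"]).to_numpy()
    out.attrs["n_dropped_low_coverage"] = int(dropped)
    return out


@dataclass
class RegionComparison:
    anova: Optional[pd.DataFrame]
    distribution_stat: Optional[float]
    distribution_p: Optional[float]
    notes: list


def compare_regions(
    predictions: pd.Series,
    region_map: pd.Series,
    training_residuals: Optional[pd.Series] = None,
) -> RegionComparison:
    """One-way ANOVA of predicted residuals across regions.

    Regions with fewer than 2 samples are skipped with a notice.  If training
    residuals are supplied, a two-sample Kolmogorov–Smirnov test compares the
    distribution of predictions with the training phenotypes.
    """
    notes: list = []
    df = pd.DataFrame({"pred": predictions, "region": region_map.reindex(predictions.index)}).dropna()
    sizes = df.groupby("region", observed=True).size()
    small = sizes[sizes < 2]
    for region, n in small.items():
        notes.append(f"region {region} has {n} sample(s); skipped")
    df = df[~df["region"].isin(small.index)]
    if df["region"].nunique() < 2:
        raise ValueError("need >=2 regions with >=2 samples each")
    model = smf.ols("pred ~ C(region)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = ["region", "residual"]
    table.index.name = "term"
    anova = table.rename(columns={"PR(>F)": "p"})[["df", "sum_sq", "F", "p"]]

    d_stat = d_p = None
    if training_residuals is not None:
        d_stat, d_p = stats.ks_2samp(df["pred"].to_numpy(), training_residuals.to_numpy())
        d_stat, d_p = float(d_stat), float(d_p)
    return RegionComparison(anova=anova, distribution_stat=d_stat, distribution_p=d_p, notes=notes)


@dataclass
class ValidationReport:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    scatter: pd.DataFrame  # prediction, decline


def validate_external(predictions: pd.Series, phenotype_decline: pd.Series) -> ValidationReport:
    """Regression of an external physiological decline on predicted residuals.

    ``phenotype_decline`` maps sample → percent change in a bleaching proxy
    (e.g. relative fv/fm decline).  Requires ≥3 overlapping samples.
    """
    common = predictions.index.intersection(phenotype_decline.index)
    if len(common) < 3:
        raise ValueError(f"need >=3 overlapping samples, found {len(common)}")
    x = predictions.reindex(common).to_numpy(dtype=float)
    z = phenotype_decline.reindex(common).to_numpy(dtype=float)
    reg = stats.linregress(x, z)
    return ValidationReport(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r2=float(reg.rvalue**2),
        p=float(reg.pvalue),
        n=int(len(common)),
        scatter=pd.DataFrame({"prediction": x, "decline": z}, index=common),
    )


def save_model(fit: ModelFit, path) -> None:
    """Persist the fit as a versioned joblib archive."""
    joblib.dump(
        {
            "version": ARCHIVE_VERSION,
            "locus_ids": fit.locus_ids,
            "locus_freq": fit.locus_freq,
            "noinfo_dosage": fit.noinfo_dosage,
            "model": fit.model,
            "cv_r2": fit.cv_r2,
            "cv_constant_folds": fit.cv_constant_folds,
            "final_r2": fit.final_r2,
            "importances": fit.importances,
            "training_residuals": fit.training_residuals,
            "config": fit.config,
            "seed": fit.seed,
        },
        path,
    )


def load_model(path) -> ModelFit:
    data = joblib.load(path)
    if data.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version: {data.get('version')}")
    return ModelFit(
        locus_ids=data["locus_ids"],
        model=data["model"],
        cv_r2=data["cv_r2"],
        cv_constant_folds=data["cv_constant_folds"],
        final_r2=data["final_r2"],
        importances=data["importances"],
        noinfo_dosage=data["noinfo_dosage"],
        locus_freq=data["locus_freq"],
        training_residuals=data["training_residuals"],
        config=data["config"],
        seed=data["seed"],
    )
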