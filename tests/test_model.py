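"""Forest fitting, cross-validation behaviour, missing-data robustness,
novel-sample prediction, and the downstream comparisons."""

import numpy as np
import pandas as pd
import pytest

import reefgxe as rg
from reefgxe.config import ModelConfig
from reefgxe.dosage import DosageMatrix
from reefgxe.model import (
    compare_regions,
    fit_and_crossvalidate,
    load_model,
    missing_data_robustness,
    predict_novel,
    save_model,
    validate_external,
)

FAST = ModelConfig(trees=150, seed=0)


def dosage_from(arr, samples=None, loci=None):
    """arr: loci × samples."""
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"g{j}" for j in range(arr.shape[1])]
    loci = loci or [f"L{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=loci, columns=samples)
    return DosageMatrix(values=df, freq=df.mean(axis=1) / 2)


def signal_dataset(seed, n=10, n_noise=57):
    """One perfectly informative locus plus genotype-like noise loci."""
    rng = np.random.default_rng(seed)
    y = pd.Series(rng.normal(0, 1, n), index=[f"g{j}" for j in range(n)])
    signal = (y.to_numpy() - y.min()) / (y.max() - y.min()) * 2
    q = rng.uniform(0.1, 0.45, n_noise)
    noise = rng.binomial(2, q[:, None], (n_noise, n)).astype(float)
    X = dosage_from(np.vstack([signal, noise]))
    return X, y


def test_constructed_signal_recovered():
    """y an exact monotone function of one locus among 57 noise loci: the
    forest recovers it with high CV skill and ranks it first in importance.

    Identifying a single informative predictor needs split-level feature
    competition (mtry = p/3, the regression convention) and enough samples
    that noise loci cannot separate the training points by chance — with
    tiny folds every feature fits perfectly and the signal is unidentifiable.
    """
    means, first = [], 0
    for seed in range(10):
        X, y = signal_dataset(seed, n=100)
        fit = fit_and_crossvalidate(X, y, ModelConfig(trees=200, n_repeats=5, predictors_per_split=19, seed=seed))
        means.append(fit.cv_r2.mean())
        first += fit.importances.index[0] == "L0"
    assert np.mean(means) >= 0.8
    assert first >= 9


def test_permutation_null_sits_at_chance_level(matched_structure, matched_fit):
    """With y permuted, held-out predictions are independent of the held-out
    observations, so the mean squared 5-point-fold correlation sits near its
    chance expectation 1/(n-1) = 0.25 — far below the matched-signal case."""
    _, phenos, _, dosages = matched_structure
    nulls = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        y = phenos.genotype_residuals
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        fit = fit_and_crossvalidate(dosages, yp, ModelConfig(trees=150, seed=seed))
        nulls.append(fit.cv_r2.mean())
    assert 0.05 < np.mean(nulls) < 0.45
    assert np.mean(nulls) < matched_fit.cv_r2.mean() - 0.3


def test_cv_shape_and_reproducibility(matched_structure, matched_fit):
    cfg, phenos, _, dosages = matched_structure
    fit = matched_fit
    assert len(fit.cv_r2) == fit.config.n_folds * fit.config.n_repeats
    again = fit_and_crossvalidate(dosages, phenos.genotype_residuals, ModelConfig(seed=7))
    assert np.array_equal(fit.cv_r2, again.cv_r2)
    assert np.array_equal(
        fit.model.predict(dosages.values.T.to_numpy()),
        again.model.predict(dosages.values.T.to_numpy()),
    )


def test_cv_mean_invariant_to_locus_order(matched_structure):
    """Shuffling predictor columns leaves the resampled skill statistically
    unchanged (tree-level randomness differs, the estimate does not)."""
    cfg, phenos, _, dosages = matched_structure
    y = phenos.genotype_residuals
    base = fit_and_crossvalidate(dosages, y, ModelConfig(trees=200, seed=3))
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(dosages.locus_ids))
    shuffled = DosageMatrix(values=dosages.values.iloc[perm], freq=dosages.freq.iloc[perm])
    alt = fit_and_crossvalidate(shuffled, y, ModelConfig(trees=200, seed=3))
    assert abs(base.cv_r2.mean() - alt.cv_r2.mean()) < 0.03


def test_missing_dosages_rejected():
    X, y = signal_dataset(1)
    X.values.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_and_crossvalidate(X, y, FAST)


def test_too_few_samples_rejected():
    X, y = signal_dataset(1)
    X = DosageMatrix(values=X.values.iloc[:, :3], freq=X.freq)
    with pytest.raises(ValueError, match="samples"):
        fit_and_crossvalidate(X, y.iloc[:3], FAST)


def test_robustness_fraction_extremes(matched_structure, matched_fit):
    """Fraction 0 reproduces the final-fit R²; fraction 1 leaves no signal."""
    _, phenos, _, dosages = matched_structure
    y = phenos.genotype_residuals
    res = missing_data_robustness(matched_fit, dosages, y, fractions=[0.0, 1.0], n_replicates=5)
    assert res.loc[res["fraction"] == 0.0, "mean"].iloc[0] == pytest.approx(matched_fit.final_r2)
    assert res.loc[res["fraction"] == 1.0, "mean"].iloc[0] <= 0.05


def test_robustness_monotone_in_missing_fraction(matched_structure, matched_fit):
    _, phenos, _, dosages = matched_structure
    y = phenos.genotype_residuals
    res = missing_data_robustness(
        matched_fit, dosages, y, fractions=[0.0, 0.25, 0.5, 0.75, 1.0], n_replicates=40
    )
    means = res["mean"].to_numpy()
    assert np.all(np.diff(means) <= 0.02)  # non-increasing up to replicate noise
    assert means[0] > means[-1]


def test_causal_importance_exceeds_null():
    """Causal loci outrank null loci in forest importance (rank test)."""
    from scipy.stats import mannwhitneyu

    causal_imp, null_imp = [], []
    for seed in range(10):
        cfg = rg.SimConfig(seed=seed, n_loci=60, n_causal=20)
        survey, truth = rg.simulate_design(cfg)
        ph = rg.compute_phenotypes(survey)
        geno = rg.simulate_genotypes(cfg, truth, target_residuals=ph.genotype_residuals)
        dm = rg.compute_dosage(geno)
        complete = dm.values.dropna().index.tolist()
        fit = fit_and_crossvalidate(
            dm, ph.genotype_residuals, ModelConfig(trees=150, seed=seed), loci=complete
        )
        for locus, imp in fit.importances.items():
            (causal_imp if locus in truth.causal_loci else null_imp).append(imp)
    assert np.mean(causal_imp) > np.mean(null_imp)
    _, p = mannwhitneyu(causal_imp, null_imp, alternative="greater")
    assert p < 0.01


def test_predict_novel_min_called_boundary(matched_fit):
    """A sample with 29 called model loci is excluded; 30 is included."""
    L = len(matched_fit.locus_ids)
    vals = np.full((L, 2), 1.0)
    vals[30:, 0] = np.nan  # sample a: 30 called
    vals[29:, 1] = np.nan  # sample b: 29 called
    newX = dosage_from(vals, samples=["a", "b"], loci=matched_fit.locus_ids)
    out = predict_novel(matched_fit, newX, min_called=30)
    assert list(out["sample_id"]) == ["a"]
    assert out.attrs["n_dropped_low_coverage"] == 1


def test_predict_novel_reproduces_training_predictions(matched_structure, matched_fit):
    _, phenos, _, dosages = matched_structure
    out = predict_novel(matched_fit, dosages, min_called=30)
    direct = matched_fit.model.predict(dosages.values.T.to_numpy())
    assert np.allclose(out.set_index("sample_id")["predicted_residual"].reindex(dosages.sample_ids), direct)


def test_predict_novel_all_missing_excluded(matched_fit):
    L = len(matched_fit.locus_ids)
    newX = dosage_from(np.full((L, 1), np.nan), samples=["empty"], loci=matched_fit.locus_ids)
    out = predict_novel(matched_fit, newX, min_called=1)
    assert len(out) == 0


def test_predict_novel_locus_mismatch_errors(matched_fit):
    newX = dosage_from(np.ones((3, 2)), loci=["X1", "X2", "X3"])
    with pytest.raises(ValueError, match="missing model loci"):
        predict_novel(matched_fit, newX)


def test_predict_novel_one_per_reef_seeded(matched_fit):
    L = len(matched_fit.locus_ids)
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(8)]
    newX = dosage_from(rng.uniform(0, 2, (L, 8)), samples=samples, loci=matched_fit.locus_ids)
    reef = pd.Series(["r1", "r1", "r1", "r2", "r2", "r3", "r3", "r3"], index=samples)
    a = predict_novel(matched_fit, newX, min_called=1, one_per_reef=True, reef_map=reef, seed=5)
    b = predict_novel(matched_fit, newX, min_called=1, one_per_reef=True, reef_map=reef, seed=5)
    assert list(a["sample_id"]) == list(b["sample_id"])
    assert len(a) == 3 and set(a["reef"]) == {"r1", "r2", "r3"}


def test_compare_regions_shift_detected():
    rng = np.random.default_rng(1)
    preds = pd.Series(rng.normal(0, 1, 40), index=[f"s{i}" for i in range(40)])
    regions = pd.Series(["north"] * 20 + ["south"] * 20, index=preds.index)
    preds.iloc[20:] += 2.0 * preds.std()
    res = compare_regions(preds, regions)
    assert res.anova.loc["region", "p"] < 0.01


def test_compare_regions_calibrated_under_null():
    rng = np.random.default_rng(2)
    rejections = 0
    for _ in range(200):
        preds = pd.Series(rng.normal(0, 1, 30), index=[f"s{i}" for i in range(30)])
        regions = pd.Series(rng.permutation(["a"] * 10 + ["b"] * 10 + ["c"] * 10), index=preds.index)
        res = compare_regions(preds, regions)
        rejections += res.anova.loc["region", "p"] < 0.05
    rate = rejections / 200
    band = 3 * np.sqrt(0.05 * 0.95 / 200)
    assert 0.05 - band <= rate <= 0.05 + band


def test_compare_regions_degenerate():
    preds = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="regions"):
        compare_regions(preds, pd.Series(["r1", "r1", "r1"], index=preds.index))
    res = compare_regions(
        pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde")),
        pd.Series(["r1", "r1", "r2", "r2", "r3"], index=list("abcde")),
    )
    assert any("r3" in n for n in res.notes)


def test_validate_external_perfect_line():
    preds = pd.Series(np.linspace(-1, 1, 11), index=[f"s{i}" for i in range(11)])
    decline = 10 * preds + 3
    rep = validate_external(preds, decline)
    assert rep.r2 == pytest.approx(1.0)
    assert rep.n == 11


def test_validate_external_needs_overlap():
    preds = pd.Series([1.0, 2.0], index=["a", "b"])
    decline = pd.Series([1.0], index=["a"])
    with pytest.raises(ValueError, match="overlap"):
        validate_external(preds, decline)


def test_model_archive_roundtrip(tmp_path, matched_structure, matched_fit):
    _, phenos, _, dosages = matched_structure
    path = tmp_path / "model.joblib"
    save_model(matched_fit, path)
    back = load_model(path)
    assert back.locus_ids == matched_fit.locus_ids
    assert np.array_equal(back.cv_r2, matched_fit.cv_r2)
    X = dosages.values.T.to_numpy()
    assert np.allclose(back.model.predict(X), matched_fit.model.predict(X))
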