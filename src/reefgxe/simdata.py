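"""Synthetic reciprocal-transplant data with known ground truth.

Every input the analysis pipeline consumes can be generated here: the
fragment-level bleaching survey, the genotype-probability panel, hourly site
temperature logs, locus annotations, and an external physiology series for
validation.  Effects are drawn once per dataset and recorded in a
:class:`GroundTruth` object so that parameter recovery and screening power can
be tested directly.

Randomness: every stage draws from an independent child stream of a single
master seed via ``numpy.random.SeedSequence(seed, spawn_key=(k,))``, where
``k`` is a fixed per-stage index (0 = design effects, 1 = fragment noise,
2 = timepoint noise, 3 = survival, 4 = early mortality, 5 = genotypes,
6 = temperature, 7 = annotations, 8 = external validation).  Any stage is
therefore reproducible in isolation from the master seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.special import expit
from scipy.stats import norm

from .config import SimConfig
from .dosage import GenotypeProbabilityTable

_STAGES = {
    "effects": 0,
    "noise": 1,
    "timepoint": 2,
    "survival": 3,
    "early_mortality": 4,
    "genotypes": 5,
    "temperature": 6,
    "annotations": 7,
    "external": 8,
}


def stage_rng(seed: int, stage: str) -> Generator:
    """Child random stream for a named pipeline stage of a master seed."""
    return default_rng(SeedSequence(seed, spawn_key=(_STAGES[stage],)))


@dataclass
class GroundTruth:
    """Latent effects behind one simulated dataset (all centred to sum ~0)."""

    genotype_effects: pd.Series
    site_effects: pd.Series
    interaction_effects: pd.DataFrame  # genotypes × sites
    causal_loci: Dict[str, float]  # locus id -> target correlation
    true_residual_by_genotype: pd.Series
    latent_by_fragment: pd.Series = field(default=None, repr=False)


def _centred_effects(rng: Generator, n: int, var: float) -> np.ndarray:
    """n draws centred to mean 0 and rescaled to mean-square exactly ``var``."""
    if var == 0 or n < 2:
        return np.zeros(n)
    x = rng.normal(0.0, 1.0, n)
    x = x - x.mean()
    ms = np.mean(x**2)
    if ms == 0:
        return np.zeros(n)
    return x * np.sqrt(var / ms)


def _double_centred_matrix(rng: Generator, n_rows: int, n_cols: int, var: float) -> np.ndarray:
    if var == 0 or n_rows < 2 or n_cols < 2:
        return np.zeros((n_rows, n_cols))
    m = rng.normal(0.0, 1.0, (n_rows, n_cols))
    m = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + m.mean()
    ms = np.mean(m**2)
    if ms == 0:
        return np.zeros((n_rows, n_cols))
    return m * np.sqrt(var / ms)


def _default_thresholds(cfg: SimConfig) -> np.ndarray:
    """Quartile cuts of the marginal latent-score distribution."""
    total_var = cfg.var_genotype + cfg.var_site + cfg.var_gxe + cfg.var_noise + cfg.var_timepoint
    if total_var == 0:
        return np.array([-0.5, 0.0, 0.5])
    sd = np.sqrt(total_var)
    return norm.ppf([0.25, 0.5, 0.75]) * sd


def simulate_design(cfg: SimConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Simulate the fragment-level bleaching survey.

    Latent fragment severity = genotype effect + site effect + interaction +
    fragment noise; each timepoint adds independent observation noise and the
    result is cut into an ordinal 0–3 bleaching score.  Survival through the
    end-of-season census follows a logistic link on latent severity (more
    bleached fragments die more often); early mortality is assigned uniformly
    at random, emulating transplantation stress unrelated to heat tolerance.

    Returns the survey table (one row per fragment × timepoint) and the
    :class:`GroundTruth` effects.
    """
    cfg.validate()
    genotypes, sites = cfg.genotype_ids, cfg.site_ids

    rng_eff = stage_rng(cfg.seed, "effects")
    g_eff = pd.Series(_centred_effects(rng_eff, cfg.n_genotypes, cfg.var_genotype), index=genotypes)
    s_eff = pd.Series(_centred_effects(rng_eff, cfg.n_sites, cfg.var_site), index=sites)
    i_eff = pd.DataFrame(
        _double_centred_matrix(rng_eff, cfg.n_genotypes, cfg.n_sites, cfg.var_gxe),
        index=genotypes,
        columns=sites,
    )

    missing = tuple(cfg.missing_combination) if cfg.missing_combination is not None else None
    if missing is not None:
        mg, ms = missing
        if mg not in genotypes or ms not in sites:
            raise ValueError(f"missing_combination {missing} not in the design")

    combos = [(g, s) for g in genotypes for s in sites if (g, s) != missing]
    n_fragments = len(combos) * cfg.n_replicates
    if cfg.n_early_mortality >= n_fragments:
        raise ValueError(
            f"n_early_mortality ({cfg.n_early_mortality}) must be below the "
            f"total fragment count ({n_fragments})"
        )

    rng_noise = stage_rng(cfg.seed, "noise")
    rows = []
    for g, s in combos:
        base = g_eff[g] + s_eff[s] + i_eff.loc[g, s]
        noise = rng_noise.normal(0.0, np.sqrt(cfg.var_noise), cfg.n_replicates)
        for k in range(cfg.n_replicates):
            rows.append((f"{g}_{s}_r{k + 1}", g, s, base + noise[k]))
    frag = pd.DataFrame(rows, columns=["fragment_id", "genotype_id", "site_id", "latent"])

    thresholds = (
        np.asarray(cfg.score_thresholds, dtype=float)
        if cfg.score_thresholds is not None
        else _default_thresholds(cfg)
    )
    rng_tp = stage_rng(cfg.seed, "timepoint")
    tp_noise = rng_tp.normal(0.0, np.sqrt(cfg.var_timepoint), (len(frag), cfg.n_timepoints))
    scores = np.digitize(frag["latent"].to_numpy()[:, None] + tp_noise, thresholds)

    rng_surv = stage_rng(cfg.seed, "survival")
    p_survive = expit(cfg.survival_intercept - cfg.survival_slope * frag["latent"].to_numpy())
    survived = rng_surv.random(len(frag)) < p_survive

    rng_em = stage_rng(cfg.seed, "early_mortality")
    em_idx = rng_em.choice(len(frag), size=cfg.n_early_mortality, replace=False)
    early = np.zeros(len(frag), dtype=bool)
    early[em_idx] = True

    records = []
    for i, row in enumerate(frag.itertuples(index=False)):
        for t in range(cfg.n_timepoints):
            records.append(
                (row.fragment_id, row.genotype_id, row.site_id, t + 1, int(scores[i, t]), early[i], bool(survived[i]))
            )
    survey = pd.DataFrame(
        records,
        columns=["fragment_id", "genotype_id", "site_id", "timepoint", "score", "early_mortality", "survived_december"],
    )

    # expected residual phenotype implied by the effects and the realized design
    present = pd.DataFrame(True, index=genotypes, columns=sites)
    if missing is not None:
        present.loc[missing[0], missing[1]] = False
    cell = i_eff.add(g_eff, axis=0).add(s_eff, axis=1)
    site_mean = (cell.where(present)).mean(axis=0)
    resid_cells = cell.sub(site_mean, axis=1).where(present)
    true_resid = resid_cells.mean(axis=1)

    # causal locus identities and target correlations live on the genotype
    # stream so simulate_genotypes can reproduce them independently
    locus_ids = [f"L{i:05d}" for i in range(cfg.n_loci)]
    rng_assign = stage_rng(cfg.seed, "genotypes")
    causal_idx = np.sort(rng_assign.choice(cfg.n_loci, size=cfg.n_causal, replace=False))
    lo, hi = cfg.target_r_range
    target_r = rng_assign.uniform(lo, hi, cfg.n_causal)
    causal = {locus_ids[i]: float(r) for i, r in zip(causal_idx, target_r)}

    truth = GroundTruth(
        genotype_effects=g_eff,
        site_effects=s_eff,
        interaction_effects=i_eff,
        causal_loci=causal,
        true_residual_by_genotype=true_resid,
        latent_by_fragment=frag.set_index("fragment_id")["latent"],
    )
    return survey, truth


def _hwe_prior(q: float) -> np.ndarray:
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2])


def _depth_weights(rng: Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    """Posterior sharpness per cell from a gamma-Poisson read-depth model.

    Weight w = d/(d+1) mixes the true-genotype point mass with the
    Hardy–Weinberg prior; w → 1 as depth → ∞, w = 0 at zero depth.
    """
    if np.isinf(mean):
        return np.ones(n)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n) if mean > 0 else np.zeros(n)
    d = rng.poisson(lam)
    return d / (d + 1.0)


def _causal_locus(
    rng: Generator,
    y_z: np.ndarray,
    lo: float,
    hi: float,
    cfg: SimConfig,
    batch: int = 64,
    max_batches: int = 8,
) -> Tuple[np.ndarray, float, float]:
    """Construct one locus whose dosage–phenotype correlation lands in [lo, hi].

    Candidate genotype vectors are drawn by thresholding a latent variable
    correlated with the phenotype at Hardy–Weinberg quantiles, softened to
    probability triplets by the depth model; candidates are drawn in batches
    until the realized dosage correlation falls inside the band (the closest
    candidate is kept as a fallback).
    """
    n = len(y_z)
    best = None
    best_dist = np.inf
    for _ in range(max_batches):
        rt = rng.uniform(lo, hi, batch)
        q = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], batch)
        z = rt[:, None] * y_z[None, :] + np.sqrt(1 - rt[:, None] ** 2) * rng.normal(0, 1, (batch, n))
        t0 = norm.ppf((1 - q) ** 2)
        t1 = norm.ppf((1 - q) ** 2 + 2 * q * (1 - q))
        g = (z > t0[:, None]).astype(int) + (z > t1[:, None]).astype(int)
        w = np.stack([_depth_weights(rng, n, cfg.depth_mean, cfg.depth_dispersion) for _ in range(batch)])
        prior = np.stack([_hwe_prior(qi) for qi in q])  # batch × 3
        onehot = np.eye(3)[g]  # batch × n × 3
        trip = w[:, :, None] * onehot + (1 - w)[:, :, None] * prior[:, None, :]
        dos = trip[:, :, 1] + 2 * trip[:, :, 2]
        sd = dos.std(axis=1)
        # y_z is standardized (population sd 1), so r reduces to a dot product
        cov = ((dos - dos.mean(axis=1, keepdims=True)) * y_z[None, :]).sum(axis=1) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(sd > 0, cov / np.where(sd > 0, sd, 1.0), np.nan)
        dist = np.where((r >= lo) & (r <= hi), 0.0, np.minimum(np.abs(r - lo), np.abs(r - hi)))
        dist = np.where(np.isnan(dist), np.inf, dist)
        j = int(np.argmin(dist))
        if dist[j] < best_dist:
            best_dist = dist[j]
            best = (trip[j], float(r[j]), float(q[j]))
        if best_dist == 0.0:
            break
    return best


def simulate_genotypes(
    cfg: SimConfig,
    truth: GroundTruth,
    target_residuals: Optional[pd.Series] = None,
) -> GenotypeProbabilityTable:
    """Simulate the genotype-probability panel (one sample per genotype).

    Non-causal loci draw true genotypes under Hardy–Weinberg equilibrium at a
    locus-specific minor-allele frequency; causal loci (IDs fixed in
    ``truth.causal_loci``) are constructed so that the realized correlation
    between their expected secondary-allele dosage and the residual phenotype
    lands inside ``cfg.target_r_range``.  All triplets are concentrated on the
    true genotype with sharpness driven by a simulated read depth; a
    configurable fraction of cells is replaced by the uninformative
    Hardy–Weinberg prior triplet.

    ``target_residuals`` overrides the phenotype the causal loci are built
    against (defaults to ``truth.true_residual_by_genotype``).
    """
    cfg.validate()
    if cfg.n_causal > 0 and cfg.n_genotypes < 5:
        raise ValueError(
            "target correlations are unattainable: need at least 5 genotypes "
            "to realize a correlation inside a narrow band"
        )
    rng = stage_rng(cfg.seed, "genotypes")
    # re-draw the assignment stream consumed in simulate_design so the two
    # stages agree on causal locus identities
    _ = rng.choice(cfg.n_loci, size=cfg.n_causal, replace=False)
    _ = rng.uniform(*cfg.target_r_range, cfg.n_causal)

    samples = cfg.genotype_ids
    locus_ids = [f"L{i:05d}" for i in range(cfg.n_loci)]
    y = (target_residuals if target_residuals is not None else truth.true_residual_by_genotype).reindex(samples)
    y_arr = y.to_numpy(dtype=float)
    if cfg.n_causal > 0:
        if y_arr.std() == 0:
            raise ValueError("residual phenotype is constant; causal correlations unattainable")
        y_z = (y_arr - y_arr.mean()) / y_arr.std()
    n = len(samples)

    probs = np.empty((cfg.n_loci, n, 3))
    realized_r: Dict[str, float] = {}
    causal_set = truth.causal_loci

    # vectorized bulk draw for non-causal loci
    q_all = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_loci)
    g_all = rng.binomial(2, q_all[:, None], (cfg.n_loci, n))
    if np.isinf(cfg.depth_mean):
        w_all = np.ones((cfg.n_loci, n))
    else:
        lam = (
            rng.gamma(cfg.depth_dispersion, cfg.depth_mean / cfg.depth_dispersion, (cfg.n_loci, n))
            if cfg.depth_mean > 0
            else np.zeros((cfg.n_loci, n))
        )
        d = rng.poisson(lam)
        w_all = d / (d + 1.0)
    prior_all = np.stack([(1 - q_all) ** 2, 2 * q_all * (1 - q_all), q_all**2], axis=1)  # loci × 3
    onehot = np.eye(3)[g_all]  # loci × n × 3
    probs[:] = w_all[:, :, None] * onehot + (1 - w_all)[:, :, None] * prior_all[:, None, :]

    lo, hi = cfg.target_r_range
    locus_pos = {lid: i for i, lid in enumerate(locus_ids)}
    causal_rows = np.zeros(cfg.n_loci, dtype=bool)
    for locus in causal_set:
        i = locus_pos[locus]
        trip, r, q = _causal_locus(rng, y_z, lo, hi, cfg)
        probs[i] = trip
        realized_r[locus] = r
        causal_rows[i] = True

    # cells with zero simulated depth carry only the prior
    informative = (w_all > 0) | causal_rows[:, None]
    if cfg.uninformative_fraction > 0:
        mask = rng.random((cfg.n_loci, n)) < cfg.uninformative_fraction
        informative &= ~mask
        rows, cols = np.where(mask)
        q_cell = q_all[rows]
        probs[rows, cols] = np.stack([(1 - q_cell) ** 2, 2 * q_cell * (1 - q_cell), q_cell**2], axis=1)

    table = GenotypeProbabilityTable(
        probs=probs,
        locus_ids=locus_ids,
        sample_ids=list(samples),
        informative=informative,
    )
    table.realized_causal_r = realized_r
    return table


@dataclass
class SiteClimate:
    """Parameters of one site's synthetic hourly temperature series (°C)."""

    baseline: float = 29.5
    seasonal_amplitude: float = 1.0
    seasonal_peak_doy: int = 227  # mid-August
    diel_range: float = 1.0
    noise_sd: float = 0.2


def simulate_temperature(
    site_params: Dict[str, SiteClimate],
    start: str,
    end: str,
    seed: int,
    gap_schedule: Optional[Dict[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Hourly per-site temperature logs over [start, end] (inclusive days).

    Temperature = baseline + seasonal sinusoid (annual period, peaking at
    ``seasonal_peak_doy``) + diel sinusoid (daily period, peaking mid
    afternoon) + white noise.  ``gap_schedule`` maps site → ISO dates whose
    observations are dropped, emulating logger failure.
    """
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    if end_ts < start_ts:
        raise ValueError("end before start")
    idx = pd.date_range(start_ts, end_ts + pd.Timedelta(hours=23), freq="h")
    rng = default_rng(SeedSequence(seed, spawn_key=(_STAGES["temperature"],)))
    frames = []
    for site in sorted(site_params):
        p = site_params[site]
        doy = idx.dayofyear.to_numpy()
        hour = idx.hour.to_numpy()
        seasonal = p.seasonal_amplitude * np.cos(2 * np.pi * (doy - p.seasonal_peak_doy) / 365.25)
        diel = (p.diel_range / 2.0) * np.cos(2 * np.pi * (hour - 15) / 24.0)
        noise = rng.normal(0.0, p.noise_sd, len(idx)) if p.noise_sd > 0 else 0.0
        temps = p.baseline + seasonal + diel + noise
        df = pd.DataFrame({"site_id": site, "timestamp": idx, "temp_c": temps})
        if gap_schedule and site in gap_schedule:
            drop_days = {pd.Timestamp(d).date() for d in gap_schedule[site]}
            df = df[~df["timestamp"].dt.date.isin(drop_days)]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def default_site_climates(site_ids: Sequence[str], seed: int) -> Dict[str, SiteClimate]:
    """Per-site climates with small seeded site-to-site variation."""
    rng = default_rng(SeedSequence(seed, spawn_key=(_STAGES["temperature"], 1)))
    out = {}
    for site in site_ids:
        out[site] = SiteClimate(
            baseline=29.5 + rng.normal(0, 0.15),
            seasonal_amplitude=1.0 + rng.normal(0, 0.1),
            diel_range=abs(0.9 + rng.normal(0, 0.3)),
            noise_sd=0.2,
        )
    return out


def simulate_annotations(
    locus_ids: Sequence[str],
    seed: int,
    n_categories: int = 40,
    mean_loci_per_category: int = 30,
    planted: Optional[Dict[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Random locus → GO-style category annotations (long format).

    Categories are assigned uniformly at random; ``planted`` maps category ID →
    explicit locus list, letting tests construct truly enriched categories.
    Returns columns (locus_id, category, namespace, name).
    """
    rng = default_rng(SeedSequence(seed, spawn_key=(_STAGES["annotations"],)))
    namespaces = ["BP", "MF", "CC"]
    rows = []
    for c in range(n_categories):
        cat = f"GO:{7000000 + c}"
        ns = namespaces[c % 3]
        size = max(2, rng.poisson(mean_loci_per_category))
        members = rng.choice(len(locus_ids), size=min(size, len(locus_ids)), replace=False)
        for m in members:
            rows.append((locus_ids[m], cat, ns, f"simulated category {c}"))
    if planted:
        for cat, members in planted.items():
            for locus in members:
                rows.append((locus, cat, "BP", "planted category"))
    return pd.DataFrame(rows, columns=["locus_id", "category", "namespace", "name"]).drop_duplicates()


def simulate_fvfm_decline(
    residuals: pd.Series,
    seed: int,
    slope: float = 10.0,
    noise_sd: float = 3.0,
) -> pd.Series:
    """Synthetic photosynthetic-efficiency decline (% change) per sample.

    Decline is a noisy linear function of the residual bleaching phenotype —
    more heat-susceptible samples lose more photochemical yield.
    """
    rng = default_rng(SeedSequence(seed, spawn_key=(_STAGES["external"],)))
    vals = slope * residuals.to_numpy(dtype=float) + rng.normal(0, noise_sd, len(residuals))
    return pd.Series(vals, index=residuals.index, name="fvfm_decline_pct")
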