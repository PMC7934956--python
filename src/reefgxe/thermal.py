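"""Summaries of hourly site temperature records.

Per-site statistics (mean, s.d., average daily range, overall max), hours
above bleaching-relevant thresholds, degree heating weeks (DHW), and a PCA of
daily mean temperatures describing how sites relate thermally.

DHW accumulates heat stress above MMM+1 °C in °C-weeks.  Two accumulation
rules are provided: ``hotspot`` (NOAA convention — each qualifying hourly
observation contributes T − MMM) and ``excess`` (contributes
T − threshold); ``hotspot`` is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import ThermalConfig

HOURS_PER_WEEK = 7 * 24


def _per_site(series: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    if len(series) == 0:
        raise ValueError("empty temperature series")
    out = {}
    for site, df in series.groupby("site_id", observed=True):
        df = df.sort_values("timestamp")
        ts = pd.to_datetime(df["timestamp"])
        if ts.duplicated().any() or not ts.is_monotonic_increasing:
            raise ValueError(f"site {site}: timestamps must be strictly increasing")
        out[site] = pd.DataFrame({"timestamp": ts.to_numpy(), "temp_c": df["temp_c"].to_numpy(dtype=float)})
    return out


def _check_sane(site: str, temps: np.ndarray, band: Tuple[float, float]) -> None:
    if len(temps) == 0:
        raise ValueError(f"site {site}: empty temperature series")
    if not np.isfinite(temps).all():
        raise ValueError(f"site {site}: non-finite temperatures")
    lo, hi = band
    if (temps < lo).any() or (temps > hi).any():
        raise ValueError(f"site {site}: temperatures outside sanity band [{lo}, {hi}] °C")


def _clip_window(df: pd.DataFrame, window: Optional[Tuple[str, str]]) -> pd.DataFrame:
    if window is None:
        return df
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    return df[(df["timestamp"] >= start) & (df["timestamp"] <= end + pd.Timedelta(hours=23, minutes=59))]


def daily_stats(df: pd.DataFrame, min_hours_per_day: int) -> pd.DataFrame:
    """Per-day mean/max/min, keeping only days with enough observations."""
    g = df.set_index("timestamp")["temp_c"].resample("D")
    out = pd.DataFrame({"mean": g.mean(), "max": g.max(), "min": g.min(), "n": g.count()})
    return out[out["n"] >= min_hours_per_day]


def degree_heating_weeks(
    series: pd.DataFrame,
    cfg: ThermalConfig,
    window: Optional[Tuple[str, str]] = None,
) -> pd.Series:
    """DHW (°C-weeks) per site.

    hotspot mode: Σ over hourly observations with T ≥ threshold of (T − MMM)/168;
    excess  mode: Σ of (T − threshold)/168.  Gaps longer than 24 h produce a
    warning (DHW is computed on the available points).
    """
    cfg.validate()
    out = {}
    for site, df in _per_site(series).items():
        df = _clip_window(df, window)
        temps = df["temp_c"].to_numpy()
        _check_sane(site, temps, cfg.sanity_band)
        gaps = df["timestamp"].diff()
        big = gaps[gaps > pd.Timedelta(hours=24)]
        if len(big):
            inventory = [f"{t} (gap {d})" for t, d in zip(df.loc[big.index, "timestamp"], big)]
            warnings.warn(f"site {site}: gaps > 24 h before {inventory}; DHW uses available points")
        hot = temps >= cfg.dhw_threshold
        if cfg.dhw_mode == "hotspot":
            contrib = temps[hot] - cfg.mmm
        else:
            contrib = temps[hot] - cfg.dhw_threshold
        out[site] = float(contrib.sum() / HOURS_PER_WEEK)
    return pd.Series(out, name="dhw").sort_index()


def summarize_sites(
    series: pd.DataFrame,
    cfg: ThermalConfig,
    window: Optional[Tuple[str, str]] = None,
) -> pd.DataFrame:
    """Per-site thermal summary mirroring a field-season temperature table.

    Columns: avg, sd, daily_range (mean over qualifying days of daily
    max − min), max, hrs_gt_<threshold> for each exceedance threshold, dhw.
    Days with fewer than ``min_hours_per_day`` observations are excluded from
    the daily statistics only.
    """
    cfg.validate()
    dhw = degree_heating_weeks(series, cfg, window=window)
    rows = []
    for site, df in _per_site(series).items():
        df = _clip_window(df, window)
        temps = df["temp_c"].to_numpy()
        _check_sane(site, temps, cfg.sanity_band)
        day = daily_stats(df, cfg.min_hours_per_day)
        row = {
            "site_id": site,
            "avg": float(temps.mean()),
            "sd": float(temps.std(ddof=1)) if len(temps) > 1 else 0.0,
            "daily_range": float((day["max"] - day["min"]).mean()) if len(day) else float("nan"),
            "max": float(temps.max()),
        }
        for thr in cfg.exceedance_thresholds:
            row[f"hrs_gt_{thr:g}"] = int((temps > thr).sum())
        row["dhw"] = dhw[site]
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id").sort_index()


@dataclass
class PcaResult:
    """Site coordinates on principal components of daily mean temperature."""

    scores: pd.DataFrame  # sites × components
    explained_variance_ratio: np.ndarray
    excluded_sites: List[str]


def daily_mean_pca(
    series: pd.DataFrame,
    cfg: ThermalConfig,
    window: Optional[Tuple[str, str]] = None,
    max_missing_fraction: float = 0.20,
) -> PcaResult:
    """PCA of the sites × days matrix of daily mean temperatures.

    Days are the common coverage across included sites; sites missing more
    than ``max_missing_fraction`` of the candidate days are excluded with a
    notice.  Columns (days) are centred before decomposition.
    """
    cfg.validate()
    per_site = {}
    for site, df in _per_site(series).items():
        df = _clip_window(df, window)
        _check_sane(site, df["temp_c"].to_numpy(), cfg.sanity_band)
        per_site[site] = daily_stats(df, cfg.min_hours_per_day)["mean"]
    all_days = sorted(set().union(*[set(s.index) for s in per_site.values()]))
    excluded = []
    for site, s in list(per_site.items()):
        if len(s) < (1.0 - max_missing_fraction) * len(all_days):
            excluded.append(site)
            warnings.warn(f"site {site} missing >{max_missing_fraction:.0%} of common days; excluded from PCA")
            del per_site[site]
    if len(per_site) < 2:
        raise ValueError("need >=2 sites with common day coverage for PCA")
    common = sorted(set.intersection(*[set(s.index) for s in per_site.values()]))
    if not common:
        raise ValueError("no common days across sites")
    mat = pd.DataFrame({site: s.reindex(common) for site, s in per_site.items()}).T  # sites × days
    pca = PCA(n_components=min(mat.shape))
    scores = pca.fit_transform(mat.to_numpy() - mat.to_numpy().mean(axis=0, keepdims=True))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=mat.index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        excluded_sites=excluded,
    )
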