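"""Configuration objects for every pipeline stage.

Each stage owns a small dataclass with validated fields; :class:`PipelineConfig`
nests them and can be round-tripped through YAML.  Unknown keys are rejected so
a typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic reciprocal-transplant experiment.

    The defaults mirror the dimensions of the field study being emulated:
    10 coral genotypes outplanted to 8 reef sites with 10 replicate fragments
    each (one genotype×site combination never outplanted), scored at 3 summer
    timepoints, with 122 fragments lost to early transplantation stress, and a
    RAD-seq panel of 13,337 biallelic loci of which 58 carry signal with
    per-locus dosage–phenotype correlations in 0.73–0.89.
    """

    n_genotypes: int = 10
    n_sites: int = 8
    n_replicates: int = 10
    n_timepoints: int = 3
    n_loci: int = 13337
    n_causal: int = 58
    # variance components of the latent bleaching severity (arbitrary latent
    # units; chosen so the two-way ANOVA F ratios land near the field study's
    # order of magnitude: site >> genotype > interaction)
    var_genotype: float = 0.04
    var_site: float = 0.20
    var_gxe: float = 0.05
    var_noise: float = 1.00
    var_timepoint: float = 0.25
    target_r_range: Tuple[float, float] = (0.73, 0.89)
    depth_mean: float = 20.0
    depth_dispersion: float = 2.0
    maf_range: Tuple[float, float] = (0.10, 0.45)
    uninformative_fraction: float = 0.0
    missing_combination: Optional[Tuple[str, str]] = ("G10", "S8")
    n_early_mortality: int = 122
    # ordinal thresholds on the latent scale; None -> quartile cuts of the
    # marginal latent distribution
    score_thresholds: Optional[Tuple[float, float, float]] = None
    survival_slope: float = 1.5
    survival_intercept: float = -0.5
    seed: int = 0

    def validate(self) -> "SimConfig":
        _check(self.n_genotypes >= 1 and self.n_sites >= 1, "need >=1 genotype and site")
        _check(self.n_replicates >= 1 and self.n_timepoints >= 1, "need >=1 replicate/timepoint")
        _check(0 <= self.n_causal <= self.n_loci, "n_causal must be in [0, n_loci]")
        for name in ("var_genotype", "var_site", "var_gxe", "var_noise", "var_timepoint"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        lo, hi = self.target_r_range
        _check(0 < lo <= hi < 1, "target_r_range must satisfy 0 < low <= high < 1")
        mlo, mhi = self.maf_range
        _check(0 < mlo <= mhi < 0.5, "maf_range must satisfy 0 < low <= high < 0.5")
        _check(0 <= self.uninformative_fraction < 1, "uninformative_fraction in [0,1)")
        _check(self.depth_mean >= 0 and self.depth_dispersion > 0, "invalid depth model")
        _check(self.n_early_mortality >= 0, "n_early_mortality must be >= 0")
        return self

    @property
    def genotype_ids(self) -> list:
        return [f"G{i + 1}" for i in range(self.n_genotypes)]

    @property
    def site_ids(self) -> list:
        return [f"S{i + 1}" for i in range(self.n_sites)]


@dataclass
class ThermalConfig:
    """Thermal-stress thresholds (°C).

    ``mmm`` is the climatological maximum monthly mean; heat stress accumulates
    above ``mmm + 1`` (the DHW threshold) following the NOAA convention.
    """

    mmm: float = 28.7
    dhw_threshold: float = 29.7
    bleaching_threshold: float = 30.5
    exceedance_thresholds: Sequence[float] = (30.5, 31.0, 32.0, 33.0)
    min_hours_per_day: int = 20
    dhw_mode: str = "hotspot"  # or "excess"
    sanity_band: Tuple[float, float] = (15.0, 40.0)

    def validate(self) -> "ThermalConfig":
        _check(self.dhw_threshold > self.mmm, "dhw_threshold must exceed mmm")
        _check(self.dhw_mode in ("hotspot", "excess"), "dhw_mode must be hotspot|excess")
        _check(self.min_hours_per_day >= 1, "min_hours_per_day must be >= 1")
        return self


@dataclass
class ModelConfig:
    """Random-forest ensemble and repeated cross-validation settings.

    ``predictors_per_split`` (mtry) defaults to 1, restricting the forest to
    additive locus effects; R² is the squared Pearson correlation between
    held-out predictions and observations.
    """

    n_folds: int = 2
    n_repeats: int = 20
    trees: int = 500
    predictors_per_split: int = 1
    noinfo_mode: str = "frequency"  # or "flat"
    seed: int = 0

    def validate(self) -> "ModelConfig":
        _check(self.n_folds >= 2, "n_folds must be >= 2")
        _check(self.n_repeats >= 1, "n_repeats must be >= 1")
        _check(self.trees >= 1, "trees must be >= 1")
        _check(self.predictors_per_split >= 1, "predictors_per_split must be >= 1")
        _check(self.noinfo_mode in ("frequency", "flat"), "noinfo_mode must be frequency|flat")
        return self


@dataclass
class EnrichConfig:
    min_category_size: int = 5
    max_category_fraction: float = 0.10
    fdr_levels: Tuple[float, float] = (0.05, 0.10)

    def validate(self) -> "EnrichConfig":
        _check(self.min_category_size >= 1, "min_category_size must be >= 1")
        _check(0 < self.max_category_fraction <= 1, "max_category_fraction in (0,1]")
        return self


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    screen_p_threshold: float = 0.01
    robustness_fractions: Sequence[float] = (0.1, 0.25, 0.5)
    robustness_replicates: int = 100
    min_called: int = 30
    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        self.thermal.validate()
        self.model.validate()
        self.enrich.validate()
        _check(0 < self.screen_p_threshold <= 1, "screen_p_threshold in (0,1]")
        for f in self.robustness_fractions:
            _check(0 <= f <= 1, "robustness fractions must lie in [0,1]")
        return self


_SECTIONS = {"sim": SimConfig, "thermal": ThermalConfig, "model": ModelConfig, "enrich": EnrichConfig}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data.pop(name) or {})
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return PipelineConfig(**kwargs).validate()


def dump_config(cfg: PipelineConfig, path) -> None:
    """Write the fully resolved configuration (every default made explicit)."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(enc(cfg), fh, sort_keys=False)
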