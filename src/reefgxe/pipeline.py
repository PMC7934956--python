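"""End-to-end pipeline: simulate → phenotype → screen → fit → robustness →
predict → enrich, on one configuration.

Every run writes the resolved configuration and seed next to its outputs so a
run directory is self-describing; a failed run leaves a ``FAILED`` sentinel
naming the stage that raised.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import io, simdata
from .config import PipelineConfig, dump_config
from .dosage import compute_dosage, screen_loci
from .enrichment import mwu_enrichment
from .model import fit_and_crossvalidate, missing_data_robustness, predict_novel, save_model, validate_external
from .phenotype import bleaching_mortality, compute_phenotypes, genotype_effect_anova, gxe_anova
from .thermal import daily_mean_pca, summarize_sites

log = logging.getLogger("reefgxe")


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> Path:
    """Run every stage on synthetic data; returns the run directory."""
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    dump_config(cfg, out / "config_resolved.yaml")
    sentinel = out / "FAILED"
    if sentinel.exists():
        sentinel.unlink()

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cfg.sim.seed = cfg.seed
        survey, truth = simdata.simulate_design(cfg.sim)
        io.write_survey(survey, out / "survey.csv")
        io.write_ground_truth(truth, out / "ground_truth.json")

        climates = simdata.default_site_climates(cfg.sim.site_ids, cfg.seed)
        temps = simdata.simulate_temperature(climates, "2015-05-01", "2015-08-15", cfg.seed)
        io.write_temperature(temps, out / "temperature.csv")
        log.info("simulate: %.1fs", time.perf_counter() - t0)

        stage = "phenotype"
        t0 = time.perf_counter()
        phenos = compute_phenotypes(survey)
        phenos.fragments.to_csv(out / "phenotypes.csv", index=False)
        gxe_anova(phenos).to_csv(out / "anova_gxe.tsv", sep="\t")
        genotype_effect_anova(phenos).to_csv(out / "anova_genotype.tsv", sep="\t")
        mort = bleaching_mortality(phenos, survey)
        pd.Series(
            {
                "wilcox_p": mort.wilcox_p,
                "regression_r2": mort.regression_r2,
                "regression_p": mort.regression_p,
                "frac_full_mortality": mort.frac_full_mortality,
            }
        ).to_csv(out / "mortality.tsv", sep="\t", header=False)
        log.info("phenotype: %.1fs", time.perf_counter() - t0)

        stage = "thermal"
        t0 = time.perf_counter()
        thermal_summary = summarize_sites(temps, cfg.thermal)
        thermal_summary.to_csv(out / "thermal_summary.tsv", sep="\t")
        pca = daily_mean_pca(temps, cfg.thermal)
        pca.scores.to_csv(out / "thermal_pca.tsv", sep="\t")
        log.info("thermal: %.1fs", time.perf_counter() - t0)

        stage = "screen"
        t0 = time.perf_counter()
        # causal loci are anchored to the realized phenotype, mirroring the
        # study's selection of loci by their observed correlation
        geno = simdata.simulate_genotypes(cfg.sim, truth, target_residuals=phenos.genotype_residuals)
        io.write_beagle(geno, out / "genotypes.beagle.tsv")
        dosages = compute_dosage(geno)
        io.write_dosage(dosages, out / "dosage.tsv")
        screen = screen_loci(dosages, phenos.genotype_residuals, cfg.screen_p_threshold)
        screen.to_csv(out / "screen.tsv", sep="\t")
        retained = screen.index[screen["retained"]].tolist()
        log.info("screen: %d/%d loci retained (%.1fs)", len(retained), len(screen), time.perf_counter() - t0)
        if len(retained) < 2:
            raise RuntimeError("fewer than 2 loci retained; cannot fit a model")

        stage = "fit"
        t0 = time.perf_counter()
        cfg.model.seed = cfg.seed
        fit = fit_and_crossvalidate(dosages, phenos.genotype_residuals, cfg.model, loci=retained)
        save_model(fit, out / "model.joblib")
        pd.Series(fit.cv_r2, name="cv_r2").to_csv(out / "cv_r2.csv", index=False)
        fit.importances.to_csv(out / "importances.tsv", sep="\t")
        log.info("fit: mean CV R2 %.3f, final R2 %.3f (%.1fs)", fit.cv_r2.mean(), fit.final_r2, time.perf_counter() - t0)

        stage = "robustness"
        t0 = time.perf_counter()
        robust = missing_data_robustness(
            fit, dosages, phenos.genotype_residuals, cfg.robustness_fractions, cfg.robustness_replicates
        )
        robust.to_csv(out / "robustness.tsv", sep="\t", index=False)
        log.info("robustness: %.1fs", time.perf_counter() - t0)

        stage = "predict"
        t0 = time.perf_counter()
        preds = predict_novel(fit, dosages, min_called=cfg.min_called, seed=cfg.seed)
        preds.to_csv(out / "predictions.csv", index=False)
        decline = simdata.simulate_fvfm_decline(phenos.genotype_residuals, cfg.seed)
        val = validate_external(preds.set_index("sample_id")["predicted_residual"], decline)
        pd.Series({"slope": val.slope, "r2": val.r2, "p": val.p, "n": val.n}).to_csv(
            out / "validation.tsv", sep="\t", header=False
        )
        log.info("predict: %.1fs", time.perf_counter() - t0)

        stage = "enrich"
        t0 = time.perf_counter()
        annot = simdata.simulate_annotations(screen.index.tolist(), cfg.seed)
        enr = mwu_enrichment(screen["r"].to_dict(), annot, cfg.enrich, fdr_levels=cfg.enrich.fdr_levels)
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        log.info("enrich: %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        sentinel.write_text(f"stage {stage} failed: {exc}\n")
        raise
    return out
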