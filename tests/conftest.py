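import numpy as np
import pandas as pd
import pytest

import reefgxe as rg
from reefgxe.config import ModelConfig, SimConfig


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size simulated survey with its ground truth (study dimensions)."""
    cfg = SimConfig(seed=11)
    survey, truth = rg.simulate_design(cfg)
    return cfg, survey, truth


@pytest.fixture(scope="session")
def default_phenotypes(default_dataset):
    _, survey, _ = default_dataset
    return rg.compute_phenotypes(survey)


@pytest.fixture(scope="session")
def matched_structure():
    """Synthetic dataset matched to the study's signal structure:

    10 genotypes, 58 predictor loci, realized dosage–phenotype correlations
    inside 0.73–0.89 (loci anchored to the realized phenotype, as in the
    study's correlation-based selection).
    """
    cfg = SimConfig(seed=7, n_loci=58, n_causal=58)
    survey, truth = rg.simulate_design(cfg)
    phenos = rg.compute_phenotypes(survey)
    geno = rg.simulate_genotypes(cfg, truth, target_residuals=phenos.genotype_residuals)
    dosages = rg.compute_dosage(geno)
    return cfg, phenos, geno, dosages


@pytest.fixture(scope="session")
def matched_fit(matched_structure):
    cfg, phenos, geno, dosages = matched_structure
    mcfg = ModelConfig(seed=7)
    return rg.fit_and_crossvalidate(dosages, phenos.genotype_residuals, mcfg)


def make_small_survey():
    """Tiny hand-sized survey for exact-value tests."""
    rows = []
    for frag, g, s, scores in [
        ("f1", "G1", "S1", (1, 1, 1)),
        ("f2", "G2", "S1", (2, 2, 2)),
        ("f3", "G1", "S2", (0, 1, 2)),
        ("f4", "G2", "S2", (3, 3, 3)),
    ]:
        for t, sc in enumerate(scores, start=1):
            rows.append((frag, g, s, t, sc, False, True))
    return pd.DataFrame(
        rows,
        columns=[
            "fragment_id",
            "genotype_id",
            "site_id",
            "timepoint",
            "score",
            "early_mortality",
            "survived_december",
        ],
    )
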