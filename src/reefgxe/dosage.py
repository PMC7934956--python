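"""Expected allele dosages from genotype probabilities, and locus screening.

A biallelic locus genotyped from low-coverage reads is summarized by a
posterior probability triplet (P_aa, P_ab, P_bb).  The expected count of the
secondary allele, ``dosage = P_ab + 2·P_bb`` ∈ [0, 2], carries the calling
uncertainty into downstream models without hard-calling genotypes.  Loci are
screened by simple linear regression of the genotype-level residual bleaching
phenotype on dosage, retaining loci with a two-sided p below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

TRIPLET_SUM_TOL = 1e-3


@dataclass
class GenotypeProbabilityTable:
    """Loci × samples grid of genotype-probability triplets.

    ``probs`` has shape (n_loci, n_samples, 3) ordered (aa, ab, bb);
    ``informative`` marks cells backed by sequencing evidence (an
    uninformative cell holds only the prior and is treated as missing
    downstream).
    """

    probs: np.ndarray
    locus_ids: List[str]
    sample_ids: List[str]
    informative: np.ndarray = None
    realized_causal_r: Dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probs must have shape (n_loci, n_samples, 3)")
        if self.probs.shape[0] != len(self.locus_ids) or self.probs.shape[1] != len(self.sample_ids):
            raise ValueError("probs shape inconsistent with locus/sample IDs")
        if self.informative is None:
            self.informative = np.ones(self.probs.shape[:2], dtype=bool)
        self.informative = np.asarray(self.informative, dtype=bool)

    def validate(self, tol: float = 1e-6) -> "GenotypeProbabilityTable":
        if (self.probs < -tol).any() or (self.probs > 1 + tol).any():
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=2)
        bad = np.abs(sums - 1.0) > tol
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"triplet does not sum to 1 at locus {self.locus_ids[i]}, "
                f"sample {self.sample_ids[j]} (sum={sums[i, j]:.6f})"
            )
        return self


@dataclass
class DosageMatrix:
    """Expected secondary-allele counts, loci × samples, in [0, 2].

    Uninformative cells are NaN.  ``freq`` is the per-locus estimated
    secondary-allele frequency (mean dosage / 2 over informative cells).
    """

    values: pd.DataFrame  # index = locus IDs, columns = sample IDs
    freq: pd.Series

    @property
    def locus_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)


def compute_dosage(probs: GenotypeProbabilityTable) -> DosageMatrix:
    """Dosage = P(ab) + 2·P(bb) per cell; uninformative cells become NaN.

    Raises if any triplet sum deviates from 1 by more than ``TRIPLET_SUM_TOL``
    (the offending cell is named).
    """
    sums = probs.probs.sum(axis=2)
    bad = np.abs(sums - 1.0) > TRIPLET_SUM_TOL
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"triplet sum off by >{TRIPLET_SUM_TOL} at locus "
            f"{probs.locus_ids[i]}, sample {probs.sample_ids[j]}"
        )
    dosage = probs.probs[:, :, 1] + 2.0 * probs.probs[:, :, 2]
    dosage = np.where(probs.informative, dosage, np.nan)
    values = pd.DataFrame(dosage, index=probs.locus_ids, columns=probs.sample_ids)
    freq = values.mean(axis=1, skipna=True) / 2.0
    freq.name = "secondary_allele_freq"
    return DosageMatrix(values=values, freq=freq)


def screen_loci(
    dosages: DosageMatrix,
    genotype_residuals: pd.Series,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-locus regression of the residual phenotype on dosage.

    Loci with any missing genotype are dropped (a locus must be called in
    every sample), as are zero-variance loci.  Returns a DataFrame indexed by
    locus with columns ``r`` (signed Pearson correlation), ``p`` (two-sided
    t-test on the regression slope) and ``retained`` (p < threshold); the full
    r vector feeds rank-based enrichment downstream.  The number of excluded
    loci is stored in ``result.attrs``.
    """
    common = [s for s in dosages.sample_ids if s in genotype_residuals.index]
    if len(common) < 3:
        raise ValueError("need >=3 genotypes with both dosage and residual phenotype")
    X = dosages.values[common].to_numpy(dtype=float)
    y = genotype_residuals.reindex(common).to_numpy(dtype=float)
    n = len(common)

    complete = ~np.isnan(X).any(axis=1)
    sd = X.std(axis=1)
    usable = complete & (sd > 0)
    if y.std() == 0:
        raise ValueError("residual phenotype is constant; correlations undefined")

    Xc = X[usable] - X[usable].mean(axis=1, keepdims=True)
    yc = y - y.mean()
    r = (Xc @ yc) / (n * X[usable].std(axis=1) * y.std())
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |r| == 1 -> infinite t -> p = 0

    idx = np.asarray(dosages.locus_ids, dtype=object)[usable]
    result = pd.DataFrame({"r": r, "p": p, "retained": p < p_threshold}, index=pd.Index(idx, name="locus_id"))
    result.attrs["n_excluded_missing"] = int((~complete).sum())
    result.attrs["n_excluded_zero_variance"] = int((complete & ~usable).sum())
    result.attrs["p_threshold"] = p_threshold
    return result
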