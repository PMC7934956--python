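"""Readers and writers for the plain-text formats shared by all stages.

Formats
-------
survey CSV
    fragment_id, genotype_id, site_id, timepoint, score, early_mortality,
    survived_december — one row per fragment × timepoint.
beagle-style genotype-probability TSV
    header ``marker  allele1  allele2`` followed by each sample ID repeated
    three times; one row per locus with the (aa, ab, bb) triplet per sample.
    A cell whose triplet is exactly flat (1/3, 1/3, 1/3) is read back as
    uninformative.
temperature CSV
    site_id, timestamp (ISO-8601), temp_c.
annotation TSV
    locus_id, semicolon-separated category IDs (wide) or one
    (locus_id, category[, namespace, name]) row per pair (long).
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd

from .dosage import DosageMatrix, GenotypeProbabilityTable
from .simdata import GroundTruth

SURVEY_COLUMNS = [
    "fragment_id",
    "genotype_id",
    "site_id",
    "timepoint",
    "score",
    "early_mortality",
    "survived_december",
]

FLAT_TRIPLET_TOL = 1e-9


def write_survey(survey: pd.DataFrame, path) -> None:
    survey[SURVEY_COLUMNS].to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} is missing columns: {missing}")
    if not df["score"].between(0, 3).all():
        raise ValueError("scores must be integers in [0, 3]")
    dup = df.duplicated(["fragment_id", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (fragment_id, timepoint) rows")
    df["early_mortality"] = df["early_mortality"].astype(bool)
    df["survived_december"] = df["survived_december"].astype(bool)
    return df


def write_beagle(table: GenotypeProbabilityTable, path) -> None:
    """Write probability triplets as a beagle-style genotype-likelihood TSV.

    Uninformative cells are written as flat (1/3, 1/3, 1/3) triplets, the
    conventional encoding for a sample with no sequencing evidence.
    """
    header = ["marker", "allele1", "allele2"]
    for s in table.sample_ids:
        header += [s, s, s]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        flat = np.full(3, 1.0 / 3.0)
        for i, locus in enumerate(table.locus_ids):
            cells = []
            for j in range(len(table.sample_ids)):
                trip = table.probs[i, j] if table.informative[i, j] else flat
                cells += [f"{v:.6f}" for v in trip]
            fh.write("\t".join([locus, "0", "1"] + cells) + "\n")


def read_beagle(path) -> GenotypeProbabilityTable:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["marker", "allele1", "allele2"]:
        raise ValueError("beagle file must start with columns marker, allele1, allele2")
    sample_cols = list(df.columns[3:])
    if len(sample_cols) % 3 != 0:
        raise ValueError("beagle file must have 3 columns per sample")
    # pandas mangles repeated sample IDs into s, s.1, s.2 — strip the suffix
    samples = [c.split(".")[0] for c in sample_cols[::3]]
    probs = df.iloc[:, 3:].to_numpy(dtype=float).reshape(len(df), len(samples), 3)
    flat = np.abs(probs - 1.0 / 3.0).max(axis=2) < 1e-4
    table = GenotypeProbabilityTable(
        probs=probs,
        locus_ids=df["marker"].astype(str).tolist(),
        sample_ids=samples,
        informative=~flat,
    )
    return table.validate(tol=1e-3)


def write_dosage(dosages: DosageMatrix, path) -> None:
    out = dosages.values.copy()
    out.insert(0, "secondary_allele_freq", dosages.freq)
    out.to_csv(path, sep="\t", index_label="locus_id")


def read_dosage(path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus_id")
    freq = df.pop("secondary_allele_freq")
    return DosageMatrix(values=df, freq=freq)


def write_temperature(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[["site_id", "timestamp", "temp_c"]].to_csv(path, index=False)


def read_temperature(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("site_id", "timestamp", "temp_c") if c not in df.columns]
    if missing:
        raise ValueError(f"temperature file {path} is missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_annotations(path) -> pd.DataFrame:
    """Read either the long or the 2-column semicolon-separated wide format."""
    df = pd.read_csv(path, sep="\t")
    if "category" in df.columns:
        return df
    if df.shape[1] < 2:
        raise ValueError("annotation file needs locus_id and category columns")
    locus_col, go_col = df.columns[:2]
    rows = []
    for _, row in df.iterrows():
        for cat in str(row[go_col]).split(";"):
            cat = cat.strip()
            if cat:
                rows.append((row[locus_col], cat))
    return pd.DataFrame(rows, columns=["locus_id", "category"])


def write_ground_truth(truth: GroundTruth, path) -> None:
    data = {
        "genotype_effects": truth.genotype_effects.to_dict(),
        "site_effects": truth.site_effects.to_dict(),
        "interaction_effects": {g: truth.interaction_effects.loc[g].to_dict() for g in truth.interaction_effects.index},
        "causal_loci": truth.causal_loci,
        "true_residual_by_genotype": truth.true_residual_by_genotype.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        data = json.load(fh)
    inter = pd.DataFrame(data["interaction_effects"]).T
    return GroundTruth(
        genotype_effects=pd.Series(data["genotype_effects"]),
        site_effects=pd.Series(data["site_effects"]),
        interaction_effects=inter,
        causal_loci=data["causal_loci"],
        true_residual_by_genotype=pd.Series(data["true_residual_by_genotype"]),
    )
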