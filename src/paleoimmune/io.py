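"""Plain-text readers and writers for the pipeline's file formats.

Summary statistics are TSVs with header CHR, POS, A1 (effect allele), A2,
Z, N; BETA/SE columns are accepted and converted to Z.  Gene maps are BED
(0-based half-open), converted internally to 1-based inclusive.  Cohorts
are a genotype matrix TSV plus a sidecar individual table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sim import AncientCohort

SUMSTATS_COLUMNS = ["CHR", "POS", "A1", "A2", "Z", "N"]


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"CHR", "POS", "A1", "A2", "N"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "Z" not in df.columns:
        if not {"BETA", "SE"} <= set(df.columns):
            raise ValueError(f"{path}: need either Z or BETA+SE columns")
        df["Z"] = df["BETA"] / df["SE"]
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["CHR", "POS", "A1", "A2", "BETA", "SE", "Z", "P", "N", "MAF"]
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """BED gene map -> 1-based inclusive (chrom, start, end, gene)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene"],
                     usecols=[0, 1, 2, 3])
    out = df.copy()
    out["start"] = df["start"].astype(int) + 1     # 0-based half-open -> 1-based
    out["end"] = df["end"].astype(int)
    return out[["gene", "chrom", "start", "end"]]


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"].astype(int) - 1,
        "end": genes["end"].astype(int),
        "gene": genes["gene"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_ld_scores(ld, path: str | Path) -> None:
    ld.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ld_scores(path: str | Path):
    from .sim import LDReference
    table = pd.read_csv(path, sep="\t")
    return LDReference(table=table, M=len(table))


def write_cohort(cohort: AncientCohort, prefix: str | Path) -> None:
    """``<prefix>.individuals.tsv``, ``<prefix>.variants.tsv``, ``<prefix>.dosage.tsv``."""
    prefix = str(prefix)
    ind = pd.DataFrame({
        "individual_id": cohort.individual_id,
        "date_bp": cohort.date_bp,
        "pseudohaploid": cohort.pseudohaploid.astype(int),
    })
    for k in range(cohort.ancestry.shape[1]):
        ind[f"anc{k}"] = cohort.ancestry[:, k]
    ind.to_csv(prefix + ".individuals.tsv", sep="\t", index=False, float_format="%.6g")
    cohort.variants.to_csv(prefix + ".variants.tsv", sep="\t", index=False)
    np.savetxt(prefix + ".dosage.tsv", cohort.dosage, fmt="%.0f", delimiter="\t")


def read_cohort(prefix: str | Path) -> AncientCohort:
    prefix = str(prefix)
    ind = pd.read_csv(prefix + ".individuals.tsv", sep="\t")
    variants = pd.read_csv(prefix + ".variants.tsv", sep="\t")
    dosage = np.loadtxt(prefix + ".dosage.tsv", delimiter="\t")
    anc_cols = [c for c in ind.columns if c.startswith("anc")]
    return AncientCohort(
        individual_id=list(ind["individual_id"]),
        date_bp=ind["date_bp"].to_numpy(float),
        ancestry=ind[anc_cols].to_numpy(float),
        dosage=dosage,
        pseudohaploid=ind["pseudohaploid"].to_numpy(bool),
        variants=variants,
    )
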