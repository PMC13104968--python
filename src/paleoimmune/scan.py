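"""Per-variant selection statistics from a dated ancient cohort.

The statistic is the slope of genotype dosage on analysis time
t = -date_bp / 1000 (units: dosage change per 1,000 years toward the
present), from a weighted least-squares fit with ancestry covariates.
Pseudo-haploid individuals, whose {0, 2} calls carry twice the binomial
sampling variance of diploid calls, are down-weighted (weight 0.5 is the
precision-exact choice).  Missing dosages are handled complete-case per
variant.  An optional genomic-control step rescales all standard errors by
sqrt(lambda_GC), lambda_GC = median(Z^2)/0.4549, absorbing residual
drift/structure variance into the calibration.

The output is a GWAS-style summary-statistic table (CHR, POS, A1, A2, BETA,
SE, Z, P, N, MAF) that every downstream module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScanConfig
from .sim import AncientCohort

# median of a chi^2_1 variate; the genomic-control denominator
CHI2_MEDIAN = 0.45493642311957185

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class EmptyScanError(RuntimeError):
    """All variants were removed by the MAF / sample-size filters."""


def run_scan(cohort: AncientCohort, config: ScanConfig | None = None) -> pd.DataFrame:
    """Weighted regression of dosage on time plus ancestry covariates.

    Returns one row per retained variant with the slope (BETA, per kyr
    toward the present), its SE, Z, two-tailed normal P, the complete-case
    sample size N and the folded allele frequency MAF.
    """
    config = config or ScanConfig()
    t = cohort.time_kyr
    anc = cohort.ancestry
    k = anc.shape[1] if config.n_covariates is None else config.n_covariates
    # ancestry rows sum to 1, so drop one column to keep the design full rank
    covars = anc[:, : max(k - 1, 0)]
    X = np.column_stack([np.ones_like(t), t, covars])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            f"covariate matrix is rank-deficient (rank < {p}); "
            "check for collinear ancestry columns"
        )

    w = np.where(cohort.pseudohaploid, config.pseudohaploid_weight, 1.0)
    D = cohort.dosage
    mask = ~np.isnan(D)
    Y = np.where(mask, D, 0.0)
    Wm = mask * w[:, None]                       # (n, V) observation weights

    # batched weighted normal equations: G_v = X' diag(w m_v) X, c_v = X' diag(w m_v) y_v
    Xouter = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    G = (Wm.T @ Xouter).reshape(-1, p, p)        # (V, p, p)
    C = (Wm * Y).T @ X                           # (V, p)
    n_used = mask.sum(axis=0)

    ok = n_used >= max(config.min_n, p + 1)
    Ginv = np.full_like(G, np.nan)
    Ginv[ok] = np.linalg.inv(G[ok])
    beta_all = np.einsum("vpq,vq->vp", Ginv, C)

    yty = (Wm * Y**2).sum(axis=0)
    rss = yty - np.einsum("vp,vp->v", beta_all, C)
    dof = n_used - p
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.where(dof > 0, rss / np.maximum(dof, 1), np.nan)
        se = np.sqrt(sigma2 * Ginv[:, 1, 1])

    # folded frequency from complete-case mean dosage
    with np.errstate(invalid="ignore"):
        freq = Y.sum(axis=0) / np.maximum(mask.sum(axis=0), 1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    keep = ok & (maf >= max(config.maf_min, 1e-12)) & (sigma2 > 1e-12) & np.isfinite(se)
    if not keep.any():
        raise EmptyScanError("no variants survive the MAF / sample-size filters")

    out = cohort.variants.loc[keep, ["CHR", "POS", "A1", "A2"]].copy()
    out["BETA"] = beta_all[keep, 1]
    out["SE"] = se[keep]
    if config.genomic_control:
        z = out["BETA"] / out["SE"]
        lam = np.median(z**2) / CHI2_MEDIAN
        out["SE"] *= np.sqrt(lam)
        out.attrs["lambda_gc"] = float(lam)
    out["Z"] = out["BETA"] / out["SE"]
    out["P"] = 2.0 * stats.norm.sf(np.abs(out["Z"]))
    out["N"] = n_used[keep]
    out["MAF"] = maf[keep]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# allele harmonization


@dataclass
class HarmonizeReport:
    n_matched: int
    n_flipped: int
    n_dropped_unmatched: int
    n_dropped_palindromic: int
    n_dropped_allele_mismatch: int
    dropped_palindromic: list = field(default_factory=list)
    dropped_mismatch: list = field(default_factory=list)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def harmonize(selection: pd.DataFrame, other: pd.DataFrame,
              ambiguous_maf: float = 0.4,
              ) -> tuple[pd.DataFrame, pd.DataFrame, HarmonizeReport]:
    """Align a second summary-statistic table onto the selection track.

    Variants are keyed on (CHR, POS); where the other table's alleles are
    swapped relative to the selection track, its Z is negated; strand-
    ambiguous pairs (A/T, C/G) at MAF > ``ambiguous_maf`` are dropped, as
    are allele mismatches and unmatched positions.  Returns the two aligned
    tables (same variant order) and a flip/drop report.
    """
    for name, df in [("selection", selection), ("other", other)]:
        dup = df.duplicated(subset=["CHR", "POS"])
        if dup.any():
            keys = df.loc[dup, ["CHR", "POS"]].itertuples(index=False, name=None)
            raise ValueError(f"duplicate variant keys in {name} table: {list(keys)[:10]}")

    merged = selection.merge(other, on=["CHR", "POS"], suffixes=("_a", "_b"))
    n_unmatched = (len(selection) - len(merged)) + (len(other) - len(merged))

    same = (merged["A1_a"] == merged["A1_b"]) & (merged["A2_a"] == merged["A2_b"])
    swapped = (merged["A1_a"] == merged["A2_b"]) & (merged["A2_a"] == merged["A1_b"])
    mismatch = ~(same | swapped)

    palindromic = _is_palindromic(merged["A1_a"], merged["A2_a"])
    if "MAF" in merged.columns:
        maf = merged["MAF"]
    elif "MAF_a" in merged.columns:
        maf = merged["MAF_a"]
    else:
        maf = pd.Series(0.5, index=merged.index)  # unknown: treat as ambiguous
    drop_pal = palindromic & (maf > ambiguous_maf) & ~mismatch

    keep = ~(mismatch | drop_pal)
    report = HarmonizeReport(
        n_matched=int(keep.sum()),
        n_flipped=int((swapped & keep).sum()),
        n_dropped_unmatched=int(n_unmatched),
        n_dropped_palindromic=int(drop_pal.sum()),
        n_dropped_allele_mismatch=int(mismatch.sum()),
        dropped_palindromic=list(
            merged.loc[drop_pal, ["CHR", "POS"]].itertuples(index=False, name=None)),
        dropped_mismatch=list(
            merged.loc[mismatch, ["CHR", "POS"]].itertuples(index=False, name=None)),
    )

    kept = merged.loc[keep].reset_index(drop=True)
    flip = np.where(kept["A1_a"] == kept["A2_b"], -1.0, 1.0)

    a_cols = {"CHR": kept["CHR"], "POS": kept["POS"],
              "A1": kept["A1_a"], "A2": kept["A2_a"]}
    left = pd.DataFrame(a_cols)
    right = pd.DataFrame(a_cols)
    for col in selection.columns:
        if col in ("CHR", "POS", "A1", "A2"):
            continue
        left[col] = kept[f"{col}_a"].to_numpy() if f"{col}_a" in kept else kept[col].to_numpy()
    for col in other.columns:
        if col in ("CHR", "POS", "A1", "A2"):
            continue
        vals = kept[f"{col}_b"].to_numpy() if f"{col}_b" in kept else kept[col].to_numpy()
        if col in ("Z", "BETA"):
            vals = vals * flip
        right[col] = vals
    return left, right, report
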