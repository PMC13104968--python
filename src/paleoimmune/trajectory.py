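"""Polygenic-score trajectories through time and the gamma_sign trend test.

An individual's polygenic score (PGS) is the effect-size-weighted sum of
risk-allele dosages, divided by the individual's number of non-missing
weight variants (so date-correlated missingness cannot masquerade as a
trend).  gamma_sign is the slope of the PGS on analysis time
t = -date_bp/1000 with ancestry covariates — "PGS change per 1,000 years
toward the present".

Its significance is assessed against an empirical null built by randomly
sign-flipping the per-variant weight contributions and recomputing the
slope.  The flips are independent fair coins per variant, which preserves
the cohort's drift/structure covariance and the frequency profile of the
weight set while destroying any weight-trend coupling; for weight sets
whose signs are exchangeable under the null this permutation scheme is
exactly calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import AncientCohort


def _pgs_matrix(cohort: AncientCohort, weights: pd.DataFrame,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Normalized per-variant contribution matrix Dn and aligned weights.

    Dn[i, j] is individual i's (possibly complemented) dosage at weight
    variant j divided by i's non-missing weight-variant count, so
    scores = Dn @ beta.  Where the weight's effect allele is the cohort's
    non-counted allele the dosage is complemented (2 - d): a weight on the
    other allele is not just a sign flip at the score level.
    """
    if weights.duplicated(subset=["CHR", "POS"]).any():
        raise ValueError("duplicate variant keys in the weight table")
    variants = cohort.variants.copy()
    variants["_col"] = np.arange(len(variants))
    merged = variants.merge(weights, on=["CHR", "POS"], suffixes=("", "_w"))
    if "A2_w" in merged.columns:
        ok = ((merged["A1_w"] == merged["A1"]) & (merged["A2_w"] == merged["A2"])) | \
             ((merged["A1_w"] == merged["A2"]) & (merged["A2_w"] == merged["A1"]))
    else:
        ok = (merged["A1_w"] == merged["A1"]) | (merged["A1_w"] == merged["A2"])
    merged = merged.loc[ok]
    if merged.empty:
        raise ValueError("no overlap between weight variants and cohort variants")
    cols = merged["_col"].to_numpy(int)
    beta = merged["BETA"].to_numpy(float)
    flip = (merged["A1_w"] == merged["A2"]).to_numpy()
    D = cohort.dosage[:, cols]
    D = np.where(flip[None, :], 2.0 - D, D)
    mask = ~np.isnan(D)
    m = mask.sum(axis=1)
    if np.any(m == 0):
        raise ValueError("some individuals have no non-missing weight variants")
    Dn = np.where(mask, D, 0.0) / m[:, None]
    aligned = cohort.variants.iloc[cols][["CHR", "POS", "A1", "A2"]].reset_index(drop=True)
    aligned["BETA"] = beta
    aligned["FLIPPED"] = flip
    return Dn, beta, cols, aligned


def compute_pgs(cohort: AncientCohort, weights: pd.DataFrame,
                ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Missingness-normalized per-individual polygenic scores.

    ``weights`` has columns CHR, POS, A1 (effect allele), BETA (and
    optionally A2; allele mismatches are dropped).  Pseudo-haploid dosages
    are used as-is.  Returns the score vector, the aligned weight table,
    and the cohort column indices of the weight variants.

    score_i = sum_j beta_j * dosage_ij / #{non-missing j}.
    """
    Dn, beta, cols, aligned = _pgs_matrix(cohort, weights)
    return Dn @ beta, aligned, cols


@dataclass
class TrajectoryResult:
    gamma_sign: float          # PGS slope per 1,000 years toward the present
    se_analytic: float
    p_empirical: float
    n_permutations: int
    scores: np.ndarray = field(repr=False)
    null_gammas: np.ndarray = field(repr=False, default=None)


def _slope_functional(t: np.ndarray, covariates: np.ndarray | None):
    """Vector a with slope = a @ y for regression of y on [1, t, covariates]."""
    cols = [np.ones_like(t), t]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    X = np.column_stack(cols)
    XtXinv = np.linalg.inv(X.T @ X)
    return (XtXinv @ X.T)[1], X, XtXinv


def gamma_test(cohort: AncientCohort, weights: pd.DataFrame,
               covariates: np.ndarray | None = None, B: int = 999,
               seed: int = 0) -> TrajectoryResult:
    """Empirical sign-flip test of a temporal PGS trend.

    p_empirical = (1 + #{|gamma_null| >= |gamma_obs|}) / (1 + B), where
    null slopes recompute the PGS slope under independent per-variant sign
    flips of the weight contributions.  Ancestry covariates default to the
    cohort's ancestry columns (one dropped for identifiability).
    """
    if B < 100:
        raise ValueError("use at least 100 permutations")
    if np.unique(np.round(cohort.date_bp, 6)).size < 3:
        raise ValueError("need at least 3 distinct dates")
    Dn, beta, _, _ = _pgs_matrix(cohort, weights)
    scores = Dn @ beta
    t = cohort.time_kyr
    if covariates is None and cohort.ancestry.shape[1] > 1:
        covariates = cohort.ancestry[:, :-1]
    a, X, XtXinv = _slope_functional(t, covariates)

    gamma_obs = float(a @ scores)
    resid = scores - X @ np.linalg.lstsq(X, scores, rcond=None)[0]
    dof = len(scores) - X.shape[1]
    se = float(np.sqrt(resid @ resid / dof * XtXinv[1, 1]))

    # gamma is linear in the flipped contributions:
    # gamma(sigma) = sum_j sigma_j c_j with c_j = (a @ Dn)_j * beta_j
    c = (a @ Dn) * beta
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(B, c.size))
    null = flips @ c
    p = (1.0 + np.sum(np.abs(null) >= abs(gamma_obs))) / (1.0 + B)
    return TrajectoryResult(
        gamma_sign=gamma_obs, se_analytic=se, p_empirical=float(p),
        n_permutations=B, scores=scores, null_gammas=null,
    )


def group_means(scores: np.ndarray, cohort: AncientCohort,
                groups: dict[str, str]) -> pd.DataFrame:
    """Mean PGS with 95% CI per user-defined individual group.

    ``groups`` maps individual id -> label.  Size-1 groups have no defined
    SE; their CI bounds are reported as NaN.
    """
    idx = {iid: i for i, iid in enumerate(cohort.individual_id)}
    unknown = set(groups) - set(idx)
    if unknown:
        raise KeyError(f"unknown individual id(s): {sorted(unknown)[:5]}")
    rows = []
    for lab in sorted(set(groups.values())):
        members = [idx[i] for i, g in groups.items() if g == lab]
        vals = scores[members]
        mean = float(vals.mean())
        if len(vals) > 1:
            se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        else:
            se, lo, hi = np.nan, np.nan, np.nan
        rows.append({"group": lab, "n": len(vals), "mean": mean,
                     "se": se, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
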