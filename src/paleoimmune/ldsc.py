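"""LD-score regression on summary-statistic tracks, with block jackknives.

The univariate fit regresses Z^2/N on l_j/M with a free intercept (so the
intercept estimates 1/N under the null and absorbs confounding inflation);
its slope is the heritability-analog h2 of the track.  The bivariate fit
regresses Z_a*Z_b/sqrt(N_a*N_b) on l_j/M; its slope is the genetic
covariance rho_g, and rg = rho_g / sqrt(h2_a * h2_b).  Working on the
Z/sqrt(N) scale makes every estimate exactly invariant to rescaling a
track's Z by c alongside N by c^2 — the natural requirement for a
selection track whose "sample size" is only an effective-precision proxy.

Standard errors come from a delete-one block jackknife over contiguous
position blocks (200 by default); the leave-one-out series are retained so
that a covariance-aware meta-analysis across traits can build the joint
estimate covariance from shared blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sim import LDReference


# ---------------------------------------------------------------------------
# blocked weighted least squares with delete-one jackknife


def contiguous_blocks(n: int, n_blocks: int) -> np.ndarray:
    """Assign n ordered items to n_blocks approximately equal contiguous blocks."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    return (np.arange(n) * n_blocks) // n


def _blocked_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                 block_ids: np.ndarray, n_blocks: int,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted LS fit plus all delete-one-block refits via sufficient stats.

    Returns (coef, loo_coefs) with loo_coefs of shape (n_blocks, p).
    """
    p = X.shape[1]
    Xw = X * w[:, None]
    G_full = Xw.T @ X
    c_full = Xw.T @ y
    # per-block contributions
    Gb = np.zeros((n_blocks, p, p))
    cb = np.zeros((n_blocks, p))
    Xouter = (X[:, :, None] * X[:, None, :]).reshape(len(y), p * p)
    for b in range(n_blocks):
        sel = block_ids == b
        Gb[b] = (Xouter[sel] * w[sel, None]).sum(axis=0).reshape(p, p)
        cb[b] = (Xw[sel].T @ y[sel])
    coef = np.linalg.solve(G_full, c_full)
    loo = np.linalg.solve(G_full[None] - Gb, (c_full[None] - cb)[..., None])[..., 0]
    return coef, loo


def jackknife_se(loo: np.ndarray, axis: int = 0) -> np.ndarray:
    """Delete-one jackknife SE from leave-one-out estimates."""
    b = loo.shape[axis]
    mean = loo.mean(axis=axis, keepdims=True)
    return np.sqrt((b - 1) / b * ((loo - mean) ** 2).sum(axis=axis))


def block_jackknife_mean(values: np.ndarray, n_blocks: int = 200,
                         ) -> tuple[float, float, np.ndarray]:
    """Mean of an ordered track with a contiguous-block jackknife SE."""
    values = np.asarray(values, float)
    ids = contiguous_blocks(len(values), n_blocks)
    total, count = values.sum(), len(values)
    bs = np.bincount(ids, weights=values, minlength=n_blocks)
    bn = np.bincount(ids, minlength=n_blocks)
    loo = (total - bs) / (count - bn)
    return float(values.mean()), float(jackknife_se(loo)), loo


# ---------------------------------------------------------------------------
# univariate fit


@dataclass
class H2Result:
    h2: float
    se: float
    intercept: float          # on the conventional E[Z^2] scale (1 under null)
    intercept_se: float
    n_blocks: int
    loo_h2: np.ndarray        # leave-one-block-out h2 estimates
    mean_n: float


def _align(sumstats: pd.DataFrame, ld: LDReference) -> pd.DataFrame:
    merged = sumstats.merge(ld.table[["CHR", "POS", "L2"]], on=["CHR", "POS"])
    if len(merged) != len(sumstats):
        raise ValueError("sumstats contain variants absent from the LD reference")
    return merged

def estimate_h2(sumstats: pd.DataFrame, ld: LDReference, n_blocks: int = 200,
                weights: np.ndarray | None = None) -> H2Result:
    """Heritability-analog of a track: slope of Z^2/N on l/M.

    Two-step weights 1/(2*(1/N + h2_0*l/M)^2), initialized from an
    unweighted pass (``weights`` overrides both steps when given).
    """
    df = _align(sumstats, ld)
    m = len(df)
    if m < 10 * n_blocks:
        raise ValueError(f"need at least {10 * n_blocks} variants for {n_blocks} blocks")
    l2 = df["L2"].to_numpy(float)
    if np.any(l2 <= 0):
        raise ValueError("non-positive LD scores")
    z = df["Z"].to_numpy(float)
    n = df["N"].to_numpy(float)
    x = l2 / ld.M
    y = z**2 / n
    X = np.column_stack([np.ones(m), x])
    if weights is None:
        c0 = np.linalg.lstsq(X, y, rcond=None)[0]
        h2_0 = max(float(c0[1]), 0.0)
        # the pass-1 intercept estimates the noise floor on the Z^2/N scale;
        # using it (rather than 1/N) keeps the weights invariant under
        # Z -> cZ, N -> c^2 N rescaling of the track
        int_0 = max(float(c0[0]), float(np.min(1.0 / n)) * 1e-3)
        weights = 1.0 / (2.0 * (int_0 + h2_0 * x) ** 2)
    ids = contiguous_blocks(m, n_blocks)
    coef, loo = _blocked_wls(X, y, weights, ids, n_blocks)
    se = jackknife_se(loo)
    mean_n = float(n.mean())
    return H2Result(
        h2=float(coef[1]), se=float(se[1]),
        intercept=float(coef[0]) * mean_n, intercept_se=float(se[0]) * mean_n,
        n_blocks=n_blocks, loo_h2=loo[:, 1], mean_n=mean_n,
    )


# ---------------------------------------------------------------------------
# bivariate fit


@dataclass
class RgResult:
    rho_g: float
    h2_a: float
    h2_b: float
    rg: float                  # NaN when either h2 estimate is non-positive
    se_rg: float
    intercept_a: float
    intercept_b: float
    intercept_ab: float        # bivariate intercept on the Z_a*Z_b scale
    n_blocks: int
    loo_rg: np.ndarray         # leave-one-block-out rg (for meta-analysis)
    loo_rho: np.ndarray

    @property
    def valid(self) -> bool:
        return np.isfinite(self.rg)


def estimate_rg(sumstats_a: pd.DataFrame, sumstats_b: pd.DataFrame,
                ld: LDReference, n_blocks: int = 200) -> RgResult:
    """Cross-track genetic correlation with a shared-block jackknife SE.

    The leave-one-out series recompute the full ratio
    rho_g / sqrt(h2_a h2_b) per block deletion.  When either full-track h2
    estimate is non-positive the correlation is reported as missing (NaN)
    rather than clipped.
    """
    if not np.array_equal(sumstats_a["POS"].to_numpy(), sumstats_b["POS"].to_numpy()):
        raise ValueError("tracks must be harmonized to the same variant set/order")
    a = _align(sumstats_a, ld)
    b = _align(sumstats_b, ld)
    m = len(a)
    h2a = estimate_h2(sumstats_a, ld, n_blocks)
    h2b = estimate_h2(sumstats_b, ld, n_blocks)

    x = a["L2"].to_numpy(float) / ld.M
    za, zb = a["Z"].to_numpy(float), b["Z"].to_numpy(float)
    na, nb = a["N"].to_numpy(float), b["N"].to_numpy(float)
    y = za * zb / np.sqrt(na * nb)
    X = np.column_stack([np.ones(m), x])

    # pass 1 unweighted, then the standard product-moment weights (all terms
    # on the invariant Z/sqrt(N) scale)
    c0 = np.linalg.lstsq(X, y, rcond=None)[0]
    int_a = max(h2a.intercept / h2a.mean_n, np.min(1.0 / na) * 1e-3)
    int_b = max(h2b.intercept / h2b.mean_n, np.min(1.0 / nb) * 1e-3)
    var_a = int_a + max(h2a.h2, 0.0) * x
    var_b = int_b + max(h2b.h2, 0.0) * x
    w = 1.0 / (var_a * var_b + (c0[1] * x + c0[0]) ** 2)
    ids = contiguous_blocks(m, n_blocks)
    coef, loo = _blocked_wls(X, y, w, ids, n_blocks)
    rho = float(coef[1])

    eps = 1e-12
    def ratio(r, ha, hb):
        if ha <= 0 or hb <= 0:
            return np.nan
        return r / np.sqrt(max(ha, eps) * max(hb, eps))

    rg = ratio(rho, h2a.h2, h2b.h2)
    loo_rg = np.array([
        ratio(loo[i, 1], h2a.loo_h2[i], h2b.loo_h2[i]) for i in range(n_blocks)
    ])
    if np.isfinite(rg) and np.all(np.isfinite(loo_rg)):
        se_rg = float(jackknife_se(loo_rg))
    else:
        rg, se_rg = np.nan, np.nan
    return RgResult(
        rho_g=rho, h2_a=h2a.h2, h2_b=h2b.h2, rg=float(rg), se_rg=se_rg,
        intercept_a=h2a.intercept, intercept_b=h2b.intercept,
        intercept_ab=float(coef[0]) * float(np.sqrt(na.mean() * nb.mean())),
        n_blocks=n_blocks, loo_rg=loo_rg, loo_rho=loo[:, 1],
    )


# ---------------------------------------------------------------------------
# covariance-aware meta-analysis


@dataclass
class MetaResult:
    estimate: float
    se: float
    z: float
    p_one_tailed: float
    condition_number: float
    regularized: bool


def meta_gls(estimates: np.ndarray, loo_matrix: np.ndarray | None = None,
             Sigma: np.ndarray | None = None, cond_max: float = 1e6,
             ridge_eps: float = 1e-3) -> MetaResult:
    """GLS pooling of per-trait estimates sharing jackknife blocks.

    The estimate covariance Sigma is built from the jackknife pseudovalues
    across traits (``loo_matrix`` of shape (n_traits, n_blocks)); a
    hand-supplied Sigma may be passed instead.  With diagonal Sigma the
    pooled estimate reduces exactly to the inverse-variance-weighted mean.
    Sigma is ridge-regularized by ridge_eps * trace/k when its condition
    number exceeds ``cond_max``.  The p-value is one-tailed in the observed
    direction of the pooled estimate.
    """
    r = np.asarray(estimates, float)
    k = r.size
    if Sigma is None:
        if loo_matrix is None:
            raise ValueError("provide either loo_matrix or Sigma")
        loo = np.asarray(loo_matrix, float)
        if loo.ndim != 2 or loo.shape[0] != k:
            raise ValueError("loo_matrix must be (n_traits, n_blocks)")
        B = loo.shape[1]
        pseudo = B * r[:, None] - (B - 1) * loo       # (k, B)
        dev = pseudo - pseudo.mean(axis=1, keepdims=True)
        Sigma = (dev @ dev.T) / (B * (B - 1))
    Sigma = np.asarray(Sigma, float)
    if Sigma.shape != (k, k):
        raise ValueError("Sigma must be k x k")

    cond = float(np.linalg.cond(Sigma))
    regularized = cond > cond_max
    if regularized:
        Sigma = Sigma + ridge_eps * np.trace(Sigma) / k * np.eye(k)
    ones = np.ones(k)
    Si = np.linalg.solve(Sigma, np.column_stack([r, ones]))
    pooled = float(ones @ Si[:, 0] / (ones @ Si[:, 1]))
    se = float((ones @ Si[:, 1]) ** -0.5)
    z = pooled / se
    return MetaResult(
        estimate=pooled, se=se, z=z,
        p_one_tailed=float(stats.norm.sf(abs(z))),
        condition_number=cond, regularized=regularized,
    )


# ---------------------------------------------------------------------------
# annotation partitioning


@dataclass
class PartitionResult:
    annotation: str
    proportion: float          # share of total signal in the annotation
    proportion_se: float
    enrichment: float          # share of signal / share of variants
    enrichment_se: float
    h2_total: float
    n_blocks: int


def partition_signal(sumstats: pd.DataFrame, ld: LDReference,
                     annotation: np.ndarray, name: str = "annotation",
                     n_blocks: int = 200) -> PartitionResult:
    """Two-category stratified fit: annotation vs complement LD scores.

    Per-variant effect variances sigma^2_c are the coefficients of the two
    stratified LD-score columns; category signal is sigma^2_c * M_c, the
    proportion is the annotation share, and enrichment divides that share
    by the annotation's share of variants.  Proportions over the
    2-partition sum to 1 by construction.
    """
    annotation = np.asarray(annotation, bool)
    m_a = int(annotation.sum())
    if m_a == 0 or m_a == ld.M:
        raise ValueError("annotation must be non-empty and not all variants")
    df = _align(sumstats, ld)
    m = len(df)
    l_a, l_c = ld.stratified_ld_scores(annotation)
    z = df["Z"].to_numpy(float)
    n = df["N"].to_numpy(float)
    y = z**2 / n
    X = np.column_stack([np.ones(m), l_a / ld.M, l_c / ld.M])
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("annotation LD scores are collinear with the complement; "
                         "the partition is unidentifiable for this annotation")
    coef0 = np.linalg.lstsq(X, y, rcond=None)[0]
    pred = np.maximum(X @ coef0, 1.0 / n)
    w = 1.0 / (2.0 * pred**2)
    ids = contiguous_blocks(m, n_blocks)
    coef, loo = _blocked_wls(X, y, w, ids, n_blocks)

    frac = m_a / ld.M
    def summarize(c):
        # coefficient on l_c/M is M * sigma^2_c; category signal is sigma^2_c * M_c
        h_a = c[1] * m_a / ld.M
        h_c = c[2] * (ld.M - m_a) / ld.M
        total = h_a + h_c
        prop = h_a / total if total != 0 else np.nan
        return prop, total
    prop, total = summarize(coef)
    loo_stats = np.array([summarize(loo[i]) for i in range(n_blocks)])
    prop_se = float(jackknife_se(loo_stats[:, 0]))
    return PartitionResult(
        annotation=name, proportion=float(prop), proportion_se=prop_se,
        enrichment=float(prop / frac), enrichment_se=float(prop_se / frac),
        h2_total=float(total), n_blocks=n_blocks,
    )
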