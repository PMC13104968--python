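"""Enumeration colocalization and single-causal fine-mapping at a locus.

Two aligned association tracks (here: selection statistics vs a GWAS or
QTL) are compared under the five classical hypotheses — no association
(H0), track-a only (H1), track-b only (H2), two distinct causal variants
(H3), one shared causal variant (H4) — by exact enumeration of Wakefield
approximate Bayes factors under a single-causal-variant model per track.
All sums run in log space; H3 enumerates the j != k pairs directly for
loci up to 1,000 variants.

Fine-mapping normalizes the per-variant ABFs into posterior inclusion
probabilities (PIPs) under a uniform causal prior, with 95% credible sets
taken as the minimal descending-PIP prefix.  The joint shared-variant
posterior multiplies the per-variant H4 posterior by PP_H4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_PRIOR_VARIANCE = 0.04      # prior variance of the standardized effect
DEFAULT_COLOC_THRESHOLD = 0.8      # PP_H4 at/above which a locus "colocalizes"
_PAIRWISE_LIMIT = 1000


def wakefield_abf(z: np.ndarray | float, n: np.ndarray | float,
                  w: float = DEFAULT_PRIOR_VARIANCE,
                  v: np.ndarray | float | None = None) -> np.ndarray | float:
    """Log approximate Bayes factor for association of a single variant.

    log ABF = 0.5*log(1 - r) + r*z^2/2 with shrinkage r = w/(v + w); the
    sampling variance of the standardized effect defaults to v = 1/n.
    """
    z = np.asarray(z, float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite Z-score")
    v = 1.0 / np.asarray(n, float) if v is None else np.asarray(v, float)
    if np.any(v <= 0) or w <= 0:
        raise ValueError("variances must be positive")
    r = w / (v + w)
    out = 0.5 * np.log1p(-r) + r * z**2 / 2.0
    return out if out.ndim else float(out)


@dataclass
class ColocResult:
    pp: np.ndarray                      # PP_H0..PP_H4, sums to 1
    log_bf: np.ndarray                  # log Bayes factors vs H0 (lbf[0] = 0)
    h4_posterior: np.ndarray            # per-variant shared-causal posterior | H4
    priors: tuple[float, float, float]  # (p1, p2, p12)
    labf_a: np.ndarray = field(repr=False, default=None)
    labf_b: np.ndarray = field(repr=False, default=None)
    pos: np.ndarray = field(repr=False, default=None)

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])


def _log_h3(la: np.ndarray, lb: np.ndarray) -> float:
    """log sum over j != k of ABF_a,j * ABF_b,k."""
    m = la.size
    if m <= _PAIRWISE_LIMIT:
        pair = la[:, None] + lb[None, :]
        np.fill_diagonal(pair, -np.inf)
        return float(logsumexp(pair))
    # large loci: log(S_a*S_b - sum_j ab_j), guarded against cancellation
    tot = logsumexp(la) + logsumexp(lb)
    diag = logsumexp(la + lb)
    diff = 1.0 - np.exp(diag - tot)
    if diff <= 0:
        return -np.inf
    return float(tot + np.log(diff))


def coloc_abf(z_a: np.ndarray, z_b: np.ndarray, n_a: np.ndarray | float,
              n_b: np.ndarray | float, pos: np.ndarray | None = None,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              w_a: float = DEFAULT_PRIOR_VARIANCE,
              w_b: float = DEFAULT_PRIOR_VARIANCE) -> ColocResult:
    """Posterior probabilities of the five sharing hypotheses at a locus."""
    z_a, z_b = np.asarray(z_a, float), np.asarray(z_b, float)
    if z_a.shape != z_b.shape or z_a.ndim != 1:
        raise ValueError("tracks must be aligned 1-D vectors")
    if z_a.size < 2:
        raise ValueError("a locus needs at least 2 variants")
    la = np.broadcast_to(wakefield_abf(z_a, n_a, w_a), z_a.shape)
    lb = np.broadcast_to(wakefield_abf(z_b, n_b, w_b), z_b.shape)

    lsum_a, lsum_b = logsumexp(la), logsumexp(lb)
    lsum_ab = logsumexp(la + lb)
    lbf = np.array([
        0.0,
        np.log(p1) + lsum_a,
        np.log(p2) + lsum_b,
        np.log(p1) + np.log(p2) + _log_h3(la, lb),
        np.log(p12) + lsum_ab,
    ])
    pp = np.exp(lbf - logsumexp(lbf))
    pp /= pp.sum()
    h4_post = np.exp(la + lb - lsum_ab)
    h4_post /= h4_post.sum()
    return ColocResult(
        pp=pp, log_bf=lbf, h4_posterior=h4_post, priors=(p1, p2, p12),
        labf_a=np.array(la), labf_b=np.array(lb),
        pos=None if pos is None else np.asarray(pos),
    )


@dataclass
class FineMapResult:
    pip: np.ndarray
    credible_set: np.ndarray      # boolean membership of the 95% set
    credible_set_size: int


def finemap_single(z: np.ndarray, n: np.ndarray | float,
                   pos: np.ndarray | None = None,
                   w: float = DEFAULT_PRIOR_VARIANCE,
                   coverage: float = 0.95) -> FineMapResult:
    """Single-causal-variant PIPs and the minimal credible set.

    PIP_j = ABF_j / sum_k ABF_k under a uniform causal prior.  The credible
    set is the shortest prefix of variants in descending-PIP order whose
    cumulative probability reaches ``coverage``; PIP ties break by
    ascending genomic position.
    """
    z = np.asarray(z, float)
    if z.size < 2:
        raise ValueError("a locus needs at least 2 variants")
    labf = np.broadcast_to(wakefield_abf(z, n, w), z.shape)
    pip = np.exp(labf - logsumexp(labf))
    pip = pip / pip.sum()
    if pos is None:
        pos = np.arange(z.size)
    order = np.lexsort((np.asarray(pos), -pip))
    cum = np.cumsum(pip[order])
    size = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    cs = np.zeros(z.size, bool)
    cs[order[:size]] = True
    return FineMapResult(pip=pip, credible_set=cs, credible_set_size=size)


@dataclass
class JointPip:
    pip_s: np.ndarray       # causal for selection (track a)
    pip_g: np.ndarray       # causal for the GWAS/QTL (track b)
    pip_sg: np.ndarray      # shared causal: H4 posterior x PP_H4


def joint_pip(coloc: ColocResult) -> JointPip:
    """Per-variant posteriors for each track and for the shared variant."""
    pip_s = np.exp(coloc.labf_a - logsumexp(coloc.labf_a))
    pip_g = np.exp(coloc.labf_b - logsumexp(coloc.labf_b))
    return JointPip(
        pip_s=pip_s / pip_s.sum(),
        pip_g=pip_g / pip_g.sum(),
        pip_sg=coloc.h4_posterior * coloc.pp_h4,
    )


def define_loci(sumstats: pd.DataFrame, z_threshold: float = 4.0,
                window_kb: float = 250.0, merge_kb: float = 250.0) -> pd.DataFrame:
    """Seed-and-merge locus intervals around strong associations.

    Seeds are variants with |Z| >= ``z_threshold``; each contributes a
    +-``window_kb`` interval; intervals on the same chromosome closer than
    ``merge_kb`` are merged.  Output intervals are 1-based inclusive.
    """
    if not sumstats["POS"].is_monotonic_increasing:
        sumstats = sumstats.sort_values(["CHR", "POS"])
    out = []
    w = int(window_kb * 1000)
    gap = int(merge_kb * 1000)
    for chrom, grp in sumstats.groupby("CHR", sort=True):
        seeds = grp.loc[grp["Z"].abs() >= z_threshold, "POS"].to_numpy()
        if seeds.size == 0:
            continue
        start, end = None, None
        for pos in seeds:
            lo, hi = max(1, pos - w), pos + w
            if start is None:
                start, end = lo, hi
            elif lo - end < gap:
                end = max(end, hi)
            else:
                out.append((chrom, start, end))
                start, end = lo, hi
        out.append((chrom, start, end))
    return pd.DataFrame(out, columns=["CHR", "START", "END"])


def extract_locus(sumstats: pd.DataFrame, chrom, start: int, end: int) -> pd.DataFrame:
    sel = (sumstats["CHR"] == chrom) & sumstats["POS"].between(start, end)
    return sumstats.loc[sel].reset_index(drop=True)
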