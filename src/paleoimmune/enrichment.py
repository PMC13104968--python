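"""Hypergeometric pathway enrichment and the immune-label excess test.

Enrichment of a prioritized gene set against each pathway uses the
upper-tail hypergeometric test on the 2x2 membership table, inside a
caller-supplied gene universe (the genes that *could* have been
prioritized — never the whole genome).  Benjamini-Hochberg q-values are
computed across all tested pathways.

Whether *immune-labelled* pathways are over-represented among the enriched
ones is assessed by a logistic regression of the enriched indicator
(q < 0.10) on the immune flag adjusted for log pathway size, calibrated by
permutation: the prioritized set is redrawn uniformly from the universe,
which preserves the redundancy/overlap structure of the pathway collection
under the null (label shuffling would not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .genesets import GeneSetCollection


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_odds_ratio(table: tuple[int, int, int, int] | np.ndarray) -> float:
    """Odds ratio (a/b)/(c/d) of a 2x2 count table (a, b, c, d).

    Exact rational arithmetic when all cells are positive; Haldane's 0.5
    continuity correction when any single cell is zero.  Two zero cells in
    one margin leave the ratio undefined.
    """
    a, b, c, d = (int(x) for x in np.ravel(table))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a == 0 and b == 0) or (c == 0 and d == 0) or \
       (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("odds ratio undefined: a zero margin in the 2x2 table")
    if min(a, b, c, d) == 0:
        return float((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
    return float(Fraction(a * d, b * c))


@dataclass
class EnrichmentResult:
    pathway: str
    k: int              # overlap of pathway with the prioritized set
    pathway_size: int   # |P ∩ U|
    universe_size: int
    prioritized_size: int
    odds_ratio: float
    p: float
    q: float = np.nan
    immune: bool = False


def hypergeom_enrich(prioritized: set[str], collection: GeneSetCollection,
                     universe: set[str]) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of every pathway, with BH q.

    Pathways are intersected with the universe before testing; the
    prioritized set must be a subset of the universe.
    """
    prioritized = set(prioritized)
    universe = set(universe)
    if not universe or not prioritized:
        raise ValueError("universe and prioritized set must be non-empty")
    if not prioritized <= universe:
        raise ValueError("prioritized genes must be a subset of the universe")
    N, n = len(universe), len(prioritized)
    sizes, ks = [], []
    for pw in collection:
        inter = set(pw.genes) & universe
        sizes.append(len(inter))
        ks.append(len(inter & prioritized))
    sizes_a, ks_a = np.array(sizes), np.array(ks)
    p = stats.hypergeom.sf(ks_a - 1, N, sizes_a, n)
    q = bh_fdr(np.clip(p, 0.0, 1.0))
    out = []
    for pw, K, k, pi, qi in zip(collection, sizes_a, ks_a, p, q):
        # 2x2 membership table: pathway x prioritized
        a, b_, c, d = k, K - k, n - k, (N - K) - (n - k)
        try:
            orr = overlap_odds_ratio((a, b_, c, d))
        except ValueError:
            orr = np.nan
        out.append(EnrichmentResult(
            pathway=pw.id, k=int(k), pathway_size=int(K), universe_size=N,
            prioritized_size=n, odds_ratio=orr, p=float(min(pi, 1.0)),
            q=float(qi), immune=pw.immune,
        ))
    return out


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class LabelAssocResult:
    odds_ratio: float       # immune-flag OR from the size-adjusted logit
    log_or: float
    p_permutation: float
    n_permutations: int
    n_enriched: int
    flagged: bool           # separation/degeneracy fallback was used


def _size_adjusted_log_or(enriched: np.ndarray, immune: np.ndarray,
                          sizes: np.ndarray) -> tuple[float, bool]:
    """Log-OR of the immune flag from logit(enriched ~ immune + log size)."""
    X = sm.add_constant(np.column_stack([immune.astype(float), np.log(sizes)]))
    if enriched.all() or not enriched.any() or immune.all() or not immune.any():
        return 0.0, True   # degenerate: no information about the flag
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(enriched.astype(float), X).fit(disp=0, maxiter=100)
        if np.abs(fit.params[1]) < 20 and fit.mle_retvals.get("converged", True):
            return float(fit.params[1]), False
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        pass
    # ridge-penalized IRLS fallback for separated fits
    beta = np.zeros(X.shape[1])
    lam = 0.5
    y = enriched.astype(float)
    for _ in range(50):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wts = np.maximum(mu * (1 - mu), 1e-8)
        H = X.T @ (X * wts[:, None]) + lam * np.eye(X.shape[1])
        g = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return float(beta[1]), True


def immune_label_test(results: list[EnrichmentResult],
                      collection: GeneSetCollection, universe: set[str],
                      B: int = 199, seed: int = 0,
                      q_threshold: float = 0.10) -> LabelAssocResult:
    """Permutation test of immune-label excess among enriched pathways.

    The observed statistic is the immune-flag odds ratio from a logistic
    regression of 1[q < 0.10] on the flag plus log pathway size.  The null
    redraws the prioritized gene set (same size, uniform from the
    universe) B times and re-runs enrichment + regression;
    p = (1 + #{OR_null >= OR_obs}) / (1 + B).
    """
    immune = np.array([r.immune for r in results])
    if immune.sum() < 2 or (~immune).sum() < 2:
        raise ValueError("need at least 2 pathways per label")
    enriched = np.array([r.q < q_threshold for r in results])
    sizes = np.array([max(r.pathway_size, 1) for r in results])
    obs, flagged = _size_adjusted_log_or(enriched, immune, sizes)

    rng = np.random.default_rng(seed)
    universe_list = sorted(universe)
    n_prior = results[0].prioritized_size
    null = np.empty(B)
    for b in range(B):
        fake = set(rng.choice(universe_list, size=n_prior, replace=False))
        res_b = hypergeom_enrich(fake, collection, universe)
        enr_b = np.array([r.q < q_threshold for r in res_b])
        null[b], _ = _size_adjusted_log_or(enr_b, immune, sizes)
    p = (1.0 + np.sum(null >= obs)) / (1.0 + B)
    return LabelAssocResult(
        odds_ratio=float(np.exp(obs)), log_or=obs, p_permutation=float(p),
        n_permutations=B, n_enriched=int(enriched.sum()), flagged=flagged,
    )
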