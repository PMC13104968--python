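"""Direction-of-activity inference for signed pathways from pQTL coupling.

For each regulator gene, the selection-pQTL genetic covariance is the mean
of (Z_sel/sqrt(N_sel)) * (Z_pqtl/sqrt(N_pqtl)) over *qualifying* variants
— those with |Z| > 3 for both selection and the protein's plasma level.
The pathway statistic averages sign_g * covariance_g over regulator genes
(sign +1 for positive regulators, -1 for negative), so a positive
statistic always reads "selection increased the pathway's activity".

Uncertainty comes from a delete-one jackknife over 200 approximately
equally sized blocks of adjacent variants, cut on the genome-ordered union
of qualifying variants across the pathway's genes (shared blocks absorb
co-regulation and correlated estimation error across genes).  A gene whose
qualifying variants would be emptied by deleting a single block is dropped
before the jackknife; the drop rule is iterated to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr, overlap_odds_ratio
from .genesets import GeneSetCollection, Pathway
from .ldsc import contiguous_blocks, jackknife_se

DEFAULT_Z_MIN = 3.0


@dataclass
class GeneCovariance:
    gene: str
    covariance: float
    n_qualifying: int
    positions: np.ndarray = field(repr=False)
    products: np.ndarray = field(repr=False)


def gene_covariance(selection: pd.DataFrame, pqtl: pd.DataFrame,
                    z_min: float = DEFAULT_Z_MIN,
                    gene: str = "") -> GeneCovariance | None:
    """Mean standardized-effect product over jointly significant variants.

    Tracks must already be harmonized to the same variant order.  Returns
    None when no variant passes the joint |Z| > z_min filter (the caller
    records the gene as dropped).
    """
    if len(selection) != len(pqtl):
        raise ValueError("tracks must be harmonized to the same variant set")
    zs = selection["Z"].to_numpy(float)
    zp = pqtl["Z"].to_numpy(float)
    ok = (np.abs(zs) > z_min) & (np.abs(zp) > z_min)
    if not ok.any():
        return None
    prod = (zs[ok] / np.sqrt(selection["N"].to_numpy(float)[ok])) * \
           (zp[ok] / np.sqrt(pqtl["N"].to_numpy(float)[ok]))
    pos = selection["POS"].to_numpy()[ok]
    order = np.argsort(pos, kind="stable")
    return GeneCovariance(
        gene=gene, covariance=float(prod.mean()), n_qualifying=int(ok.sum()),
        positions=pos[order], products=prod[order],
    )


@dataclass
class ActivityResult:
    pathway: str
    statistic: float            # mean over genes of sign_g * covariance_g
    se: float
    z: float
    p: float
    q: float
    direction: str              # "increased" | "decreased"
    n_genes: int
    n_blocks: int
    genes_dropped: dict[str, str]
    immune: bool = False
    gene_covariances: dict[str, float] = field(default_factory=dict)


def pathway_activity(selection: pd.DataFrame, pqtl_tables: dict[str, pd.DataFrame],
                     pathway: Pathway, n_blocks: int = 200,
                     z_min: float = DEFAULT_Z_MIN,
                     coloc_gate: dict[str, float] | None = None,
                     coloc_threshold: float = 0.8) -> ActivityResult:
    """Signed average selection-pQTL covariance with a block jackknife.

    ``coloc_gate`` optionally maps gene -> selection-pQTL PP_H4; genes
    below ``coloc_threshold`` are excluded before averaging (the gate the
    real analysis applies; synthetic tests may bypass it by passing None).
    """
    signs = pathway.regulator_signs()
    if not signs:
        raise ValueError(f"pathway {pathway.id} carries no signed regulators")
    dropped: dict[str, str] = {}
    covs: dict[str, GeneCovariance] = {}
    for gene, sign in signs.items():
        if gene not in pqtl_tables:
            dropped[gene] = "no pQTL track"
            continue
        if coloc_gate is not None and coloc_gate.get(gene, 0.0) < coloc_threshold:
            dropped[gene] = "below colocalization threshold"
            continue
        gc = gene_covariance(selection, pqtl_tables[gene], z_min=z_min, gene=gene)
        if gc is None:
            dropped[gene] = "no qualifying variants"
        else:
            covs[gene] = gc

    # iterate the single-block-emptying drop rule to a fixed point
    while True:
        if not covs:
            raise ValueError(
                f"all genes of pathway {pathway.id} were dropped: {dropped}")
        union = np.unique(np.concatenate([g.positions for g in covs.values()]))
        nb = min(n_blocks, union.size)
        if nb < 2:
            raise ValueError(
                f"pathway {pathway.id} has too few qualifying variants to jackknife")
        block_of = dict(zip(union, contiguous_blocks(union.size, nb)))
        removed = False
        for gene, gc in list(covs.items()):
            gene_blocks = {block_of[p] for p in gc.positions}
            if len(gene_blocks) < 2:
                dropped[gene] = "qualifying set emptied by a jackknife block"
                del covs[gene]
                removed = True
        if not removed:
            break

    genes = sorted(covs)
    sign_arr = np.array([signs[g] for g in genes], float)
    # per-gene per-block sums and counts of the products
    sums = np.zeros((len(genes), nb))
    counts = np.zeros((len(genes), nb))
    for i, g in enumerate(genes):
        gc = covs[g]
        b = np.array([block_of[p] for p in gc.positions])
        np.add.at(sums[i], b, gc.products)
        np.add.at(counts[i], b, 1.0)
    tot_sum = sums.sum(axis=1)
    tot_cnt = counts.sum(axis=1)
    stat = float(np.mean(sign_arr * tot_sum / tot_cnt))
    loo_cov = (tot_sum[:, None] - sums) / (tot_cnt[:, None] - counts)
    loo_stat = (sign_arr[:, None] * loo_cov).mean(axis=0)
    se = float(jackknife_se(loo_stat))
    z = stat / se if se > 0 else np.inf * np.sign(stat)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ActivityResult(
        pathway=pathway.id, statistic=stat, se=se, z=float(z), p=p, q=np.nan,
        direction="increased" if stat > 0 else "decreased",
        n_genes=len(genes), n_blocks=nb, genes_dropped=dropped,
        immune=pathway.immune,
        gene_covariances={g: covs[g].covariance for g in genes},
    )


def analyze_pathways(selection: pd.DataFrame, pqtl_tables: dict[str, pd.DataFrame],
                     collection: GeneSetCollection, n_blocks: int = 200,
                     z_min: float = DEFAULT_Z_MIN,
                     coloc_gate: dict[str, float] | None = None) -> pd.DataFrame:
    """Run pathway_activity across all signed pathways; BH-adjust p-values."""
    results = []
    for pw in collection:
        if not pw.signed:
            continue
        try:
            results.append(pathway_activity(
                selection, pqtl_tables, pw, n_blocks=n_blocks, z_min=z_min,
                coloc_gate=coloc_gate))
        except ValueError:
            continue
    if not results:
        return pd.DataFrame(columns=[
            "pathway", "statistic", "se", "z", "p", "q", "direction",
            "n_genes", "n_blocks", "immune"])
    df = pd.DataFrame([{
        "pathway": r.pathway, "statistic": r.statistic, "se": r.se,
        "z": r.z, "p": r.p, "direction": r.direction,
        "n_genes": r.n_genes, "n_blocks": r.n_blocks, "immune": r.immune,
    } for r in results])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


@dataclass
class ActivationSummary:
    table: pd.DataFrame         # increased/decreased x immune/non-immune counts
    odds_ratio: float           # NaN when a margin is zero
    p_permutation: float
    n_significant: int


def activation_summary(results: pd.DataFrame, q_threshold: float = 0.10,
                       B: int = 9999, seed: int = 0) -> ActivationSummary:
    """Immune-vs-direction contingency among significant pathways.

    Counts significant (q < threshold) pathways by inferred direction and
    immune label, forms the increased-activation odds ratio for immune vs
    non-immune pathways, and attaches a one-tailed permutation p-value
    obtained by shuffling the immune flags.
    """
    sig = results.loc[results["q"] < q_threshold]
    if sig.empty:
        return ActivationSummary(
            table=pd.DataFrame(), odds_ratio=np.nan, p_permutation=np.nan,
            n_significant=0)
    imm = sig["immune"].to_numpy(bool)
    inc = (sig["direction"] == "increased").to_numpy()
    counts = pd.DataFrame(
        {"increased": [int((imm & inc).sum()), int((~imm & inc).sum())],
         "decreased": [int((imm & ~inc).sum()), int((~imm & ~inc).sum())]},
        index=["immune", "non_immune"],
    )
    a, b = counts.loc["immune", "increased"], counts.loc["immune", "decreased"]
    c, d = counts.loc["non_immune", "increased"], counts.loc["non_immune", "decreased"]
    try:
        orr = overlap_odds_ratio((a, b, c, d))
    except ValueError:
        return ActivationSummary(table=counts, odds_ratio=np.nan,
                                 p_permutation=np.nan, n_significant=len(sig))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        perm = rng.permutation(imm)
        pa, pb = int((perm & inc).sum()), int((perm & ~inc).sum())
        pc, pd_ = int((~perm & inc).sum()), int((~perm & ~inc).sum())
        try:
            if overlap_odds_ratio((pa, pb, pc, pd_)) >= orr:
                hits += 1
        except ValueError:
            hits += 1   # degenerate permutations count as extreme (conservative)
    p = (1.0 + hits) / (1.0 + B)
    return ActivationSummary(table=counts, odds_ratio=float(orr),
                             p_permutation=float(p), n_significant=len(sig))
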