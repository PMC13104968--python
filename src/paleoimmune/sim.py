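"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator produces, end to end:

* per-variant allele-frequency trajectories under Wright-Fisher drift plus
  additive selection, separately within each ancestral component;
* a dated ancient cohort sampled from those trajectories, with a time-varying
  mixture of ancestral components (structure confounding), missingness and
  pseudo-haploid calls;
* block-diagonal LD references with exchangeable within-block correlation,
  for which LD scores are available in closed form;
* GWAS / pQTL summary-statistic tables whose genetic coupling to the
  selection track is controlled exactly (a target genetic correlation for
  GWAS; a per-gene signed coupling for pQTLs);
* gene maps and pathway collections with immune labels and signed
  positive/negative regulator subsets.

Everything is driven by ``numpy.random.default_rng`` and bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .genesets import GeneSetCollection, Pathway

MISSING = np.nan


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrajectorySet:
    """Allele-frequency paths: ``freq[variant, ancestry, generation]``."""

    freq: np.ndarray          # (V, K, G+1), generation 0 = oldest
    s: np.ndarray             # (V,) per-generation additive coefficient on alt
    p0: np.ndarray            # (V, K) initial frequencies per component

    @property
    def n_variants(self) -> int:
        return self.freq.shape[0]

    @property
    def generations(self) -> int:
        return self.freq.shape[2] - 1


@dataclass
class AncientCohort:
    """Dated individuals with ancestry covariates and dosage genotypes.

    ``dosage`` holds alt-allele counts in {0, 1, 2} (diploid) or {0, 2}
    (pseudo-haploid), with NaN for missing calls.
    """

    individual_id: list[str]
    date_bp: np.ndarray                 # years before present, positive = older
    ancestry: np.ndarray                # (n, K), rows on the simplex
    dosage: np.ndarray                  # (n, V) float with NaN = missing
    pseudohaploid: np.ndarray           # (n,) bool
    variants: pd.DataFrame              # CHR, POS, A1 (alt, counted), A2 (ref)

    def __post_init__(self) -> None:
        if np.any(self.date_bp < 0):
            raise ValueError("date_bp must be non-negative")
        if not np.allclose(self.ancestry.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ancestry rows must sum to 1")
        ph = self.dosage[self.pseudohaploid]
        if ph.size and not np.all(np.isnan(ph) | (ph == 0) | (ph == 2)):
            raise ValueError("pseudo-haploid rows must contain only {0, 2, missing}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def time_kyr(self) -> np.ndarray:
        """Analysis time: -date_bp in units of 1,000 years (0 = present)."""
        return -self.date_bp / 1000.0


@dataclass
class LDReference:
    """Block-diagonal LD, exchangeable within each block at correlation r_b.

    The LD score of variant j is l_j = sum_k r_jk^2 over its block
    (including itself), i.e. 1 + (m - 1) r_b^2 for a block of size m; per-
    block correlations differ, which is what gives the LD scores spread.
    """

    table: pd.DataFrame       # CHR, POS, BLOCK, L2, R (block correlation)
    M: int

    def __post_init__(self) -> None:
        if np.any(self.table["L2"].to_numpy() < 1.0 - 1e-12):
            raise ValueError("LD scores must be >= 1")

    @property
    def ld_scores(self) -> np.ndarray:
        return self.table["L2"].to_numpy(float)

    @property
    def blocks(self) -> np.ndarray:
        return self.table["BLOCK"].to_numpy(int)

    @property
    def block_r(self) -> np.ndarray:
        """Within-block correlation, one value per block."""
        return self.table.groupby("BLOCK")["R"].first().to_numpy(float)

    def stratified_ld_scores(self, annotation: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant LD scores restricted to an annotation and its complement.

        ``annotation`` is a boolean mask over the M variants.  For the
        exchangeable-block model the stratified scores have the closed form
        l_{A,j} = r_b^2 * (|A ∩ block(j)| - 1[j in A]) + 1[j in A].
        """
        annotation = np.asarray(annotation, bool)
        if annotation.shape != (self.M,):
            raise ValueError("annotation mask must have one entry per variant")
        blocks = self.blocks
        r2 = self.table["R"].to_numpy(float) ** 2
        n_in_block = np.bincount(blocks, weights=annotation.astype(float))
        block_sizes = np.bincount(blocks)
        in_a = annotation.astype(float)
        l_annot = r2 * (n_in_block[blocks] - in_a) + in_a
        n_out = block_sizes[blocks] - n_in_block[blocks]
        l_comp = r2 * (n_out - (1.0 - in_a)) + (1.0 - in_a)
        return l_annot, l_comp


# ---------------------------------------------------------------------------
# variant maps


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("C", "T"), ("G", "T"),
                 ("A", "T"), ("C", "G")]  # last two strand-ambiguous


def make_variant_table(n_variants: int, rng: np.random.Generator,
                       chrom: int = 1, spacing: int = 1000) -> pd.DataFrame:
    pick = rng.integers(0, len(_ALLELE_PAIRS), size=n_variants)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pick])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pick])
    return pd.DataFrame({
        "CHR": chrom,
        "POS": spacing * (np.arange(n_variants) + 1),
        "A1": a1,   # alt, the counted/effect allele
        "A2": a2,
    })


def make_ld_reference(config: SimConfig, variants: pd.DataFrame | None = None) -> LDReference:
    rng = np.random.default_rng(config.seed)
    if variants is None:
        variants = make_variant_table(config.n_variants, rng)
    m = config.variants_per_block
    blocks = np.repeat(np.arange(config.n_blocks), m)
    block_r = rng.uniform(*config.ld_r_range, size=config.n_blocks)
    r = block_r[blocks]
    table = variants.copy()
    table["BLOCK"] = blocks
    table["L2"] = 1.0 + (m - 1) * r**2
    table["R"] = r
    return LDReference(table=table, M=config.n_variants)


# ---------------------------------------------------------------------------
# trajectories and cohorts


def simulate_trajectories(config: SimConfig, deterministic: bool = False,
                          rng: np.random.Generator | None = None,
                          p0: np.ndarray | None = None,
                          s: np.ndarray | None = None) -> TrajectorySet:
    """Forward Wright-Fisher paths with additive selection.

    The expected next-generation frequency is p' = p + s*p*(1-p) (first-order
    additive selection on the alt allele), followed by binomial sampling of
    2N gametes; ``deterministic=True`` skips the sampling (infinite-N limit).
    Frequencies absorb at 0 and 1.
    """
    if config.pop_size < 10:
        raise ValueError("pop_size must be >= 10")
    if config.generations < 2:
        raise ValueError("generations must be >= 2")
    rng = rng or np.random.default_rng(config.seed)
    V, K, G = config.n_variants, config.n_ancestries, config.generations

    if p0 is None:
        base = rng.uniform(0.05, 0.95, size=V)
        if K > 1 and config.fst > 0:
            f = config.fst
            a = base * (1 - f) / f
            b = (1 - base) * (1 - f) / f
            p0 = rng.beta(a[:, None], b[:, None], size=(V, K))
        else:
            p0 = np.repeat(base[:, None], K, axis=1)
    p0 = np.asarray(p0, float)

    if s is None:
        s = np.zeros(V)
        n_sel = int(round(config.frac_selected * V))
        if n_sel:
            idx = rng.choice(V, size=n_sel, replace=False)
            s[idx] = rng.uniform(*config.s_range, size=n_sel)
    s = np.asarray(s, float)

    freq = np.empty((V, K, G + 1))
    freq[:, :, 0] = p0
    p = p0.copy()
    two_n = 2 * config.pop_size
    sv = s[:, None]
    for g in range(1, G + 1):
        p = np.clip(p + sv * p * (1.0 - p), 0.0, 1.0)
        if not deterministic:
            p = rng.binomial(two_n, p) / two_n
        freq[:, :, g] = p
    return TrajectorySet(freq=freq, s=s, p0=p0)


def _schedule_proportions(config: SimConfig, date_bp: np.ndarray) -> np.ndarray:
    props = np.zeros((date_bp.size, config.n_ancestries))
    assigned = np.zeros(date_bp.size, bool)
    oldest = max(start for start, _, _ in config.admixture_schedule)
    for start, end, p in config.admixture_schedule:
        inside = (~assigned) & (date_bp <= start) & (date_bp > end)
        if start == oldest:
            inside |= (~assigned) & (date_bp >= start)
        props[inside] = p
        assigned |= inside
    props[~assigned] = config.admixture_schedule[-1][2]
    return props


def sample_cohort(trajectories: TrajectorySet, config: SimConfig,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[AncientCohort, pd.DataFrame]:
    """Draw a dated cohort and record the simulation truth per variant.

    Dates are uniform over the simulated time depth; each individual's
    ancestry is a Dirichlet draw around the schedule proportions at their
    date; genotypes are binomial in the ancestry-mixed frequency at their
    date, then thinned by missingness and pseudo-haploid masking.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n, V, K, G = (config.n_individuals, trajectories.n_variants,
                  config.n_ancestries, trajectories.generations)
    span = G * config.years_per_generation

    date_bp = rng.uniform(0.0, span, size=n)
    gen_idx = np.clip(np.round((span - date_bp) / config.years_per_generation), 0, G).astype(int)

    base = _schedule_proportions(config, date_bp)
    if K > 1:
        alpha = config.ancestry_concentration * base + 1e-3
        gammas = rng.standard_gamma(alpha)
        ancestry = gammas / gammas.sum(axis=1, keepdims=True)
    else:
        ancestry = np.ones((n, 1))

    # ancestry-mixed alt-allele frequency per individual x variant
    f = np.einsum("vkn,nk->nv", trajectories.freq[:, :, gen_idx], ancestry)
    f = np.clip(f, 0.0, 1.0)

    pseudo = rng.random(n) < config.pseudohaploid_rate
    dosage = rng.binomial(2, f).astype(float)
    if pseudo.any():
        dosage[pseudo] = 2.0 * rng.binomial(1, f[pseudo])
    if config.missing_rate > 0:
        dosage[rng.random((n, V)) < config.missing_rate] = MISSING
    if np.any(np.all(np.isnan(dosage), axis=0)):
        raise ValueError("a variant has no non-missing genotypes; "
                         "lower missing_rate or raise n_individuals")

    variants = make_variant_table(V, np.random.default_rng(config.seed))
    cohort = AncientCohort(
        individual_id=[f"ind{i:05d}" for i in range(n)],
        date_bp=date_bp,
        ancestry=ancestry,
        dosage=dosage,
        pseudohaploid=pseudo,
        variants=variants,
    )
    truth = variants.copy()
    truth["BLOCK"] = np.repeat(np.arange(config.n_blocks), config.variants_per_block)[:V]
    truth["true_s"] = trajectories.s
    for k in range(K):
        truth[f"freq_anc{k}"] = trajectories.p0[:, k]
    return cohort, truth


def simulate_cohort(config: SimConfig, deterministic: bool = False,
                    ) -> tuple[AncientCohort, pd.DataFrame]:
    """Convenience wrapper: trajectories then cohort, from one seed."""
    traj = simulate_trajectories(config, deterministic=deterministic)
    return sample_cohort(traj, config)


# ---------------------------------------------------------------------------
# summary statistics


def _propagate_block(values: np.ndarray, block_r: np.ndarray, block_size: int) -> np.ndarray:
    """Multiply a stacked per-variant vector by the block LD matrices R_b."""
    v = values.reshape(-1, block_size)
    r = block_r[:, None]
    return ((1.0 - r) * v + r * v.sum(axis=1, keepdims=True)).ravel()


def _correlated_noise(rng: np.random.Generator, block_r: np.ndarray,
                      block_size: int) -> np.ndarray:
    """Per-block exchangeable MVN(0, R_b) noise."""
    n_blocks = block_r.size
    eye = np.eye(block_size)
    corr = (block_r[:, None, None] * (1.0 - eye)[None]) + eye[None]
    chol = np.linalg.cholesky(corr)
    eta = rng.standard_normal((n_blocks, block_size, 1))
    return (chol @ eta)[..., 0].ravel()


def simulate_sumstats_pair(ld: LDReference, n_a: int, n_b: int, rg_target: float,
                           h2_a: float = 0.2, h2_b: float = 0.2,
                           seed: int = 0, effect_mask: np.ndarray | None = None,
                           su: np.ndarray | None = None, noise: bool = True,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two coupled Z-score tracks obeying the LD-score relationship.

    Standardized per-variant effects are drawn jointly at correlation
    ``rg_target``; marginal Z-scores are the LD-propagated effects scaled by
    sqrt(N) plus block-correlated noise, so that
    E[Z_a,j * Z_b,j] = sqrt(N_a N_b) * rho_g * l_j / M (+0 intercept).
    ``effect_mask`` restricts causal variants to a subset (used by the
    signal-partitioning round trips).  ``su`` supplies the standardized
    track-a effect directions (e.g. a selection truth table).
    """
    if not -1.0 <= rg_target <= 1.0:
        raise ValueError("rg_target must be in [-1, 1]")
    if n_a <= 1 or n_b <= 1:
        raise ValueError("sample sizes must exceed 1")
    rng = np.random.default_rng(seed)
    M = ld.M
    block_size = int(np.bincount(ld.blocks).max())
    if not np.all(np.bincount(ld.blocks) == block_size):
        raise ValueError("pair simulation requires equally sized LD blocks")
    n_blocks = M // block_size

    if effect_mask is None:
        effect_mask = np.ones(M, bool)
    m_eff = int(effect_mask.sum())
    if su is None:
        su = rng.standard_normal(M)
    su = np.where(effect_mask, su, 0.0)
    sd = su[effect_mask].std()
    if sd > 0:
        su = su / sd
    g = np.where(effect_mask, rng.standard_normal(M), 0.0)
    beta_a = np.sqrt(h2_a / m_eff) * su
    beta_b = np.sqrt(h2_b / m_eff) * (rg_target * su + np.sqrt(1 - rg_target**2) * g)

    block_r = ld.block_r
    tables = []
    for n_s, beta in [(n_a, beta_a), (n_b, beta_b)]:
        z = np.sqrt(n_s) * _propagate_block(beta, block_r, block_size)
        if noise:
            z = z + _correlated_noise(rng, block_r, block_size)
        df = ld.table[["CHR", "POS", "A1", "A2"]].copy()
        df["Z"] = z
        df["N"] = n_s
        tables.append(df)
    return tables[0], tables[1]


def simulate_gwas_sumstats(truth: pd.DataFrame, ld: LDReference, n_gwas: int,
                           rg_target: float, seed: int = 0, h2: float = 0.2,
                           h2_sel: float = 0.2, n_sel: int = 1000,
                           noise: bool = True) -> pd.DataFrame:
    """GWAS Z-scores with a target genetic correlation to the selection track.

    The selection effect directions are the truth table's ``true_s`` column
    (standardized); the GWAS causal effects are drawn at correlation
    ``rg_target`` with them and propagated through block LD.
    """
    su = truth["true_s"].to_numpy(float)
    if su.std() > 0:
        su = (su - su.mean()) / su.std()
    _, gwas = simulate_sumstats_pair(
        ld, n_a=n_sel, n_b=n_gwas, rg_target=rg_target, h2_a=h2_sel, h2_b=h2,
        seed=seed, su=su, noise=noise,
    )
    return gwas


# ---------------------------------------------------------------------------
# genes, pQTLs, pathways


def simulate_genes(variants: pd.DataFrame, n_genes: int,
                   cis_flank: int = 2000) -> pd.DataFrame:
    """Tile genes along the simulated chromosome; 1-based inclusive windows."""
    pos = variants["POS"].to_numpy()
    centers = np.linspace(pos.min(), pos.max(), n_genes).astype(int)
    return pd.DataFrame({
        "gene": [f"G{i:04d}" for i in range(n_genes)],
        "chrom": variants["CHR"].iloc[0],
        "start": np.maximum(1, centers - cis_flank),
        "end": centers + cis_flank,
    })


def simulate_pqtl_tables(truth: pd.DataFrame, genes: pd.DataFrame,
                         selection: pd.DataFrame,
                         coupling: dict[str, float],
                         n_pqtl: int = 35_000, seed: int = 0,
                         k_causal: int = 25, boost: float = 5.0,
                         ) -> dict[str, pd.DataFrame]:
    """Per-gene plasma-protein association tables with signed selection coupling.

    Each gene receives genome-wide (cis + trans) effects: independent noise
    plus large-effect causal boosts, a subset of which land on
    selection-significant variants with random signs.  A nonzero coupling c
    adds |c| * Z_sel and applies sign(c) to the whole track, so flipping the
    coupling sign negates the gene's Z-scores exactly under a reused seed.
    With c = 0 the selection-pQTL products are sign-balanced (null).
    """
    unknown = set(coupling) - set(genes["gene"])
    if unknown:
        raise KeyError(f"unknown gene id(s) in coupling: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    z_sel = selection["Z"].to_numpy(float)
    pos = selection["POS"].to_numpy()
    strong = np.flatnonzero(np.abs(z_sel) > 3.5)
    M = len(selection)

    out: dict[str, pd.DataFrame] = {}
    for _, row in genes.iterrows():
        gene = row["gene"]
        c = float(coupling.get(gene, 0.0))
        eta = rng.standard_normal(M)
        cis = np.flatnonzero((pos >= row["start"]) & (pos <= row["end"]))
        n_strong = min(k_causal, strong.size)
        hits = strong[rng.choice(strong.size, size=n_strong, replace=False)] if n_strong else np.array([], int)
        trans = rng.integers(0, M, size=10)
        causal = np.unique(np.concatenate([cis, hits, trans]))
        signs = rng.choice([-1.0, 1.0], size=causal.size)
        eta[causal] += signs * (boost + np.abs(rng.standard_normal(causal.size)))
        if c != 0.0:
            z = np.sign(c) * (abs(c) * z_sel + eta)
        else:
            z = eta
        df = selection[["CHR", "POS", "A1", "A2"]].copy()
        df["Z"] = z
        df["N"] = n_pqtl
        out[gene] = df
    return out


def make_pathways(genes: list[str] | pd.DataFrame, n_pathways: int,
                  immune_fraction: float = 0.3, signed_fraction: float = 0.5,
                  seed: int = 0, size_range: tuple[int, int] = (8, 25),
                  ) -> GeneSetCollection:
    """Random pathway collection with immune labels and signed subsets.

    Signed pathways draw their genes from a shared shuffled pool without
    replacement (refilled when exhausted), keeping overlap between signed
    gene sets low.
    """
    if isinstance(genes, pd.DataFrame):
        genes = list(genes["gene"])
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if size_range[1] > len(genes):
        raise ValueError("pathway size exceeds gene universe")
    rng = np.random.default_rng(seed)
    n_immune = int(round(immune_fraction * n_pathways))
    n_signed = int(round(signed_fraction * n_pathways))
    immune = np.zeros(n_pathways, bool)
    immune[rng.choice(n_pathways, size=n_immune, replace=False)] = True
    signed = np.zeros(n_pathways, bool)
    signed[rng.choice(n_pathways, size=n_signed, replace=False)] = True

    pool: list[str] = []
    pathways = []
    for i in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if signed[i]:
            members: list[str] = []
            while len(members) < size:
                if not pool:
                    pool = list(rng.permutation(genes))
                g = pool.pop()
                if g not in members:
                    members.append(g)
            half = size // 2
            positive, negative = members[:half], members[half:]
        else:
            members = list(rng.choice(genes, size=size, replace=False))
            positive, negative = [], []
        pathways.append(Pathway(
            id=f"PW{i:04d}", genes=members, immune=bool(immune[i]),
            positive=positive, negative=negative,
        ))
    return GeneSetCollection(pathways)
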