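# Methods

This note documents the models implemented in `paleoimmune`, the defaults
and their units, the design decisions taken where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Time and sign conventions

Dates are years before present (BP, positive = older).  All regressions
use analysis time t = −date_BP/1000, in units of 1,000 years (kyr), so a
positive slope always reads "rising toward the present".  Genotype dosage
counts the alt allele (column A1 in all summary-statistic tables); a
positive selection slope therefore means the A1 allele was favored.

## Synthetic cohorts

`simulate_trajectories` runs a forward Wright–Fisher model per variant and
ancestral component: the expected next-generation frequency is
p′ = p + s·p(1−p) (first-order additive selection on the alt allele),
followed by binomial sampling of 2N gametes; frequencies absorb at 0
and 1.  A deterministic mode skips the sampling (infinite-N limit), which
makes the trajectory reproducible by a one-line recurrence and is used as
an oracle in the tests.

Defaults (`SimConfig`) describe a compact Holocene-like design, chosen
once for realism and testability:

| parameter | default | why |
|---|---|---|
| `generations` | 400 | ×25 y/gen ≈ 10,000 years of record |
| `pop_size` | 10,000 diploids | the standard human effective-size figure; drift at this N is visible but does not dominate |
| `n_ancestries` | 3 | hunter-gatherer / farmer / steppe components |
| `admixture_schedule` | HG → 80% farmer at 8 ky BP → 40% steppe at 5 ky BP | the canonical West Eurasian turnover; makes ancestry shift with time and confounds naive frequency-vs-time regression |
| `fst` | 0.10 | Balding–Nichols divergence of component frequencies; sets the confounding amplitude |
| `frac_selected`, `s_range` | 5%, s ∈ [0.005, 0.03] | strong-but-plausible per-generation coefficients |
| `missing_rate`, `pseudohaploid_rate` | 5%, 30% | aDNA-style data loss; pseudo-haploid calls are dosage {0, 2} with a per-individual flag |
| `ld_r_range` | (0.1, 0.9) | per-block exchangeable correlation range (below) |

Individual dates are uniform over the time depth; ancestry is a Dirichlet
draw (concentration 50) around the schedule proportions at the
individual's date; genotypes are binomial in the ancestry-mixed frequency
at that date.

LD is block-diagonal and exchangeable *within* block at a correlation r_b
drawn per block from `ld_r_range`.  LD scores are then closed-form,
ℓ_j = 1 + (m−1)r_b², and — crucially — vary across blocks; with a single
global r every ℓ_j is identical and the LD-score regression cannot
separate slope from intercept.  Cohort genotypes are deliberately LD-free
(LD lives in the summary-statistic generators, where the estimators
consume it); this keeps the per-variant scan tests independent.

The GWAS/pQTL generators draw standardized causal effects jointly with the
selection effects at a target correlation, propagate them through the
block LD matrices, and add MVN(0, R) noise, so
E[Z_a,j·Z_b,j] = √(N_a N_b)·ρ_g·ℓ_j/M holds by construction.  The pQTL
generator applies a gene's signed coupling c as
Z = sign(c)·(|c|·Z_sel + η): the sign multiplies the whole track, so
flipping all couplings negates every statistic exactly under a reused
seed, while c = 0 leaves sign-balanced large effects at
selection-significant positions (the pathway-activity null).

What the generator does **not** emulate: realistic demography and
recombination maps, aDNA damage/contamination, date uncertainty,
ascertainment of the variant panel, and LD between cohort genotypes.
Passing tests therefore validate the estimators' statistical contracts
under the stated model, not their behavior on real ancient genomes.

## Selection scan

Per variant, weighted least squares of dosage on [1, t, ancestry
covariates] over complete cases, with pseudo-haploid individuals weighted
0.5 — the precision-exact weight, since a {0, 2} call has binomial
variance 4p(1−p) versus 2p(1−p) for a diploid call.  One ancestry column
is dropped (rows sum to 1).  Variants are removed when the folded
frequency is below `maf_min` (default 0.01), the complete-case count is
below `min_n` (default 30), or the dosage is constant.

The drift component of a trajectory adds variance that a fixed-effect
regression does not model, inflating the null Z distribution roughly
uniformly across variants (both the drift slope and the sampling SE scale
with √(p(1−p))).  Genomic control — SEs multiplied by
√(median(Z²)/0.4549) — absorbs this: at the generator defaults the
type-I error at α = 0.05 lands inside [0.04, 0.06] on 10⁴ neutral
structured variants, and the corrected Z track is close to N(0, 1)
(KS < 0.02).  `genomic_control` is on by default.  The module boundary
accepts a different backend (e.g. a mixed model with a relatedness random
effect) without touching downstream code.

Harmonization matches variants on (CHR, POS), flips the other track's Z
where alleles are swapped, drops allele mismatches, unmatched positions,
and strand-ambiguous pairs (A/T, C/G) at MAF > 0.4 (where strand cannot be
resolved from frequency), and reports all counts.

## Polygenic trajectory test

score_i = Σ_j β_j·d′_ij / m_i, where d′ is the dosage of the weight's
effect allele (complemented, 2−d, when that allele is the non-counted
one — a plain sign flip would mis-handle the per-individual missingness
normalization m_i) and m_i is i's non-missing weight-variant count.
γ_sign is the slope of scores on t with ancestry covariates.

The null recomputes the slope under independent ±1 flips of each
variant's contribution; γ is linear in the flips
(γ(σ) = Σ_j σ_j c_j), so B = 999 permutations cost one matrix product.
For weights whose signs are exchangeable under the null this test is
exactly calibrated, whatever the drift/structure covariance of the cohort
— the flips preserve it.  p = (1 + #{|γ_null| ≥ |γ_obs|})/(1 + B).  This
permutation null is a deliberately assumption-light stand-in for a
drift-aware parametric null; it tests coupling between weights and
frequency trends, not the trend's absolute magnitude.

## LD-score regression

All fits run on the standardized scale: Z²/N on ℓ_j/M (univariate;
slope = h², intercept ≈ 1/N, reported ×N so the conventional null value
is 1) and Z_a Z_b/√(N_a N_b) on ℓ_j/M (bivariate; slope = ρ_g), both with
free intercepts to absorb confounding and sample overlap.  Weights are
two-step: an unweighted pass, then 1/(2(î + ĥ²ℓ/M)²) with the pass-1
intercept î — using î rather than 1/N makes every estimate exactly
invariant to rescaling a track's Z by c alongside N by c², which matters
because a selection track has no conventional sample size (the scan's
median complete-case count is used as N; ρ_g with selection is on an
arbitrary but internally consistent scale, and r_g is scale-free).

SEs come from a delete-one jackknife over 200 contiguous variant blocks;
the bivariate leave-one-out series recompute the full ratio
ρ_g/√(h²_a h²_b).  r_g is reported missing (NaN) when either h² estimate
is non-positive — never clipped.  `meta_gls` pools per-trait estimates
with a covariance built from the shared-block jackknife pseudovalues
(Σ = cov(pseudovalues)/B), pooled mean (1ᵀΣ⁻¹r)/(1ᵀΣ⁻¹1); with diagonal Σ
this is exactly inverse-variance weighting.  Σ is ridge-regularized by
10⁻³·trace/k only when its condition number exceeds 10⁶.  The
annotation partition fits two stratified LD-score columns (closed-form
under the block model) and reports the annotation's share of total signal
and its per-variant enrichment.

## Colocalization and fine-mapping

The atomic unit is the Wakefield log approximate Bayes factor,
log ABF = ½log(1−r) + r·z²/2 with r = w/(v + w), v = 1/N on the
standardized scale and prior effect variance w = 0.04 for all tracks
(configurable per track; the selection track has no established prior
scale, so the conventional default is used and flagged here).  Hypothesis
Bayes factors are exact enumerations under a single causal variant per
track, with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the method's canonical
defaults).  All sums run in log space; the two-causal-variants term
enumerates the j ≠ k pairs directly up to 1,000 variants (no cancellation)
and falls back to a guarded log-difference beyond that.

PIPs normalize the per-variant ABFs under a uniform causal prior; the 95%
credible set is the minimal descending-PIP prefix reaching 0.95, ties
broken by ascending position for determinism.  The joint shared-variant
posterior multiplies the per-variant H4 posterior by PP_H4.  Loci are
seeded at |Z| ≥ threshold, padded by ±window, and merged when closer than
a gap (defaults 4.0 / 250 kb / 250 kb); a PP_H4 ≥ 0.8 convention is used
where a binary "colocalizes" call is needed.  Multi-causal fine-mapping
with LD matrices is out of scope; apparent secondary signals are handled
by splitting loci, not by conditioning.

## Pathway enrichment and the immune-label test

Enrichment is the upper-tail hypergeometric probability of the observed
overlap between a prioritized gene set and each pathway, both intersected
with an explicit caller-supplied universe (the genes that *could* have
been prioritized — never the whole genome), with BH q-values across all
tested pathways and 2×2 odds ratios (exact rational arithmetic; Haldane
0.5 correction when a single cell is zero, undefined on a zero margin).

Whether immune-labelled pathways are over-represented among enriched ones
(q < 0.10) is tested by logistic regression of the enriched indicator on
the immune flag plus log pathway size, calibrated by permutation:
the *prioritized gene set* is redrawn uniformly from the universe
(B times) and the whole enrichment + regression pipeline re-run.
Resampling the gene set rather than shuffling labels preserves the
redundancy and size structure of the pathway collection under the null,
which label shuffling would destroy.  Separated or degenerate fits fall
back to a ridge-penalized IRLS (λ = 0.5) and are flagged; permutation
ties count as extreme (conservative).

## Signed pathway activity

For each regulator gene, the selection–pQTL genetic covariance is the
mean of (Z_sel/√N_sel)·(Z_pqtl/√N_pqtl) over variants with |Z| > 3 on
both tracks; the direct product estimator is used rather than a per-gene
bivariate LD-score fit because per-gene heritability estimates are too
noisy at these filter depths (the genome-wide r_g remains available as a
qualitative cross-check).  The pathway statistic averages
sign_g × covariance_g over genes (+1 positive regulators, −1 negative),
so a positive value always decodes as "activity increased".

Uncertainty: the genome-ordered union of qualifying variants across the
pathway's genes is cut into 200 approximately equal contiguous blocks
(shared blocks absorb co-regulation and correlated estimation error); a
gene whose qualifying set would be emptied by deleting one block is
dropped (iterated to a fixed point — the rule is idempotent), then
leave-one-block-out recomputation gives the jackknife SE, Z and two-sided
p, with BH FDR across pathways.  An optional per-gene colocalization gate
(PP_H4 ≥ 0.8 between selection and the gene's pQTL) filters genes before
averaging; synthetic tests may bypass it.  `activation_summary`
tabulates increased/decreased × immune/non-immune among significant
pathways, with the odds ratio and a label-shuffling permutation p.

## Numerical and testing notes

* Every generator and test is driven by `numpy.random.default_rng` with
  explicit seeds; outputs are bit-reproducible.
* Oracles are independent of the code paths they check: a one-line
  recurrence for deterministic trajectories, plain least squares for the
  scan slope, explicit-arithmetic enumeration for the coloc posteriors
  (including the pairwise j ≠ k sum — the shortcut S_A·S_B − Σ cancels
  catastrophically when one variant dominates), exact `Fraction`
  arithmetic and literal draw enumeration for the hypergeometric tail,
  and hand-evaluated GLS for the meta-analysis.
* Problem sizes in the test-suite calibrations (10⁴ scan variants, 500
  trajectory cohorts, 100 activity seeds, 50k-variant LDSC tracks, 500
  fine-mapping loci) were chosen so the whole suite runs in well under a
  minute per module on one CPU while keeping Monte-Carlo error small
  relative to the asserted bands.
* Known limitations: the scan is a fixed-effect approximation whose
  calibration is empirical (via genomic control) rather than exact; the
  trajectory null tests coupling, not absolute neutrality; LD-score
  estimates at 50k variants carry ~0.03–0.07 jackknife SEs; and none of
  the generators model aDNA damage, date error or panel ascertainment.
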