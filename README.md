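# paleoimmune

Tools for linking ancient-DNA selection statistics to present-day disease
risk, causal variants and genes, and the direction of pathway activity.

Time-stratified ancient genomes make it possible to score every variant for
allele-frequency change over the last ~10,000 years beyond what drift and
population structure explain.  Such per-variant selection statistics
(beta, SE, Z) look exactly like GWAS summary statistics, which means the
statistical-genetics toolbox built for GWAS can be pointed at natural
selection itself.  `paleoimmune` implements that inference stack at desk
scale, for method developers and population geneticists who want a fully
seeded, testable sandbox:

* **selection scan** — per-variant weighted regression of genotype dosage on
  time (t = −date_BP/1000) with ancestry covariates, pseudo-haploid
  down-weighting, complete-case missingness and genomic control
  (λ_GC = median(Z²)/0.4549);
* **polygenic trajectory test** — the slope γ_sign of a polygenic score on
  time, tested against an exactly calibrated per-variant sign-flip null;
* **cross-track LD-score regression** — heritability analogs from
  E[Z²] = 1 + N·h²·ℓ_j/M, genetic covariance from
  E[Z_a Z_b] = √(N_a N_b)·ρ_g·ℓ_j/M, r_g = ρ_g/√(h²_a h²_b) with
  200-block jackknife SEs, GLS meta-analysis across traits sharing
  jackknife blocks, and annotation partitioning of signal;
* **colocalization / fine-mapping** — Wakefield log-ABFs, exact enumeration
  of the five sharing hypotheses (PP_H0..PP_H4), single-causal PIPs with
  95% credible sets, and the joint shared-variant posterior
  PIP_Sel,GWAS = (per-variant H4 posterior) × PP_H4;
* **pathway enrichment** — upper-tail hypergeometric tests inside an
  explicit gene universe, BH FDR, and a permutation-calibrated,
  size-adjusted logistic test of immune-label excess;
* **signed pathway activity** — the average selection–pQTL genetic
  covariance across positive/negative regulator genes (variants with
  |Z| > 3 on both tracks, products on the Z/√N scale), jackknifed over 200
  blocks of adjacent variants, yielding an increased/decreased call per
  pathway;
* **synthetic data** — a Wright–Fisher forward simulator with additive
  selection, a three-component admixture schedule (hunter-gatherer →
  farmer → steppe turnover) that confounds naive frequency-vs-time
  regression, block LD with closed-form LD scores, and coupled
  GWAS/pQTL/pathway generators with known truth.

## Worked example

```python
from paleoimmune import (SimConfig, ScanConfig, simulate_trajectories, sample_cohort,
                         run_scan, make_ld_reference, simulate_sumstats_pair,
                         estimate_rg, coloc_abf, finemap_single, joint_pip,
                         simulate_genes, simulate_pqtl_tables)

# 1. dated cohort (800 individuals, 20k variants, 10 kyr) -> selection scan
cfg = SimConfig(seed=1, n_blocks=400, variants_per_block=50, frac_selected=0.02)
cohort, truth = sample_cohort(simulate_trajectories(cfg), cfg)
selection = run_scan(cohort, ScanConfig())

# 2. genetic correlation between two coupled summary-statistic tracks
ld = make_ld_reference(cfg)
a, b = simulate_sumstats_pair(ld, n_a=100_000, n_b=100_000, rg_target=-0.4,
                              h2_a=0.3, h2_b=0.3, seed=2)
rg = estimate_rg(a, b, ld, n_blocks=200)

# 3. colocalization of selection with a coupled protein QTL at the top locus
genes = simulate_genes(cohort.variants, n_genes=40)
pqtl = simulate_pqtl_tables(truth, genes, selection, {"G0010": 1.0}, seed=3)["G0010"]
top = selection.loc[selection.Z.abs().idxmax()]
sl = selection[selection.POS.between(top.POS - 25_000, top.POS + 25_000)]
pl = pqtl[pqtl.POS.isin(sl.POS)]
res = coloc_abf(sl.Z.to_numpy(), pl.Z.to_numpy(), sl.N.to_numpy(), pl.N.to_numpy())
fm = finemap_single(sl.Z.to_numpy(), sl.N.to_numpy(), pos=sl.POS.to_numpy())
```

prints, step by step:

```
scanned 19839 variants, lambda_GC = 1.26, |Z|>4 hits: 159
rg = -0.393 (jackknife SE 0.054)
locus 8458000-8508000 (51 variants): PP_H4 = 1.000, top PIP_Sel = 1.00,
credible set size = 1, top joint PIP = 1.00
```

Reading the output: the scan is inflated by structure/drift before genomic
control (λ_GC = 1.26) and yields 159 strong candidate variants; the
LD-score regression recovers the simulated genetic correlation of −0.4
within one jackknife SE; and at the strongest selected locus the
enumeration assigns essentially all posterior mass to a single shared
causal variant between selection and the coupled protein QTL.

A command-line interface mirrors the library
(`paleoimmune simulate|scan|trajectory|rg|coloc|enrich|activity`); see
`paleoimmune --help`.

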