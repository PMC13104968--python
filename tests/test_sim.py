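"""Generator checks: trajectory dynamics, cohort sampling, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from paleoimmune.config import SimConfig
from paleoimmune.genesets import write_gmt
from paleoimmune.sim import (
    make_ld_reference,
    make_pathways,
    sample_cohort,
    simulate_genes,
    simulate_gwas_sumstats,
    simulate_pqtl_tables,
    simulate_sumstats_pair,
    simulate_trajectories,
)


def selection_recurrence(p0: float, s: float, generations: int) -> float:
    """Independent one-line oracle for the deterministic trajectory."""
    p = p0
    for _ in range(generations):
        p = p + s * p * (1.0 - p)
    return p


class TestTrajectories:
    def test_deterministic_neutral_path_is_constant(self):
        cfg = SimConfig(seed=0, n_blocks=2, variants_per_block=5,
                        n_ancestries=1, frac_selected=0.0, generations=50)
        traj = simulate_trajectories(cfg, deterministic=True)
        assert np.allclose(traj.freq, traj.freq[:, :, [0]])

    def test_deterministic_selection_matches_recurrence_oracle(self):
        cfg = SimConfig(seed=0, n_blocks=1, variants_per_block=1,
                        n_ancestries=1, generations=100)
        traj = simulate_trajectories(
            cfg, deterministic=True, p0=np.array([[0.2]]), s=np.array([0.05]))
        expected = selection_recurrence(0.2, 0.05, 100)
        assert traj.freq[0, 0, -1] == pytest.approx(expected, rel=1e-12)

    def test_neutral_drift_is_a_martingale(self):
        # mean final frequency stays at p0 within Monte-Carlo error
        cfg = SimConfig(seed=3, n_blocks=200, variants_per_block=50,
                        n_ancestries=1, frac_selected=0.0, generations=100,
                        pop_size=1000)
        p0 = np.full((cfg.n_variants, 1), 0.3)
        traj = simulate_trajectories(cfg, p0=p0)
        final = traj.freq[:, 0, -1]
        se = final.std() / np.sqrt(final.size)
        assert abs(final.mean() - 0.3) < 3 * se

    def test_heterozygosity_decays_at_the_drift_rate(self):
        # E[p(1-p)] at generation t is p0(1-p0) * (1 - 1/2N)^t
        cfg = SimConfig(seed=4, n_blocks=250, variants_per_block=50,
                        n_ancestries=1, frac_selected=0.0, generations=80,
                        pop_size=200)
        p0 = np.full((cfg.n_variants, 1), 0.5)
        traj = simulate_trajectories(cfg, p0=p0)
        t = cfg.generations
        expected = 0.25 * (1.0 - 1.0 / (2 * cfg.pop_size)) ** t
        observed = (traj.freq[:, 0, -1] * (1 - traj.freq[:, 0, -1])).mean()
        assert observed == pytest.approx(expected, rel=0.10)

    def test_rejects_degenerate_parameters(self):
        with pytest.raises(ValueError, match="pop_size"):
            simulate_trajectories(SimConfig(pop_size=5, n_blocks=1, variants_per_block=2))
        with pytest.raises(ValueError, match="generations"):
            simulate_trajectories(SimConfig(generations=1, n_blocks=1, variants_per_block=2))

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = SimConfig(seed=9, n_blocks=4, variants_per_block=10, generations=30)
        a = simulate_trajectories(cfg)
        b = simulate_trajectories(cfg)
        assert np.array_equal(a.freq, b.freq) and np.array_equal(a.s, b.s)


class TestCohort:
    def test_clean_cohort_has_complete_diploid_dosages(self):
        cfg = SimConfig(seed=1, n_blocks=4, variants_per_block=10,
                        n_individuals=50, generations=40,
                        missing_rate=0.0, pseudohaploid_rate=0.0)
        cohort, _ = sample_cohort(simulate_trajectories(cfg), cfg)
        assert not np.isnan(cohort.dosage).any()
        assert set(np.unique(cohort.dosage)) <= {0.0, 1.0, 2.0}

    def test_all_pseudohaploid_dosages_are_even(self):
        cfg = SimConfig(seed=2, n_blocks=4, variants_per_block=10,
                        n_individuals=50, generations=40, pseudohaploid_rate=1.0)
        cohort, _ = sample_cohort(simulate_trajectories(cfg), cfg)
        vals = cohort.dosage[~np.isnan(cohort.dosage)]
        assert set(np.unique(vals)) <= {0.0, 2.0}

    def test_dosages_are_binomial_in_the_true_frequency(self):
        # single ancestry, constant frequency 0.5: mean dosage/2 ~ 0.5
        cfg = SimConfig(seed=3, n_blocks=1, variants_per_block=1,
                        n_individuals=5000, n_ancestries=1, generations=40,
                        missing_rate=0.0, pseudohaploid_rate=0.0)
        traj = simulate_trajectories(cfg, deterministic=True,
                                     p0=np.array([[0.5]]), s=np.array([0.0]))
        cohort, _ = sample_cohort(traj, cfg)
        f = cohort.dosage.mean() / 2.0
        se = np.sqrt(0.5 * 0.5 / (2 * cfg.n_individuals))
        assert abs(f - 0.5) < 3 * se

    def test_truth_table_is_aligned_and_contiguous(self, small_cohort, small_config):
        _, truth = small_cohort
        assert len(truth) == small_config.n_variants
        blocks = truth["BLOCK"].to_numpy()
        assert np.all(np.diff(blocks) >= 0)
        assert truth["POS"].is_monotonic_increasing


class TestSumstatsGenerators:
    def test_ld_scores_bounded_by_block_size(self, small_ld, small_config):
        l2 = small_ld.ld_scores
        assert np.all(l2 >= 1.0)
        assert np.all(l2 <= small_config.variants_per_block)

    def test_rg1_no_noise_ranks_match_selection_effects(self, ldsc_reference):
        _, ld = ldsc_reference
        truth = ld.table[["CHR", "POS", "A1", "A2"]].copy()
        truth["true_s"] = np.random.default_rng(0).normal(size=ld.M)
        gwas = simulate_gwas_sumstats(truth, ld, n_gwas=10_000, rg_target=1.0,
                                      seed=1, noise=False)
        block0 = ld.blocks == 0
        z = gwas.loc[block0, "Z"].to_numpy()
        s = truth.loc[block0, "true_s"].to_numpy()
        rho = pd.Series(z).corr(pd.Series(s), method="spearman")
        assert rho == pytest.approx(1.0)

    def test_pair_rejects_bad_arguments(self, small_ld):
        with pytest.raises(ValueError, match="rg_target"):
            simulate_sumstats_pair(small_ld, 100, 100, rg_target=1.5)
        with pytest.raises(ValueError, match="sample sizes"):
            simulate_sumstats_pair(small_ld, 1, 100, rg_target=0.0)

    def test_pqtl_coupling_flip_negates_z_exactly(self, small_cohort, small_selection, gene_map):
        _, truth = small_cohort
        coupling = {g: 0.7 for g in gene_map["gene"][:5]}
        pos = simulate_pqtl_tables(truth, gene_map, small_selection, coupling, seed=7)
        neg = simulate_pqtl_tables(truth, gene_map, small_selection,
                                   {g: -c for g, c in coupling.items()}, seed=7)
        for g in coupling:
            assert np.array_equal(pos[g]["Z"].to_numpy(), -neg[g]["Z"].to_numpy())

    def test_pqtl_unknown_gene_rejected(self, small_cohort, small_selection, gene_map):
        _, truth = small_cohort
        with pytest.raises(KeyError, match="unknown gene"):
            simulate_pqtl_tables(truth, gene_map, small_selection, {"NOPE": 1.0})


class TestPathways:
    def test_immune_fraction_one_flags_everything(self):
        genes = [f"G{i}" for i in range(60)]
        pws = make_pathways(genes, 12, immune_fraction=1.0, seed=0)
        assert all(p.immune for p in pws)

    def test_signed_fraction_zero_yields_unsigned_sets(self):
        genes = [f"G{i}" for i in range(60)]
        pws = make_pathways(genes, 12, signed_fraction=0.0, seed=0)
        assert not any(p.signed for p in pws)

    def test_signed_subsets_partition_their_genes(self):
        genes = [f"G{i}" for i in range(80)]
        pws = make_pathways(genes, 20, signed_fraction=1.0, seed=3)
        for p in pws:
            assert set(p.positive) | set(p.negative) == set(p.genes)
            assert not set(p.positive) & set(p.negative)

    def test_gmt_output_is_byte_identical_across_runs(self, tmp_path):
        genes = [f"G{i}" for i in range(40)]
        paths = []
        for run in range(2):
            out = tmp_path / f"run{run}.gmt"
            write_gmt(make_pathways(genes, 8, seed=5), out)
            paths.append(out.read_bytes())
        assert paths[0] == paths[1]

    def test_oversized_pathways_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_pathways([f"G{i}" for i in range(10)], 3, size_range=(5, 20))
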