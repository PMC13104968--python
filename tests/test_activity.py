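"""Signed pathway activity: hand oracles, symmetries, drop rule, jackknife."""

import numpy as np
import pandas as pd
import pytest

from paleoimmune.activity import (
    activation_summary,
    analyze_pathways,
    gene_covariance,
    pathway_activity,
)
from paleoimmune.genesets import GeneSetCollection, Pathway
from paleoimmune.sim import make_pathways, simulate_pqtl_tables


def track(z, n=10_000, pos=None):
    m = len(z)
    return pd.DataFrame({
        "CHR": 1,
        "POS": np.arange(1, m + 1) * 100 if pos is None else pos,
        "A1": "A", "A2": "G", "Z": np.asarray(z, float), "N": n,
    })


class TestGeneCovariance:
    def test_self_covariance_is_positive_mean_of_z2_over_n(self):
        z = np.array([4.0, -5.0, 0.5, 3.5])
        sel = track(z, n=1_000)
        gc = gene_covariance(sel, sel)
        qualifying = np.array([4.0, -5.0, 3.5])
        assert gc.covariance == pytest.approx((qualifying**2 / 1_000).mean())
        assert gc.covariance > 0

    def test_negating_the_pqtl_track_negates_the_covariance(self):
        rng = np.random.default_rng(0)
        sel = track(rng.normal(0, 3, 40))
        pq = track(rng.normal(0, 3, 40))
        g1 = gene_covariance(sel, pq)
        g2 = gene_covariance(sel, pq.assign(Z=-pq["Z"]))
        assert g1.covariance == pytest.approx(-g2.covariance, rel=1e-12)

    def test_hand_computed_four_variant_mean(self):
        sel = track([4.0, 5.0, -4.0, 6.0], n=100)
        pq = track([3.5, -4.0, 5.0, 4.0], n=400)
        gc = gene_covariance(sel, pq)
        prods = [4 * 3.5, 5 * -4, -4 * 5, 6 * 4]
        expected = np.mean(prods) / np.sqrt(100 * 400)
        assert gc.covariance == pytest.approx(expected, rel=1e-12)
        assert gc.n_qualifying == 4

    def test_no_qualifying_variants_returns_none(self):
        assert gene_covariance(track([1.0, 2.0]), track([5.0, 5.0])) is None


def two_gene_setup(seed=0, m=400, flip=False):
    rng = np.random.default_rng(seed)
    zsel = rng.normal(0, 3, m)
    sel = track(zsel)
    sign = -1.0 if flip else 1.0
    tables = {
        "GA": track(sign * (zsel + rng.normal(0, 1, m))),
        "GB": track(sign * (-zsel + rng.normal(0, 1, m))),
    }
    return sel, tables


class TestPathwayActivity:
    def test_sign_flip_of_all_regulators_negates_the_statistic(self):
        sel, tables = two_gene_setup()
        pw = Pathway("p", ["GA", "GB"], positive=["GA", "GB"])
        fl = Pathway("p", ["GA", "GB"], negative=["GA", "GB"])
        r1 = pathway_activity(sel, tables, pw, n_blocks=20)
        r2 = pathway_activity(sel, tables, fl, n_blocks=20)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
        assert {r1.direction, r2.direction} == {"increased", "decreased"}

    def test_pqtl_negation_negates_the_statistic(self):
        sel, tables = two_gene_setup()
        _, neg = two_gene_setup(flip=True)
        pw = Pathway("p", ["GA", "GB"], positive=["GA"], negative=["GB"])
        r1 = pathway_activity(sel, tables, pw, n_blocks=20)
        r2 = pathway_activity(sel, neg, pw, n_blocks=20)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)

    def test_drop_rule_is_idempotent(self):
        # gene GC has a single qualifying variant: it always sits in one
        # jackknife block, so the drop rule removes it
        sel, tables = two_gene_setup(m=400)
        z = np.zeros(400)
        z[10] = 6.0
        tables["GC"] = track(z)
        sel2 = sel.copy()
        sel2.loc[10, "Z"] = 6.0
        pw = Pathway("p", ["GA", "GB", "GC"], positive=["GA", "GB", "GC"])
        r1 = pathway_activity(sel2, tables, pw, n_blocks=50)
        assert "GC" in r1.genes_dropped
        retained = Pathway("p", ["GA", "GB"], positive=["GA", "GB"])
        r2 = pathway_activity(sel2, tables, retained, n_blocks=50)
        assert not any(v == "qualifying set emptied by a jackknife block"
                       for v in r2.genes_dropped.values())
        assert r2.statistic == pytest.approx(r1.statistic, rel=1e-9)

    def test_all_genes_dropped_raises_with_reasons(self):
        sel = track(np.zeros(50))
        pw = Pathway("p", ["GA"], positive=["GA"])
        with pytest.raises(ValueError, match="dropped"):
            pathway_activity(sel, {"GA": track(np.zeros(50))}, pw, n_blocks=5)

    def test_coloc_gate_excludes_unsupported_genes(self):
        sel, tables = two_gene_setup()
        pw = Pathway("p", ["GA", "GB"], positive=["GA", "GB"])
        res = pathway_activity(sel, tables, pw, n_blocks=20,
                               coloc_gate={"GA": 0.95, "GB": 0.1})
        assert res.genes_dropped == {"GB": "below colocalization threshold"}
        assert res.n_genes == 1

    def test_jackknife_se_tracks_analytic_se_on_iid_products(self):
        # one gene, iid products: jackknife SE ~ sd/sqrt(n)
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = 4000
            zsel = np.where(rng.random(m) < 0.5, 4.0, -4.0) + rng.normal(0, .2, m)
            zp = np.where(rng.random(m) < 0.5, 4.0, -4.0) + rng.normal(0, .2, m)
            sel, pq = track(zsel), track(zp)
            pw = Pathway("p", ["G"], positive=["G"])
            res = pathway_activity(sel, {"G": pq}, pw, n_blocks=200)
            gc = gene_covariance(sel, pq)
            analytic = gc.products.std(ddof=1) / np.sqrt(gc.products.size)
            ratios.append(res.se / analytic)
        assert abs(np.mean(ratios) - 1.0) < 0.25

    def test_paired_regulator_sets_reach_concordant_directions(self, small_cohort,
                                                               small_selection, gene_map):
        # positive regulators coupled +, negative regulators coupled -:
        # both encode "process increased" and the calls should agree
        _, truth = small_cohort
        sel = small_selection
        genes = list(gene_map["gene"])
        agreements = 0
        for pair in range(6):
            pos_g = genes[4 * pair: 4 * pair + 2]
            neg_g = genes[4 * pair + 2: 4 * pair + 4]
            coupling = {g: 0.8 for g in pos_g} | {g: -0.8 for g in neg_g}
            tables = simulate_pqtl_tables(truth, gene_map, sel, coupling,
                                          seed=100 + pair)
            pw_pos = Pathway("pos", pos_g, positive=pos_g)
            pw_neg = Pathway("neg", neg_g, negative=neg_g)
            d1 = pathway_activity(sel, tables, pw_pos, n_blocks=30).direction
            d2 = pathway_activity(sel, tables, pw_neg, n_blocks=30).direction
            agreements += d1 == d2 == "increased"
        assert agreements >= 5


class TestActivationSummary:
    def frame(self, qs, directions, immune):
        return pd.DataFrame({
            "pathway": [f"p{i}" for i in range(len(qs))],
            "q": qs, "direction": directions, "immune": immune,
        })

    def test_paper_style_table_reproduces_or(self):
        qs, dirs, imm = [], [], []
        for n, d, i in [(33, "increased", True), (2, "decreased", True),
                        (22, "increased", False), (17, "decreased", False)]:
            qs += [0.01] * n
            dirs += [d] * n
            imm += [i] * n
        out = activation_summary(self.frame(qs, dirs, imm), B=499, seed=0)
        assert out.odds_ratio == 12.75
        assert out.p_permutation < 0.05

    def test_zero_margin_is_flagged_undefined(self):
        df = self.frame([0.01] * 4, ["increased"] * 4, [True, True, False, False])
        out = activation_summary(df, B=99)
        assert np.isnan(out.odds_ratio)

    def test_no_significant_pathways_yields_empty_summary(self):
        df = self.frame([0.9, 0.8], ["increased", "decreased"], [True, False])
        out = activation_summary(df)
        assert out.n_significant == 0 and out.table.empty

    def test_random_labels_permutation_p_is_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 60
        for _ in range(reps):
            n = 40
            imm = rng.random(n) < 0.5
            dirs = np.where(rng.random(n) < 0.6, "increased", "decreased")
            if imm.all() or not imm.any():
                continue
            df = self.frame([0.01] * n, list(dirs), list(imm))
            try:
                out = activation_summary(df, B=199, seed=int(rng.integers(1e6)))
            except ValueError:
                continue
            if np.isfinite(out.odds_ratio) and out.p_permutation <= 0.05:
                rejections += 1
        assert rejections / reps <= 0.12


class TestAnalyzePathways:
    def test_null_coupling_keeps_pathway_z_small(self, small_cohort,
                                                 small_selection, gene_map):
        _, truth = small_cohort
        coupling = {g: 0.0 for g in gene_map["gene"]}
        tables = simulate_pqtl_tables(truth, gene_map, small_selection,
                                      coupling, seed=5)
        pws = make_pathways(gene_map, 12, signed_fraction=1.0, seed=2)
        df = analyze_pathways(small_selection, tables, pws, n_blocks=40)
        assert len(df) >= 10
        assert (df["z"].abs() < 3).mean() >= 0.9

    def test_strong_coupling_is_called_increased_and_significant(
            self, small_cohort, small_selection, gene_map):
        _, truth = small_cohort
        pws = make_pathways(gene_map, 10, signed_fraction=1.0, seed=4)
        target = next(p for p in pws if p.signed)
        coupling = {g: 0.0 for g in gene_map["gene"]}
        coupling.update({g: 1.0 for g in target.positive})
        coupling.update({g: -1.0 for g in target.negative})
        tables = simulate_pqtl_tables(truth, gene_map, small_selection,
                                      coupling, seed=6)
        df = analyze_pathways(small_selection, tables, pws, n_blocks=40)
        row = df.set_index("pathway").loc[target.id]
        assert row["direction"] == "increased"
        assert row["q"] < 0.10
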