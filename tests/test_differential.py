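"""Size factors, BH, NB Wald DGE, DEU interaction test, PCA, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aberex.differential import (
    AnalysisThresholds,
    bh_adjust,
    candidate_filter,
    cluster_deu_heatmap_input,
    deu_test,
    dge_wald,
    estimate_size_factors,
    exclude_genes,
    intersect_cohorts,
    pca_top_variable,
)
from aberex.simulate import SimulationConfig, simulate_gene_counts

from conftest import make_gene


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        c = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(estimate_size_factors(c), 1.0)

    def test_doubled_column_scales_factor(self):
        base = np.array([10, 25, 40, 100])
        c = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = estimate_size_factors(c)
        assert np.allclose(sf["c"] / sf["a"], 2.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            c = pd.DataFrame(rng.integers(1, 500, size=(30, 5)))
            sf = estimate_size_factors(c)
            logc = np.log(c.values.astype(float))
            geo = logc.mean(axis=1)
            want = np.exp(np.median(logc - geo[:, None], axis=0))
            assert np.allclose(sf.values, want)


class TestBH:
    def test_analytic_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_nan_propagates_and_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2, so q = (0.02, -, 0.04)
        assert np.allclose(q[[0, 2]], [0.02, 0.04])

    def test_matches_naive_sort_oracle(self, rng):
        def naive(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank_from_top, i in enumerate(order[::-1]):
                rank = m - rank_from_top
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return np.minimum(q, 1)

        for _ in range(30):
            p = rng.random(int(rng.integers(1, 60)))
            assert np.allclose(bh_adjust(p), naive(p))

    def test_permutation_invariant(self, rng):
        p = rng.random(40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestExcludeGenes:
    def test_biotype_rules(self):
        genes = [
            make_gene("G1", "chr1", "+", [(0, 10)], biotype="processed_pseudogene"),
            make_gene("G2", "chr1", "+", [(20, 30)], biotype="protein_coding"),
            make_gene("G3", "chr1", "+", [(40, 50)], biotype="Mt_rRNA"),
            make_gene("G4", "chr1", "+", [(60, 70)], biotype="IG_V_gene"),
            make_gene("G5", "chr1", "+", [(80, 90)], biotype="TR_J_gene"),
            make_gene("G6", "chr1", "+", [(95, 99)], biotype="lncRNA"),
        ]
        kept = {g.gene_id for g in exclude_genes(genes)}
        assert kept == {"G2", "G6"}

    def test_matches_regex_oracle(self, rng):
        import re

        biotypes = [
            "protein_coding", "lncRNA", "rRNA", "rRNA_pseudogene",
            "transcribed_unprocessed_pseudogene", "Mt_tRNA", "IG_V_pseudogene",
            "TR_C_gene", "snoRNA", "misc_RNA",
        ]
        pats = ["pseudogene", "Mt_rRNA", "Mt_tRNA", "^rRNA", "^IG_V", "^TR_"]
        genes = [
            make_gene(f"G{i}", "chr1", "+", [(i * 10, i * 10 + 5)],
                      biotype=rng.choice(biotypes))
            for i in range(40)
        ]
        kept = {g.gene_id for g in exclude_genes(genes)}
        want = {
            g.gene_id
            for g in genes
            if not any(re.search(p, g.biotype) for p in pats)
        }
        assert kept == want


class TestThresholds:
    def test_defaults(self):
        t = AnalysisThresholds()
        assert (t.q_max, t.lfc_min, t.count_min) == (0.05, 0.5, 10.0)
        assert (t.deu_padj_max, t.deu_lfc_min) == (0.05, 0.5)
        assert t.pfs_cutoff_months == 60.0
        assert t.pca_top_n == 5000
        assert t.gsea_min_mean_reads == 1.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            AnalysisThresholds(q_max=-0.01)

    def test_candidate_boundary_truth_table(self):
        t = AnalysisThresholds()
        eps = 1e-9
        lfcs = [0.5 - eps, 0.5, 0.5 + eps, -0.5, -0.49]
        qs = [0.05 - eps, 0.05, 0.05 + eps]
        means = [10 - eps, 10.0, 10 + eps]
        rows = list(itertools.product(lfcs, qs, means))
        df = pd.DataFrame(
            {
                "log2fc_shrunk": [r[0] for r in rows],
                "log2fc": [r[0] for r in rows],
                "q": [r[1] for r in rows],
                "base_mean": [r[2] for r in rows],
            }
        )
        got = candidate_filter(df, t)
        for i, (lfc, q, mean) in enumerate(rows):
            want = abs(lfc) >= 0.5 and q <= 0.05 and mean >= 10
            assert got.iloc[i] == want, (lfc, q, mean)


class TestDGE:
    def test_all_zero_gene_excluded(self):
        sim = SimulationConfig(seed=7, n_mut=4, n_wt=4, n_genes_expr=50)
        cm, _ = simulate_gene_counts(sim, null=True)
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        res = dge_wald(counts, sim.condition)
        assert np.isnan(res.iloc[0]["p"])
        assert np.isnan(res.iloc[0]["q"])
        assert res["p"].notna().sum() == len(counts) - 1

    def test_planted_lfc_recovered(self):
        # planted log2FC = 1 at mu = 100, n = 10+10, against a null
        # background (size factors would absorb a cohort-wide shift)
        rng = np.random.default_rng(99)
        n, mu_wt = 10, 100.0
        rows, planted = [], []
        for i in range(400):
            lfc = 1.0 if i < 60 else 0.0
            planted.append(lfc == 1.0)
            mu_mut = mu_wt * 2**lfc
            a = 0.02 + 2 / mu_mut
            mut = rng.negative_binomial(1 / a, 1 / (1 + a * mu_mut), n)
            a = 0.02 + 2 / mu_wt
            wt = rng.negative_binomial(1 / a, 1 / (1 + a * mu_wt), n)
            rows.append(np.concatenate([mut, wt]))
        counts = pd.DataFrame(
            rows, columns=[f"m{i}" for i in range(n)] + [f"w{i}" for i in range(n)]
        )
        res = dge_wald(counts, ["mut"] * n + ["wt"] * n)
        assert abs(res.loc[planted, "log2fc"].mean() - 1.0) < 0.15

    def test_scaling_one_sample_is_normalized_away(self):
        sim = SimulationConfig(seed=8, n_mut=5, n_wt=5, n_genes_expr=300)
        cm, _ = simulate_gene_counts(sim, null=True)
        res1 = dge_wald(cm.counts, sim.condition)
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 4
        res2 = dge_wald(scaled, sim.condition)
        # size factors absorb the global scaling; statistics match closely
        # (exact equality is impossible: NB sampling is not scale-invariant)
        ok = res1["wald_stat"].notna() & res2["wald_stat"].notna()
        corr = np.corrcoef(res1.loc[ok, "wald_stat"], res2.loc[ok, "wald_stat"])[0, 1]
        assert corr > 0.98

    def test_sample_relabel_invariance(self):
        sim = SimulationConfig(seed=9, n_mut=4, n_wt=4, n_genes_expr=100)
        cm, _ = simulate_gene_counts(sim, null=True)
        res1 = dge_wald(cm.counts, sim.condition)
        perm = np.random.default_rng(0).permutation(cm.counts.shape[1])
        res2 = dge_wald(
            cm.counts.iloc[:, perm], sim.condition.iloc[perm], test_level="mut"
        )
        assert np.allclose(res1["p"].values, res2["p"].values, equal_nan=True,
                           atol=1e-10)


class TestIntersect:
    def _res(self, genes, qs, lfcs):
        return pd.DataFrame({"q": qs, "log2fc": lfcs}, index=genes)

    def test_disjoint_sets_empty(self):
        a = self._res(["g1", "g2"], [0.01, 0.5], [1, 1])
        b = self._res(["g1", "g2"], [0.5, 0.01], [1, 1])
        assert len(intersect_cohorts(a, b)) == 0

    def test_identical_sets(self):
        a = self._res(["g1", "g2"], [0.01, 0.02], [1, -1])
        out = intersect_cohorts(a, a)
        assert set(out.index) == {"g1", "g2"}
        assert out["concordant"].all()

    def test_matches_set_oracle(self, rng):
        genes = [f"g{i}" for i in range(100)]
        a = self._res(genes, rng.random(100), rng.normal(size=100))
        b = self._res(genes, rng.random(100), rng.normal(size=100))
        out = intersect_cohorts(a, b, q_max=0.2)
        want = {g for g in genes if a.loc[g, "q"] <= 0.2 and b.loc[g, "q"] <= 0.2}
        assert set(out.index) == want


class TestDEU:
    def _toy_counts(self, rng, n_groups=20, bins_per_group=4, n=6, depth=2000):
        idx, groups = [], []
        rows = []
        for g in range(n_groups):
            props = rng.dirichlet(np.full(bins_per_group, 5.0))
            for b in range(bins_per_group):
                idx.append(f"g{g}:{b}")
                groups.append(f"g{g}")
                mu = depth * props[b]
                a = 0.02 + 2 / mu
                rows.append(rng.negative_binomial(1 / a, 1 / (1 + a * mu), 2 * n))
        counts = pd.DataFrame(
            rows, index=idx,
            columns=[f"m{i}" for i in range(n)] + [f"w{i}" for i in range(n)],
        )
        return counts, pd.Series(groups, index=idx), ["mut"] * n + ["wt"] * n

    def test_constant_fraction_portion_is_null(self):
        # a bin that is an exact constant fraction of its group in every
        # sample shows no usage change
        n = 8
        totals = np.array([1000, 1200, 800, 1500, 900, 1100, 1300, 1000] * 2)
        this = (0.25 * totals).astype(int)
        other = totals - this
        counts = pd.DataFrame(
            [this, other], index=["b1", "b2"],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        gm = pd.Series(["g", "g"], index=["b1", "b2"])
        res = deu_test(counts, gm, ["mut"] * n + ["wt"] * n)
        assert abs(res.loc["b1", "usage_log2fc"]) < 0.02
        assert res.loc["b1", "p"] > 0.5

    def test_single_portion_group_untested(self, rng):
        counts, gm, cond = self._toy_counts(rng, n_groups=3)
        counts.loc["solo"] = rng.integers(10, 100, counts.shape[1])
        gm.loc["solo"] = "solo_group"
        res = deu_test(counts, gm, cond)
        assert np.isnan(res.loc["solo", "p"])

    def test_significance_flag_boundary_semantics(self, rng):
        counts, gm, cond = self._toy_counts(rng)
        res = deu_test(counts, gm, cond)
        tested = res.dropna(subset=["p"])
        want = (tested["padj"] <= 0.05) & (tested["usage_log2fc"].abs() >= 0.5)
        assert (tested["significant"] == want).all()

    def test_sample_relabel_invariance(self, rng):
        counts, gm, cond = self._toy_counts(rng, n_groups=6)
        res1 = deu_test(counts, gm, cond)
        perm = rng.permutation(counts.shape[1])
        res2 = deu_test(
            counts.iloc[:, perm], gm,
            list(np.array(cond)[perm]), test_level="mut",
        )
        assert np.allclose(res1["p"].values, res2["p"].values, equal_nan=True,
                           atol=1e-8)


class TestPCA:
    def test_identical_samples_identical_scores(self, rng):
        base = rng.integers(1, 200, size=50)
        counts = pd.DataFrame({"a": base, "b": base, "c": base * 2})
        scores, _ = pca_top_variable(counts, top_n=50)
        # a and b are identical libraries; c differs only by depth,
        # which normalization removes
        assert np.allclose(scores.loc["a"], scores.loc["b"], atol=1e-8)

    def test_batch_adjustment_removes_additive_shift(self, rng):
        m, n = 200, 12
        base = rng.lognormal(4, 1, size=m)
        counts = np.vstack(
            [rng.poisson(base) for _ in range(n)]
        ).T.astype(float)
        batch = np.array(["A", "B"] * (n // 2))
        # pure per-gene additive shift on log scale for batch B
        shift = rng.normal(0, 2.0, size=m)
        counts[:, batch == "B"] *= 2.0 ** shift[:, None]
        df = pd.DataFrame(counts.astype(int),
                          columns=[f"s{i}" for i in range(n)])
        s_raw, _ = pca_top_variable(df, top_n=200, batch=None)
        s_adj, _ = pca_top_variable(df, top_n=200, batch=batch)

        def sep(scores):
            a = scores.values[batch == "A", 0]
            b = scores.values[batch == "B", 0]
            pooled = np.sqrt((a.var() + b.var()) / 2)
            return abs(a.mean() - b.mean()) / pooled

        assert sep(s_raw) > 3.0  # batch dominates PC1 before adjustment
        assert sep(s_adj) < 1.0  # indistinguishable from noise after

    def test_explained_variance_bounded(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(100, 8)))
        x = np.log2(counts.values / estimate_size_factors(counts).values + 1)
        scores, ratio = pca_top_variable(counts, top_n=50)
        assert ratio.sum() <= 1.0 + 1e-9
        assert (np.diff(ratio) <= 1e-12).all()

    def test_top_n_larger_than_rows_warns(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 5)))
        with pytest.warns(UserWarning, match="using all"):
            pca_top_variable(counts, top_n=5000)


class TestClusterHeatmap:
    def test_z_rows_standardized_and_blocks_recovered(self, rng):
        n = 12
        samples = [f"s{i}" for i in range(n)]
        block = np.array([1] * (n // 2) + [0] * (n // 2))
        rows, names = [], []
        for b in range(10):
            mu = 100 + 80 * (block if b < 5 else 1 - block)
            rows.append(rng.poisson(mu))
            names.append(f"bin{b}")
        counts = pd.DataFrame(rows, index=names, columns=samples)
        deu = pd.DataFrame({"significant": True}, index=names)
        z, sample_order, bin_order = cluster_deu_heatmap_input(
            deu, counts, size_factors=pd.Series(1.0, index=samples)
        )
        assert np.allclose(z.values.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.values.std(axis=1), 1, atol=1e-9)
        # leaf order separates the two planted bin blocks
        first_half = set(bin_order[:5])
        assert first_half in ({0, 1, 2, 3, 4}, {5, 6, 7, 8, 9})

    def test_single_bin_trivial_order(self, rng):
        counts = pd.DataFrame(
            [rng.integers(10, 100, 6)], index=["b"], columns=list("abcdef")
        )
        deu = pd.DataFrame({"significant": [True]}, index=["b"])
        z, s_ord, b_ord = cluster_deu_heatmap_input(
            deu, counts, size_factors=pd.Series(1.0, index=counts.columns)
        )
        assert list(b_ord) == [0]

    def test_constant_row_dropped_with_warning(self):
        counts = pd.DataFrame(
            {"a": [5, 10], "b": [5, 20], "c": [5, 30]}, index=["flat", "var"]
        )
        deu = pd.DataFrame({"significant": [True, True]}, index=["flat", "var"])
        with pytest.warns(UserWarning, match="constant"):
            z, _, _ = cluster_deu_heatmap_input(
                deu, counts, size_factors=pd.Series(1.0, index=counts.columns)
            )
        assert list(z.index) == ["var"]
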