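"""RPKM, NB differential expression, clustering and GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from k27compare.expression_analysis import (
    cluster_expression_groups,
    cluster_tissues,
    de_test,
    gsea,
    rpkm,
    sample_correlation_clustering,
    tissue_specificity_rank,
)
from k27compare.synthetic_data import (
    generate_genome,
    simulate_expression,
    simulate_tracks,
)
from tests.conftest import small_config


class TestRpkm:
    def test_worked_example_and_scaling(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["g1", "g2"])
        lengths = pd.Series([2000, 500], index=["g1", "g2"])
        totals = pd.Series([10_000_000], index=["s1"])
        out = rpkm(counts, lengths, totals)
        assert out.loc["g1", "s1"] == 5.0
        assert out.loc["g2", "s1"] == 0.0
        doubled = rpkm(counts, lengths, totals * 2)
        assert (doubled == out / 2).all().all()

    def test_missing_length_is_error(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError, match="g1"):
            rpkm(counts, pd.Series(dtype=float), pd.Series([1e6], index=["s1"]))


class TestDeTest:
    def test_identical_conditions_no_calls(self):
        counts = pd.DataFrame(
            {"a1": [100, 50], "a2": [100, 50], "b1": [100, 50], "b2": [100, 50]},
            index=["g1", "g2"],
        )
        res = de_test(counts[["a1", "a2"]], counts[["b1", "b2"]])
        assert (res.table["log2fc"] == 0).all()
        assert not res.table["de"].any()

    def test_fourfold_change_log2fc(self):
        counts = pd.DataFrame(
            {"a1": [100], "a2": [100], "b1": [25], "b2": [25]}, index=["g1"]
        )
        # equal size factors are anchored by a majority of stable genes
        for g in range(2, 6):
            counts.loc[f"g{g}"] = [1000, 1000, 1000, 1000]
        res = de_test(counts[["a1", "a2"]], counts[["b1", "b2"]])
        assert res.table.loc["g1", "log2fc"] == pytest.approx(
            np.log2(100.5 / 25.5), abs=0.15
        )

    def test_all_zero_gene(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 10], "b1": [0, 10], "b2": [0, 10]},
            index=["g0", "g1"],
        )
        res = de_test(counts[["a1", "a2"]], counts[["b1", "b2"]])
        assert res.table.loc["g0", "pvalue"] == 1.0
        assert res.table.loc["g0", "log2fc"] == 0.0

    def test_sensitivity_and_null_rate_on_generator(self):
        config = small_config(
            n_genes=300, n_peaks=60, samples=("mut",),
            chrom_lengths={"chr1": 500_000, "chr2": 300_000},
            peak_classes=[], expression_fold=4.0, seed=21,
        )
        genome = generate_genome(config)
        _, truth = simulate_tracks(genome, config)
        # force DE truth for 60 genes (targets of peaks exist but no
        # effects were configured) -> build explicit truth
        truth.genes.loc[truth.genes.index[:60], "de_mut"] = "up"
        counts = simulate_expression(genome, truth, config)
        mut = counts[["mut_rep1", "mut_rep2"]]
        wt = counts[["wt_rep1", "wt_rep2"]]
        res = de_test(mut, wt)
        de_true = truth.genes["de_mut"] == "up"
        sens = res.table.loc[de_true.values, "de"].mean()
        fpr = res.table.loc[~de_true.values, "de"].mean()
        assert sens >= 0.9
        assert fpr <= 0.07

    def test_literal_criteria_flag_inverts(self):
        counts = pd.DataFrame(
            {"a1": [400, 100], "a2": [410, 100], "b1": [100, 100], "b2": [90, 100]},
            index=["g1", "g2"],
        )
        res = de_test(counts[["a1", "a2"]], counts[["b1", "b2"]],
                      literal_criteria=True)
        assert not res.table.loc["g1", "de"]  # |log2fc| > 1 excluded literally


class TestClustering:
    def test_three_archetype_patterns_recovered(self):
        rng = np.random.default_rng(0)
        patterns = {
            0: [2.0, 2.0, 0.0, 0.0],  # up in clf/lhp1 mutants
            1: [0.0, 0.0, 2.0, 2.0],  # up in bmi1/ring1 mutants
            2: [-2.0, -2.0, -2.0, -2.0],  # down everywhere
        }
        rows, labels = [], []
        for lab, pat in patterns.items():
            for _ in range(30):
                rows.append(np.array(pat) + rng.normal(0, 0.2, 4))
                labels.append(lab)
        mat = pd.DataFrame(rows, columns=["clf", "lhp1", "bmi1", "ring1"])
        groups, _ = cluster_expression_groups(mat, k=3, seed=1)
        assert adjusted_rand_score(labels, groups) >= 0.9

    def test_sample_correlation_structure(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        mat = pd.DataFrame(
            {
                "a1": base + rng.normal(0, 0.1, 200),
                "a2": base + rng.normal(0, 0.1, 200),
                "b": -base + rng.normal(0, 0.1, 200),
            }
        )
        link, corr = sample_correlation_clustering(mat)
        # brute-force Pearson agreement
        expected = np.corrcoef(mat["a1"], mat["a2"])[0, 1]
        assert corr.loc["a1", "a2"] == pytest.approx(expected, abs=1e-12)
        # a1/a2 merge first; anti-correlated b joins last at height ~2
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[-1, 2] > 1.5

    def test_duplicated_samples_merge_at_zero(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=50)
        mat = pd.DataFrame({"a": col, "b": col, "c": rng.normal(size=50)})
        link, _ = sample_correlation_clustering(mat)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_sample_is_error(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            sample_correlation_clustering(mat)

    def test_tissue_archetypes_recovered_and_order_invariant(self):
        rng = np.random.default_rng(3)
        archetypes = rng.normal(0, 3, size=(40, 8))
        cols, truth = {}, {}
        for t in range(8):
            for r in range(3):
                name = f"t{t}_{r}"
                cols[name] = archetypes[:, t] + rng.normal(0, 0.3, 40)
                truth[name] = t
        expr = pd.DataFrame(cols)
        labels = cluster_tissues(expr, k=8, seed=4)
        assert adjusted_rand_score(
            [truth[c] for c in expr.columns], labels.to_numpy()
        ) == 1.0
        shuffled = expr[list(expr.columns[::-1])]
        labels2 = cluster_tissues(shuffled, k=8, seed=4)
        # same partition under column permutation
        assert adjusted_rand_score(
            labels.reindex(shuffled.columns).to_numpy(), labels2.to_numpy()
        ) == 1.0


class TestTissueSpecificity:
    def test_group_specific_gene_ranks_first(self):
        expr = pd.DataFrame(
            {
                "flower1": [100.0, 10, 10],
                "flower2": [90.0, 10, 10],
                "leaf": [2.0, 10, 10],
                "root": [2.0, 10, 10],
            },
            index=["gF", "g1", "g2"],
        )
        ranked = tissue_specificity_rank(expr, ["flower1", "flower2"])
        assert ranked.index[0] == "gF"

    def test_uniform_gene_scores_zero_before_standardization(self):
        expr = pd.DataFrame(
            {"a": [10.0, 10], "b": [10.0, 10], "c": [10.0, 10]},
            index=["g1", "g2"],
        )
        ranked = tissue_specificity_rank(expr, ["a"])
        assert (ranked == 0).all()

    def test_low_expression_filter_and_bruteforce(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.uniform(2, 50, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"t{j}" for j in range(6)],
        )
        expr.iloc[0] = 0.5  # removed by the mean < 2 filter
        ranked = tissue_specificity_rank(expr, ["t0", "t1"])
        assert "g0" not in ranked.index
        logx = np.log2(expr.iloc[1:] + 1)
        raw = logx[["t0", "t1"]].mean(axis=1) - logx[
            ["t2", "t3", "t4", "t5"]
        ].mean(axis=1)
        z = (raw - raw.mean()) / raw.std(ddof=0)
        pd.testing.assert_series_equal(
            ranked, z.sort_values(ascending=False), check_names=False
        )

    def test_group_covering_all_tissues_is_error(self):
        expr = pd.DataFrame({"a": [5.0, 5], "b": [5.0, 5]})
        with pytest.raises(ValueError):
            tissue_specificity_rank(expr, ["a", "b"])


class TestGsea:
    def _ranked(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    def test_top5_unweighted_closed_form(self):
        ranked = self._ranked()
        res = gsea(ranked, {f"g{i}" for i in range(5)}, n_perm=100, seed=1,
                   weight=0.0)
        assert res.es == pytest.approx(1.0)
        assert set(res.leading_edge) == {f"g{i}" for i in range(5)}

    def test_reversed_ranking_negates_es(self):
        ranked = self._ranked(seed=2)
        gene_set = {f"g{i}" for i in range(10)}
        fwd = gsea(ranked, gene_set, n_perm=50, seed=3, weight=0.0)
        rev = gsea(ranked[::-1], gene_set, n_perm=50, seed=3, weight=0.0)
        assert fwd.es == pytest.approx(-rev.es, abs=1e-9)

    def test_null_calibration(self):
        ranked = self._ranked(seed=4)
        rng = np.random.default_rng(5)
        n_nonsig = 0
        n_sim = 40
        for i in range(n_sim):
            gene_set = set(rng.choice(ranked.index, 15, replace=False))
            res = gsea(ranked, gene_set, n_perm=200, seed=int(i), weight=1.0)
            n_nonsig += res.pvalue > 0.05
        assert n_nonsig / n_sim >= 0.9
        assert 1 / 201 <= res.pvalue <= 1.0

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError):
            gsea(self._ranked(), {"absent"}, n_perm=10, seed=0)
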