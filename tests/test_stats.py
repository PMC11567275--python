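"""Diversity, ordination, PERMANOVA, Procrustes and gated comparisons.

scikit-bio and scipy serve as independent cross-check oracles where they
implement the same statistic.
"""

import math

import numpy as np
import pandas as pd
import pytest

import dualvirome as dv
from dualvirome.stats import DistanceMatrix, permanova_null_pvalues


class TestAlphaDiversity:
    def table(self, counts):
        return pd.DataFrame({"s1": counts})

    def test_uniform_closed_forms(self):
        t = self.table([5, 5, 5, 5])
        assert dv.alpha_diversity(t, "observed")["s1"] == 4
        assert dv.alpha_diversity(t, "shannon")["s1"] == pytest.approx(math.log(4))
        assert dv.alpha_diversity(t, "simpson")["s1"] == pytest.approx(0.75)

    def test_chao1_no_singletons_equals_observed(self):
        t = self.table([3, 4, 5])
        assert dv.alpha_diversity(t, "chao1")["s1"] == 3

    def test_chao1_hand_formula(self):
        # S=5, F1=2, F2=2 -> 5 + 4/(2*2) = 6
        t = self.table([1, 1, 2, 2, 3])
        assert dv.alpha_diversity(t, "chao1")["s1"] == pytest.approx(6.0)

    def test_empty_sample_zero(self):
        t = self.table([0, 0])
        for metric in ("observed", "chao1", "ace", "shannon", "simpson"):
            assert dv.alpha_diversity(t, metric)["s1"] == 0.0

    @pytest.mark.parametrize("metric,skbio_name", [
        ("chao1", "chao1"), ("shannon", "shannon"), ("simpson", "simpson"),
        ("ace", "ace"),
    ])
    def test_against_scikit_bio(self, metric, skbio_name):
        from skbio.diversity import alpha as ska
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=40)
        counts[:5] = 1  # ensure singletons
        ours = dv.alpha_diversity(pd.DataFrame({"s": counts}), metric)["s"]
        func = getattr(ska, skbio_name)
        if metric == "shannon":
            theirs = func(counts, base=math.e)
        elif metric == "chao1":
            theirs = func(counts, bias_corrected=False)  # classic form
        else:
            theirs = func(counts)
        if metric == "simpson":
            theirs = float(theirs)  # skbio simpson is 1 - dominance, same form
        assert ours == pytest.approx(float(theirs), rel=1e-9)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            dv.alpha_diversity(self.table([1]), "faith_pd")


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = pd.DataFrame({"a": [1, 2], "b": [1, 2]})
        assert dv.bray_curtis(t).data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = pd.DataFrame({"a": [1, 0], "b": [0, 3]})
        assert dv.bray_curtis(t).data[0, 1] == 1.0

    def test_hand_formula(self):
        t = pd.DataFrame({"a": [1, 1], "b": [1, 3]})
        assert dv.bray_curtis(t).data[0, 1] == pytest.approx(1 / 3)

    def test_two_zero_samples_flagged(self):
        t = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        dm = dv.bray_curtis(t)
        assert dm.data[0, 1] == 0.0
        assert dm.flags["zero_sample_pairs"] == [("a", "b")]

    def test_against_scipy(self):
        from scipy.spatial.distance import braycurtis
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.integers(0, 50, size=(20, 5)),
                         columns=list("abcde"))
        dm = dv.bray_curtis(t)
        for i, ci in enumerate(t.columns):
            for j, cj in enumerate(t.columns):
                assert dm.data[i, j] == pytest.approx(
                    braycurtis(t[ci], t[cj]) if i != j else 0.0)


class TestPcoa:
    def test_two_samples_unit_distance(self):
        dm = DistanceMatrix(ids=["a", "b"], data=np.array([[0, 1], [1, 0.0]]))
        coords = dv.pcoa(dm).coordinates
        assert sorted(np.abs(coords["PC1"]).tolist()) == pytest.approx([0.5, 0.5])

    def test_euclidean_distances_recovered_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = dv.pcoa(DistanceMatrix(ids=list("abcdef"), data=d))
        c = res.coordinates.values
        d_rec = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        assert np.allclose(d_rec, d, atol=1e-8)

    def test_three_equidistant_samples_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = dv.pcoa(DistanceMatrix(ids=list("abc"), data=d))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_against_scikit_bio(self):
        import skbio
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.integers(1, 40, size=(25, 6)))
        dm = dv.bray_curtis(t)
        ours = dv.pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, ids=[str(i) for i in dm.ids]))
        n_pos = len(ours.eigenvalues)
        assert np.allclose(ours.eigenvalues,
                           theirs.eigvals.values[:n_pos], atol=1e-8)
        for k in range(min(3, n_pos)):
            a = ours.coordinates.values[:, k]
            b = theirs.samples.values[:, k]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)  # sign-free


class TestPermanova:
    def labelled_table(self, seed=0, effect=0.0, n=8):
        rng = np.random.default_rng(seed)
        labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        x = np.exp(rng.normal(0, 1, size=(30, 1))
                   + rng.normal(0, 0.8, size=(30, n))
                   + effect * (labels == "b"))
        return pd.DataFrame(np.round(x * 20)), labels

    def test_seed_determinism(self):
        t, labels = self.labelled_table(1)
        dm = dv.bray_curtis(t)
        p1 = dv.permanova(dm, labels, n_perm=499, seed=11)
        p2 = dv.permanova(dm, labels, n_perm=499, seed=11)
        assert p1.p_value == p2.p_value and p1.statistic == p2.statistic

    def test_exhaustive_floor_one_over_35(self):
        """4+4 design with maximal separation: exact p = 1/35."""
        t, labels = self.labelled_table(2, effect=8.0)
        res = dv.permanova(dv.bray_curtis(t), labels, exhaustive=True)
        assert res.p_value == pytest.approx(1 / 35)
        assert res.n_permutations == 70  # distinct label assignments

    def test_exhaustive_matches_brute_force_oracle(self):
        """Exact p equals direct enumeration over all C(6,3) assignments."""
        import itertools
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.integers(1, 40, size=(15, 6)))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = dv.bray_curtis(t)
        res = dv.permanova(dm, labels, exhaustive=True)
        from dualvirome.stats import _pseudo_f
        d2 = dm.data ** 2
        f_obs, _ = _pseudo_f(d2, labels, 2)
        fs = [
            _pseudo_f(d2, np.array(p), 2)[0]
            for p in set(itertools.permutations(labels))
        ]
        expected = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.p_value == pytest.approx(expected)

    def test_statistic_matches_scikit_bio(self):
        import skbio
        t, labels = self.labelled_table(6, effect=1.0)
        dm = dv.bray_curtis(t)
        ours = dv.permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=[str(i) for i in dm.ids]),
            grouping=list(labels), permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_single_group_rejected(self):
        t, _ = self.labelled_table(7)
        with pytest.raises(ValueError):
            dv.permanova(dv.bray_curtis(t), ["a"] * 8)

    def test_detects_planted_group_effect(self):
        t, labels = self.labelled_table(8, effect=3.0)
        res = dv.permanova(dv.bray_curtis(t), labels, n_perm=999, seed=1)
        assert res.p_value <= 0.05
        assert res.effect > 0.3  # R2

    def test_detects_simulated_diet_effect_across_seeds(self):
        """The planted diet shift is PERMANOVA-detectable at n=4/group."""
        import dataclasses
        from dualvirome.simulate import StudyDesign
        hits = 0
        for seed in range(15):
            community = dataclasses.replace(dv.CommunityConfig(), effect_log2fc=4.0)
            gt = dv.build_community(community, seed=seed,
                                    design=StudyDesign(groups=["low", "high"],
                                                       seed=seed))
            cov = dv.simulate_coverage(gt, seed=seed)
            bulk = cov[cov["assay"] == "bulk"]
            table = dv.build_feature_table(
                bulk, "bacterial",
                feature_ids=[b.species_id for b in gt.bacteria])
            labels = gt.design.sample_frame().set_index("sample_id") \
                .loc[table.samples, "group"].values
            res = dv.permanova(dv.bray_curtis(table.counts), labels,
                               n_perm=999, seed=seed)
            hits += res.p_value <= 0.05
        assert hits >= 14

    def test_null_type_one_error_with_discreteness_floor(self):
        """At 4+4 the rejection rate is bounded by the 1/35 partition floor;
        a quick 300-rep check keeps it in a loose sanity band."""
        p = permanova_null_pvalues(4, 25, 300, n_perm=199, seed=3)
        rate = (p <= 0.05).mean()
        assert 0.005 <= rate <= 0.08


class TestProcrustes:
    def config(self, seed=0, n=8, k=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, k)),
                            index=[f"s{i}" for i in range(n)])

    def test_rotated_scaled_copy_perfect_fit(self):
        x = self.config(1)
        theta = 0.7
        rot = np.eye(3)
        rot[:2, :2] = [[math.cos(theta), -math.sin(theta)],
                       [math.sin(theta), math.cos(theta)]]
        y = pd.DataFrame((x.values @ rot) * 3.7 + 1.2, index=x.index)
        res = dv.procrustes_test(x, y, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect == pytest.approx(1.0)

    def test_m2_matches_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes
        x, y = self.config(2), self.config(3)
        res = dv.procrustes_test(x, y, n_perm=9, seed=0)
        _, _, disparity = scipy_procrustes(x.values, y.values)
        assert res.statistic == pytest.approx(disparity, rel=1e-9)

    def test_independent_noise_not_significant(self):
        hits = 0
        for seed in range(100):
            x, y = self.config(seed * 2 + 10), self.config(seed * 2 + 11)
            res = dv.procrustes_test(x, y, n_perm=199, seed=seed)
            hits += res.p_value > 0.05
        assert hits >= 90  # >= 90% of null runs stay non-significant

    def test_joint_relabeling_invariance(self):
        x, y = self.config(4), self.config(5)
        perm = np.random.default_rng(0).permutation(len(x))
        m2 = dv.procrustes_test(x, y, n_perm=9, seed=0).statistic
        m2_perm = dv.procrustes_test(x.iloc[perm], y.iloc[perm],
                                     n_perm=9, seed=0).statistic
        assert m2 == pytest.approx(m2_perm)

    def test_mismatched_ids_rejected(self):
        x = self.config(6)
        y = self.config(7)
        y.index = [f"t{i}" for i in range(len(y))]
        with pytest.raises(ValueError):
            dv.procrustes_test(x, y)


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        res = dv.group_compare([1, 2, 3, 4, 1, 2, 3, 4],
                               ["a"] * 4 + ["b"] * 4)
        assert res.p_value == 1.0

    def test_skewed_data_takes_rank_branch(self):
        rng = np.random.default_rng(0)
        values = np.exp(rng.normal(0, 3, size=40))  # heavily lognormal
        labels = ["a"] * 20 + ["b"] * 20
        res = dv.group_compare(values, labels)
        assert res.method.startswith("wilcoxon")

    def test_normal_data_takes_t_branch(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, size=40)
        res = dv.group_compare(values, ["a"] * 20 + ["b"] * 20)
        assert res.method == "t_test"

    def test_exact_wilcoxon_complete_separation_4v4(self):
        """All 'b' above all 'a': two-sided exact p = 2/70."""
        values = np.exp([0.0, 0.1, 0.2, 0.3, 5.0, 5.4, 5.8, 6.2]) + \
            np.array([0, 7, 0, 11, 0, 13, 0, 17]) * 1e-4
        res = dv.group_compare(values, ["a"] * 4 + ["b"] * 4)
        if res.method.startswith("wilcoxon"):
            assert res.p_value == pytest.approx(2 / 70)
        else:  # normality gate may pass for an 8-point sample; t also rejects
            assert res.p_value < 0.01

    def test_three_groups_rank_branch_runs_dunn(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([np.exp(rng.normal(0, 2, 10)),
                                 np.exp(rng.normal(1, 2, 10)),
                                 np.exp(rng.normal(4, 2, 10))])
        labels = np.repeat(["a", "b", "c"], 10)
        res = dv.group_compare(values, labels)
        assert res.method in ("kruskal_dunn", "anova_tukey")
        if res.method == "kruskal_dunn":
            assert len(res.extras["dunn"]) == 3  # all pairs

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            dv.group_compare([1, 2, 3], ["a", "a", "b"])


class TestCorrelateFdr:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        frame = dv.correlate_fdr({"pos": (x, x), "neg": (x, -x)},
                                 method="pearson")
        assert frame.loc["pos", "r"] == pytest.approx(1.0)
        assert frame.loc["neg", "r"] == pytest.approx(-1.0)

    def test_bh_all_equal_pvalues_unchanged(self):
        """m equal p-values: BH adjusts each to p * m / m = p."""
        rng = np.random.default_rng(3)
        # build 10 pairs with identical p by reusing the same data
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        pairs = {f"pair{i}": (x, y) for i in range(10)}
        frame = dv.correlate_fdr(pairs, method="spearman")
        assert np.allclose(frame["p_adj"], frame["p"])

    def test_zero_variance_flagged(self):
        frame = dv.correlate_fdr({"flat": (np.ones(5), np.arange(5.0))})
        assert frame.loc["flat", "flag"] == "zero_variance"
        assert np.isnan(frame.loc["flat", "r"])

    def test_df_reported_as_n_minus_two(self):
        frame = dv.correlate_fdr({"x": (np.arange(8.0), np.arange(8.0) ** 2)})
        assert frame.loc["x", "df"] == 6
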