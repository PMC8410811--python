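"""Alpha-diversity estimator tests: frozen hand-computed oracles,
scikit-bio cross-checks, and sampling-theory properties."""

import math

import numpy as np
import pytest
import skbio.diversity.alpha as skalpha
from hypothesis import given
from hypothesis import strategies as st

from amdtox import diversity as dv
from amdtox.exceptions import EmptySampleError
from amdtox.io import read_tree

count_vectors = st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=40).filter(
    lambda c: sum(c) > 1
)


class TestFrequencyCounts:
    def test_hand_tabulation(self):
        fc = dv.frequency_counts([5, 1, 1, 2])
        assert fc.f == {1: 2, 2: 1, 5: 1}
        assert fc.s_obs == 4 and fc.n == 9
        single = dv.frequency_counts([10])
        assert single.f == {10: 1} and single.s_obs == 1 and single.n == 10

    def test_empty_sample_raises(self):
        with pytest.raises(EmptySampleError):
            dv.frequency_counts([0, 0, 0])

    @given(count_vectors)
    def test_conservation_identities(self, counts):
        fc = dv.frequency_counts(counts)
        assert sum(k * v for k, v in fc.f.items()) == fc.n
        assert sum(fc.f.values()) == fc.s_obs


class TestRichness:
    def test_chao1_frozen_example(self):
        fc = dv.FrequencyCounts(f={1: 4, 2: 2, 9: 4}, s_obs=10, n=44)
        assert dv.chao1(fc)["estimate"] == pytest.approx(12.0)

    def test_chao1_no_singletons_equals_s_obs(self):
        fc = dv.frequency_counts([3, 3, 7])
        res = dv.chao1(fc)
        assert res["estimate"] == 3 == res["lci"] == res["hci"]

    def test_jackknife_frozen_example(self):
        fc = dv.FrequencyCounts(f={1: 5, 19: 5}, s_obs=10, n=100)
        assert dv.jackknife1(fc) == pytest.approx(14.95)
        with pytest.raises(ValueError):
            dv.jackknife1(dv.FrequencyCounts(f={1: 1}, s_obs=1, n=1))

    def test_ace_hand_formula_oracle(self):
        # counts {1,1,2,3,12}: S_rare=4, S_abund=1, N_rare=7, F1=2,
        # C = 5/7, gamma^2 = (4/C)*8/42 - 1 = 1/15,
        # ACE = 1 + 4/C + (2/C)*gamma^2 = 6.78667 (independent hand chain)
        c = 5.0 / 7.0
        gamma2 = (4 / c) * (8 / 42.0) - 1
        oracle = 1 + 4 / c + (2 / c) * gamma2
        fc = dv.frequency_counts([1, 1, 2, 3, 12])
        assert dv.ace(fc)["estimate"] == pytest.approx(oracle, rel=1e-12)

    def test_ace_all_abundant_equals_s_obs(self):
        fc = dv.frequency_counts([11, 12, 50])
        assert dv.ace(fc)["estimate"] == 3.0

    def test_ace_all_singletons_falls_back_to_chao1(self):
        fc = dv.frequency_counts([1, 1, 1])
        res = dv.ace(fc)
        assert res.get("fallback") == "chao1"
        assert res["estimate"] == dv.chao1(fc, ci=False)["estimate"]

    @given(count_vectors)
    def test_estimates_match_scikit_bio(self, counts):
        arr = np.asarray(counts)
        if arr[arr > 0].sum() == 0:
            return
        fc = dv.frequency_counts(arr)
        assert dv.chao1(fc)["estimate"] == pytest.approx(
            float(skalpha.chao1(arr, bias_corrected=True)), rel=1e-9
        )
        pos = arr[arr > 0]
        rare = pos[pos <= 10]
        if rare.size and rare.sum() != (pos == 1).sum():  # skbio ACE defined
            assert dv.ace(fc)["estimate"] == pytest.approx(
                float(skalpha.ace(pos)), rel=1e-9
            )

    @given(count_vectors)
    def test_richness_estimators_bounded_below_by_s_obs(self, counts):
        fc = dv.frequency_counts(counts)
        res = dv.chao1(fc)
        assert res["estimate"] >= fc.s_obs - 1e-9
        assert res["lci"] - 1e-9 <= res["estimate"] <= res["hci"] + 1e-9
        assert dv.jackknife1(fc) >= fc.s_obs - 1e-9
        assert dv.ace(fc)["estimate"] >= fc.s_obs - 1e-6
        if fc[1] == 0:
            assert res["estimate"] == fc.s_obs
            assert dv.jackknife1(fc) == fc.s_obs

    def test_chao1_consistent_under_deep_sampling(self):
        from amdtox.synthetic import CommunityScenario, gen_otu_table

        t = gen_otu_table(CommunityScenario(s_true=80, sigma_log=0.8, depth=40000, seed=5))
        fc = dv.frequency_counts(t.iloc[:, 0].to_numpy())
        assert fc[1] == 0  # every taxon seen repeatedly
        assert dv.chao1(fc)["estimate"] == 80


class TestDiversityIndices:
    def test_shannon_values(self):
        assert dv.shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))
        assert dv.shannon([17]) == 0.0
        assert dv.shannon([2, 2]) == pytest.approx(0.693, abs=1e-3)

    def test_shannon_bootstrap_interval_brackets_estimate(self, toy_counts):
        res = dv.shannon(toy_counts, ci=True, n_boot=200, random_state=0)
        assert res["lci"] <= res["estimate"] + 0.1
        assert res["hci"] >= res["lci"]

    def test_np_shannon_term_by_term_oracle(self):
        counts, n = [4, 3, 2, 1], 10
        c_hat = 1 - 1 / n
        oracle = 0.0
        for ci in counts:
            p = c_hat * ci / n
            oracle -= p * math.log(p) / (1 - (1 - p) ** n)
        assert dv.np_shannon(counts) == pytest.approx(oracle, rel=1e-12)

    def test_np_shannon_all_singletons_undefined(self):
        assert math.isnan(dv.np_shannon([1, 1, 1]))

    def test_np_shannon_converges_to_plug_in_without_singletons(self):
        # with F1 = 0 the coverage shrinkage vanishes and the remaining
        # Horvitz-Thompson correction decays with depth
        counts = np.array([200, 300, 500])
        assert dv.np_shannon(counts) == pytest.approx(dv.shannon(counts), abs=1e-6)

    def test_np_shannon_exceeds_plug_in_on_skewed_community(self):
        from amdtox.synthetic import CommunityScenario, gen_otu_table

        t = gen_otu_table(CommunityScenario(s_true=400, sigma_log=1.5, depth=3000, seed=11))
        counts = t.iloc[:, 0].to_numpy()
        assert dv.np_shannon(counts) >= dv.shannon(counts)

    @given(count_vectors)
    def test_shannon_bound_and_permutation_invariance(self, counts):
        arr = np.asarray(counts)
        arr = arr[arr > 0]
        if arr.sum() == 0:
            return
        h = dv.shannon(arr)
        assert h <= math.log(arr.size) + 1e-9
        assert dv.shannon(arr[::-1]) == pytest.approx(h, rel=1e-12)

    def test_simpson(self):
        assert dv.simpson([9]) == (1.0, 1.0)
        lam, inv = dv.simpson([3, 3, 3, 3])
        assert lam == pytest.approx(0.25) and inv == pytest.approx(4.0)
        assert dv.simpson([1, 1, 2])[0] == pytest.approx(0.375)

    def test_goods_coverage(self):
        assert dv.goods_coverage(dv.frequency_counts([2, 3, 4])) == 100.0
        assert dv.goods_coverage(
            dv.FrequencyCounts(f={1: 2, 49: 2}, s_obs=4, n=100)
        ) == pytest.approx(98.0)
        assert dv.goods_coverage(
            dv.FrequencyCounts(f={1: 3, 197: 1}, s_obs=4, n=200)
        ) == pytest.approx(98.5)


class TestRarefaction:
    def test_endpoints(self, toy_counts):
        s_obs = (toy_counts > 0).sum()
        n = toy_counts.sum()
        out = dv.rarefaction_curve(toy_counts, [1, n])
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(s_obs)

    def test_monotone_and_concave(self, toy_counts):
        depths = np.arange(1, toy_counts.sum() + 1)
        curve = dv.rarefaction_curve(toy_counts, depths)
        diffs = np.diff(curve)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_matches_monte_carlo_subsampling(self, toy_counts):
        # independent oracle: 50,000 explicit without-replacement draws
        rng = np.random.default_rng(123)
        labels = np.repeat(np.arange(toy_counts.size), toy_counts)
        n, m, draws = labels.size, 7, 50_000
        richness = np.empty(draws)
        for i in range(draws):
            sub = rng.choice(n, size=m, replace=False)
            richness[i] = np.unique(labels[sub]).size
        mc_mean = richness.mean()
        mc_se = richness.std(ddof=1) / math.sqrt(draws)
        exact = dv.rarefaction_curve(toy_counts, [m])[0]
        assert abs(exact - mc_mean) <= 3 * mc_se

    def test_depth_beyond_n_raises(self, toy_counts):
        with pytest.raises(ValueError):
            dv.rarefaction_curve(toy_counts, [toy_counts.sum() + 1])


class TestFaithPD:
    def test_hand_path_union(self, toy_newick):
        tree = read_tree(toy_newick)
        # A:1 + inner(0.5) + C:3 + inner(2) + E:4 = 10.5
        assert dv.faith_pd(["A", "C", "E"], tree) == pytest.approx(10.5)

    def test_star_tree_unit_branches(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(A:1,B:1,C:1,D:1);\n")
        assert dv.faith_pd(["A", "C"], read_tree(p)) == pytest.approx(2.0)

    def test_all_tips_is_total_length(self, toy_newick):
        tree = read_tree(toy_newick)
        assert dv.faith_pd(list("ABCDE"), tree) == pytest.approx(13.5)

    def test_matches_scikit_bio(self, tmp_path):
        # bifurcating root, as the reference implementation requires
        p = tmp_path / "rooted.nwk"
        p.write_text("((A:1,B:2):0.5,((C:3,D:1):2,E:4):0.1);\n")
        tree = read_tree(p)
        for observed, vec in [(["B", "D"], [0, 1, 0, 1, 0]),
                              (["A", "E"], [1, 0, 0, 0, 1]),
                              (list("ABCDE"), [1] * 5)]:
            mine = dv.faith_pd(observed, tree)
            ref = skalpha.faith_pd(vec, taxa=list("ABCDE"), tree=tree)
            assert mine == pytest.approx(float(ref))

    def test_missing_tip_named(self, toy_newick):
        with pytest.raises(KeyError, match="Zz"):
            dv.faith_pd(["Zz"], read_tree(toy_newick))


class TestAlphaDiversityEstimator:
    def test_report_invariants_at_study_scale(self):
        # a community at amplicon depth: coverage high, richness estimators
        # bracketed, bounds ordered
        from amdtox.synthetic import CommunityScenario, gen_otu_table

        table = gen_otu_table(CommunityScenario(s_true=2500, sigma_log=2.0,
                                                depth=26160, seed=3))
        est = dv.AlphaDiversity(n_boot=100, random_state=0).fit(table)
        row = est.report_.iloc[0]
        assert row["n_reads"] == 26160
        assert 0 <= row["goods_coverage_pct"] <= 100
        assert row["chao1"] >= row["s_obs"]
        assert row["ace"] >= row["s_obs"]
        assert row["jackknife1"] >= row["s_obs"]
        assert row["chao1_lci"] <= row["chao1"] <= row["chao1_hci"]
        assert row["shannon"] <= math.log(row["s_obs"])
        assert row["np_shannon"] >= row["shannon"]
        assert 0 < row["simpson_dominance"] < 1
        assert row["inv_simpson"] == pytest.approx(1 / row["simpson_dominance"])

    def test_single_otu_sample(self):
        import pandas as pd

        est = dv.AlphaDiversity(n_boot=10, random_state=0).fit(
            pd.DataFrame({"s": [50]}, index=["otu1"])
        )
        row = est.report_.iloc[0]
        assert row["s_obs"] == 1 and row["shannon"] == 0.0
        assert row["goods_coverage_pct"] == 100.0
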