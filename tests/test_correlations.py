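"""Multi-layer correlation analysis tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, ttest_ind

from glycotyper.correlations import (
    count_upregulated,
    enzyme_igp_matrix,
    flag_correlation_compare,
    gene_wise_layer_correlation,
    sample_wise_concordance,
    spearman,
)


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(0, 1, 20)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_manual_rank_computation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_warns_nan(self):
        with pytest.warns(UserWarning):
            out = spearman([1.0, 2.0], [2.0, 1.0])
        assert np.isnan(out)

    def test_nan_pairs_ignored(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        assert spearman(x, y) == pytest.approx(1.0)


@pytest.fixture()
def linked_layers(rng):
    samples = [f"s{i}" for i in range(12)]
    a = pd.DataFrame(rng.normal(0, 1, (8, 12)),
                     index=[f"f{i}" for i in range(8)], columns=samples)
    b = a.copy()
    b.index = [f"p{i}" for i in range(8)]
    links = {f"f{i}": f"p{i}" for i in range(8)}
    return a, b, links


class TestSampleWiseConcordance:
    def test_identical_layers_give_one(self, linked_layers):
        a, b, links = linked_layers
        rho = sample_wise_concordance(a, b, links)
        assert np.allclose(rho.to_numpy(), 1.0)

    def test_shuffled_features_average_to_zero(self, rng):
        samples = [f"s{i}" for i in range(10)]
        rhos = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            a = pd.DataFrame(r.normal(0, 1, (30, 10)),
                             index=[f"f{i}" for i in range(30)], columns=samples)
            b = pd.DataFrame(r.normal(0, 1, (30, 10)),
                             index=[f"p{i}" for i in range(30)], columns=samples)
            links = {f"f{i}": f"p{i}" for i in range(30)}
            rhos.append(sample_wise_concordance(a, b, links).mean())
        assert abs(np.mean(rhos)) < 0.05

    def test_disturbed_samples_rank_lower(self, cohort):
        links = dict(zip(cohort.speg_links.index, cohort.speg_links["protein_id"]))
        rho = sample_wise_concordance(cohort.speg, cohort.protein, links)
        clusters = cohort.truth["sample_clusters"]
        disturbed = rho[clusters == 3].median()
        undisturbed = rho[clusters != 3].median()
        assert disturbed < undisturbed


class TestGeneWiseCorrelation:
    def test_identical_layers(self, linked_layers):
        a, b, links = linked_layers
        out = gene_wise_layer_correlation(a, b, links)
        assert np.allclose(out["rho"], 1.0)

    def test_bh_step_up_hand_example(self, linked_layers):
        from statsmodels.stats.multitest import multipletests

        # {0.01, 0.02, 0.03, 0.04} -> all adjusted to 0.04
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)
        # and the same step-up is what the module applies
        a, b, links = linked_layers
        out = gene_wise_layer_correlation(a, b, links)
        manual = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        assert np.allclose(out["q"].to_numpy(), manual)

    def test_matches_naive_double_loop(self, rng):
        from scipy.stats import spearmanr

        samples = [f"s{i}" for i in range(10)]
        a = pd.DataFrame(rng.normal(0, 1, (10, 10)),
                         index=[f"f{i}" for i in range(10)], columns=samples)
        b = pd.DataFrame(rng.normal(0, 1, (10, 10)),
                         index=[f"p{i}" for i in range(10)], columns=samples)
        links = {f"f{i}": f"p{i}" for i in range(10)}
        out = gene_wise_layer_correlation(a, b, links)
        for i in range(10):
            rho, p = spearmanr(a.loc[f"f{i}"], b.loc[f"p{i}"])
            assert out.loc[f"f{i}", "rho"] == pytest.approx(rho, abs=1e-12)
            assert out.loc[f"f{i}", "p"] == pytest.approx(p, abs=1e-12)

    def test_rho_bounded_and_q_monotone(self, cohort):
        links = dict(zip(cohort.links.index, cohort.links["protein_id"]))
        out = gene_wise_layer_correlation(cohort.igp, cohort.protein, links)
        assert out["rho"].between(-1, 1).all()
        ordered = out.sort_values("p")
        assert (ordered["q"].diff().dropna() >= -1e-12).all()
        assert (out["q"] <= 1).all()


class TestEnzymeIgpMatrix:
    def test_identical_row_gives_unit_correlation(self, rng):
        samples = [f"s{i}" for i in range(10)]
        igp = pd.DataFrame(rng.normal(0, 1, (4, 10)),
                           index=[f"g{i}" for i in range(4)], columns=samples)
        enz = pd.DataFrame(
            np.vstack([igp.loc["g0"].to_numpy(), rng.normal(0, 1, 10)]),
            index=["E0", "E1"], columns=samples)
        grid, _, _ = enzyme_igp_matrix(enz, igp)
        assert grid.loc["E0", "g0"] == pytest.approx(1.0)
        assert grid.to_numpy().min() >= -1 and grid.to_numpy().max() <= 1

    def test_matches_pairwise_spearman(self, rng):
        from scipy.stats import spearmanr

        samples = [f"s{i}" for i in range(15)]
        igp = pd.DataFrame(rng.normal(0, 1, (5, 15)),
                           index=[f"g{i}" for i in range(5)], columns=samples)
        enz = pd.DataFrame(rng.normal(0, 1, (3, 15)),
                           index=[f"E{i}" for i in range(3)], columns=samples)
        grid, _, _ = enzyme_igp_matrix(enz, igp)
        for e in enz.index:
            for g in igp.index:
                expected = spearmanr(enz.loc[e], igp.loc[g]).statistic
                assert grid.loc[e, g] == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance_of_values(self, rng):
        samples = [f"s{i}" for i in range(12)]
        igp = pd.DataFrame(rng.normal(0, 1, (6, 12)),
                           index=[f"g{i}" for i in range(6)], columns=samples)
        enz = pd.DataFrame(rng.normal(0, 1, (4, 12)),
                           index=[f"E{i}" for i in range(4)], columns=samples)
        grid1, _, _ = enzyme_igp_matrix(enz, igp)
        perm_rows = ["E2", "E0", "E3", "E1"]
        grid2, _, _ = enzyme_igp_matrix(enz.loc[perm_rows], igp)
        pd.testing.assert_frame_equal(grid1.loc[perm_rows], grid2)


class TestFlagCompare:
    def test_identical_groups_p_one(self):
        rho = pd.Series([0.1, 0.2, 0.1, 0.2], index=list("abcd"))
        flag = pd.Series([True, True, False, False], index=list("abcd"))
        t, p, med = flag_correlation_compare(rho, flag)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_welch_on_five_values(self):
        rho = pd.Series([0.9, 0.8, 0.1, 0.2, 0.15], index=list("abcde"))
        flag = pd.Series([True, True, False, False, False], index=list("abcde"))
        t, p, _ = flag_correlation_compare(rho, flag)
        t_exp, p_exp = ttest_ind([0.9, 0.8], [0.1, 0.2, 0.15], equal_var=False)
        assert t == pytest.approx(float(t_exp))
        assert p == pytest.approx(float(p_exp))

    def test_planted_gap_power(self):
        n_sig = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            vals = np.concatenate([r.normal(0.5, 0.2, 40), r.normal(0.0, 0.2, 120)])
            rho = pd.Series(vals, index=[f"g{i}" for i in range(160)])
            flag = pd.Series([True] * 40 + [False] * 120, index=rho.index)
            _, p, _ = flag_correlation_compare(rho, flag)
            n_sig += p < 1e-6
        assert n_sig >= 38  # >= 95%


class TestCountUpregulated:
    def test_all_below_threshold(self):
        z = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
        counts, t, p = count_upregulated(z, ["a", "b"], ["c", "d"])
        assert (counts == 0).all()
        assert p == 1.0

    def test_single_gene_shift_gives_unit_difference(self):
        z = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
        z.iloc[0, :2] = 2.0  # one gene above threshold in set A only
        counts, t, p = count_upregulated(z, ["a", "b"], ["c", "d"])
        assert counts[["a", "b"]].mean() - counts[["c", "d"]].mean() == 1.0

    def test_planted_rate_difference_sign(self):
        signs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            za = r.normal(0.7, 1.0, (22, 30))
            zb = r.normal(-0.3, 1.0, (22, 30))
            z = pd.DataFrame(np.hstack([za, zb]),
                             columns=[f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)])
            counts, t, p = count_upregulated(
                z, [f"a{i}" for i in range(30)], [f"b{i}" for i in range(30)])
            signs.append(t > 0)
        assert all(signs)
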