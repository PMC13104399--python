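"""Decision tree, omnibus tests, Holm pairwise adjustment and selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from duoprot import differential as D
from duoprot.preprocess import PreprocessParams, preprocess_pipeline
from duoprot.synthetic import SyntheticSpec, generate_dataset


def groups_from(rng, specs):
    return {g: rng.normal(mu, sd, n) for g, (mu, sd, n) in specs.items()}


class TestChooseTests:
    def test_equal_variance_normals_choose_fisher(self):
        """Under three equal-variance normal groups the decision tree picks
        classic ANOVA at the theoretical rate: each Shapiro-Wilk p is
        uniform under normality, so all three pass with probability 0.95^3
        and Levene passes ~0.95 of the remainder, i.e. ~0.81 overall."""
        rng = np.random.default_rng(0)
        picks = []
        for _ in range(200):
            g = groups_from(rng, {"N": (0, 1, 60), "P": (0, 1, 60), "D": (0, 1, 60)})
            picks.append(D.choose_tests(g).test)
        rate = np.mean([p == D.FISHER for p in picks])
        expected = 0.95**3 * 0.95
        sd = np.sqrt(expected * (1 - expected) / 200)
        assert abs(rate - expected) < 4 * sd

    def test_heteroscedastic_normals_choose_welch(self):
        """Strong heteroscedasticity: Levene rejects essentially always, so
        the Welch branch is taken whenever all groups pass normality
        (~0.95^3 of seeds)."""
        rng = np.random.default_rng(1)
        picks = []
        for _ in range(100):
            g = groups_from(rng, {"N": (0, 1, 80), "P": (0, 6, 80), "D": (0, 1, 80)})
            picks.append(D.choose_tests(g).test)
        assert np.mean([p == D.WELCH for p in picks]) >= 0.75
        assert D.FISHER not in picks

    def test_heavy_tailed_group_chooses_kruskal(self):
        rng = np.random.default_rng(2)
        picks = []
        for _ in range(50):
            g = {"N": rng.standard_cauchy(80), "P": rng.normal(0, 1, 80),
                 "D": rng.normal(0, 1, 80)}
            picks.append(D.choose_tests(g).test)
        assert np.mean([p == D.KRUSKAL for p in picks]) >= 0.9

    def test_identical_values_flagged_degenerate(self):
        g = {"N": np.ones(5), "P": np.ones(4), "D": np.ones(6)}
        with pytest.raises(D.DegenerateProtein):
            D.choose_tests(g)


class TestOmnibus:
    @pytest.mark.parametrize("test", [D.FISHER, D.KRUSKAL])
    def test_null_p_uniform(self, test):
        """Under the null the omnibus p-value is ~Uniform(0,1) (KS check)."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(400):
            g = groups_from(rng, {"N": (0, 1, 11), "P": (0, 1, 6), "D": (0, 1, 9)})
            ps.append(D.omnibus_pvalue(g, test))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("test", [D.FISHER, D.WELCH, D.KRUSKAL])
    def test_large_shift_detected(self, test):
        rng = np.random.default_rng(4)
        g = groups_from(rng, {"N": (0, 1, 60), "P": (0, 1, 60), "D": (10, 1, 60)})
        assert D.omnibus_pvalue(g, test) < 1e-6

    def test_two_groups_rejected(self):
        g = {"N": np.arange(5.0), "D": np.arange(5.0) + 1}
        with pytest.raises(ValueError, match="3 groups"):
            D.omnibus_pvalue(g, D.FISHER)


class TestHolm:
    def test_step_down_hand_examples(self):
        np.testing.assert_allclose(D.holm_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.04, 0.04])
        np.testing.assert_allclose(D.holm_adjust([0.5, 0.6, 0.9]),
                                   [1.0, 1.0, 1.0])
        np.testing.assert_allclose(D.holm_adjust([0.2]), [0.2])  # m = 1

    def test_against_statsmodels_on_random_vectors(self):
        """Property: equals the reference step-down implementation on 1000
        random p-vectors of varying length."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 8))
            expected = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(D.holm_adjust(p), expected, atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            p = rng.random(3)
            adj = D.holm_adjust(p)
            assert (adj >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()


class TestPairwise:
    def test_dunn_hand_computed_example(self):
        """No ties, groups [1,2],[3,4],[5,6]: mean ranks 1.5/3.5/5.5,
        se = sqrt(3.5), z_AB = -1.0690, z_AC = -2.1381."""
        g = {"A": np.array([1.0, 2.0]), "B": np.array([3.0, 4.0]),
             "C": np.array([5.0, 6.0])}
        p = D.dunn_pairwise_p(g)
        assert p[("A", "B")] == pytest.approx(2 * stats.norm.sf(2.0 / np.sqrt(3.5)))
        assert p[("A", "C")] == pytest.approx(2 * stats.norm.sf(4.0 / np.sqrt(3.5)))

    @pytest.mark.parametrize("test", [D.FISHER, D.WELCH, D.KRUSKAL])
    def test_three_contrasts_with_holm_and_fc(self, test):
        rng = np.random.default_rng(7)
        g = groups_from(rng, {"N": (0, 1, 11), "P": (2, 1, 6), "D": (-2, 1, 9)})
        pw = D.pairwise_holm(g, test)
        assert sorted(pw["contrast"]) == ["N_vs_D", "N_vs_P", "P_vs_D"]
        assert (pw["holm_p"] >= pw["raw_p"] - 1e-12).all()
        fc = dict(zip(pw["contrast"], pw["log2_fc"]))
        assert fc["N_vs_P"] == pytest.approx(g["P"].mean() - g["N"].mean())
        assert fc["N_vs_D"] < 0 < fc["N_vs_P"]  # sign matches mean ordering

    def test_fold_change_antisymmetry(self):
        rng = np.random.default_rng(8)
        g = groups_from(rng, {"N": (0, 1, 8), "P": (1, 1, 8), "D": (2, 1, 8)})
        pw = D.pairwise_holm(g, D.FISHER)
        fc = dict(zip(pw["contrast"], pw["log2_fc"]))
        reversed_g = {"D": g["D"], "P": g["P"], "N": g["N"]}
        pw_r = D.pairwise_holm(reversed_g, D.FISHER)
        fc_r = dict(zip(pw_r["contrast"], pw_r["log2_fc"]))
        assert fc["N_vs_D"] == pytest.approx(-fc_r["D_vs_N"])


@pytest.fixture(scope="module")
def null_table():
    matrix, _ = generate_dataset(SyntheticSpec(
        n_proteins=1500, n_differential=0, missing_slope=0.0,
        missing_mid=-np.inf, seed=11))
    processed, _ = preprocess_pipeline(matrix, PreprocessParams(seed=11))
    return D.run_differential(processed)


class TestSelection:
    def test_null_selection_below_alpha(self, null_table):
        """Type-I control on a complete null matrix: the omnibus+pairwise
        gate selects fewer than alpha * n proteins."""
        selected = D.select_significant(null_table)
        assert len(selected) <= 0.05 * len(null_table)
        # the pairwise gate tightens the omnibus-only selection
        omnibus_only = D.select_significant(
            null_table, D.SignificanceRule(require_pairwise=False))
        assert len(selected) < len(omnibus_only)

    def test_alpha_one_not_allowed_but_loose_alpha_selects_everything(self,
                                                                      null_table):
        with pytest.raises(ValueError):
            D.SignificanceRule(alpha=1.0)
        nearly_all = D.select_significant(
            null_table, D.SignificanceRule(alpha=0.999999, require_pairwise=False))
        assert len(nearly_all) >= 0.99 * len(null_table)

    def test_sorted_by_omnibus_p(self, null_table):
        sel = D.select_significant(null_table,
                                   D.SignificanceRule(alpha=0.5,
                                                      require_pairwise=False))
        assert (np.diff(sel["omnibus_p"]) >= 0).all()


@pytest.fixture()
def table():
    return pd.DataFrame({
            "protein_id": ["a", "b", "c"],
            "omnibus_p": [0.001, 0.5, 0.001],
            "raw_p_N_vs_P": [0.001, 0.5, 0.01],
            "holm_p_N_vs_P": [0.003, 1.0, 0.03],
        "log2_fc_N_vs_P": [2.0, 0.5, -3.0],
    })


class TestVolcano:

    def test_category_rule(self, table):
        v = D.volcano_table(table, "N_vs_P")
        assert v["category"].tolist() == ["significant & up", "ns",
                                          "significant & down"]
        assert v["neg_log10_p"].iloc[0] == pytest.approx(3.0)
        assert len(v) == len(table)  # row conservation

    def test_unknown_contrast_fatal(self, table):
        with pytest.raises(ValueError, match="N_vs_D"):
            D.volcano_table(table, "N_vs_D")


class TestTwoGroup:
    def test_branches(self):
        rng = np.random.default_rng(9)
        name, p = D.two_group_test(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        assert name == "student_t"
        name, _ = D.two_group_test(rng.normal(0, 1, 60), rng.normal(0, 8, 60))
        assert name == "welch_t"
        name, _ = D.two_group_test(rng.standard_cauchy(60), rng.normal(0, 1, 60))
        assert name == "mann_whitney"
        with pytest.raises(D.DegenerateProtein):
            D.two_group_test(np.ones(5), np.ones(5))
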