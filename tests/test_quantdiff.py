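"""ANOVA/Tukey, P_ST, trait PCA, LDA and the quasibinomial GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cryptolin import quantdiff
from cryptolin.datatypes import TraitTable


def make_table(values, groups, **extra):
    df = pd.DataFrame({"trait": values, "lineage": groups, **extra})
    return TraitTable(df)


class TestAnova:
    def test_hand_computed_two_groups(self):
        # groups {1, 2, 3} and {5, 6, 10}: means 2 and 7, grand mean 4.5
        # SSB = 3(2-4.5)^2 + 3(7-4.5)^2 = 37.5; SSW = 2 + 14 = 16
        y = [1.0, 2.0, 3.0, 5.0, 6.0, 10.0]
        g = ["a", "a", "a", "b", "b", "b"]
        res = quantdiff.anova_oneway(np.array(y), groups=np.array(g))
        msb = 37.5 / 1
        msw = 16.0 / 4
        assert res.F == pytest.approx(msb / msw, abs=1e-10)
        assert res.p == pytest.approx(stats.f.sf(msb / msw, 1, 4), abs=1e-12)
        assert res.sigma2_within == pytest.approx(msw, abs=1e-10)
        assert res.sigma2_between == pytest.approx((msb - msw) / 3, abs=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        res = quantdiff.anova_oneway(y, groups=g)
        ref = stats.f_oneway(y[:10], y[10:20], y[20:])
        assert res.F == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_f_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c"], 8)
        base = quantdiff.anova_oneway(y, groups=g).F
        scaled = quantdiff.anova_oneway(3.7 * y - 11.0, groups=g).F
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_negative_between_component_truncated(self):
        # identical group means: MSB < MSW almost surely -> truncation
        y = np.array([1.0, -1.0, 2.0, -2.0, 1.5, -1.5, 2.5, -2.5])
        g = np.array(["a", "a", "b", "b", "a", "a", "b", "b"])
        res = quantdiff.anova_oneway(y, groups=g)
        if res.sigma2_between_raw < 0:
            assert res.sigma2_between == 0.0

    def test_zero_within_variance_rejected(self):
        y = np.array([1.0, 1.0, 2.0, 2.0])
        g = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="F undefined"):
            quantdiff.anova_oneway(y, groups=g)


class TestTukey:
    def test_planted_separation_gives_distinct_letters(self):
        rng = np.random.default_rng(3)
        y = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(10, 1, 30), rng.normal(20, 1, 30)]
        )
        g = np.repeat(["a", "b", "c"], 30)
        _, letters = quantdiff.tukey_hsd(y, groups=g)
        assert len({letters["a"], letters["b"], letters["c"]}) == 3

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=60)
        g = np.repeat(["a", "b"], 30)
        _, letters = quantdiff.tukey_hsd(y, groups=g)
        assert set(letters["a"]) & set(letters["b"])

    def test_intermediate_group_shares_letters_both_ways(self):
        rng = np.random.default_rng(5)
        y = np.concatenate(
            [rng.normal(0, 1, 40), rng.normal(1.0, 1, 40), rng.normal(2.0, 1, 40)]
        )
        g = np.repeat(["lo", "mid", "hi"], 40)
        table, letters = quantdiff.tukey_hsd(y, groups=g)
        # if lo-hi differ but mid differs from neither, mid gets both letters
        rej = {frozenset((r["group1"], r["group2"])): r["reject"] for _, r in table.iterrows()}
        if rej[frozenset(("lo", "hi"))] and not rej[frozenset(("lo", "mid"))] \
                and not rej[frozenset(("mid", "hi"))]:
            assert set(letters["mid"]) == set(letters["lo"]) | set(letters["hi"])


class TestPst:
    def test_zero_between_gives_zero(self):
        assert quantdiff.pst(0.0, 3.0).value == 0.0

    def test_zero_within_gives_one(self):
        assert quantdiff.pst(2.0, 0.0).value == 1.0

    def test_equal_components_default_scaling(self):
        # c = 1, h2 = 0.5: 2 s / (2 s + 2 s) = 0.5
        assert quantdiff.pst(1.7, 1.7).value == pytest.approx(0.5, abs=1e-12)

    def test_invariant_under_trait_rescaling(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([rng.normal(0, 1, 25), rng.normal(2, 1, 25)])
        g = np.repeat(["a", "b"], 25)
        p1 = quantdiff.pst_from_anova(y, groups=g).value
        p2 = quantdiff.pst_from_anova(5.0 * y, groups=g).value
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_bad_heritability_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            quantdiff.pst(1.0, 1.0, h2=0.0)


class TestTraitPca:
    def test_duplicate_trait_columns_equal_loadings(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        df = pd.DataFrame(
            {"t1": x, "t2": x.copy(), "t3": rng.normal(size=40), "lineage": "a"}
        )
        res = quantdiff.trait_pca(TraitTable(df), ["t1", "t2", "t3"])
        assert res.loadings.loc["t1", "PC1"] == pytest.approx(
            res.loadings.loc["t2", "PC1"], abs=1e-10
        )

    def test_planted_two_factor_share(self):
        rng = np.random.default_rng(8)
        f1, f2 = rng.normal(size=(2, 200))
        noise = 0.05 * rng.normal(size=(200, 4))
        X = np.column_stack([f1, f1, f2, f2]) + noise
        df = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        df["lineage"] = "x"
        res = quantdiff.trait_pca(TraitTable(df), ["a", "b", "c", "d"])
        assert res.percent_variance[:2].sum() > 95.0

    def test_constant_trait_dropped_with_warning(self):
        df = pd.DataFrame(
            {"t1": np.arange(10.0), "flat": 1.0, "lineage": "a"}
        )
        with pytest.warns(UserWarning, match="constant"):
            res = quantdiff.trait_pca(TraitTable(df), ["t1", "flat"])
        assert res.dropped_traits == ["flat"]

    def test_scores_invariant_to_individual_order(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        df["lineage"] = "x"
        res1 = quantdiff.trait_pca(TraitTable(df), ["a", "b", "c"])
        perm = rng.permutation(30)
        res2 = quantdiff.trait_pca(TraitTable(df.iloc[perm]), ["a", "b", "c"])
        back = res2.scores.loc[df.index]
        assert np.allclose(np.abs(back.to_numpy()), np.abs(res1.scores.to_numpy()), atol=1e-8)


class TestLda:
    def test_perfect_separation_classifies_all(self):
        df = pd.DataFrame(
            {
                "t": np.concatenate([np.random.default_rng(0).normal(0, 0.1, 20),
                                     np.random.default_rng(1).normal(10, 0.1, 20)]),
                "lineage": np.repeat(["a", "b"], 20),
            }
        )
        res = quantdiff.lda_classify(TraitTable(df), ["t"])
        assert res.correct_rate["overall"] == 1.0

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "t1": rng.normal(size=600),
                "t2": rng.normal(size=600),
                "lineage": np.repeat(["a", "b"], 300),
            }
        )
        res = quantdiff.lda_classify(TraitTable(df), ["t1", "t2"])
        assert 0.4 <= res.correct_rate["overall"] <= 0.65

    def test_planted_diagnostic_trait_has_top_correlation(self):
        rng = np.random.default_rng(11)
        n = 60
        group = np.repeat([0, 1], n)
        diag = group * 3.0 + rng.normal(0, 1, 2 * n)
        df = pd.DataFrame(
            {
                "diagnostic": diag,
                "noise1": rng.normal(size=2 * n),
                "noise2": rng.normal(size=2 * n),
                "lineage": np.where(group == 0, "a", "b"),
            }
        )
        res = quantdiff.lda_classify(TraitTable(df), ["diagnostic", "noise1", "noise2"])
        strengths = res.trait_posterior_r.abs().max(axis=1)
        assert strengths.idxmax() == "diagnostic"


class TestQuasibinomialGlm:
    def test_saturated_model_reproduces_log_odds(self):
        # {10/20 vs 15/20}: coefficient = log[(15*10)/(5*10)] = 1.0986
        res = quantdiff.quasibinomial_glm(
            successes=[10, 15], totals=[20, 20], groups=["a", "b"]
        )
        assert res.coefficients["C[b]"] == pytest.approx(np.log(3.0), abs=1e-6)
        assert res.group_proportions["a"] == pytest.approx(0.5)
        assert res.group_proportions["b"] == pytest.approx(0.75)

    def test_identical_proportions_flat_coefficient(self):
        rng = np.random.default_rng(12)
        totals = np.full(60, 40)
        succ = rng.binomial(40, 0.3, size=60)
        groups = np.repeat(["a", "b"], 30)
        res = quantdiff.quasibinomial_glm(succ, totals, groups)
        assert abs(res.coefficients["C[b]"]) < 0.5
        assert abs(res.tvalues["C[b]"]) < 2.0

    def test_pure_binomial_dispersion_near_one(self):
        rng = np.random.default_rng(13)
        totals = np.full(200, 30)
        succ = rng.binomial(30, 0.4, size=200)
        groups = np.repeat(["a", "b"], 100)
        res = quantdiff.quasibinomial_glm(succ, totals, groups)
        assert 0.7 <= res.dispersion <= 1.3

    def test_overdispersed_counts_detected(self):
        rng = np.random.default_rng(14)
        p = rng.beta(2.0, 3.0, size=200)  # beta-binomial mixing
        succ = rng.binomial(40, p)
        res = quantdiff.quasibinomial_glm(
            succ, np.full(200, 40), np.repeat(["a", "b"], 100)
        )
        assert res.dispersion > 2.0

    def test_complete_separation_flagged(self):
        with pytest.warns(UserWarning, match="separation"):
            res = quantdiff.quasibinomial_glm(
                successes=[0, 0, 20, 20], totals=[20, 20, 20, 20],
                groups=["a", "a", "b", "b"],
            )
        assert res.separated
        assert np.isfinite(res.coefficients).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="totals"):
            quantdiff.quasibinomial_glm([1], [0], ["a"])
        with pytest.raises(ValueError, match="successes"):
            quantdiff.quasibinomial_glm([5], [4], ["a"])


def test_pst_rank_agrees_with_fst_on_default_calibration(default_dataset):
    """Strong flowering-time offsets make quantitative divergence comparable
    to the neutral marker divergence of the same simulated lineages."""
    from cryptolin import popgen

    ds = default_dataset
    pure = ds.pure_mask()
    t = ds.traits.data[pure]
    pair = t["lineage"].isin(["eff1", "eff2"])
    pst = quantdiff.pst_from_anova(
        t.loc[pair, "first_flowering"], groups=t.loc[pair, "lineage"]
    )
    assert pst.value > 0.5
    fst = popgen.wc_fst(ds.genotypes.subset(pure), ds.labels[pure].to_numpy())
    assert fst.pairwise.loc["eff1", "eff2"] > 0.5
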