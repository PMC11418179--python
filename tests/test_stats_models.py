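import numpy as np
import pandas as pd
import pytest

from strikescape import (
    fit_lmm_reml,
    lda_accuracy,
    lda_fit,
    pairwise_contrasts,
    satterthwaite_df,
    type2_anova,
)
from strikescape.stats_models import (
    ModelError,
    _gls_pieces,
    _group_slices,
    _profiled_neg2_reml,
    compare_lmm_aic,
)


def one_way_data(rng, n_groups=10, per_group=10, sigma_b=2.0, sigma_e=1.0):
    b = rng.normal(0, sigma_b, n_groups)
    y = np.repeat(b, per_group) + rng.normal(0, sigma_e, n_groups * per_group)
    return pd.DataFrame(
        {"y": y, "ind": np.repeat([f"i{j}" for j in range(n_groups)], per_group)}
    )


class TestREML:
    def test_balanced_one_way_matches_anova_estimators(self, rng):
        """On a balanced one-way layout REML variance components equal the
        classical ANOVA moment estimators MSW and (MSB - MSW)/m."""
        df = one_way_data(rng)
        fit = fit_lmm_reml(df, "y", [], "ind")
        m = 10
        gm = df.groupby("ind")["y"].mean()
        msb = m * gm.var(ddof=1)
        msw = (
            (df["y"] - df.groupby("ind")["y"].transform("mean")) ** 2
        ).sum() / (10 * (m - 1))
        assert fit.sigma2_residual == pytest.approx(msw, abs=1e-6)
        assert fit.sigma2_individual == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent implementation check against statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        n = 150
        sp = rng.choice(["a", "b", "c"], n)
        ind = rng.choice([f"i{j}" for j in range(18)], n)
        shift = dict(zip([f"i{j}" for j in range(18)], rng.normal(0, 1.2, 18)))
        y = (
            1.0
            + 2.0 * (sp == "b")
            + 0.5 * (sp == "c")
            + np.array([shift[i] for i in ind])
            + rng.normal(0, 1, n)
        )
        df = pd.DataFrame({"y": y, "species": sp, "ind": ind})
        fit = fit_lmm_reml(df, "y", ["species"], "ind")
        ref = smf.mixedlm("y ~ species", df, groups=df["ind"]).fit(reml=True)
        np.testing.assert_allclose(
            fit.coef.to_numpy(), ref.fe_params.to_numpy(), atol=1e-5
        )
        assert fit.sigma2_individual == pytest.approx(ref.cov_re.iloc[0, 0], rel=1e-3)
        assert fit.sigma2_residual == pytest.approx(ref.scale, rel=1e-3)

    def test_zero_variance_estimated_at_boundary(self):
        """Data with no between-individual variance: the REML estimate of
        sigma2_b has ~half its mass exactly on the boundary (the classical
        behaviour for a true zero variance component), so the median
        estimate is 0 and the mean ratio to residual variance is small."""
        ratios = []
        for r in range(60):
            sub = np.random.default_rng(r)
            df = one_way_data(sub, sigma_b=0.0)
            fit = fit_lmm_reml(df, "y", [], "ind")
            ratios.append(fit.sigma2_individual / fit.sigma2_residual)
        boundary_frac = np.mean(np.array(ratios) <= 1e-4)
        assert 0.35 <= boundary_frac  # ~0.5 expected; binomial error allowed
        assert np.mean(ratios) < 0.08

    def test_fixed_effect_recovery(self):
        """A 2.0-unit species difference is recovered without bias."""
        ests = []
        for r in range(100):
            rng = np.random.default_rng(1000 + r)
            n_ind = 40
            sp = np.repeat(["a", "b"], n_ind // 2)
            strikes = rng.integers(3, 8, n_ind)
            ind = np.repeat(np.arange(n_ind), strikes)
            b = rng.normal(0, 1.0, n_ind)
            y = 2.0 * (np.array(sp)[ind] == "b") + b[ind] + rng.normal(0, 1, len(ind))
            df = pd.DataFrame({"y": y, "species": np.array(sp)[ind], "ind": ind})
            fit = fit_lmm_reml(df, "y", ["species"], "ind")
            ests.append(fit.coef["species[b]"])
        assert np.mean(ests) == pytest.approx(2.0, abs=0.1)

    def test_reml_optimum_beats_random_gamma_probes(self, rng):
        df = one_way_data(rng, sigma_b=1.0)
        fit = fit_lmm_reml(df, "y", [], "ind")
        slices = _group_slices(fit.groups)
        opt, *_ = _profiled_neg2_reml(fit.X, fit.y, slices, fit.gamma)
        for g in np.exp(rng.uniform(-8, 8, 50)):
            probe, *_ = _profiled_neg2_reml(fit.X, fit.y, slices, g)
            assert opt <= probe + 1e-8

    def test_gamma_zero_reduces_to_ols(self, rng):
        n = 80
        x = rng.normal(0, 1, n)
        y = 1 + 2 * x + rng.normal(0, 1, n)
        ind = rng.choice(list("abcdef"), n)
        df = pd.DataFrame({"y": y, "x": x, "ind": ind})
        fit = fit_lmm_reml(df, "y", ["x"], "ind")
        A, b, *_ = _gls_pieces(fit.X, fit.y, _group_slices(fit.groups), 0.0)
        beta_ols = np.linalg.solve(A, b)
        X = fit.X
        np.testing.assert_allclose(
            beta_ols, np.linalg.lstsq(X, fit.y, rcond=None)[0], atol=1e-8
        )

    def test_needs_two_groups(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "ind": ["a", "a"]})
        with pytest.raises(ModelError):
            fit_lmm_reml(df, "y", [], "ind")


class TestTests:
    def make_fit(self, rng, effect=0.0, n_ind=24):
        sp = np.repeat(["a", "b", "c", "d"], n_ind // 4)
        strikes = rng.integers(3, 8, n_ind)
        ind = np.repeat(np.arange(n_ind), strikes)
        st = rng.choice(["edge", "corner"], len(ind))
        b = rng.normal(0, 1.0, n_ind)
        y = (
            effect * (np.array(sp)[ind] == "b")
            + b[ind]
            + rng.normal(0, 1, len(ind))
        )
        df = pd.DataFrame(
            {"y": y, "species": np.array(sp)[ind], "strike_type": st, "ind": ind}
        )
        return fit_lmm_reml(df, "y", ["species", "strike_type"], "ind")

    def test_overwhelming_effect_has_tiny_p(self, rng):
        fit = self.make_fit(rng, effect=5.0)
        an = type2_anova(fit)
        assert an.loc[an["factor"] == "species", "p_value"].iloc[0] < 1e-4

    def test_satterthwaite_df_near_classical_on_balanced_design(self):
        """Balanced one-way layout with many groups: Satterthwaite df for a
        group contrast approaches the classical between-group df."""
        rng = np.random.default_rng(5)
        G, m = 30, 6
        sp = np.repeat(["a", "b"], G // 2)
        b = rng.normal(0, 1.0, G)
        y = b.repeat(m) + rng.normal(0, 1.0, G * m)
        df = pd.DataFrame(
            {"y": y, "species": np.repeat(sp, m), "ind": np.repeat(np.arange(G), m)}
        )
        fit = fit_lmm_reml(df, "y", ["species"], "ind")
        L = np.zeros(len(fit.coef))
        L[1] = 1.0
        ddf = satterthwaite_df(fit, L)
        # classical df for a between-individual contrast: G - 2
        assert ddf == pytest.approx(G - 2, rel=0.05)

    def test_type2_f_invariant_to_factor_order(self, rng):
        fit_ab = self.make_fit(rng, effect=1.0)
        # rebuild the same data, then refit with both factor orders
        table = pd.DataFrame(
            {
                "y": fit_ab.y,
                "species": fit_ab.X[:, 1:4] @ [1, 2, 3],
                "strike_type": fit_ab.X[:, 4],
                "ind": fit_ab.groups,
            }
        )
        table["species"] = table["species"].map({0.0: "a", 1.0: "b", 2.0: "c", 3.0: "d"})
        table["strike_type"] = table["strike_type"].map({0.0: "corner", 1.0: "edge"})
        f1 = fit_lmm_reml(table, "y", ["species", "strike_type"], "ind")
        f2 = fit_lmm_reml(table, "y", ["strike_type", "species"], "ind")
        a1 = type2_anova(f1).set_index("factor")
        a2 = type2_anova(f2).set_index("factor")
        for fac in ("species", "strike_type"):
            assert a1.loc[fac, "F"] == pytest.approx(a2.loc[fac, "F"], rel=1e-6)

    def test_tukey_two_levels_equals_unadjusted(self, rng):
        n = 60
        sp = rng.choice(["a", "b"], n)
        ind = rng.choice(list("pqrstu"), n)
        y = (sp == "b") * 1.0 + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "species": sp, "ind": ind})
        fit = fit_lmm_reml(df, "y", ["species"], "ind")
        tukey = pairwise_contrasts(fit, "species", adjust="tukey")
        none = pairwise_contrasts(fit, "species", adjust="none")
        assert tukey["p_value"].iloc[0] == pytest.approx(
            none["p_value"].iloc[0], rel=1e-6
        )

    def test_identical_means_give_zero_contrasts(self):
        rng = np.random.default_rng(9)
        sp = np.repeat(["a", "b", "c", "d"], 12)
        ind = np.tile([f"i{j}" for j in range(12)], 4)
        y = np.tile(rng.normal(0, 1, 12), 4)  # identical per individual
        df = pd.DataFrame({"y": y, "species": sp, "ind": ind})
        fit = fit_lmm_reml(df, "y", ["species"], "ind")
        con = pairwise_contrasts(fit, "species")
        np.testing.assert_allclose(con["estimate"], 0.0, atol=1e-10)

    def test_targeted_contrast_has_smallest_p(self):
        """Only one species pair truly differs; that contrast dominates."""
        rng = np.random.default_rng(11)
        n_ind = 32
        sp = np.repeat(["gen", "mol", "scale", "hyb"], n_ind // 4)
        ind = np.repeat(np.arange(n_ind), 6)
        y = 3.0 * (np.array(sp)[ind] == "scale") + rng.normal(0, 1, len(ind))
        df = pd.DataFrame({"y": y, "species": np.array(sp)[ind], "ind": ind})
        fit = fit_lmm_reml(df, "y", ["species"], "ind")
        con = pairwise_contrasts(fit, "species")
        con["has_scale"] = con["contrast"].str.contains("scale")
        assert con[con.has_scale]["p_value"].max() < con[~con.has_scale]["p_value"].min()

    def test_ml_aic_comparison_prefers_true_model(self, rng):
        fit1 = self.make_fit(rng, effect=3.0)
        table = pd.DataFrame(
            {
                "y": fit1.y,
                "species": pd.Series(fit1.X[:, 1:4] @ [1, 2, 3]).map(
                    {0.0: "a", 1.0: "b", 2.0: "c", 3.0: "d"}
                ),
                "strike_type": pd.Series(fit1.X[:, 4]).map({0.0: "c", 1.0: "e"}),
                "ind": fit1.groups,
            }
        )
        full = fit_lmm_reml(table, "y", ["species", "strike_type"], "ind", method="ML")
        null = fit_lmm_reml(table, "y", ["strike_type"], "ind", method="ML")
        tab = compare_lmm_aic([full, null])
        assert tab["model"].iloc[0] == "species + strike_type"
        assert tab["delta_aic"].iloc[1] > 2


class TestLDA:
    def test_first_axis_parallel_to_mean_difference(self, rng):
        n = 300
        mu = np.array([10.0, 0, 0, 0, 0])
        X = np.vstack(
            [rng.normal(0, 1, (n, 5)), rng.normal(0, 1, (n, 5)) + mu]
        )
        labels = np.array(["a"] * n + ["b"] * n)
        fit = lda_fit(X, labels)
        v = fit.scalings[:, 0]
        cos = abs(v @ mu) / (np.linalg.norm(v) * np.linalg.norm(mu))
        assert cos > 0.99
        assert fit.n_axes == 1  # 2 groups -> 1 axis

    def test_permuted_labels_kill_between_class_signal(self, rng):
        n = 400
        X = np.vstack(
            [rng.normal(0, 1, (n, 5)), rng.normal(0, 1, (n, 5)) + [5, 0, 0, 0, 0]]
        )
        labels = np.array(["a"] * n + ["b"] * n)
        signal = lda_fit(X, labels).eigenvalues[0]
        perm = rng.permutation(labels)
        assert lda_fit(X, perm).eigenvalues[0] < 0.05 * signal

    def test_four_groups_five_vars_gives_three_axes(self, rng):
        X = rng.normal(0, 1, (100, 5))
        labels = rng.choice(list("abcd"), 100)
        assert lda_fit(X, labels).n_axes == 3

    def test_matches_sklearn_classification(self, rng):
        """Accuracy agrees with scikit-learn's LDA as independent oracle."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(0, 1, (200, 5))
        labels = rng.choice(list("abc"), 200)
        X[labels == "a", 0] += 2.0
        X[labels == "b", 1] += 2.0
        fit = lda_fit(X, labels)
        ours = lda_accuracy(fit, X, labels)
        sk = LinearDiscriminantAnalysis().fit(X, labels).score(X, labels)
        assert ours == pytest.approx(sk, abs=1e-12)

    def test_perfect_separation_and_affine_invariance(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.1, (50, 5)), rng.normal(0, 0.1, (50, 5)) + 10]
        )
        labels = np.array(["a"] * 50 + ["b"] * 50)
        fit = lda_fit(X, labels)
        assert lda_accuracy(fit, X, labels) == 1.0
        # rescaling any variable leaves accuracy unchanged
        scale = np.array([1.0, 100.0, 0.01, 1.0, 5.0])
        fit2 = lda_fit(X * scale, labels)
        assert lda_accuracy(fit2, X * scale, labels) == 1.0

    def test_shuffled_four_group_accuracy_near_chance(self, rng):
        X = rng.normal(0, 1, (400, 5))
        labels = np.repeat(list("abcd"), 100)
        fit = lda_fit(X, labels)
        acc = lda_accuracy(fit, X, labels)
        assert 0.20 <= acc <= 0.35  # resubstitution overfits slightly above 0.25

    def test_loo_defined_on_tiny_groups(self, rng):
        X = rng.normal(0, 1, (8, 2))
        labels = np.array(list("abcdabcd"))
        fit = lda_fit(X, labels)
        acc = lda_accuracy(fit, X, labels, scheme="loo")
        assert 0.0 <= acc <= 1.0
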