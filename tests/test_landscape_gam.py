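import numpy as np
import pandas as pd
import pytest

from strikescape import (
    SmoothSpec,
    compare_models,
    find_peaks,
    fit_gam,
    fit_gam_shrinkage,
    predict_surface,
    tps_basis_2d,
)
from strikescape.landscape_gam import (
    GAMError,
    _penalty_total,
    farthest_point_knots,
)


def bimodal(g, p):
    """Two Gaussian performance peaks separated by a valley."""
    return 4.0 * np.exp(-((g - 2.5) ** 2 + (p - 2.0) ** 2) / (2 * 1.1**2)) + 6.5 * np.exp(
        -((g - 5.0) ** 2 + (p - 6.5) ** 2) / (2 * 1.5**2)
    )


class TestBasis:
    def test_penalty_psd_with_three_dim_null_space(self, rng):
        pts = rng.uniform(0, 10, (40, 2))
        B, S = tps_basis_2d(pts, farthest_point_knots(pts, 20))
        ev = np.linalg.eigvalsh(S)
        assert ev.min() >= -1e-10
        assert (np.abs(ev) < 1e-8 * ev.max()).sum() == 3
        # any coefficient vector confined to the null-space columns has
        # zero penalty
        beta = np.zeros(S.shape[0])
        beta[-3:] = rng.normal(0, 1, 3)
        assert beta @ S @ beta == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_and_too_few_knots_rejected(self, rng):
        pts = rng.uniform(0, 1, (10, 2))
        with pytest.raises(GAMError, match="duplicate"):
            tps_basis_2d(pts, np.vstack([pts[:3], pts[:1]]))
        with pytest.raises(GAMError, match="at least"):
            tps_basis_2d(pts, pts[:3])

    def test_unpenalized_full_basis_interpolates(self, rng):
        """lambda = 0 with knots at every data point reproduces noise-free
        samples of a smooth function (scipy's TPS interpolator agrees)."""
        from scipy.interpolate import RBFInterpolator

        pts = rng.uniform(0, 10, (30, 2))
        f = np.sin(pts[:, 0] / 3) + np.cos(pts[:, 1] / 4)
        df = pd.DataFrame({"g": pts[:, 0], "p": pts[:, 1], "y": f})
        fit = fit_gam(df, "y", [], [SmoothSpec(("g", "p"), k=30)], lambdas=[1e-12])
        np.testing.assert_allclose(fit.fitted, f, atol=1e-6)
        # independent oracle at fresh points
        test = rng.uniform(1, 9, (20, 2))
        ours = fit.predict(pd.DataFrame({"g": test[:, 0], "p": test[:, 1]}))
        ref = RBFInterpolator(pts, f, kernel="thin_plate_spline")(test)
        np.testing.assert_allclose(ours, ref, atol=1e-4)

    def test_farthest_point_knots_deterministic_and_spacefilling(self, rng):
        pts = rng.uniform(0, 1, (200, 2))
        k1 = farthest_point_knots(pts, 25)
        k2 = farthest_point_knots(pts, 25)
        np.testing.assert_array_equal(k1, k2)
        assert len(np.unique(k1, axis=0)) == 25


class TestFit:
    def test_infinite_lambda_gives_least_squares_plane(self, rng):
        pts = rng.uniform(0, 10, (50, 2))
        y = 1 + 0.5 * pts[:, 0] - 0.2 * pts[:, 1] + rng.normal(0, 0.3, 50)
        df = pd.DataFrame({"g": pts[:, 0], "p": pts[:, 1], "y": y})
        fit = fit_gam(df, "y", [], [SmoothSpec(("g", "p"), k=20)], lambdas=[1e12])
        assert fit.edf_total == pytest.approx(3.0, abs=1e-3)
        X = np.column_stack([np.ones(50), pts])
        plane = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.fitted, plane, atol=1e-6)

    def test_linear_truth_selects_minimal_edf(self, rng):
        g = rng.uniform(0, 10, 200)
        y = 1.0 + 0.7 * g + rng.normal(0, 0.5, 200)
        df = pd.DataFrame({"g": g, "y": y})
        fit = fit_gam(df, "y", [], [SmoothSpec(("g",))])
        assert fit.edf_total <= 3.5
        ols = np.polyval(np.polyfit(g, y, 1), g)
        assert np.max(np.abs(fit.fitted - ols) / np.abs(ols)) < 0.02

    def test_fixed_lambda_equals_dense_solve(self, rng):
        """Penalized coefficients match a brute-force solve of the normal
        equations assembled independently."""
        g = rng.uniform(0, 10, 80)
        p = rng.uniform(0, 10, 80)
        y = bimodal(g, p) + rng.normal(0, 0.5, 80)
        df = pd.DataFrame({"g": g, "p": p, "y": y})
        lam = np.array([2.3])
        fit = fit_gam(df, "y", [], [SmoothSpec(("g", "p"))], lambdas=lam)
        S = _penalty_total(fit.X.shape[1], fit.smooths, lam)
        beta = np.linalg.solve(fit.X.T @ fit.X + S, fit.X.T @ fit.y)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-8)

    def test_edf_monotone_in_lambda_and_rss_nondecreasing(self, rng):
        g = rng.uniform(0, 10, 100)
        p = rng.uniform(0, 10, 100)
        y = bimodal(g, p) + rng.normal(0, 0.5, 100)
        df = pd.DataFrame({"g": g, "p": p, "y": y})
        edfs, rsss = [], []
        for lam in [1e-4, 1e-2, 1, 1e2, 1e4]:
            fit = fit_gam(df, "y", [], [SmoothSpec(("g", "p"))], lambdas=[lam])
            edfs.append(fit.edf_total)
            rsss.append(fit.rss)
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(rsss, rsss[1:]))

    def test_all_linear_terms_reproduce_multiple_regression(self, rng):
        n = 100
        df = pd.DataFrame(
            {
                "x1": rng.normal(0, 1, n),
                "x2": rng.normal(0, 1, n),
                "species": rng.choice(["a", "b"], n),
            }
        )
        df["y"] = (
            1 + 2 * df.x1 - df.x2 + (df.species == "b") * 0.5 + rng.normal(0, 1, n)
        )
        fit = fit_gam(df, "y", ["x1", "x2", "species"], [])
        X = np.column_stack(
            [np.ones(n), (df.species == "b").astype(float), df.x1, df.x2]
        )
        beta = np.linalg.lstsq(X, df.y, rcond=None)[0]
        np.testing.assert_allclose(np.sort(fit.coef), np.sort(beta), atol=1e-8)

    def test_reml_agrees_with_mgcv(self, tmp_path, rng):
        """Validation-grade cross-check of the REML-selected fit against R's
        mgcv on the same data (predictions, not coefficients — the bases
        differ)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        n = 120
        g = rng.uniform(0, 8, n)
        p = rng.uniform(0, 8, n)
        y = bimodal(g, p) + rng.normal(0, 0.8, n)
        df = pd.DataFrame({"g": g, "p": p, "y": y})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "pred.csv"
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            library(mgcv)
            d <- read.csv("{csv}")
            m <- gam(y ~ s(g, p, k = 30), data = d, method = "REML")
            write.csv(data.frame(mu = predict(m), edf = sum(m$edf)),
                      "{out}", row.names = FALSE)
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out)
        fit = fit_gam(df, "y", [], [SmoothSpec(("g", "p"), k=30)])
        r = np.corrcoef(fit.fitted, ref["mu"])[0, 1]
        assert r > 0.98
        assert np.abs(fit.fitted - ref["mu"]).mean() < 0.25


class TestShrinkage:
    def test_noise_covariate_shrinks_relevant_survives(self, rng):
        n = 250
        g = rng.uniform(0, 10, n)
        junk = rng.uniform(0, 10, n)
        y = 2 * np.sin(g) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"g": g, "junk": junk, "y": y})
        fit = fit_gam_shrinkage(
            df, "y", [], [SmoothSpec(("g",)), SmoothSpec(("junk",))]
        )
        assert fit.edf_by_smooth["s(junk)"] < 0.5
        assert fit.edf_by_smooth["s(g)"] > 2.0

    def test_zero_null_penalty_reproduces_plain_fit(self, rng):
        n = 100
        g = rng.uniform(0, 10, n)
        y = 2 * np.sin(g) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"g": g, "y": y})
        plain = fit_gam(df, "y", [], [SmoothSpec(("g",))])
        zero = fit_gam_shrinkage(df, "y", [], [SmoothSpec(("g",))], null_penalty=0.0)
        np.testing.assert_allclose(plain.coef, zero.coef, atol=1e-8)


class TestModelComparison:
    def test_duplicate_fit_has_zero_delta(self, rng):
        g = rng.uniform(0, 10, 60)
        df = pd.DataFrame({"g": g, "y": np.sin(g) + rng.normal(0, 0.2, 60)})
        f = fit_gam(df, "y", [], [SmoothSpec(("g",))])
        tab = compare_models([f, f], ["m1", "m2"])
        assert tab["delta_aic"].iloc[1] == 0.0
        assert tab["equivalent"].all()

    def test_2d_smooth_beats_1d_on_interacting_surface(self):
        wins = 0
        for r in range(20):
            rng = np.random.default_rng(7000 + r)
            g = rng.uniform(0, 8, 130)
            p = rng.uniform(0, 8, 130)
            y = bimodal(g, p) + rng.normal(0, 0.8, 130)
            df = pd.DataFrame({"g": g, "p": p, "y": y})
            f2 = fit_gam(df, "y", [], [SmoothSpec(("g", "p"))])
            f1 = fit_gam(df, "y", [], [SmoothSpec(("g",)), SmoothSpec(("p",))])
            tab = compare_models([f2, f1], ["2d", "1d"])
            wins += tab["model"].iloc[0] == "2d" and tab["delta_aic"].iloc[1] > 2
        assert wins >= 18

    def test_pure_noise_term_within_aic_penalty_band(self, rng):
        n = 150
        g = rng.uniform(0, 10, n)
        junk = rng.normal(0, 1, n)
        y = np.sin(g) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"g": g, "junk": junk, "y": y})
        base = fit_gam(df, "y", [], [SmoothSpec(("g",))])
        extra = fit_gam(df, "y", ["junk"], [SmoothSpec(("g",))])
        # one extra useless parameter costs at most ~+2 AIC
        assert -0.5 < extra.aic - base.aic < 2.5

    def test_mismatched_data_rejected(self, rng):
        g = rng.uniform(0, 10, 50)
        d1 = pd.DataFrame({"g": g, "y": np.sin(g)})
        d2 = pd.DataFrame({"g": g, "y": np.cos(g)})
        f1 = fit_gam(d1, "y", ["g"], [])
        f2 = fit_gam(d2, "y", ["g"], [])
        with pytest.raises(GAMError, match="different"):
            compare_models([f1, f2])


class TestSurface:
    def fit_bimodal(self, seed=0, n=130):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 8, n)
        p = rng.uniform(0, 8, n)
        y = bimodal(g, p) + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"g": g, "p": p, "y": y})
        return fit_gam(df, "y", [], [SmoothSpec(("g", "p"))])

    def test_prediction_at_observed_point_equals_fitted(self):
        fit = self.fit_bimodal()
        mu = fit.predict(fit.data)
        np.testing.assert_allclose(mu, fit.fitted, atol=1e-10)

    def test_mask_fraction_monotone_in_distance(self):
        fit = self.fit_bimodal()
        fracs = [
            predict_surface(fit, (40, 40), support_distance=d).support.mean()
            for d in (0.2, 0.5, 1.0, 2.0)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_planar_data_gives_flat_surface_no_peaks(self, rng):
        g = rng.uniform(0, 10, 100)
        p = rng.uniform(0, 10, 100)
        y = 1 + 0.3 * g + 0.1 * p  # noiseless plane
        df = pd.DataFrame({"g": g, "p": p, "y": y})
        fit = fit_gam(df, "y", [], [SmoothSpec(("g", "p"))])
        surf = predict_surface(fit, (30, 30), support_distance=5.0)
        d2x = np.diff(surf.z, 2, axis=0)
        d2y = np.diff(surf.z, 2, axis=1)
        assert np.abs(d2x).max() < 1e-4 and np.abs(d2y).max() < 1e-4
        assert find_peaks(surf) == []

    def test_two_gaussians_detected_near_truth(self):
        fit = self.fit_bimodal(seed=3)
        surf = predict_surface(fit, (60, 60))
        peaks = find_peaks(surf)
        assert len(peaks) == 2
        locs = [(q.x, q.y) for q in peaks]
        for tg, tp in [(2.5, 2.0), (5.0, 6.5)]:
            assert min(np.hypot(a - tg, b - tp) for a, b in locs) <= 0.5
        # the two optima are separated by a genuine valley
        (key, saddle), = surf.saddles.items()
        assert saddle < min(q.height for q in peaks)

    def test_single_gaussian_gives_one_peak(self, rng):
        g = rng.uniform(0, 8, 120)
        p = rng.uniform(0, 8, 120)
        y = 5 * np.exp(-((g - 4) ** 2 + (p - 4) ** 2) / 4) + rng.normal(0, 0.3, 120)
        df = pd.DataFrame({"g": g, "p": p, "y": y})
        fit = fit_gam(df, "y", [], [SmoothSpec(("g", "p"))])
        peaks = find_peaks(predict_surface(fit, (50, 50)))
        assert len(peaks) == 1
        assert np.hypot(peaks[0].x - 4, peaks[0].y - 4) < 0.5
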