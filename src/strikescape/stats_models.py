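"""Random-intercept linear mixed models and linear discriminant analysis.

The mixed model is ``y = X beta + Z b + e`` with a single random intercept
per individual: ``b ~ N(0, sigma2_b)``, ``e ~ N(0, sigma2_e)``.  Repeated
strikes by the same fish are correlated, and the random intercept absorbs
that.  REML estimates are obtained by profiling the variance ratio
``gamma = sigma2_b / sigma2_e``: for fixed gamma the fixed effects are
generalized least squares and the residual variance has a closed form, so
the REML criterion reduces to a 1-D optimization in log gamma.  Because the
grouping is a simple intercept, ``(I + gamma Z Z')^{-1}`` is block diagonal
with closed-form blocks (Woodbury), so no dense n x n solve is ever needed.

Hypothesis tests use Satterthwaite denominator degrees of freedom computed
from the observed information of ``(sigma2_b, sigma2_e)`` on the REML
surface; multi-degree-of-freedom F tests combine per-eigencontrast df the
way lmerTest does.  Pairwise contrasts of estimated marginal means use the
studentized-range (Tukey) adjustment.

LDA solves the generalized eigenproblem of between- versus within-class
scatter directly; classification uses the Gaussian discriminant rule with
pooled covariance and (by default) empirical class priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import f as f_dist
from scipy.stats import studentized_range, t as t_dist


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design matrix construction (treatment coding, intercept always included)
# ---------------------------------------------------------------------------


def _build_design(
    table: pd.DataFrame, fixed_factors: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]], dict[str, list]]:
    """Treatment-coded design matrix with a term -> column-index map."""
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    term_cols: dict[str, list[int]] = {}
    levels: dict[str, list] = {}
    for term in fixed_factors:
        x = table[term]
        if x.dtype.kind in "OUSb" or isinstance(x.dtype, pd.CategoricalDtype):
            lv = sorted(pd.unique(x.dropna()))
            if len(lv) < 2:
                raise ModelError(f"factor {term!r} has < 2 levels after cleaning")
            levels[term] = lv
            idx = []
            for l in lv[1:]:
                idx.append(len(cols))
                cols.append((x == l).to_numpy(dtype=float))
                names.append(f"{term}[{l}]")
            term_cols[term] = idx
        else:
            term_cols[term] = [len(cols)]
            cols.append(x.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("singular fixed-effect design matrix")
    return X, names, term_cols, levels


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _group_slices(groups: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def _gls_pieces(X, y, slices, gamma):
    """A = X'V0^-1 X, b = X'V0^-1 y, quadratic form pieces and log|V0|.

    V0 = I + gamma Z Z' is block diagonal; per block of size m its inverse is
    I - (gamma / (1 + gamma m)) J.
    """
    p = X.shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    for idx in slices:
        Xi, yi = X[idx], y[idx]
        m = len(idx)
        c = gamma / (1.0 + gamma * m)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        A += Xi.T @ Xi - c * np.outer(sx, sx)
        bvec += Xi.T @ yi - c * sx * sy
        yVy += yi @ yi - c * sy * sy
        logdet += np.log1p(gamma * m)
    return A, bvec, yVy, logdet


def _profiled_neg2_reml(X, y, slices, gamma, method="REML"):
    n, p = X.shape
    A, bvec, yVy, logdet = _gls_pieces(X, y, slices, gamma)
    beta = linalg.solve(A, bvec, assume_a="pos")
    rss = yVy - bvec @ beta  # r' V0^-1 r at the GLS solution
    if rss <= 0:
        rss = 1e-300
    if method == "REML":
        dof = n - p
        sig2 = rss / dof
        _, ld_A = np.linalg.slogdet(A)
        val = dof * np.log(2 * np.pi * sig2) + dof + logdet + ld_A
    else:  # ML
        sig2 = rss / n
        val = n * np.log(2 * np.pi * sig2) + n + logdet
    return val, beta, sig2, A


@dataclass
class LMMFit:
    """A fitted random-intercept linear mixed model."""

    response: str
    fixed_factors: list[str]
    group: str
    coef: pd.Series
    sigma2_individual: float
    sigma2_residual: float
    loglik: float
    method: str
    converged: bool
    n_obs: int
    n_groups: int
    fitted: np.ndarray
    residuals: np.ndarray
    aic: float
    # internals needed by the tests/contrasts
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)
    term_cols: dict = field(repr=False, default_factory=dict)
    factor_levels: dict = field(repr=False, default_factory=dict)

    @property
    def gamma(self) -> float:
        return self.sigma2_individual / self.sigma2_residual

    def coef_cov(self, theta: tuple[float, float] | None = None) -> np.ndarray:
        """Covariance of fixed effects at variance components theta."""
        s2b, s2e = theta if theta is not None else (
            self.sigma2_individual,
            self.sigma2_residual,
        )
        slices = _group_slices(self.groups)
        A, _, _, _ = _gls_pieces(self.X, self.y, slices, s2b / s2e)
        return s2e * linalg.inv(A)

    def qq_table(self) -> pd.DataFrame:
        """Quantile-quantile table of standardized residuals (normality check)."""
        from scipy.stats import norm

        r = np.sort(self.residuals / np.std(self.residuals, ddof=1))
        n = len(r)
        theo = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        return pd.DataFrame({"theoretical": theo, "sample": r})


def fit_lmm_reml(
    table: pd.DataFrame,
    response: str,
    fixed_factors: list[str],
    group: str,
    method: str = "REML",
) -> LMMFit:
    """Fit a random-intercept LMM by profiled REML (or ML for AIC comparison).

    The variance ratio ``gamma`` is optimized on a log grid + bounded scalar
    search, with the boundary ``gamma = 0`` always considered, so a
    zero-variance random effect is estimated at the boundary rather than
    causing non-convergence.
    """
    data = table.dropna(subset=[response, group, *fixed_factors]).reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    groups = data[group].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise ModelError("need at least 2 grouping levels")
    X, names, term_cols, levels = _build_design(data, fixed_factors)
    slices = _group_slices(groups)
    n, p = X.shape

    def obj(log_gamma: float) -> float:
        return _profiled_neg2_reml(X, y, slices, np.exp(log_gamma), method)[0]

    # multi-start bounded search over log gamma, plus the boundary
    best_lg, best_val = None, np.inf
    for lo, hi in [(-12.0, 0.0), (0.0, 12.0), (-30.0, -12.0)]:
        res = optimize.minimize_scalar(
            obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
        )
        if res.fun < best_val:
            best_val, best_lg = res.fun, float(res.x)
    val0 = _profiled_neg2_reml(X, y, slices, 0.0, method)[0]
    if val0 <= best_val + 1e-9:
        gamma_hat, best_val = 0.0, val0
    else:
        gamma_hat = float(np.exp(best_lg))

    val, beta, sig2e, A = _profiled_neg2_reml(X, y, slices, gamma_hat, method)
    sig2b = gamma_hat * sig2e
    fitted = X @ beta
    # BLUP-free marginal residuals (used for the qq normality check)
    resid = y - fitted
    n_par = p + 2  # fixed effects + two variance components
    aic = val + 2 * n_par
    return LMMFit(
        response=response,
        fixed_factors=list(fixed_factors),
        group=group,
        coef=pd.Series(beta, index=names),
        sigma2_individual=sig2b,
        sigma2_residual=sig2e,
        loglik=-0.5 * val,
        method=method,
        converged=True,
        n_obs=n,
        n_groups=len(slices),
        fitted=fitted,
        residuals=resid,
        aic=aic,
        X=X,
        y=y,
        groups=groups,
        term_cols=term_cols,
        factor_levels=levels,
    )


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------


def _reml_loglik_theta(fit: LMMFit, s2b: float, s2e: float) -> float:
    """Unprofiled REML log-likelihood at variance components (s2b, s2e)."""
    X, y = fit.X, fit.y
    slices = _group_slices(fit.groups)
    n, p = X.shape
    gamma = s2b / s2e
    A0, bvec, yVy, logdet0 = _gls_pieces(X, y, slices, gamma)
    beta = linalg.solve(A0, bvec, assume_a="pos")
    rss = yVy - bvec @ beta
    _, ld_A = np.linalg.slogdet(A0 / s2e)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi * s2e) + logdet0 + rss / s2e + ld_A
    )


def _theta_cov(fit: LMMFit, rel_step: float = 1e-5) -> np.ndarray:
    """Covariance of (s2b_hat, s2e_hat): inverse observed REML information.

    Finite-difference Hessian with a relative step; at the gamma = 0
    boundary the s2b coordinate steps forward only, keeping V positive
    definite.
    """
    th = np.array([fit.sigma2_individual, fit.sigma2_residual])
    h = rel_step * np.maximum(np.abs(th), fit.sigma2_residual)

    def ll(t):
        return _reml_loglik_theta(fit, max(t[0], 0.0), t[1])

    H = np.zeros((2, 2))
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        H[i, i] = (ll(th + ei) - 2 * ll(th) + ll(th - ei)) / h[i] ** 2 \
            if th[i] - h[i] > 0 else (ll(th + 2 * ei) - 2 * ll(th + ei) + ll(th)) / h[i] ** 2
    e0 = np.array([h[0], 0.0])
    e1 = np.array([0.0, h[1]])
    if th[0] - h[0] > 0:
        H[0, 1] = H[1, 0] = (
            ll(th + e0 + e1) - ll(th + e0 - e1) - ll(th - e0 + e1) + ll(th - e0 - e1)
        ) / (4 * h[0] * h[1])
    else:
        H[0, 1] = H[1, 0] = (
            ll(th + e0 + e1) - ll(th + e0) - ll(th + e1) + ll(th)
        ) / (h[0] * h[1])
    info = -H
    try:
        return linalg.inv(info)
    except linalg.LinAlgError:
        return linalg.pinvh(info)


def _contrast_var_grad(fit: LMMFit, L: np.ndarray) -> tuple[float, np.ndarray]:
    """f(theta) = L C(theta) L' for a single contrast row, and its FD gradient."""
    th = np.array([fit.sigma2_individual, fit.sigma2_residual])

    def f(t):
        C = fit.coef_cov((max(t[0], 0.0), t[1]))
        return float(L @ C @ L)

    h = 1e-5 * np.maximum(np.abs(th), fit.sigma2_residual)
    g = np.zeros(2)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        if th[i] - h[i] > 0:
            g[i] = (f(th + ei) - f(th - ei)) / (2 * h[i])
        else:
            g[i] = (f(th + ei) - f(th)) / h[i]
    return f(th), g


def satterthwaite_df(fit: LMMFit, L: np.ndarray) -> float:
    """Satterthwaite denominator df for the scalar contrast L beta."""
    fval, g = _contrast_var_grad(fit, np.asarray(L, dtype=float))
    A = _theta_cov(fit)
    denom = float(g @ A @ g)
    if denom <= 0:
        return float(fit.n_obs - fit.X.shape[1])
    return 2.0 * fval**2 / denom


def type2_anova(fit: LMMFit) -> pd.DataFrame:
    """Type II F tests per fixed factor with Satterthwaite denominator df.

    Each factor is tested adjusting for the other fixed factors (the model
    has no interactions, so the Wald test of the factor's coefficients is
    the type II test).  Multi-df denominator df combine per-eigencontrast
    Satterthwaite df.
    """
    if not fit.converged:
        raise ModelError("fit did not converge")
    C = fit.coef_cov()
    beta = fit.coef.to_numpy()
    A_th = _theta_cov(fit)
    rows = []
    for term, cols in fit.term_cols.items():
        q = len(cols)
        L = np.zeros((q, len(beta)))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        M = L @ C @ L.T
        Lb = L @ beta
        try:
            F = float(Lb @ linalg.solve(M, Lb, assume_a="pos")) / q
        except linalg.LinAlgError:
            raise ModelError(f"non-estimable contrast for factor {term!r}")
        # eigendecompose the contrast covariance -> independent 1-df pieces
        w, P = linalg.eigh(M)
        keep = w > 1e-12 * w.max()
        nus = []
        for k in np.flatnonzero(keep):
            Lk = P[:, k] @ L
            fval, g = _contrast_var_grad(fit, Lk)
            den = float(g @ A_th @ g)
            nus.append(2 * fval**2 / den if den > 0 else fit.n_obs - len(beta))
        nus = np.asarray(nus)
        good = nus > 2
        if good.any():
            E = float(np.sum(nus[good] / (nus[good] - 2)))
            ddf = 2 * E / (E - good.sum()) if E > good.sum() else float(np.min(nus))
        else:
            ddf = float(np.min(nus))
        p = float(f_dist.sf(F, q, ddf))
        rows.append(
            {"factor": term, "F": F, "num_df": q, "den_df": ddf, "p_value": p}
        )
    return pd.DataFrame(rows)


def pairwise_contrasts(
    fit: LMMFit, factor: str, adjust: str = "tukey"
) -> pd.DataFrame:
    """All pairwise differences of estimated marginal means for one factor.

    With treatment coding and an additive model, EMM differences reduce to
    coefficient differences.  Tukey adjustment uses the studentized range
    with Satterthwaite df per contrast.
    """
    if factor not in fit.factor_levels:
        raise ModelError(f"{factor!r} is not a categorical fixed factor of this fit")
    lv = fit.factor_levels[factor]
    if len(lv) < 2:
        raise ModelError(f"factor {factor!r} has < 2 levels")
    k = len(lv)
    p = len(fit.coef)
    # coefficient vector per level: reference level -> zeros
    vecs = {lv[0]: np.zeros(p)}
    for l, c in zip(lv[1:], fit.term_cols[factor]):
        v = np.zeros(p)
        v[c] = 1.0
        vecs[l] = v
    C = fit.coef_cov()
    beta = fit.coef.to_numpy()
    rows = []
    for a, b in combinations(lv, 2):
        L = vecs[a] - vecs[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ C @ L))
        df = satterthwaite_df(fit, L)
        tstat = est / se if se > 0 else 0.0
        if adjust == "tukey" and k > 2:
            pval = float(studentized_range.sf(abs(tstat) * np.sqrt(2), k, df))
        else:
            pval = float(2 * t_dist.sf(abs(tstat), df))
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "df": df,
                "t": tstat,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)


def compare_lmm_aic(fits: list[LMMFit]) -> pd.DataFrame:
    """AIC table for alternative mixed-model specifications (ML-based)."""
    if any(f.method != "ML" for f in fits):
        raise ModelError("AIC comparison across fixed-effect structures requires ML fits")
    df = pd.DataFrame(
        {
            "model": [" + ".join(f.fixed_factors) for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values("aic", ignore_index=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# linear discriminant analysis
# ---------------------------------------------------------------------------


@dataclass
class LDAFit:
    """Discriminant axes from the between/within generalized eigenproblem."""

    scalings: np.ndarray  # variables x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # per-axis between/within variance ratio
    group_means: pd.DataFrame  # groups x variables
    priors: pd.Series
    pooled_cov: np.ndarray
    variable_names: list[str]

    @property
    def n_axes(self) -> int:
        return self.scalings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        center = (self.priors.to_numpy() @ self.group_means.to_numpy())
        return (X - center) @ self.scalings

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Gaussian LDA rule: largest discriminant score with group priors."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.variable_names):
            raise ModelError(
                f"expected {len(self.variable_names)} variables, got {X.shape[1]}"
            )
        M = self.group_means.to_numpy()
        Sinv_M = linalg.solve(self.pooled_cov, M.T, assume_a="pos")  # p x g
        lin = X @ Sinv_M  # n x g
        const = -0.5 * np.einsum("gp,pg->g", M, Sinv_M) + np.log(
            self.priors.to_numpy()
        )
        labels = np.asarray(self.group_means.index)
        return labels[np.argmax(lin + const, axis=1)]


def lda_fit(
    X: np.ndarray,
    labels,
    *,
    variable_names: list[str] | None = None,
    priors: str = "empirical",
) -> LDAFit:
    """Fit LDA axes by the generalized eigenproblem Sb v = lambda Sw v.

    Axes are ordered by decreasing between/within variance ratio; at most
    ``min(groups - 1, variables)`` axes are returned.  A singular
    within-class scatter gets a tiny diagonal ridge (1e-8 x trace / p).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    if g < 2:
        raise ModelError("need at least 2 classes")
    if n <= p:
        raise ModelError(f"need more observations ({n}) than variables ({p})")
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = np.zeros((g, p))
    for i, lab in enumerate(groups):
        Xi = X[labels == lab]
        mi = Xi.mean(axis=0)
        means[i] = mi
        d = Xi - mi
        Sw += d.T @ d
        Sb += len(Xi) * np.outer(mi - grand, mi - grand)
    if np.linalg.matrix_rank(Sw) < p:
        Sw = Sw + (1e-8 * np.trace(Sw) / p) * np.eye(p)
    w, V = linalg.eigh(Sb, Sw)
    order = np.argsort(w)[::-1]
    n_axes = min(g - 1, p)
    V = V[:, order[:n_axes]]
    w = np.maximum(w[order[:n_axes]], 0.0)
    if priors == "equal":
        pri = np.full(g, 1.0 / g)
    else:
        pri = counts / n
    names = variable_names or [f"x{i}" for i in range(p)]
    return LDAFit(
        scalings=V,
        eigenvalues=w,
        group_means=pd.DataFrame(means, index=groups, columns=names),
        priors=pd.Series(pri, index=groups),
        pooled_cov=Sw / (n - g),
        variable_names=names,
    )


def lda_accuracy(
    fit: LDAFit, X: np.ndarray, labels, scheme: str = "resubstitution"
) -> float:
    """Fraction of observations classified into their own group.

    ``resubstitution`` scores the supplied fit on the supplied data;
    ``loo`` refits without each observation in turn (an honest error rate
    for small samples).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if scheme == "resubstitution":
        return float(np.mean(fit.predict(X) == labels))
    if scheme != "loo":
        raise ModelError(f"unknown scheme {scheme!r}")
    hits = 0
    for i in range(len(X)):
        keep = np.ones(len(X), dtype=bool)
        keep[i] = False
        if len(np.unique(labels[keep])) < 2:
            continue  # degenerate: class vanished; cannot score this point
        sub = lda_fit(X[keep], labels[keep], variable_names=fit.variable_names)
        hits += int(sub.predict(X[i : i + 1])[0] == labels[i])
    return hits / len(X)


def confusion_matrix(fit: LDAFit, X: np.ndarray, labels) -> pd.DataFrame:
    """Rows = true group, columns = predicted group, counts."""
    pred = fit.predict(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    groups = list(fit.group_means.index)
    mat = pd.DataFrame(0, index=groups, columns=groups)
    for t, p_ in zip(labels, pred):
        mat.loc[t, p_] += 1
    return mat
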