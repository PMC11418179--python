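"""Penalized thin-plate-spline GAMs and the bite performance landscape.

Bite performance (length or volume of gel removed per strike) is modeled as

    y = parametric terms (species, strike type, linear kinematics)
        + f(peak gape, peak protrusion) + e

where ``f`` is a thin-plate spline: radial basis eta(r) = r^2 log r in 2D
(|r|^3 in 1D) about space-filling knots, plus a polynomial null space
{1, x, y}, with a curvature penalty that is positive semidefinite with
null-space dimension 3.  Smoothness (lambda per smooth) is selected by the
exact Gaussian REML criterion; effective degrees of freedom (edf) are the
trace of the influence matrix.  Shrinkage smooths add a light penalty on
the null space so irrelevant terms can shrink to ~0 edf during selection.

The fitted surface over a (gape, protrusion) grid is masked to the region
supported by observations (no extrapolated "peaks") and scanned for local
maxima over the 8-neighborhood; saddle heights between peak pairs are
computed by a union-find sweep (the valley diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial import cKDTree

from .stats_models import _build_design, ModelError


class GAMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# thin-plate spline basis
# ---------------------------------------------------------------------------


def _tps_eta(r: np.ndarray, d: int) -> np.ndarray:
    """TPS radial function: r^2 log r in 2D, |r|^3 in 1D (0 at r = 0)."""
    r = np.asarray(r, dtype=float)
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
        return out
    if d == 1:
        return np.abs(r) ** 3
    raise GAMError(f"thin-plate basis implemented for 1 or 2 variables, not {d}")


def _radial_matrix(a: np.ndarray, b: np.ndarray, d: int) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return _tps_eta(np.sqrt((diff**2).sum(axis=2)), d)


def _poly_cols(x: np.ndarray) -> np.ndarray:
    """Null-space polynomial columns {1, x, (y)}."""
    return np.column_stack([np.ones(len(x)), x])


def farthest_point_knots(points: np.ndarray, k: int) -> np.ndarray:
    """Space-filling knot subset by greedy farthest-point thinning.

    Deterministic: starts from the point farthest from the centroid, then
    repeatedly adds the observation maximizing its distance to the chosen
    set.  Duplicated coordinates are collapsed first.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) <= k:
        return pts
    centroid = pts.mean(axis=0)
    chosen = [int(np.argmax(((pts - centroid) ** 2).sum(axis=1)))]
    dist = np.sqrt(((pts - pts[chosen[0]]) ** 2).sum(axis=1))
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.sqrt(((pts - pts[nxt]) ** 2).sum(axis=1)))
    return pts[chosen]


def tps_basis_2d(
    points: np.ndarray, knots: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Thin-plate basis and penalty about a knot set (2D, or 1D points).

    Returns ``(B, S)`` in the null-space-absorbed parametrization: the
    first ``m - M`` columns are radial (penalized), the last ``M`` are the
    polynomial null space {1, x, y} (unpenalized), where ``m`` is the knot
    count and ``M = d + 1``.  ``S`` is positive semidefinite with exactly
    ``M`` zero eigenvalues; any coefficient vector confined to the null
    space has zero penalty by construction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    knots = np.atleast_2d(np.asarray(knots, dtype=float))
    if points.shape[1] != knots.shape[1]:
        raise GAMError("points and knots must share dimension")
    d = knots.shape[1]
    M = d + 1
    if len(np.unique(knots, axis=0)) != len(knots):
        raise GAMError("duplicate knots")
    if len(knots) < M + 1:
        raise GAMError(f"need at least {M + 1} distinct knots")
    Tk = _poly_cols(knots)  # m x M
    Ekk = _radial_matrix(knots, knots, d)
    # absorb the conditional-positive-definiteness constraint T' delta = 0
    Z = linalg.null_space(Tk.T)  # m x (m - M)
    S_rad = Z.T @ Ekk @ Z
    S_rad = 0.5 * (S_rad + S_rad.T)
    B = np.column_stack([_radial_matrix(points, knots, d) @ Z, _poly_cols(points)])
    S = np.zeros((B.shape[1], B.shape[1]))
    S[: S_rad.shape[0], : S_rad.shape[0]] = S_rad
    return B, S


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothSpec:
    """One smooth term: 1 or 2 covariates, basis size, optional shrinkage."""

    variables: tuple[str, ...]
    k: int | None = None  # default: 30 for 2D, 10 for 1D
    shrinkage: bool = False

    def __post_init__(self):
        if len(self.variables) not in (1, 2):
            raise GAMError("a smooth takes 1 or 2 variables")
        d = len(self.variables)
        k = self.k if self.k is not None else (30 if d == 2 else 10)
        if k < d + 2:
            raise GAMError(f"basis size k={k} below null-space dimension + 1")
        object.__setattr__(self, "k", k)

    @property
    def label(self) -> str:
        return "s(" + ",".join(self.variables) + ")"


@dataclass
class _FittedSmooth:
    spec: SmoothSpec
    knots: np.ndarray
    Z: np.ndarray
    col_means: np.ndarray
    cols: slice
    S_block: np.ndarray  # penalty on this block (possibly shrinkage-modified)
    rank: int
    logdet_pos: float
    lam: float = np.nan
    edf: float = np.nan

    def build(self, values: np.ndarray) -> np.ndarray:
        """Centered basis columns for new covariate values (n x d array)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        d = self.knots.shape[1]
        E = _radial_matrix(values, self.knots, d) @ self.Z
        P = values  # linear columns only; intercept absorbed by the model
        return np.column_stack([E, P]) - self.col_means


def _make_smooth(
    spec: SmoothSpec, data: pd.DataFrame, null_penalty: float
) -> tuple[np.ndarray, "_FittedSmooth"]:
    pts = data[list(spec.variables)].to_numpy(dtype=float)
    d = pts.shape[1]
    knots = farthest_point_knots(pts, spec.k)
    if len(knots) < d + 2:
        raise GAMError(f"{spec.label}: too few distinct covariate points")
    Tk = _poly_cols(knots)
    Z = linalg.null_space(Tk.T)
    S_rad = Z.T @ _radial_matrix(knots, knots, d) @ Z
    S_rad = 0.5 * (S_rad + S_rad.T)
    raw = np.column_stack([_radial_matrix(pts, knots, d) @ Z, pts])
    col_means = raw.mean(axis=0)
    B = raw - col_means  # sum-to-zero constraint: intercept lives elsewhere
    p_block = B.shape[1]
    S = np.zeros((p_block, p_block))
    S[: S_rad.shape[0], : S_rad.shape[0]] = S_rad
    if null_penalty > 0:
        # shrinkage: lightly penalize the (linear) null space so the whole
        # term can be shrunk to ~0 edf if the covariate is irrelevant
        scale = null_penalty * np.trace(S_rad) / S_rad.shape[0]
        S[S_rad.shape[0] :, S_rad.shape[0] :] = scale * np.eye(d)
    ev = linalg.eigvalsh(S)
    pos = ev[ev > 1e-10 * max(ev.max(), 1.0)]
    fitted = _FittedSmooth(
        spec=spec,
        knots=knots,
        Z=Z,
        col_means=col_means,
        cols=slice(0, 0),  # set by caller
        S_block=S,
        rank=len(pos),
        logdet_pos=float(np.sum(np.log(pos))),
    )
    return B, fitted


@dataclass
class GAMFit:
    """A penalized-spline additive model fit."""

    response: str
    parametric_terms: list[str]
    smooths: list[_FittedSmooth]
    coef: np.ndarray
    coef_names: list[str]
    lambdas: np.ndarray
    edf_by_smooth: dict[str, float]
    edf_parametric: float
    edf_total: float
    reml_score: float
    aic: float
    sigma2: float
    rss: float
    fitted: np.ndarray
    n_obs: int
    converged: bool
    # prediction context
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    Vb: np.ndarray = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    para_cols: dict = field(repr=False, default_factory=dict)
    factor_levels: dict = field(repr=False, default_factory=dict)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    def predict(self, newdata: pd.DataFrame, se: bool = False):
        X = self._design(newdata)
        mu = X @ self.coef
        if not se:
            return mu
        sev = np.sqrt(np.einsum("ij,jk,ik->i", X, self.Vb, X))
        return mu, sev

    def _design(self, newdata: pd.DataFrame) -> np.ndarray:
        n = len(newdata)
        p = len(self.coef)
        X = np.zeros((n, p))
        X[:, 0] = 1.0
        for term, cols in self.para_cols.items():
            if term == "Intercept":
                continue
            if term in self.factor_levels:
                lv = self.factor_levels[term]
                for l, c in zip(lv[1:], cols):
                    X[:, c] = (newdata[term] == l).to_numpy(dtype=float)
            else:
                X[:, cols[0]] = newdata[term].to_numpy(dtype=float)
        for sm in self.smooths:
            vals = newdata[list(sm.spec.variables)].to_numpy(dtype=float)
            X[:, sm.cols] = sm.build(vals)
        return X


def _assemble(
    table: pd.DataFrame,
    response: str,
    parametric_terms: list[str],
    smooths: list[SmoothSpec],
    null_penalty: float,
):
    need = [response, *parametric_terms, *{v for s in smooths for v in s.variables}]
    data = table.dropna(subset=need).reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    Xp, names, para_cols, levels = _build_design(data, list(parametric_terms))
    blocks = [Xp]
    fitted_smooths: list[_FittedSmooth] = []
    offset = Xp.shape[1]
    for spec in smooths:
        B, fs = _make_smooth(spec, data, null_penalty if spec.shrinkage else 0.0)
        fs.cols = slice(offset, offset + B.shape[1])
        offset += B.shape[1]
        blocks.append(B)
        names += [f"{spec.label}.{j}" for j in range(B.shape[1])]
        fitted_smooths.append(fs)
    X = np.column_stack(blocks)
    return data, y, X, names, para_cols, levels, fitted_smooths


def _penalty_total(p: int, smooths: list[_FittedSmooth], lams: np.ndarray) -> np.ndarray:
    S = np.zeros((p, p))
    for sm, lam in zip(smooths, lams):
        S[sm.cols, sm.cols] += lam * sm.S_block
    return S


def _reml_score(XtX, Xty, yty, n, p_null, smooths, lams):
    """Exact Gaussian REML score (-2 restricted loglik, sigma^2 profiled)."""
    p = XtX.shape[0]
    A = XtX + _penalty_total(p, smooths, lams)
    try:
        cf = linalg.cho_factor(A)
    except linalg.LinAlgError:
        return np.inf, None
    beta = linalg.cho_solve(cf, Xty)
    rss_pen = yty - Xty @ beta  # RSS + beta' S beta at the PLS solution
    if rss_pen <= 0:
        rss_pen = 1e-300
    Mp = p - sum(sm.rank for sm in smooths)
    sig2 = rss_pen / (n - Mp)
    ld_A = 2 * np.sum(np.log(np.diag(cf[0])))
    ld_S = sum(
        sm.rank * np.log(lam) + sm.logdet_pos for sm, lam in zip(smooths, lams)
    )
    score = (n - Mp) * (np.log(2 * np.pi * sig2) + 1) + ld_A - ld_S
    return score, beta


def fit_gam(
    table: pd.DataFrame,
    response: str,
    parametric_terms: list[str] = (),
    smooths: list[SmoothSpec] = (),
    method: str = "REML",
    *,
    lambdas: np.ndarray | None = None,
    null_penalty: float = 0.0,
) -> GAMFit:
    """Fit a Gaussian additive model with REML-selected smoothing.

    For fixed lambda the fit is penalized least squares
    ``beta = (X'X + sum_i lambda_i S_i)^-1 X'y``; lambda is chosen by
    minimizing the exact Gaussian REML score over log lambda with
    multi-start Nelder-Mead (starts at lambda in {1e-3, 1, 1e3}).  Passing
    ``lambdas`` skips selection (used by the oracle tests).  ``null_penalty``
    > 0 activates shrinkage on smooths flagged ``shrinkage=True``.
    """
    smooths = list(smooths)
    data, y, X, names, para_cols, levels, fsm = _assemble(
        table, response, list(parametric_terms), smooths, null_penalty
    )
    n, p = X.shape
    n_null = p - sum(sm.rank for sm in fsm)
    if n <= n_null:
        raise GAMError(f"too few complete rows (n={n}) for the unpenalized part")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    converged = True
    if not fsm:
        lams = np.array([])
    elif lambdas is not None:
        lams = np.asarray(lambdas, dtype=float)
        if len(lams) != len(fsm):
            raise GAMError("one lambda per smooth required")
    else:
        def obj(log_lams):
            s, _ = _reml_score(XtX, Xty, yty, n, n_null, fsm, np.exp(log_lams))
            return s

        starts = [np.full(len(fsm), v) for v in (np.log(1e-3), 0.0, np.log(1e3))]
        best = None
        for x0 in starts:
            if len(fsm) == 1:
                res = optimize.minimize_scalar(
                    lambda v: obj(np.array([v])),
                    bounds=(x0[0] - 12, x0[0] + 12),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                cand = (res.fun, np.array([res.x]), True)
            else:
                res = optimize.minimize(
                    obj,
                    x0,
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 200 * len(fsm)},
                )
                cand = (res.fun, res.x, bool(res.success))
            if best is None or cand[0] < best[0]:
                best = cand
        if not np.isfinite(best[0]):
            raise GAMError("REML optimization failed to find a finite score")
        lams = np.exp(best[1])
        converged = best[2]

    score, beta = _reml_score(XtX, Xty, yty, n, n_null, fsm, lams) if len(fsm) else (
        np.nan,
        None,
    )
    A = XtX + _penalty_total(p, fsm, lams)
    cf = linalg.cho_factor(A)
    if beta is None:
        beta = linalg.cho_solve(cf, Xty)
    F = linalg.cho_solve(cf, XtX)  # influence matrix (coefficient space)
    edf_diag = np.diag(F)
    edf_by = {}
    for sm, lam in zip(fsm, lams):
        sm.lam = float(lam)
        sm.edf = float(edf_diag[sm.cols].sum())
        edf_by[sm.spec.label] = sm.edf
    p_para = len([c for cols in para_cols.values() for c in cols]) + 1
    edf_para = float(edf_diag[:p_para].sum())
    edf_total = float(edf_diag.sum())
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    aic = n * np.log(rss / n) + 2 * (edf_total + 1) + n * np.log(2 * np.pi) + n
    Mp = n_null
    sig2 = (rss + float(beta @ _penalty_total(p, fsm, lams) @ beta)) / (n - Mp)
    Vb = sig2 * linalg.cho_solve(cf, np.eye(p))
    return GAMFit(
        response=response,
        parametric_terms=list(parametric_terms),
        smooths=fsm,
        coef=beta,
        coef_names=names,
        lambdas=lams,
        edf_by_smooth=edf_by,
        edf_parametric=edf_para,
        edf_total=edf_total,
        reml_score=float(score) if np.size(score) else np.nan,
        aic=float(aic),
        sigma2=float(sig2),
        rss=rss,
        fitted=fitted,
        n_obs=n,
        converged=converged,
        X=X,
        y=y,
        Vb=Vb,
        data=data,
        para_cols=para_cols,
        factor_levels=levels,
    )


def fit_gam_shrinkage(
    table: pd.DataFrame,
    response: str,
    parametric_terms: list[str] = (),
    smooths: list[SmoothSpec] = (),
    *,
    null_penalty: float = 0.1,
    **kwargs,
) -> GAMFit:
    """Shrinkage variant: every smooth's null space is lightly penalized.

    With ``null_penalty = 0`` this reproduces :func:`fit_gam` exactly.
    """
    smooths = [
        SmoothSpec(s.variables, s.k, shrinkage=True) for s in smooths
    ]
    return fit_gam(
        table,
        response,
        parametric_terms,
        smooths,
        null_penalty=null_penalty,
        **kwargs,
    )


def compare_models(fits: list[GAMFit], labels: list[str] | None = None) -> pd.DataFrame:
    """AIC model-selection table; fits must share response and data rows."""
    if not fits:
        raise GAMError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if f.response != ref.response or f.n_obs != ref.n_obs or not np.allclose(
            np.sort(f.y), np.sort(ref.y)
        ):
            raise GAMError("fits compare different responses or data")
    labels = labels or [
        " + ".join(f.parametric_terms + [s.spec.label for s in f.smooths]) or "null"
        for f in fits
    ]
    df = pd.DataFrame(
        {
            "model": labels,
            "aic": [f.aic for f in fits],
            "edf_total": [f.edf_total for f in fits],
        }
    ).sort_values("aic", ignore_index=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["equivalent"] = df["delta_aic"] < 2.0
    return df


# ---------------------------------------------------------------------------
# performance surface and peak detection
# ---------------------------------------------------------------------------


@dataclass
class Peak:
    x: float
    y: float
    height: float
    grid_index: tuple[int, int]


@dataclass
class PerformanceSurface:
    """Predicted performance over a (gape, protrusion) grid."""

    x_var: str
    y_var: str
    x: np.ndarray  # grid axis values (nx,)
    y: np.ndarray  # grid axis values (ny,)
    z: np.ndarray  # predictions (nx, ny)
    se: np.ndarray
    support: np.ndarray  # bool (nx, ny); True where data-supported
    peaks: list[Peak] = field(default_factory=list)
    saddles: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        return pd.DataFrame(
            {
                self.x_var: xx.ravel(),
                self.y_var: yy.ravel(),
                "predicted": self.z.ravel(),
                "se": self.se.ravel(),
                "supported": self.support.ravel(),
            }
        )


def predict_surface(
    fit: GAMFit,
    grid: tuple[int, int] = (60, 60),
    *,
    smooth_index: int = 0,
    support_quantile: float = 0.95,
    support_distance: float | None = None,
) -> PerformanceSurface:
    """Predict the 2D smooth's response surface over a rectangular grid.

    Other covariates are held at reference levels (most frequent factor
    level, mean of numeric terms).  The support mask keeps grid points
    within distance ``d`` of at least one observation, with ``d`` defaulting
    to the ``support_quantile`` quantile of nearest-neighbor distances
    among observations — peaks are only ever reported inside this region.
    """
    sms = [s for s in fit.smooths if len(s.spec.variables) == 2]
    if not sms:
        raise GAMError("fit has no 2D smooth to predict a surface from")
    sm = sms[smooth_index]
    xv, yv = sm.spec.variables
    obs = fit.data[[xv, yv]].to_numpy(dtype=float)
    x_lo, y_lo = obs.min(axis=0)
    x_hi, y_hi = obs.max(axis=0)
    nx, ny = grid
    gx = np.linspace(x_lo, x_hi, nx)
    gy = np.linspace(y_lo, y_hi, ny)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    newdata = pd.DataFrame({xv: xx.ravel(), yv: yy.ravel()})
    # reference levels for everything else
    for term in fit.parametric_terms:
        if term in (xv, yv):
            continue
        col = fit.data[term]
        if term in fit.factor_levels:
            newdata[term] = col.mode().iloc[0]
        else:
            newdata[term] = float(col.mean())
    for other in fit.smooths:
        for v in other.spec.variables:
            if v not in newdata.columns:
                newdata[v] = float(fit.data[v].mean())
    mu, se = fit.predict(newdata, se=True)

    tree = cKDTree(obs)
    if support_distance is None:
        nn = tree.query(obs, k=2)[0][:, 1]
        support_distance = float(np.quantile(nn, support_quantile))
    d_grid = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))[0]
    support = (d_grid <= support_distance).reshape(nx, ny)
    if not support.any():
        raise GAMError("no grid point is supported by the observations")
    return PerformanceSurface(
        x_var=xv,
        y_var=yv,
        x=gx,
        y=gy,
        z=mu.reshape(nx, ny),
        se=se.reshape(nx, ny),
        support=support,
    )


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_peaks(
    surface: PerformanceSurface,
    *,
    min_separation: float | None = None,
    min_prominence: float | None = None,
) -> list[Peak]:
    """Local maxima of the supported surface, with saddle heights.

    A candidate peak cell must exceed all 8 neighbors, all of which must
    themselves be supported (so monotone ramps produce no boundary
    "peaks").  Candidates closer than ``min_separation`` (in the grid's
    data units; default 2 grid steps) are merged, keeping the higher.
    Candidates whose topographic prominence — height above the highest
    saddle connecting them to any higher peak, found by a descending
    union-find sweep — falls below ``min_prominence`` (default 5% of the
    supported surface range) are discarded as noise wiggles.  Saddle
    heights between surviving peak pairs are stored in ``surface.saddles``
    (the valley diagnostic).
    """
    z, sup = surface.z, surface.support
    if not sup.any():
        raise GAMError("empty supported region")
    nx, ny = z.shape
    dx = surface.x[1] - surface.x[0] if nx > 1 else 1.0
    dy = surface.y[1] - surface.y[0] if ny > 1 else 1.0
    if min_separation is None:
        min_separation = 2.0 * max(dx, dy)
    if min_prominence is None:
        min_prominence = 0.05 * float(z[sup].max() - z[sup].min())

    raw: list[Peak] = []
    for i in range(nx):
        for j in range(ny):
            if not sup[i, j]:
                continue
            ok = True
            for di, dj in _NEIGHBORS:
                a, b = i + di, j + dj
                if not (0 <= a < nx and 0 <= b < ny) or not sup[a, b]:
                    ok = False  # require a fully supported neighborhood
                    break
                if z[a, b] >= z[i, j]:
                    ok = False
                    break
            if ok:
                raw.append(
                    Peak(
                        x=float(surface.x[i]),
                        y=float(surface.y[j]),
                        height=float(z[i, j]),
                        grid_index=(i, j),
                    )
                )
    raw.sort(key=lambda p: -p.height)
    candidates: list[Peak] = []
    for p in raw:
        if all(
            np.hypot(p.x - q.x, p.y - q.y) >= min_separation for q in candidates
        ):
            candidates.append(p)

    saddles, comp_min = _saddle_sweep(surface, candidates)
    peaks: list[Peak] = []
    for k, p in enumerate(candidates):
        higher_saddles = [
            s
            for (a, b), s in saddles.items()
            if (a == k and candidates[b].height > p.height)
            or (b == k and candidates[a].height > p.height)
        ]
        if higher_saddles:
            prom = p.height - max(higher_saddles)
        else:
            # highest point of its connected component: prominence relative
            # to the lowest supported level it drains to
            prom = p.height - comp_min.get(k, z[sup].min())
        if prom >= min_prominence:
            peaks.append(p)

    surface.peaks = peaks
    surface.saddles = {
        (peaks.index(candidates[a]), peaks.index(candidates[b])): s
        for (a, b), s in saddles.items()
        if candidates[a] in peaks and candidates[b] in peaks
    }
    return peaks


def _saddle_sweep(
    surface: PerformanceSurface, peaks: list[Peak]
) -> tuple[dict, dict]:
    """Descending union-find sweep over supported cells.

    Returns the level at which each peak pair first connects, and per peak
    the minimum height of the connected component it ends up in.
    """
    z, sup = surface.z, surface.support
    nx, ny = z.shape
    cells = [(i, j) for i in range(nx) for j in range(ny) if sup[i, j]]
    cells.sort(key=lambda c: -z[c])
    parent: dict = {}
    peak_of: dict = {}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    peak_cells = {p.grid_index: k for k, p in enumerate(peaks)}
    saddles: dict = {}
    active = set()
    for c in cells:
        parent[c] = c
        peak_of[c] = {peak_cells[c]} if c in peak_cells else set()
        active.add(c)
        i, j = c
        for di, dj in _NEIGHBORS:
            nb = (i + di, j + dj)
            if nb in active:
                ra, rb = find(c), find(nb)
                if ra == rb:
                    continue
                merged = peak_of[ra] | peak_of[rb]
                for a in peak_of[ra]:
                    for b in peak_of[rb]:
                        key = tuple(sorted((a, b)))
                        saddles.setdefault(key, float(z[c]))
                parent[ra] = rb
                peak_of[rb] = merged
    comp_min: dict = {}
    for c in cells:  # last cell of each component in the sweep is its minimum
        comp_min[find(c)] = min(comp_min.get(find(c), np.inf), float(z[c]))
    peak_comp_min = {
        k: comp_min[find(p.grid_index)] for k, p in enumerate(peaks)
    }
    return saddles, peak_comp_min
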