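"""Spatially explicit regression and correlation for gridded diversity data.

Diversity surfaces on geographic grids are spatially autocorrelated, so
ordinary regression understates uncertainty. Three corrections are provided:

* a simultaneous autoregressive (SAR) *error* model
  ``y = X beta + u,  u = lambda W u + eps``, fitted by maximum likelihood
  with the log-determinant evaluated from precomputed eigenvalues of the
  row-standardized neighbor matrix W;
* all-subsets AIC model averaging over SAR fits (Akaike weights, summed
  per-predictor support, full model-averaged coefficients);
* Dutilleul's modified t-test, which corrects a Pearson correlation by an
  effective sample size estimated from both variables' spatial
  autocorrelation profiles.

Responses and predictors are z-standardized before fitting so coefficients
are comparable standardized effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .grids import GridSpec, pairwise_haversine_m

__all__ = [
    "SpatialWeights", "grid_neighbors", "zscore", "fit_ols", "fit_sar_error",
    "nagelkerke_r2", "akaike_weights", "all_subsets_average", "modified_ttest",
    "SARFit", "ModelSet", "DutilleulResult",
]


# ---------------------------------------------------------------- weights

@dataclass
class SpatialWeights:
    """Row-standardized spatial weights on an ordered set of grid cells."""

    cell_ids: np.ndarray
    W: np.ndarray                   # row-standardized, zero diagonal
    scheme: str
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of W (real: W is similar to a symmetric matrix)."""
        if self._eigs is None:
            d = np.count_nonzero(self.W, axis=1).astype(float)
            # W = D^-1 A with symmetric 0/1 A, so W ~ D^-1/2 A D^-1/2
            A = self.W * d[:, None]
            if not np.allclose(A, A.T, atol=1e-10):
                self._eigs = np.sort(np.linalg.eigvals(self.W).real)
            else:
                s = 1.0 / np.sqrt(d)
                self._eigs = np.sort(np.linalg.eigvalsh(A * s[:, None] * s[None, :]))
        return self._eigs

    @property
    def lambda_bounds(self) -> tuple[float, float]:
        e = self.eigenvalues
        return 1.0 / e[0], 1.0 / e[-1]


def grid_neighbors(cell_ids, grid: GridSpec, scheme: str = "queen",
                   k: int = 4) -> SpatialWeights:
    """Queen (8-cell) adjacency on the cell lattice, kNN repair for islands.

    Cells with no lattice neighbor in the set are attached to their ``k``
    nearest cells by great-circle centroid distance; links are symmetrized
    before row standardization so W stays similar to a symmetric matrix.
    """
    cell_ids = np.asarray(sorted(cell_ids), dtype=np.int64)
    n = len(cell_ids)
    if n < 2:
        raise ValueError("need at least 2 cells to build spatial weights")
    if scheme not in ("queen", "knn"):
        raise ValueError(f"unknown scheme {scheme!r}")
    col, row = grid.id_to_colrow(cell_ids)
    A = np.zeros((n, n))
    if scheme == "queen":
        pos = {(c, r): i for i, (c, r) in enumerate(zip(col, row))}
        for i, (c, r) in enumerate(zip(col, row)):
            for dc in (-1, 0, 1):
                for dr in (-1, 0, 1):
                    if dc == dr == 0:
                        continue
                    j = pos.get((c + dc, r + dr))
                    if j is not None:
                        A[i, j] = 1.0
    lon, lat = grid.cell_center(cell_ids)
    D = pairwise_haversine_m(lon, lat)
    np.fill_diagonal(D, np.inf)
    island = np.flatnonzero(A.sum(axis=1) == 0) if scheme == "queen" else range(n)
    kk = min(k, n - 1)
    for i in island:
        nearest = np.argpartition(D[i], kk - 1)[:kk]
        A[i, nearest] = 1.0
    A = np.maximum(A, A.T)
    W = A / A.sum(axis=1, keepdims=True)
    return SpatialWeights(cell_ids, W, scheme)


# ---------------------------------------------------------------- fitting

def zscore(df: pd.DataFrame | pd.Series):
    """Standardize to zero mean, unit (sample) SD."""
    sd = df.std(ddof=1)
    if np.any(np.asarray(sd) == 0):
        raise ValueError("cannot z-standardize a constant column")
    return (df - df.mean()) / sd


@dataclass
class SARFit:
    """One fitted SAR error (or, with lam=0 frozen, OLS) model."""

    lam: float                       # spatial error coefficient lambda
    beta: pd.Series                  # coefficients, "(Intercept)" first
    se: pd.Series                    # asymptotic standard errors of beta
    sigma2: float
    loglik: float
    n: int
    k: int                           # parameter count used in AIC

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC."""
        return self.aic + 2.0 * self.k * (self.k + 1) / (self.n - self.k - 1)

    def zvalues(self) -> pd.Series:
        return self.beta / self.se

    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues())), index=self.beta.index)


def _design(X: pd.DataFrame | None, n: int):
    if X is None or X.shape[1] == 0:
        return np.ones((n, 1)), ["(Intercept)"]
    M = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
    return M, ["(Intercept)", *X.columns]


def _check_rank(X: pd.DataFrame) -> None:
    M = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = []
        for j, name in enumerate(X.columns):
            others = np.delete(M, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, M[:, j], rcond=None)
            if np.allclose(others @ proj, M[:, j], atol=1e-8):
                bad.append(name)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_ols(y: pd.Series, X: pd.DataFrame | None) -> SARFit:
    """Gaussian ML linear regression (lambda frozen at 0).

    AIC uses k = #coefficients + 1 (for sigma^2) + 1 (for the lambda slot),
    so OLS and SAR fits are scored on the same parameter ruler and a SAR fit
    with lambda-hat = 0 matches OLS exactly.
    """
    n = len(y)
    M, names = _design(X, n)
    if X is not None and X.shape[1]:
        _check_rank(X)
    if n <= M.shape[1] + 2:
        raise ValueError("too few observations for the requested design")
    beta, *_ = np.linalg.lstsq(M, np.asarray(y, dtype=float), rcond=None)
    e = np.asarray(y, dtype=float) - M @ beta
    sigma2 = e @ e / n
    loglik = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    return SARFit(0.0, pd.Series(beta, index=names), pd.Series(se, index=names),
                  float(sigma2), float(loglik), n, k=len(names) + 2)


def fit_sar_error(y: pd.Series, X: pd.DataFrame | None,
                  weights: SpatialWeights, lam: float | None = None) -> SARFit:
    """ML fit of the SAR error model by profile likelihood in lambda.

    For a trial lambda the data are filtered by (I - lambda W); beta and
    sigma^2 then have closed forms and the concentrated log-likelihood is
    ``-(n/2)(ln 2pi + ln sigma2 + 1) + sum ln(1 - lambda e_i)`` over the
    eigenvalues e_i of W. Lambda is found by bounded scalar optimization,
    or held fixed when ``lam`` is given (lam=0 reproduces OLS exactly).
    """
    n = len(y)
    if n != weights.n:
        raise ValueError("weights do not match the number of observations")
    yv = np.asarray(y, dtype=float)
    M, names = _design(X, n)
    if X is not None and X.shape[1]:
        _check_rank(X)
    if n <= M.shape[1] + 2:
        raise ValueError("too few observations for the requested design")
    W = weights.W
    eigs = weights.eigenvalues
    lo, hi = weights.lambda_bounds
    lo, hi = lo + 1e-6, hi - 1e-6

    Wy, WM = W @ yv, W @ M

    def concentrated(lam: float):
        ys = yv - lam * Wy
        Ms = M - lam * WM
        beta, *_ = np.linalg.lstsq(Ms, ys, rcond=None)
        e = ys - Ms @ beta
        sigma2 = e @ e / n
        logdet = np.log1p(-lam * eigs).sum()
        ll = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet
        return ll, beta, sigma2, Ms

    if lam is None:
        res = minimize_scalar(lambda la: -concentrated(la)[0], bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-10})
        if not res.success:
            raise RuntimeError(f"SAR profile-likelihood optimization failed: {res.message}")
        lam = float(res.x)
        if min(lam - lo, hi - lam) < 1e-4:
            import warnings
            warnings.warn(f"lambda-hat = {lam:.4f} sits at the feasible boundary",
                          stacklevel=2)
    elif not (lo <= lam <= hi):
        raise ValueError(f"fixed lambda {lam} outside the feasible interval")
    ll, beta, sigma2, Ms = concentrated(lam)
    cov = sigma2 * np.linalg.inv(Ms.T @ Ms)
    se = np.sqrt(np.diag(cov))
    return SARFit(lam, pd.Series(beta, index=names), pd.Series(se, index=names),
                  float(sigma2), float(ll), n, k=len(names) + 2)


def nagelkerke_r2(fit: SARFit, null_fit: SARFit) -> float:
    """Nagelkerke pseudo-R^2 of a fit against the intercept-only null."""
    n = fit.n
    ll, ll0 = fit.loglik, null_fit.loglik
    if ll < ll0:
        import warnings
        warnings.warn("model log-likelihood below the null; pseudo-R^2 <= 0",
                      stacklevel=2)
    num = 1.0 - np.exp(-2.0 / n * (ll - ll0))
    den = 1.0 - np.exp(2.0 / n * ll0)
    return float(num / den)


# ------------------------------------------------------- model averaging

def akaike_weights(aics) -> np.ndarray:
    """exp(-dAIC/2) normalized over the candidate set (sums to 1)."""
    aics = np.asarray(aics, dtype=float)
    w = np.exp(-(aics - aics.min()) / 2.0)
    return w / w.sum()


def signif_code(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class ModelSet:
    """All-subsets SAR model comparison for one response."""

    response: str
    predictors: list[str]
    models: pd.DataFrame             # one row per subset: terms, aic, weight
    best: SARFit
    null: SARFit
    support: pd.Series               # per-predictor summed Akaike weight w
    coef_ave: pd.Series              # full model-averaged coefficients
    coef_ave_p: pd.Series            # z-test p of the averaged coefficient

    @property
    def w1(self) -> float:
        return float(self.models["weight"].max())

    @property
    def r2(self) -> float:
        return nagelkerke_r2(self.best, self.null)

    def table(self) -> pd.DataFrame:
        """Per-predictor table shaped like a model-averaging results table."""
        best_p = self.best.pvalues()
        rows = []
        for term in self.predictors:
            in_best = term in self.best.beta.index
            coef = self.best.beta[term] if in_best else np.nan
            rows.append({
                "term": term,
                "Coef": coef,
                "Coef_signif": signif_code(best_p[term]) if in_best else "",
                "w": self.support[term],
                "Coef_ave": self.coef_ave[term],
                "Coef_ave_signif": signif_code(self.coef_ave_p[term]),
            })
        out = pd.DataFrame(rows)
        out.attrs["R2"] = self.r2
        out.attrs["w1"] = self.w1
        out.attrs["response"] = self.response
        return out


def check_collinearity(X: pd.DataFrame, threshold: float = 0.7) -> None:
    """Refuse predictor sets with strongly correlated pairs.

    Mirrors standard practice of splitting such predictors into separate
    candidate model groups rather than averaging over an ill-posed set.
    """
    corr = X.corr().abs()
    for a, b in combinations(X.columns, 2):
        if corr.loc[a, b] >= threshold:
            raise ValueError(
                f"|r({a}, {b})| = {corr.loc[a, b]:.3f} >= {threshold}; "
                "split these predictors into separate model groups"
            )


def all_subsets_average(y: pd.Series, X: pd.DataFrame, weights: SpatialWeights,
                        predictor_set: list[str] | None = None,
                        collinearity_threshold: float = 0.7,
                        standardize: bool = True, ic: str = "aic") -> ModelSet:
    """Fit every non-empty predictor subset as a SAR error model and average.

    Akaike weights are exp(-dAIC/2) normalized over the subsets; each
    predictor's support w sums the weights of models containing it, and
    Coef_ave is the *full* average (coefficient taken as 0 in models that
    exclude the predictor), as is standard for multimodel inference with
    weak predictors.
    """
    predictors = list(predictor_set or X.columns)
    X = X[predictors].astype(float)
    check_collinearity(X, collinearity_threshold)
    if standardize:
        y = zscore(y)
        X = zscore(X)
    null = fit_sar_error(y, None, weights)
    fits = []
    for r in range(1, len(predictors) + 1):
        for subset in combinations(predictors, r):
            fits.append((subset, fit_sar_error(y, X[list(subset)], weights)))
    if ic not in ("aic", "aicc"):
        raise ValueError(f"ic must be 'aic' or 'aicc', got {ic!r}")
    aics = np.array([getattr(f, ic) for _, f in fits])
    delta = aics - aics.min()
    w = akaike_weights(aics)
    best_idx = int(np.argmin(aics))
    support = pd.Series(0.0, index=predictors)
    coef_ave = pd.Series(0.0, index=predictors)
    var_ave = pd.Series(0.0, index=predictors)
    for (subset, fit), wi in zip(fits, w):
        for term in subset:
            support[term] += wi
            coef_ave[term] += wi * fit.beta[term]
            # unconditional variance (Buckland et al.): model variance plus
            # between-model spread, accumulated below
    for term in predictors:
        acc = 0.0
        for (subset, fit), wi in zip(fits, w):
            b = fit.beta[term] if term in subset else 0.0
            s = fit.se[term] if term in subset else 0.0
            acc += wi * np.sqrt(s ** 2 + (b - coef_ave[term]) ** 2)
        var_ave[term] = acc ** 2
    zvals = coef_ave / np.sqrt(var_ave.where(var_ave > 0, np.inf))
    coef_ave_p = pd.Series(2 * stats.norm.sf(np.abs(zvals)), index=predictors)
    models = pd.DataFrame({
        "terms": ["+".join(s) for s, _ in fits],
        "n_terms": [len(s) for s, _ in fits],
        "aic": aics,
        "delta": delta,
        "weight": w,
    }).sort_values("aic", ignore_index=True)
    return ModelSet(getattr(y, "name", "y") or "y", predictors, models,
                    fits[best_idx][1], null, support, coef_ave, coef_ave_p)


# ------------------------------------------------------- modified t-test

@dataclass
class DutilleulResult:
    r: float                         # Pearson correlation
    m_hat: float                     # effective sample size
    t: float
    p: float
    n: int
    n_classes: int


def _class_autocorr(z: np.ndarray, class_of: np.ndarray, n_classes: int) -> np.ndarray:
    """Moran-type autocorrelation of a centered variable per distance class."""
    n = len(z)
    denom = z @ z / n
    off = class_of >= 0
    idx = class_of[off]
    sums = np.bincount(idx, weights=np.outer(z, z)[off], minlength=n_classes)
    cnts = np.bincount(idx, minlength=n_classes)
    rho = np.divide(sums, cnts, out=np.zeros(n_classes), where=cnts > 0) / denom
    return np.clip(rho, -1.0, 1.0)


def modified_ttest(x, y, lon, lat, n_classes: int | None = None) -> DutilleulResult:
    """Dutilleul's spatially corrected test of a Pearson correlation.

    Spatial correlation matrices for x and y are built from distance-class
    autocorrelations; the effective sample size is
    ``M = 1 + tr(B Sx) tr(B Sy) / tr(B Sx B Sy)`` with B the centering
    matrix, and the t statistic is referred to Student's t with M - 2
    degrees of freedom. For spatially independent data M ~ n and the
    classical test is recovered.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("modified t-test needs at least 10 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) variable")
    D = pairwise_haversine_m(lon, lat)
    iu = ~np.eye(n, dtype=bool)
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(iu.sum() / 2) + 1))     # Sturges
    dmax = D[iu].max()
    class_of = np.minimum((D / dmax * n_classes).astype(int), n_classes - 1)
    class_of[~iu] = -1

    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))

    rho_x = _class_autocorr(xc, class_of, n_classes)
    rho_y = _class_autocorr(yc, class_of, n_classes)
    Sx = np.where(iu, rho_x[class_of], 1.0)
    Sy = np.where(iu, rho_y[class_of], 1.0)
    BSx = Sx - Sx.mean(axis=0, keepdims=True)
    BSy = Sy - Sy.mean(axis=0, keepdims=True)
    m_hat = 1.0 + np.trace(BSx) * np.trace(BSy) / np.sum(BSx * BSy.T)
    m_hat = float(min(m_hat, n))
    if m_hat <= 2:
        return DutilleulResult(r, m_hat, np.nan, 1.0, n, n_classes)
    t = r * np.sqrt((m_hat - 2) / max(1.0 - r * r, 1e-15))
    p = float(2 * stats.t.sf(abs(t), m_hat - 2))
    return DutilleulResult(r, m_hat, float(t), p, n, n_classes)
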