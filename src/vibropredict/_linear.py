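"""Ordinary and penalized least-squares fits of one term subset.

Thin wrappers around statsmodels (OLS inference) and scikit-learn
(cross-validated LASSO / ridge / elastic net) that return a uniform
:class:`LinearFit` record, so the subset search can treat every candidate the
same way regardless of how its coefficients were estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import (
    ElasticNet,
    ElasticNetCV,
    Lasso,
    LassoCV,
    Ridge,
    RidgeCV,
)
from sklearn.model_selection import KFold, LeaveOneOut

__all__ = ["LinearFit", "fit_ols", "regularized_fit", "RankDeficientError"]

REG_METHODS = ("lasso", "ridge", "elastic_net")


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""


@dataclass
class LinearFit:
    """One subset's linear coefficients, inference statistics and fit metrics.

    ``beta`` includes the intercept under the name ``const``; inference fields
    are NaN for penalized fits, where classical standard errors do not apply.
    ``rmse`` uses the n-denominator so that ``rmse**2 * n == sum(resid**2)``.
    """

    terms: tuple[str, ...]
    beta: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    ci95: pd.DataFrame
    r2: float
    rmse: float
    mae: float
    pearson_r: float
    f_stat: float
    df1: int
    df2: int
    p_model: float
    nobs: int
    fittedvalues: np.ndarray = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)
    optimization: str = "none"
    alpha: float = float("nan")

    @property
    def sum_abs_beta(self) -> float:
        """Σ|β_j| over the non-intercept coefficients."""
        return float(self.beta.drop("const").abs().sum())

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor for new rows (columns must cover ``terms``)."""
        Z = X[list(self.terms)].to_numpy(dtype=float)
        b = self.beta[list(self.terms)].to_numpy()
        return float(self.beta["const"]) + Z @ b


def _check_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted QR flags the columns that add no new direction
        from scipy.linalg import qr

        _, R, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        names = ["const", *X.columns]
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise RankDeficientError(f"design matrix is rank deficient; collinear terms: {bad}")


def _metrics(y: np.ndarray, fitted: np.ndarray) -> tuple[float, float, float, float]:
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if np.std(fitted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(fitted, y)[0, 1])
    else:
        r = float("nan")
    return r2, rmse, mae, r


def fit_ols(y, X: pd.DataFrame) -> LinearFit:
    """Least-squares fit with intercept and full classical inference.

    Parameters
    ----------
    y : array-like, percent outcome (0–100 scale)
    X : DataFrame of term columns (no constant column)
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > k + 1 observations (n={len(y)}, k={X.shape[1]})")
    _check_rank(X)
    design = sm.add_constant(X.to_numpy(dtype=float), prepend=True)
    names = ["const", *X.columns]
    res = sm.OLS(y, design).fit()
    fitted = np.asarray(res.fittedvalues)
    r2, rmse, mae, r = _metrics(y, fitted)
    ci = res.conf_int(alpha=0.05)
    return LinearFit(
        terms=tuple(X.columns),
        beta=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        ci95=pd.DataFrame(ci, index=names, columns=["lower", "upper"]),
        r2=r2,
        rmse=rmse,
        mae=mae,
        pearson_r=r,
        f_stat=float(res.fvalue),
        df1=int(res.df_model),
        df2=int(res.df_resid),
        p_model=float(res.f_pvalue),
        nobs=len(y),
        fittedvalues=fitted,
        resid=y - fitted,
        optimization="none",
    )


def default_alpha_grid(n_points: int = 50, lo: float = 1e-4, hi: float = 10.0) -> np.ndarray:
    """Logarithmic penalty-strength grid used by default for every method."""
    return np.logspace(np.log10(lo), np.log10(hi), n_points)


def regularized_fit(
    y,
    X: pd.DataFrame,
    method: str,
    alphas=None,
    l1_ratio: float = 0.5,
    seed: int | None = 0,
) -> LinearFit:
    """Penalized fit with penalty strength chosen by cross-validated squared error.

    Leave-one-out CV is used up to n = 40 (no fold randomness at small n);
    larger samples use a seeded 5-fold split.  A single-element ``alphas`` grid
    skips cross-validation and fits at that strength directly.
    """
    if method not in REG_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {REG_METHODS}")
    y = np.asarray(y, dtype=float)
    alphas = default_alpha_grid() if alphas is None else np.asarray(list(alphas), dtype=float)
    if alphas.size == 0:
        raise ValueError("empty penalty-strength grid")
    Xa = X.to_numpy(dtype=float)
    n = len(y)
    cv = LeaveOneOut() if n <= 40 else KFold(5, shuffle=True, random_state=seed)

    if alphas.size == 1:
        alpha = float(alphas[0])
        est = {
            "lasso": Lasso(alpha=alpha, max_iter=50_000),
            "ridge": Ridge(alpha=alpha),
            "elastic_net": ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000),
        }[method]
    elif method == "lasso":
        est = LassoCV(alphas=alphas, cv=cv, max_iter=50_000)
    elif method == "ridge":
        est = RidgeCV(alphas=alphas)  # efficient leave-one-out
    else:
        est = ElasticNetCV(alphas=alphas, l1_ratio=l1_ratio, cv=cv, max_iter=50_000)
    est.fit(Xa, y)
    alpha = float(getattr(est, "alpha_", alphas[0]))
    fitted = est.predict(Xa)
    r2, rmse, mae, r = _metrics(y, fitted)
    names = ["const", *X.columns]
    beta = pd.Series([float(est.intercept_), *np.ravel(est.coef_)], index=names)
    nan = pd.Series(np.nan, index=names)
    k = X.shape[1]
    df2 = n - k - 1
    # model F from the closed form on R^2 (classical per-coefficient inference
    # is not defined after shrinkage)
    f_stat = (r2 / k) / ((1.0 - r2) / df2) if 0 <= r2 < 1 and df2 > 0 else float("nan")
    p_model = float(stats.f.sf(f_stat, k, df2)) if f_stat == f_stat else float("nan")
    return LinearFit(
        terms=tuple(X.columns),
        beta=beta,
        se=nan.copy(),
        tvalues=nan.copy(),
        pvalues=nan.copy(),
        ci95=pd.DataFrame({"lower": nan, "upper": nan}),
        r2=r2,
        rmse=rmse,
        mae=mae,
        pearson_r=r,
        f_stat=float(f_stat),
        df1=k,
        df2=df2,
        p_model=p_model,
        nobs=n,
        fittedvalues=fitted,
        resid=y - fitted,
        optimization=method,
        alpha=alpha,
    )
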