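"""Sigmoid-transformed linear regression of aided speech intelligibility.

The model predicts the aided word recognition score at 65 dB SPL
(``WRS_65dB``, percent) from a linear predictor ``x`` squashed through a
logistic function with a fixed ceiling of 100::

    WRS_65dB = 100 / (1 + exp(-a * (x - c)))
    x        = beta_0 + beta_1*age + beta_2*BC_PTA4 + beta_3*WRS_max

The linear stage is an ordinary (or penalized) least-squares fit; the logistic
stage fits only the slope ``a`` and midpoint ``c`` by bounded least squares on
the linear predictions.  The transform keeps predictions inside the natural
0–100 band of a word recognition score and flattens the response near the
ceiling, where monosyllabic scores saturate.

:class:`SigmoidLinearModel` follows the statsmodels convention: construct the
model from data, call :meth:`~SigmoidLinearModel.fit`, and work with the
returned :class:`SigmoidLinearResults` (coefficients, uncertainties,
diagnostics, ``summary()``, ``predict``).  The published three-predictor model
is packaged as :data:`PUBLISHED_MODEL` with its constants treated as data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from ._linear import LinearFit, fit_ols, regularized_fit

__all__ = [
    "SigmoidParams",
    "sigmoid_predict",
    "linear_predictor",
    "fit_sigmoid",
    "f_from_r2",
    "PublishedModel",
    "PUBLISHED_MODEL",
    "SigmoidLinearModel",
    "SigmoidLinearResults",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic output transform: slope ``a`` (> 0), midpoint ``c`` and a fixed
    ceiling of 100 percent.  Output at ``x = c`` is exactly 50."""

    slope: float
    midpoint: float
    ceiling: float = 100.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"sigmoid slope must be positive, got {self.slope}")


def sigmoid_predict(x, params: SigmoidParams):
    """Evaluate the logistic transform; strictly increasing in ``x``."""
    x = np.asarray(x, dtype=float)
    out = params.ceiling / (1.0 + np.exp(-params.slope * (x - params.midpoint)))
    return float(out) if out.ndim == 0 else out


def linear_predictor(age, bc_pta4, wrs_max, beta: Mapping[str, float]):
    """x = β₀ + β₁·age + β₂·BC_PTA4 + β₃·WRS_max for the three clinical inputs.

    ``beta`` maps ``const``/``age``/``bc_pta4``/``wrs_max`` to coefficients on
    the raw clinical scales (years, dB HL, percent).  Inputs outside the ranges
    observed in the development cohort trigger a warning, not an error.
    """
    _warn_outside_range(age, 27.0, 78.0, "age [y]")
    _warn_outside_range(bc_pta4, 3.75, 50.0, "BC_PTA4 [dB HL]")
    _warn_outside_range(wrs_max, 60.0, 100.0, "WRS_max [%]")
    x = (
        beta["const"]
        + beta["age"] * np.asarray(age, dtype=float)
        + beta["bc_pta4"] * np.asarray(bc_pta4, dtype=float)
        + beta["wrs_max"] * np.asarray(wrs_max, dtype=float)
    )
    return float(x) if np.ndim(x) == 0 else x


def _warn_outside_range(value, lo: float, hi: float, label: str) -> None:
    v = np.asarray(value, dtype=float)
    if np.any((v < lo) | (v > hi)):
        warnings.warn(
            f"{label} outside the development cohort range [{lo}, {hi}]; "
            "prediction is an extrapolation",
            stacklevel=3,
        )


def f_from_r2(r2: float, k: int, n: int) -> float:
    """Model F-statistic from R² with (k, n−k−1) degrees of freedom."""
    df2 = n - k - 1
    if df2 <= 0 or not 0.0 <= r2 < 1.0:
        return float("nan")
    return (r2 / k) / ((1.0 - r2) / df2)


# ---------------------------------------------------------------------------
# sigmoid fitting


def fit_sigmoid(
    x,
    y,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    n_starts: int = 5,
) -> SigmoidParams:
    """Bounded least-squares fit of (slope, midpoint) to percent outcomes.

    ``bounds`` is ``((a_lo, a_hi), (c_lo, c_hi))``; by default the slope is
    confined to (0, 1] and the midpoint to the observed linear-predictor range
    widened by 20 score units.  A deterministic coarse grid (12 log-spaced
    slopes × 15 midpoints) seeds ``n_starts`` local optimizations, so the
    returned residual sum of squares never exceeds the best grid point's.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 points to fit a sigmoid, got {len(x)}")
    if np.ptp(y) == 0:
        raise ValueError("all outcomes equal: sigmoid slope is unidentifiable")
    if np.any((y < 0) | (y > 100)):
        raise ValueError("outcomes must lie in [0, 100] percent")
    if bounds is None:
        bounds = ((1e-4, 1.0), (float(x.min()) - 20.0, float(x.max()) + 20.0))
    (a_lo, a_hi), (c_lo, c_hi) = bounds

    def resid(p):
        a, c = p
        return y - 100.0 / (1.0 + np.exp(-a * (x - c)))

    grid_a = np.geomspace(max(a_lo, 1e-4), a_hi, 12)
    grid_c = np.linspace(c_lo, c_hi, 15)
    sse = np.array([[np.sum(resid((a, c)) ** 2) for c in grid_c] for a in grid_a])
    order = np.dstack(np.unravel_index(np.argsort(sse, axis=None), sse.shape))[0]
    best = None
    for ia, ic in order[:n_starts]:
        sol = least_squares(
            resid,
            x0=[grid_a[ia], grid_c[ic]],
            bounds=([a_lo, c_lo], [a_hi, c_hi]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a, c = best.x
    for val, lo, hi, name in ((a, a_lo, a_hi, "slope"), (c, c_lo, c_hi, "midpoint")):
        if abs(val - lo) < 1e-8 * max(1.0, abs(lo)) or abs(val - hi) < 1e-8 * max(1.0, abs(hi)):
            warnings.warn(f"sigmoid {name} hit its bound ({val:g}); widen the bounds")
    return SigmoidParams(slope=float(a), midpoint=float(c))


# ---------------------------------------------------------------------------
# published final model (constants are data, not fit results)


@dataclass(frozen=True)
class PublishedModel:
    """The published three-predictor model: raw-scale coefficients and the
    logistic transform 100/(1 + e^(−0.063·(x − 57.2941)))."""

    beta: Mapping[str, float] = None
    sigmoid: SigmoidParams = SigmoidParams(slope=0.063, midpoint=57.2941)

    def __post_init__(self) -> None:
        if self.beta is None:
            object.__setattr__(
                self,
                "beta",
                {"const": 79.614, "age": -0.2809, "bc_pta4": -0.0795, "wrs_max": 0.1957},
            )

    def linear_predictor(self, age, bc_pta4, wrs_max):
        return linear_predictor(age, bc_pta4, wrs_max, self.beta)

    def predict(self, age=None, bc_pta4=None, wrs_max=None, data: pd.DataFrame | None = None):
        """Predicted WRS_65dB (percent) for scalars, arrays or a DataFrame with
        ``age``/``bc_pta4``/``wrs_max`` columns."""
        if data is not None:
            age, bc_pta4, wrs_max = data["age"], data["bc_pta4"], data["wrs_max"]
        x = self.linear_predictor(age, bc_pta4, wrs_max)
        return sigmoid_predict(x, self.sigmoid)


PUBLISHED_MODEL = PublishedModel()


# ---------------------------------------------------------------------------
# Model / Results


class SigmoidLinearModel:
    """Sigmoid-transformed linear regression of a percent outcome.

    Parameters
    ----------
    endog : array-like
        Outcome on the 0–100 percent scale.
    exog : DataFrame
        Term columns (no constant; an intercept is always added).
    """

    def __init__(self, endog, exog: pd.DataFrame):
        self.endog = np.asarray(endog, dtype=float)
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog, dtype=float))
            exog.columns = [f"x{i}" for i in range(exog.shape[1])]
        self.exog = exog
        if len(self.endog) != len(exog):
            raise ValueError("endog and exog lengths differ")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str = "wrs_65", terms: Sequence[str] = ()
    ) -> "SigmoidLinearModel":
        terms = list(terms) or [c for c in data.columns if c != outcome]
        return cls(data[outcome], data[terms])

    def fit(
        self,
        method: str = "none",
        alphas=None,
        l1_ratio: float = 0.5,
        seed: int | None = 0,
        sigmoid_bounds=None,
    ) -> "SigmoidLinearResults":
        """Fit the linear stage (``method`` in {none, lasso, ridge,
        elastic_net}) then the logistic output transform on its predictions."""
        if method == "none":
            linear = fit_ols(self.endog, self.exog)
        else:
            linear = regularized_fit(
                self.endog, self.exog, method, alphas=alphas, l1_ratio=l1_ratio, seed=seed
            )
        sig = fit_sigmoid(linear.fittedvalues, self.endog, bounds=sigmoid_bounds)
        return SigmoidLinearResults(self, linear, sig)


class SigmoidLinearResults:
    """Fitted sigmoid-transformed linear regression.

    Carries the linear-stage coefficients with their classical inference
    (``params``, ``bse``, ``tvalues``, ``pvalues``, ``conf_int``), the fitted
    logistic transform, and goodness-of-fit metrics of the *transformed*
    predictions against the observed outcome (``rsquared``, ``rmse``, ``mae``,
    ``pearson_r``, ``fvalue``).
    """

    def __init__(self, model: SigmoidLinearModel, linear: LinearFit, sigmoid: SigmoidParams):
        self.model = model
        self.linear = linear
        self.sigmoid = sigmoid
        y = model.endog
        self.linear_fittedvalues = np.asarray(linear.fittedvalues, dtype=float)
        self.fittedvalues = sigmoid_predict(self.linear_fittedvalues, sigmoid)
        self.resid = y - self.fittedvalues
        sst = float(np.sum((y - y.mean()) ** 2))
        self.rsquared = 1.0 - float(np.sum(self.resid**2)) / sst if sst > 0 else float("nan")
        self.rmse = float(np.sqrt(np.mean(self.resid**2)))
        self.mae = float(np.mean(np.abs(self.resid)))
        self.pearson_r = (
            float(np.corrcoef(self.fittedvalues, y)[0, 1])
            if np.std(self.fittedvalues) > 0
            else float("nan")
        )
        self.nobs = len(y)
        self.df_model = len(linear.terms)
        self.df_resid = self.nobs - self.df_model - 1
        self.fvalue = f_from_r2(self.rsquared, self.df_model, self.nobs)
        self.f_pvalue = (
            float(stats.f.sf(self.fvalue, self.df_model, self.df_resid))
            if self.fvalue == self.fvalue
            else float("nan")
        )

    # linear-stage inference, statsmodels-style names
    @property
    def params(self) -> pd.Series:
        return self.linear.beta

    @property
    def bse(self) -> pd.Series:
        return self.linear.se

    @property
    def tvalues(self) -> pd.Series:
        return self.linear.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self.linear.pvalues

    def conf_int(self) -> pd.DataFrame:
        return self.linear.ci95

    @property
    def sum_abs_beta(self) -> float:
        return self.linear.sum_abs_beta

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted WRS_65dB (percent) for new rows covering the fit's terms."""
        return sigmoid_predict(self.linear.predict(data), self.sigmoid)

    def summary(self) -> str:
        rows = []
        for name in self.params.index:
            rows.append(
                f"{name:>16} {self.params[name]:>10.4f} {self.bse[name]:>9.3f} "
                f"{self.tvalues[name]:>8.3f} "
                f"[{self.conf_int().loc[name, 'lower']:>8.3f}, "
                f"{self.conf_int().loc[name, 'upper']:>8.3f}] "
                f"{self.pvalues[name]:>9.4g}"
            )
        lines = [
            "Sigmoid-transformed linear regression",
            "=" * 72,
            f"n = {self.nobs}   terms = {len(self.linear.terms)}   "
            f"optimization = {self.linear.optimization}",
            f"sigmoid: WRS = 100 / (1 + exp(-{self.sigmoid.slope:.4g} * "
            f"(x - {self.sigmoid.midpoint:.4f})))",
            "-" * 72,
            f"{'term':>16} {'coef':>10} {'std err':>9} {'t':>8} {'95% CI':>20} {'P>|t|':>9}",
            *rows,
            "-" * 72,
            f"R2 = {self.rsquared:.4f}   RMSE = {self.rmse:.4f}   MAE = {self.mae:.4f}   "
            f"r = {self.pearson_r:.4f}",
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.4f}   "
            f"p = {self.f_pvalue:.4g}   sum|beta| = {self.sum_abs_beta:.4f}",
            "=" * 72,
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Write the model as a plain-text key-value file."""
        lines = [f"optimization = {self.linear.optimization}"]
        for name in self.params.index:
            lines.append(f"beta[{name}] = {float(self.params[name])!r}")
        lines.append(f"sigmoid.slope = {float(self.sigmoid.slope)!r}")
        lines.append(f"sigmoid.midpoint = {float(self.sigmoid.midpoint)!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model_file(path: str | Path) -> tuple[dict[str, float], SigmoidParams]:
    """Read a plain-text model file back into (beta mapping, sigmoid params)."""
    beta: dict[str, float] = {}
    extra: dict[str, float] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key.startswith("beta[") and key.endswith("]"):
            beta[key[5:-1]] = float(val)
        elif key.startswith("sigmoid."):
            extra[key.split(".", 1)[1]] = float(val)
    return beta, SigmoidParams(slope=extra["slope"], midpoint=extra["midpoint"])
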