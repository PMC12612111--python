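"""Goodness-of-fit, residual outlier analysis and test-retest consistency.

Model evaluation follows speech-audiometry practice: residuals are
``measured − predicted`` word recognition scores (percent); outliers are
flagged with Tukey fences (1.5 × IQR beyond the residual quartiles); and a
measured/predicted pair counts as *consistent* when its difference lies
within the 95 % test-retest band of the Freiburg monosyllabic test at that
score.  Patients are split into high performers (HP, aided WRS_65dB ≥ 70 %)
and low performers (LP, < 70 %).

The default test-retest table is derived from the binomial variability of a
20-item word list: the 95 % half-width at score ``p`` is
``1.96·√(p·(100−p)/20)`` percentage points, evaluated on the 5 % score grid.
It ships as an editable plain-text table (``data/freiburg_ci.csv``) so a site
can substitute its own critical differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CiTable",
    "ResidualReport",
    "goodness_metrics",
    "iqr_outliers",
    "ci_consistency",
    "classify_performance",
    "evaluate_predictions",
]


def goodness_metrics(predicted, observed) -> dict[str, float]:
    """R², RMSE, MAE and Pearson r of predictions against observations.

    R² is ``1 − SS_res/SS_tot``; with a constant observed vector R² and r are
    reported as NaN (undefined), never silently as 0.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    if len(p) < 2:
        raise ValueError("need at least 2 observations")
    resid = o - p
    sst = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    r = (
        float(np.corrcoef(p, o)[0, 1])
        if np.std(p) > 0 and np.std(o) > 0
        else float("nan")
    )
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        "pearson_r": r,
    }


def iqr_outliers(residuals, quartile_method: str = "linear") -> dict:
    """Quartiles, Tukey fences and outlier flags of a residual vector.

    ``quartile_method`` is any quantile estimator accepted by
    :func:`numpy.percentile` (default: linear interpolation of order
    statistics).  A residual is flagged iff it lies strictly outside
    [Q1 − 1.5·IQR, Q3 + 1.5·IQR].
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) < 4:
        raise ValueError(f"need ≥ 4 residuals for a quartile analysis, got {len(r)}")
    q1, q3 = (float(q) for q in np.percentile(r, [25, 75], method=quartile_method))
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = (r < lower) | (r > upper)
    return {
        "q1": q1,
        "q3": q3,
        "iqr": iqr,
        "lower_fence": lower,
        "upper_fence": upper,
        "outlier": flags,
    }


class CiTable:
    """Score → 95 % test-retest half-width (percent) on the 5 % score grid."""

    def __init__(self, half_widths: dict[float, float]):
        for score, hw in half_widths.items():
            if hw < 0:
                raise ValueError(f"negative half-width {hw} at score {score}")
        self.half_widths = dict(sorted(half_widths.items()))
        self._scores = np.array(list(self.half_widths), dtype=float)

    @classmethod
    def binomial(cls, n_items: int = 20) -> "CiTable":
        """Half-widths from binomial variability of an ``n_items``-word list."""
        scores = np.arange(0.0, 100.1, 5.0)
        hw = 1.96 * np.sqrt(scores * (100.0 - scores) / n_items)
        return cls(dict(zip(scores, hw)))

    @classmethod
    def from_file(cls, path: str | Path) -> "CiTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["score"].astype(float), df["half_width"].astype(float))))

    @classmethod
    def default(cls) -> "CiTable":
        """The packaged editable table (regenerate with :meth:`binomial`)."""
        ref = resources.files("vibropredict").joinpath("data/freiburg_ci.csv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            {"score": list(self.half_widths), "half_width": list(self.half_widths.values())}
        ).to_csv(path, index=False)

    def half_width(self, score: float) -> float:
        """Half-width at ``score``; off-grid scores use the nearest grid point."""
        if score in self.half_widths:
            return self.half_widths[score]
        import warnings

        nearest = float(self._scores[np.argmin(np.abs(self._scores - score))])
        warnings.warn(
            f"score {score} not in the test-retest table; using nearest grid point {nearest}"
        )
        return self.half_widths[nearest]


def ci_consistency(
    measured: float, predicted: float, table: CiTable | None = None
) -> dict[str, float | bool]:
    """Test-retest consistency of one measured/predicted pair.

    Consistent iff |measured − predicted| ≤ half-width(measured).  The
    adjusted difference shrinks the raw difference toward zero by the
    half-width (floored at zero, sign preserved) — the correction applied to
    measurements before display.
    """
    if not (0.0 <= measured <= 100.0 and 0.0 <= predicted <= 100.0):
        raise ValueError("scores must lie in [0, 100]")
    table = table or CiTable.default()
    hw = table.half_width(measured)
    diff = measured - predicted
    adjusted = float(np.sign(diff) * max(0.0, abs(diff) - hw))
    return {"consistent": bool(abs(diff) <= hw), "adjusted_difference": adjusted}


def classify_performance(wrs_65: float) -> str:
    """High performer (HP) iff aided WRS_65dB ≥ 70 %, else low performer (LP)."""
    if not 0.0 <= wrs_65 <= 100.0:
        raise ValueError(f"WRS must lie in [0, 100], got {wrs_65}")
    return "HP" if wrs_65 >= 70.0 else "LP"


@dataclass
class ResidualReport:
    """Per-patient residual analysis of one model on one cohort."""

    table: pd.DataFrame  # per-patient: measured, predicted, residual, flags
    metrics: dict[str, float]
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    quartile_method: str = "linear"

    @property
    def outlier_ids(self) -> list:
        return list(self.table.index[self.table["outlier"]])

    def summary(self) -> str:
        hp = int((self.table["performance"] == "HP").sum())
        lp = int((self.table["performance"] == "LP").sum())
        m = self.metrics
        lines = [
            "Residual report",
            "=" * 60,
            f"n = {len(self.table)}   HP = {hp}   LP = {lp}",
            f"R2 = {m['r2']:.4f}  RMSE = {m['rmse']:.4f}  MAE = {m['mae']:.4f}  "
            f"r = {m['pearson_r']:.4f}",
            f"residual quartiles: Q1 = {self.q1:.2f}  Q3 = {self.q3:.2f}  "
            f"IQR = {self.iqr:.2f}",
            f"Tukey fences: [{self.lower_fence:.2f}, {self.upper_fence:.2f}]",
            f"outliers: {self.outlier_ids or 'none'}",
            f"test-retest inconsistent: "
            f"{list(self.table.index[~self.table['ci_consistent']]) or 'none'}",
            "=" * 60,
        ]
        return "\n".join(lines)


def evaluate_predictions(
    measured,
    predicted,
    ids: Sequence | None = None,
    ci_table: CiTable | None = None,
    quartile_method: str = "linear",
) -> ResidualReport:
    """Full residual analysis: metrics, quartiles, fences, outliers, HP/LP and
    test-retest consistency flags."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    metrics = goodness_metrics(predicted, measured)
    resid = measured - predicted
    frag = iqr_outliers(resid, quartile_method=quartile_method)
    ci_table = ci_table or CiTable.default()
    cons, adj = [], []
    for m, p in zip(measured, predicted):
        res = ci_consistency(float(m), float(np.clip(p, 0.0, 100.0)), ci_table)
        cons.append(res["consistent"])
        adj.append(res["adjusted_difference"])
    table = pd.DataFrame(
        {
            "measured": measured,
            "predicted": predicted,
            "residual": resid,
            "outlier": frag["outlier"],
            "ci_consistent": cons,
            "adjusted_difference": adj,
            "performance": [classify_performance(m) for m in measured],
        },
        index=ids if ids is not None else pd.RangeIndex(len(measured)),
    )
    return ResidualReport(
        table=table,
        metrics=metrics,
        q1=frag["q1"],
        q3=frag["q3"],
        iqr=frag["iqr"],
        lower_fence=frag["lower_fence"],
        upper_fence=frag["upper_fence"],
        quartile_method=quartile_method,
    )


def plot_report(report: ResidualReport, out_prefix: str | Path) -> list[Path]:
    """Scatter (CI-adjusted measured vs predicted) and residual histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    t = report.table
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    adj_measured = t["predicted"] + t["adjusted_difference"]
    ax.scatter(t["predicted"], adj_measured, c=np.where(t["outlier"], "crimson", "steelblue"))
    lims = [min(t.min().min(), 50), 100]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("predicted WRS$_{65dB}$ [%]")
    ax.set_ylabel("measured WRS$_{65dB}$ (CI-adjusted) [%]")
    p = out_prefix.with_name(out_prefix.name + "_scatter.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(t["residual"], bins=10, color="steelblue", edgecolor="white")
    for fence in (report.lower_fence, report.upper_fence):
        ax.axvline(fence, color="crimson", ls="--", lw=1)
    ax.set_xlabel("residual (measured − predicted) [%]")
    ax.set_ylabel("count")
    p = out_prefix.with_name(out_prefix.name + "_residuals.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
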