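"""Predictor screening and construction of the second-degree term set.

From four base clinical variables the model search works with 14 candidate
terms: the 4 z-standardized variables, their 4 squares and the 6 pairwise
products.  Quadratic and interaction terms are built from the standardized
bases and deliberately *not* re-standardized, so a product term keeps its
interpretation as "joint deviation from the cohort mean".

Screening uses Spearman's rank correlation (average ranks for ties, two-sided
p from the t-approximation) with Cohen's descriptive labels at |ρ| thresholds
0.10 / 0.30 / 0.50, and records each candidate's expected coefficient sign —
the sign its rank correlation with the outcome carries — for the
sign-coherence filter applied during the subset search.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TermSpec",
    "DesignMatrix",
    "spearman_screen",
    "build_terms",
    "expected_signs",
    "cohen_label",
    "BASE_VARIABLES",
    "PUBLISHED_BASE_SIGNS",
]

#: base variables of the development cohort, in canonical order
BASE_VARIABLES = ("age", "bc_pta4", "vib_pta4", "wrs_max")

#: expected coefficient signs of the base variables, from the development
#: cohort's rank correlations with the outcome
PUBLISHED_BASE_SIGNS: dict[str, int] = {"age": -1, "bc_pta4": -1, "vib_pta4": -1, "wrs_max": +1}


@dataclass(frozen=True)
class TermSpec:
    """One candidate term: linear, quadratic or pairwise interaction."""

    name: str
    kind: str  # {"linear", "quadratic", "interaction"}
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        n = {"linear": 1, "quadratic": 1, "interaction": 2}[self.kind]
        if len(self.components) != n:
            raise ValueError(f"{self.kind} term needs {n} component(s), got {self.components}")
        if self.kind == "interaction" and self.components[0] == self.components[1]:
            raise ValueError("interaction components must be distinct")


@dataclass
class DesignMatrix:
    """Patients × terms matrix of standardized term values.

    ``standardization`` stores the per-base-variable mean and (ddof=1) SD used
    for the z-transform, enabling back-transformation of coefficients.
    """

    values: pd.DataFrame
    terms: tuple[TermSpec, ...]
    standardization: dict[str, tuple[float, float]]

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def subset(self, names: Sequence[str]) -> pd.DataFrame:
        return self.values[list(names)]


def cohen_label(rho: float) -> str:
    """Cohen's descriptive strength label for a correlation coefficient."""
    a = abs(rho)
    if not a == a:
        return "undefined"
    if a >= 0.50:
        return "strong"
    if a >= 0.30:
        return "moderate"
    if a >= 0.10:
        return "weak"
    return "negligible"


def spearman_screen(
    data: pd.DataFrame, outcome: str, candidates: Sequence[str]
) -> pd.DataFrame:
    """Rank-correlation screen of candidate predictors against the outcome.

    Returns one row per candidate with ``rho`` (tie-corrected, average ranks),
    two-sided ``p`` from the t-approximation, Cohen ``label`` and
    ``expected_sign`` = sign(ρ).  A constant candidate yields ρ = NaN and the
    label "undefined" (never silently 0).
    """
    y = data[outcome].to_numpy(dtype=float)
    rows = []
    for name in candidates:
        x = data[name].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 4:
            raise ValueError(f"need ≥ 4 complete observations for {name!r} vs {outcome!r}")
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rho, p = float("nan"), float("nan")
        else:
            res = stats.spearmanr(x[ok], y[ok])
            rho, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "variable": name,
                "rho": rho,
                "p": p,
                "label": cohen_label(rho),
                "expected_sign": int(np.sign(rho)) if rho == rho else 0,
                "n": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def build_terms(data: pd.DataFrame, base: Sequence[str] = BASE_VARIABLES) -> DesignMatrix:
    """Z-standardize the base variables and emit the full second-degree term set.

    For ``b`` base variables the matrix has ``b`` linear + ``b`` quadratic +
    ``b(b−1)/2`` interaction columns (14 at b = 4).  Standardization uses the
    sample SD (ddof=1); a constant base variable is an error.
    """
    std: dict[str, tuple[float, float]] = {}
    z = pd.DataFrame(index=data.index)
    for name in base:
        col = data[name].to_numpy(dtype=float)
        mu, sd = float(np.mean(col)), float(np.std(col, ddof=1))
        if sd == 0:
            raise ValueError(f"base variable {name!r} is constant (sd = 0); cannot standardize")
        std[name] = (mu, sd)
        z[name] = (col - mu) / sd
    terms: list[TermSpec] = [TermSpec(n, "linear", (n,)) for n in base]
    values = z.copy()
    for name in base:
        t = TermSpec(f"{name}^2", "quadratic", (name,))
        terms.append(t)
        values[t.name] = z[name] ** 2
    for a, b in combinations(base, 2):
        t = TermSpec(f"{a}×{b}", "interaction", (a, b))
        terms.append(t)
        values[t.name] = z[a] * z[b]
    return DesignMatrix(values=values, terms=tuple(terms), standardization=std)


def expected_signs(
    design: DesignMatrix,
    outcome,
    base_signs: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """Expected coefficient sign for every term in the design matrix.

    Linear terms take the sign supplied in ``base_signs`` (default: the
    development cohort's correlation signs for the four clinical variables,
    else the sign of the term's own rank correlation).  Quadratic and
    interaction terms always use the sign of their own rank correlation with
    the outcome; a sign of 0 (undefined correlation) matches any coefficient.
    """
    base_signs = dict(PUBLISHED_BASE_SIGNS if base_signs is None else base_signs)
    y = np.asarray(outcome, dtype=float)
    signs: dict[str, int] = {}
    for t in design.terms:
        if t.kind == "linear" and t.name in base_signs:
            signs[t.name] = int(base_signs[t.name])
            continue
        col = design.values[t.name].to_numpy(dtype=float)
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            signs[t.name] = 0
        else:
            rho = stats.spearmanr(col, y).statistic
            signs[t.name] = int(np.sign(rho)) if rho == rho else 0
    return signs
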