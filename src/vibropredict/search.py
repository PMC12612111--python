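"""Exhaustive sign-constrained subset search with outlier-rank final selection.

The model search mirrors a seven-step clinical model-building workflow:

1. screen the base variables and build the 14-term design matrix
   (:mod:`vibropredict.features`);
2. fit ordinary least squares for *every* subset of the candidate terms at the
   requested sizes (364 three-term + 1001 four-term subsets at 14 terms);
3. discard fits whose coefficient signs contradict the screening correlations
   (a plausibility filter, not a score) and keep the ten best per subset size
   by R², ties broken by smaller Σ|β| and smaller MAE;
4. fit the logistic output transform to each surviving model;
5. re-rank on the transformed predictions and keep the best few per size;
6. add cross-validated LASSO / ridge / elastic-net variants of each finalist,
   then rank all of them by their mean prediction-error rank on the hard
   cases — patients whose absolute residual exceeds the model's own MAE —
   with ties going to the higher R²;
7. the winner is refit on the raw clinical scale when its terms allow it
   (see :class:`ModelSearchResults.final_model`).

Nothing in the search hard-codes which variable wins; exclusions (e.g. of the
Vibrogram PTA) must emerge from the ranking itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._linear import LinearFit, RankDeficientError, fit_ols, regularized_fit
from .features import (
    BASE_VARIABLES,
    DesignMatrix,
    build_terms,
    expected_signs,
    spearman_screen,
)
from .model import SigmoidLinearModel, SigmoidLinearResults

__all__ = [
    "enumerate_subsets",
    "fit_ols",
    "regularized_fit",
    "sign_coherent",
    "rank_models",
    "select_final",
    "RankingEntry",
    "ModelSearch",
    "ModelSearchResults",
    "LinearFit",
    "RankDeficientError",
]

log = logging.getLogger(__name__)


def enumerate_subsets(terms: Sequence, k: int) -> list[tuple]:
    """All C(len(terms), k) subsets in deterministic lexicographic order."""
    if not 1 <= k <= len(terms):
        raise ValueError(f"subset size {k} outside 1..{len(terms)}")
    return list(combinations(terms, k))


def sign_coherent(fit: LinearFit, expected: Mapping[str, int]) -> bool:
    """True iff every non-intercept coefficient matches its expected sign.

    A zero coefficient matches any expectation, and an expected sign of 0
    (undefined screening correlation) accepts any coefficient.  Every term in
    the fit must have an entry in ``expected``.
    """
    for term in fit.terms:
        if term not in expected:
            raise KeyError(f"no expected sign for term {term!r}")
        want = int(expected[term])
        got = float(fit.beta[term])
        if want != 0 and got != 0 and int(np.sign(got)) != want:
            return False
    return True


@dataclass
class RankingEntry:
    """One candidate in the ranking: its linear fit, optional sigmoid-stage
    results, sign-coherence flag and selection bookkeeping."""

    fit: LinearFit
    sign_ok: bool
    rank_keys: tuple = ()
    results: SigmoidLinearResults | None = None
    avg_outlier_rank: float = float("nan")
    outlier_cases: tuple = ()
    selected: bool = False

    @property
    def terms(self) -> tuple[str, ...]:
        return self.fit.terms

    @property
    def optimization(self) -> str:
        return self.fit.optimization


def _order_keys(r2: float, sum_abs_beta: float, mae: float) -> tuple:
    # R² descending, then smaller Σ|β| (shrinkage/stability proxy), then MAE
    return (-r2, sum_abs_beta, mae)


def rank_models(
    fits: Sequence[LinearFit], expected: Mapping[str, int], top: int = 10
) -> list[RankingEntry]:
    """Sign-filter and rank linear fits; returns at most ``top`` entries.

    Sign coherence is a hard filter: an incoherent model is never returned
    while any coherent one exists (incoherent fits are simply dropped).
    """
    if not fits:
        raise ValueError("rank_models needs at least one fit")
    entries = [
        RankingEntry(
            fit=f,
            sign_ok=sign_coherent(f, expected),
            rank_keys=_order_keys(f.r2, f.sum_abs_beta, f.mae),
        )
        for f in fits
    ]
    coherent = [e for e in entries if e.sign_ok]
    if not coherent:
        warnings.warn("no sign-coherent model among the candidates; returning an empty ranking")
        return []
    coherent.sort(key=lambda e: e.rank_keys)
    return coherent[:top]


def select_final(
    candidates: Sequence[RankingEntry],
    outcome,
    outlier_ids: Sequence[int] | None = None,
) -> RankingEntry:
    """Pick the winner by lowest mean prediction-error rank on the hard cases.

    Every candidate must carry full-pipeline (post-sigmoid) predictions.  The
    case set is either ``outlier_ids`` (positional indices) or, by default,
    the union over candidates of the observations whose absolute residual
    exceeds that candidate's own MAE.  Candidates are ranked per case by
    absolute prediction error (average ranks on ties); the lowest mean rank
    wins, ties broken by higher R².  Sign-coherent candidates always outrank
    incoherent ones.  With no hard case at all, selection falls back to R²
    with a warning.
    """
    if not candidates:
        raise ValueError("select_final needs at least one candidate")
    for e in candidates:
        if e.results is None:
            raise ValueError(f"candidate {e.terms} lacks post-sigmoid results")
    y = np.asarray(outcome, dtype=float)
    if outlier_ids is None:
        cases: set[int] = set()
        for e in candidates:
            cases |= set(np.flatnonzero(np.abs(e.results.resid) > e.results.mae))
        case_idx = sorted(cases)
    else:
        case_idx = sorted(int(i) for i in outlier_ids)
    if not case_idx:
        warnings.warn("no outlier cases for any model; falling back to R² ranking")
        for e in candidates:
            e.avg_outlier_rank = float("nan")
    else:
        errs = np.array(
            [[abs(y[i] - float(e.results.fittedvalues[i])) for i in case_idx] for e in candidates]
        )
        ranks = np.apply_along_axis(stats.rankdata, 0, errs)  # smaller error = rank 1
        for e, row in zip(candidates, ranks.mean(axis=1)):
            e.avg_outlier_rank = float(row)
            e.outlier_cases = tuple(case_idx)
    def key(e: RankingEntry):
        rank = e.avg_outlier_rank if e.avg_outlier_rank == e.avg_outlier_rank else np.inf
        return (not e.sign_ok, rank, -e.results.rsquared)

    winner = min(candidates, key=key)
    winner.selected = True
    return winner


@dataclass
class ModelSearchResults:
    """Everything the search produced: screen, design, ranking and winner."""

    screen: pd.DataFrame
    design: DesignMatrix
    expected: dict[str, int]
    n_fits: dict[int, int]
    top_linear: dict[int, list[RankingEntry]]
    candidates: list[RankingEntry]
    selected: RankingEntry
    final_model: SigmoidLinearResults
    ranking: pd.DataFrame = field(default=None)

    def summary(self) -> str:
        head = [
            "Model search over second-degree terms",
            "=" * 72,
            "fits per subset size: "
            + ", ".join(f"k={k}: {n}" for k, n in sorted(self.n_fits.items())),
            f"candidates after sigmoid + regularization: {len(self.candidates)}",
            f"selected: {' + '.join(self.selected.terms)} "
            f"[{self.selected.optimization}] "
            f"avg outlier rank = {self.selected.avg_outlier_rank:.2f}",
            "",
        ]
        return "\n".join(head) + self.final_model.summary()


class ModelSearch:
    """Exhaustive subset search for a sigmoid-transformed linear model.

    Parameters
    ----------
    data : DataFrame
        Modelling table with the outcome and base-variable columns.
    outcome : str
        Outcome column (percent, 0–100).
    base : sequence of str
        Base variables entering the second-degree term set.
    subset_sizes : sequence of int
        Term-subset sizes to enumerate exhaustively.
    top : int
        Linear-stage models kept per subset size (step 3).
    n_sigmoid_best : int
        Models kept per subset size after the sigmoid stage (step 5).
    regularization : sequence of str
        Penalized variants added per finalist in step 6 (subset of
        {"lasso", "ridge", "elastic_net"}; the unpenalized fit is always kept).
    base_signs : mapping, optional
        Expected signs of the base variables; defaults to the development
        cohort's correlation signs.
    outlier_ids : sequence of int, optional
        Fixed hard-case indices for the final ranking (default: auto).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str = "wrs_65",
        base: Sequence[str] = BASE_VARIABLES,
        subset_sizes: Sequence[int] = (3, 4),
        top: int = 10,
        n_sigmoid_best: int = 3,
        regularization: Sequence[str] = ("lasso", "ridge", "elastic_net"),
        base_signs: Mapping[str, int] | None = None,
        outlier_ids: Sequence[int] | None = None,
        sigmoid_bounds=None,
        alphas=None,
        seed: int = 0,
    ):
        self.data = data
        self.outcome = outcome
        self.base = tuple(base)
        self.subset_sizes = tuple(subset_sizes)
        self.top = top
        self.n_sigmoid_best = n_sigmoid_best
        self.regularization = tuple(regularization)
        self.base_signs = base_signs
        self.outlier_ids = outlier_ids
        self.sigmoid_bounds = sigmoid_bounds
        self.alphas = alphas
        self.seed = seed

    def fit(self) -> ModelSearchResults:
        y = self.data[self.outcome].to_numpy(dtype=float)
        screen = spearman_screen(self.data, self.outcome, self.base)
        design = build_terms(self.data, self.base)
        expected = expected_signs(design, y, self.base_signs)

        # step 2: exhaustive OLS
        n_fits: dict[int, int] = {}
        fits_by_k: dict[int, list[LinearFit]] = {}
        for k in self.subset_sizes:
            fits: list[LinearFit] = []
            for subset in enumerate_subsets(design.term_names, k):
                try:
                    fits.append(fit_ols(y, design.subset(subset)))
                except RankDeficientError:
                    log.debug("skipping rank-deficient subset %s", subset)
            fits_by_k[k] = fits
            n_fits[k] = len(fits)
            log.info("subset size %d: %d models fitted", k, len(fits))

        # step 3: sign filter + metric ranking
        top_linear = {k: rank_models(fits, expected, top=self.top) for k, fits in fits_by_k.items()}

        # step 4: sigmoid stage for each survivor
        for k, entries in top_linear.items():
            for e in entries:
                mdl = SigmoidLinearModel(y, design.subset(e.terms))
                e.results = mdl.fit(sigmoid_bounds=self.sigmoid_bounds)

        # step 5: re-rank on transformed predictions, keep the best few per size
        finalists: list[RankingEntry] = []
        for k, entries in top_linear.items():
            ordered = sorted(
                entries,
                key=lambda e: _order_keys(e.results.rsquared, e.results.sum_abs_beta, e.results.mae),
            )
            finalists.extend(ordered[: self.n_sigmoid_best])

        # step 6: regularized variants, then outlier-rank selection
        candidates: list[RankingEntry] = list(finalists)
        for e in finalists:
            for method in self.regularization:
                mdl = SigmoidLinearModel(y, design.subset(e.terms))
                try:
                    res = mdl.fit(
                        method=method, alphas=self.alphas, seed=self.seed,
                        sigmoid_bounds=self.sigmoid_bounds,
                    )
                except ValueError as exc:  # e.g. sigmoid unidentifiable after full shrinkage
                    log.debug("skipping %s on %s: %s", method, e.terms, exc)
                    continue
                candidates.append(
                    RankingEntry(fit=res.linear, sign_ok=sign_coherent(res.linear, expected),
                                 results=res)
                )
        selected = select_final(candidates, y, outlier_ids=self.outlier_ids)

        final = self._refit_raw(selected, design) or selected.results
        ranking = _ranking_table(candidates)
        return ModelSearchResults(
            screen=screen,
            design=design,
            expected=expected,
            n_fits=n_fits,
            top_linear=top_linear,
            candidates=candidates,
            selected=selected,
            final_model=final,
            ranking=ranking,
        )

    def _refit_raw(self, entry: RankingEntry, design: DesignMatrix) -> SigmoidLinearResults | None:
        """Refit the winning subset on the raw clinical scale.

        Only possible when every selected term is linear: the z-transform is
        affine, so the raw-scale OLS spans the same prediction space and the
        refit changes the coefficient scale, not the predictions.  Quadratic or
        interaction winners stay on the standardized scale (the
        standardization metadata travels with the design matrix).
        """
        kinds = {t.name: t.kind for t in design.terms}
        if any(kinds[name] != "linear" for name in entry.terms):
            return None
        mdl = SigmoidLinearModel.from_dataframe(
            self.data, outcome=self.outcome, terms=list(entry.terms)
        )
        return mdl.fit(sigmoid_bounds=self.sigmoid_bounds)


def _ranking_table(candidates: Sequence[RankingEntry]) -> pd.DataFrame:
    rows = []
    for e in candidates:
        r = e.results
        rows.append(
            {
                "terms": " + ".join(e.terms),
                "k": len(e.terms),
                "optimization": e.optimization,
                "R2": r.rsquared,
                "RMSE": r.rmse,
                "MAE": r.mae,
                "r": r.pearson_r,
                "F": r.fvalue,
                "p": r.f_pvalue,
                "sum_abs_beta": r.sum_abs_beta,
                "sign_ok": e.sign_ok,
                "avg_outlier_rank": e.avg_outlier_rank,
                "selected": e.selected,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["sign_ok", "avg_outlier_rank", "R2"], ascending=[False, True, False]
    ).reset_index(drop=True)
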