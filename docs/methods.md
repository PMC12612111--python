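# Methods

This note documents the statistical model, the synthetic-cohort generator,
the numerical choices, and the open design decisions made while building
`vibropredict`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The prediction model

The outcome is the aided Freiburg monosyllabic word recognition score at
65 dB SPL (WRS₆₅dB), a percentage on a 0–100 scale measured in 5 % steps
(20-word lists). A purely linear model can predict outside that range and
ignores the saturation of word scores near the ceiling; the package therefore
fits a two-stage model:

1. **Linear stage.** Ordinary least squares of the outcome on a subset of
   candidate terms, with intercept. Classical inference (SE, t, 95 % CI, p)
   comes from statsmodels. Penalized variants (LASSO, ridge, elastic net with
   mixing 0.5) use scikit-learn with the penalty strength chosen by
   cross-validated squared error on a 50-point logarithmic grid spanning
   1e−4…10; classical standard errors are not defined after shrinkage and are
   reported as NaN.
2. **Logistic stage.** The linear predictions `x` are passed through
   `100/(1 + exp(−a(x − c)))`. Only the slope `a` and midpoint `c` are free;
   the ceiling is fixed at 100 because the outcome is a percentage of a fixed
   word list. `(a, c)` are fitted by bounded least squares against the
   observed outcomes.

Goodness-of-fit metrics (R² = 1 − SSres/SStot, RMSE with n-denominator, MAE,
Pearson r) are always computed on the *transformed* predictions. The model F
statistic uses the closed form F = (R²/k)/((1 − R²)/(n − k − 1)), which keeps
it consistent with the post-transform R².

### Sigmoid fitting: bounds and starts

The slope is confined to (0, 1] and the midpoint to the observed
linear-predictor range widened by ±20 score units — weak-information bounds
that stabilize the fit at n = 20 without constraining any plausible solution.
A deterministic 12 × 15 coarse grid (log-spaced slopes × linear midpoints) is
evaluated first; the five best grid points seed local bounded least-squares
runs, and the best solution is returned, so the final residual sum of squares
never exceeds the best grid point's. Hitting a bound raises a warning, never
an error. Predictions are only clipped to [0, 100] for reporting, never
during fitting.

## Candidate terms and screening

Four base predictors (age, BC_PTA4, VIB_PTA4, WRS_max) are z-standardized
(sample SD, ddof = 1) and expanded into 14 terms: 4 linear, 4 quadratic,
6 pairwise interactions. Quadratic and interaction terms are products of
standardized bases and are *not* re-standardized — re-scaling a product term
would destroy its interpretation as a joint deviation, and the affine
structure needed for raw-scale back-transformation of linear subsets is
preserved either way. The standardization metadata travels with the design
matrix.

Screening uses Spearman's ρ with average ranks for ties and a two-sided
t-approximation p-value — the standard small-sample choice at n = 20 —
labelled by Cohen's thresholds (0.10/0.30/0.50 on |ρ|). A constant candidate
yields an explicitly undefined ρ (NaN), never a silent 0.

### Sign coherence

Each term carries an *expected sign*: for the four clinical base variables
the development cohort's correlation signs (age −, BC_PTA4 −, VIB_PTA4 −,
WRS_max +); for quadratic/interaction terms the sign of the term's own rank
correlation with the outcome, computed on the data at hand. A fitted model is
sign-coherent iff every non-intercept coefficient matches its expectation;
zero coefficients match anything, as does an expectation of 0. Sign coherence
is a **hard filter**, not a score — a clinically implausible model is
discarded no matter how well it fits. This is the design reading of a
procedure that describes signs as a correctness check.

## Subset search and selection

All subsets of sizes 3 and 4 are fitted exhaustively (364 + 1001 = 1365
models). Ranking within the sign-coherent survivors is by R² descending,
ties broken by smaller Σ|β| (a stability/shrinkage proxy, consistent with
the later regularization step) and then smaller MAE. The ten best per size
get a sigmoid stage; the three best per size after transformation gain
penalized variants; and the final choice among all of these is by **mean
prediction-error rank on the hard cases** — the union, over candidates, of
observations whose absolute post-sigmoid residual exceeds that candidate's
own MAE — with average ranks on ties and higher R² as the tiebreak. With no
hard case at all the selection falls back to R² with a warning. The
hard-case ranking deliberately uses post-transform predictions, since the
MAE it references is quoted for the transformed model.

No variable is ever excluded by rule; any exclusion (e.g. of VIB_PTA4) must
emerge from the ranking.

The winning subset is refit on the raw clinical scale when all its terms are
linear: the z-transform is affine, so the raw refit spans the same prediction
space and only changes the coefficient scale to interpretable clinical units
(percent per year, per dB, per percent). For winners containing quadratic or
interaction terms no such exact raw refit of the *subset* exists, and the
standardized-scale coefficients are reported together with the
standardization metadata.

Cross-validation for penalized fits is leave-one-out up to n = 40 (no fold
randomness in small cohorts) and a seeded 5-fold split beyond that; ridge
uses the efficient closed-form LOO throughout.

## Synthetic cohorts

The generator emulates the development study's cohort at the level the
pipeline consumes — the joint distribution of age, BC_PTA4, VIB_PTA4,
WRS_max and WRS₆₅dB — with three controlled features:

* **Marginals**: mean 47.0 ± 16.1 y (range 27–78) for age, 28.0 ± 10.1 dB
  (3.75–50) for BC_PTA4, 40.2 ± 11.9 dB (16.3–61.3) for VIB_PTA4,
  88.5 ± 12.3 % (60–100) for WRS_max, 81.5 ± 9.0 % (60–95) for WRS₆₅dB.
* **Rank correlations with the outcome**: −0.522 (BC_PTA4), +0.555
  (WRS_max), −0.464 (VIB_PTA4), via a Gaussian copula with latent Pearson
  correlations r = 2·sin(πρ/6) (exact for bivariate normals). Pairs without a
  stated target default to 0; a non-PSD completed matrix is an error unless
  the nearest-PSD repair (eigenvalue clipping + diagonal renormalization) is
  requested.
* **Granularity**: word scores in 5 % steps; PTA4-level thresholds in
  1.25 dB steps (the mean of four 5 dB-step thresholds). Range limits printed
  at coarser precision are snapped to the nearest grid point.

Truncation to the stated ranges is applied through the truncated-normal
inverse CDF rather than by rejection or clipping. This choice has three
properties that motivated it: it leaves no point mass at the range limits;
it preserves the copula's population Spearman ρ exactly (the marginal map is
strictly monotone); and it keeps the marginal moments controllable. The
parent (μ, σ) of each truncated normal is calibrated numerically so the
*truncated* mean matches the stated mean; the SD is matched as a secondary
objective because a stated SD can exceed the maximum any truncated normal
supports on a finite range (age 16.1 y on a 51-y range and WRS_max 12.3 % on
a 40 % range both do), in which case the generated spread is the closest
attainable and the mean still matches. Discretization to the measurement
grids attenuates the realized rank correlations by a further ~0.02 through
ties; this is an inherent property of granular measurements, not corrected
for.

The coupling efficiency CE = VIB − BC is a *derived* variable: its weak
negative outcome correlation in the development data cannot be imposed
independently once VIB and BC have the stated marginals and outcome
correlations (their contributions to cov(CE, outcome) nearly cancel), so the
emergent CE correlation of generated cohorts is near zero. Analyses that
specifically target CE behaviour should not rely on the generator.

Generated records carry near-flat per-frequency threshold maps that
reproduce the drawn PTA4 exactly in 5 dB steps; audiogram *shape* is
deliberately not modelled. Consequently, passing tests demonstrate the
pipeline's behaviour under the study's summary-level statistical structure —
they do not validate per-frequency analyses, coupler-type effects, or any
feature of real cohorts beyond the controlled marginals, rank correlations
and granularity.

**Planted cohorts** overwrite the drawn outcome with
`sigmoid(β₀ + Σβ_j·x_j) + N(0, noise_sd)`, clipped to [0, 100] and rounded
to 5 % steps, giving a known truth for recovery experiments. The recovery
harness uses n = 200 and noise SD 3 % over 20 seeds — large enough that a
correct pipeline should almost always retain the planted base terms, small
enough to run in a couple of minutes on one CPU; the noise level is of the
order of the test-retest variability of a 20-word list relative to the
planted signal.

## Residual analysis and evaluation

Residuals are measured − predicted (percent). Quartiles use linear
interpolation of order statistics (the common default; configurable, since
reported quartile/IQR values in small cohorts visibly depend on rounding —
comparisons against printed values are made at 0.1 tolerance). Outliers are
values strictly outside the Tukey fences Q1 − 1.5·IQR and Q3 + 1.5·IQR,
computed on **raw** residuals; the test-retest correction below affects only
consistency classification and display.

Test-retest consistency uses a score → 95 % half-width table for the
Freiburg monosyllabic test. The packaged default derives the half-width at
score p from the binomial variability of a 20-item list,
1.96·√(p(100 − p)/20), on the 5 % grid; it ships as an editable plain-text
CSV so sites can substitute empirically measured critical differences. A
measured/predicted pair is consistent iff its absolute difference is within
the half-width at the measured score; the displayed "adjusted difference"
shrinks the raw difference toward zero by that half-width (floored at zero,
sign preserved) — a documented convention, flagged in output, for an
adjustment that clinical reports describe but do not formalize.

High/low performer classification splits at aided WRS₆₅dB ≥ 70 %.

## Reproducibility

Every stochastic component takes an explicit seed (NumPy `default_rng`);
pipeline runs write all intermediates as delimited text plus a JSON manifest
(stages, seed, package versions), and re-running a config reproduces every
output byte for byte. The acceptance script derives all sub-seeds from its
single `--seed` argument.

## Known limitations

* The development cohort's per-patient predictor/outcome table is not
  distributed; evaluation against it is supported (drop the table at
  `data/supplement_cohort.csv`) but cannot run here, and the packaged
  stand-in cohort is synthetic except for the published per-patient ages.
* The generator controls summary structure only; conclusions about real
  cohorts require real data.
* The published model's constants are packaged as data and never refit; the
  search pipeline reproduces the *procedure*, not the exact published
  coefficients, unless given the original data.
* Selection behaviour with fewer than ~10 sign-coherent models per size, or
  with no hard cases, degrades to documented fallbacks (shorter lists, R²
  ranking) rather than erroring.
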