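"""Synthetic cohorts with the development study's statistical structure.

The generator emulates a 20-patient Vibrant Soundbridge cohort at the level
the modelling pipeline consumes: the joint distribution of age, BC_PTA4,
VIB_PTA4, WRS_max and the outcome WRS_65dB.  Three ingredients define it:

* **marginals** — per-variable mean/SD/range from the development cohort's
  summary statistics, realised as truncated normals whose parent parameters
  are calibrated so the *truncated* mean hits the target (the SD is matched
  as closely as the range permits; a stated SD can exceed what any truncated
  normal supports on a finite range, in which case the spread is the closest
  attainable);
* **rank correlations** — a Gaussian copula whose latent Pearson correlations
  are ``r = 2·sin(π·ρ/6)``, exact for bivariate normals, so the population
  Spearman ρ of the generated (pre-rounding) values equals the target;
  unstated pairs default to 0 and the completed matrix is repaired to the
  nearest positive-semidefinite matrix on request;
* **measurement granularity** — word scores move in 5 % steps (20-word
  Freiburg lists) and PTA4-level thresholds in 1.25 dB steps (mean of four
  5 dB-step thresholds).

Truncation is applied through the truncated-normal inverse CDF, not by
rejection or clipping: this leaves no point mass at the range limits,
preserves the copula's rank structure exactly, and keeps the calibrated
moments valid.  Per-frequency audiogram *shape* is out of scope; records get
near-flat threshold maps whose PTA4 reproduces the drawn value exactly.

:func:`generate_planted` replaces the drawn outcome with a known
sigmoid-linear truth plus noise, for parameter-recovery experiments, and
:func:`reference_cohort` rebuilds a 20-patient table carrying the published
per-patient ages (everything else synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import PTA4_FREQS, PatientRecord
from .model import SigmoidParams, sigmoid_predict

__all__ = [
    "Marginal",
    "CohortSpec",
    "PlantedModel",
    "STUDY_SPEC",
    "REFERENCE_AGES",
    "generate",
    "generate_planted",
    "generate_frame",
    "reference_cohort",
]

#: per-patient ages (years) of the 20 implanted ears in the development study
REFERENCE_AGES: tuple[int, ...] = (
    78, 58, 30, 36, 67, 57, 35, 41, 33, 61, 32, 27, 30, 46, 69, 54, 37, 28, 53, 68,
)


@dataclass(frozen=True)
class Marginal:
    """Target mean/SD, hard range and measurement step of one variable."""

    mean: float
    sd: float
    lo: float
    hi: float
    step: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean {self.mean} outside range [{self.lo}, {self.hi}]")
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")

    @property
    def grid_lo(self) -> float:
        # range limits printed at coarser precision are snapped to the
        # measurement grid (nearest step)
        return round(self.lo / self.step) * self.step

    @property
    def grid_hi(self) -> float:
        return round(self.hi / self.step) * self.step


@dataclass
class CohortSpec:
    """Size, marginals, rank-correlation targets and seed of a synthetic cohort."""

    n: int = 20
    marginals: dict[str, Marginal] = field(default_factory=dict)
    spearman_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be ≥ 1")
        for pair, rho in self.spearman_targets.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"Spearman target for {pair} outside [-1, 1]: {rho}")
            for v in pair:
                if v not in self.marginals:
                    raise ValueError(f"Spearman target names unknown variable {v!r}")


def _study_spec(n: int = 20, seed: int = 0) -> CohortSpec:
    return CohortSpec(
        n=n,
        marginals={
            "age": Marginal(47.0, 16.1, 27.0, 78.0, 1.0),
            "bc_pta4": Marginal(28.0, 10.1, 3.75, 50.0, 1.25),
            "vib_pta4": Marginal(40.2, 11.9, 16.3, 61.3, 1.25),
            "wrs_max": Marginal(88.5, 12.3, 60.0, 100.0, 5.0),
            "wrs_65": Marginal(81.5, 9.0, 60.0, 95.0, 5.0),
        },
        spearman_targets={
            ("bc_pta4", "wrs_65"): -0.522,
            ("wrs_max", "wrs_65"): 0.555,
            ("vib_pta4", "wrs_65"): -0.464,
        },
        seed=seed,
    )


#: the development study's cohort conditions (n = 20)
STUDY_SPEC: CohortSpec = _study_spec()


@dataclass(frozen=True)
class PlantedModel:
    """Known truth for recovery experiments: raw-scale β, sigmoid, noise SD.

    ``beta`` maps ``const`` and base-variable names to raw-scale coefficients;
    ``noise_sd`` is the SD (percent) of additive Gaussian outcome noise.
    """

    beta: Mapping[str, float]
    sigmoid: SigmoidParams = SigmoidParams(slope=0.063, midpoint=57.2941)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be ≥ 0, got {self.noise_sd}")

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        x = np.full(len(frame), float(self.beta.get("const", 0.0)))
        for name, b in self.beta.items():
            if name != "const":
                x = x + b * frame[name].to_numpy(dtype=float)
        return x


# ---------------------------------------------------------------------------
# marginal calibration and copula machinery


def _calibrate_parent(m: Marginal) -> tuple[float, float]:
    """Parent (μ, σ) whose truncation to [lo, hi] matches the target moments.

    The truncated mean is matched essentially exactly; the SD enters the loss
    with a smaller weight because some stated SDs are unattainable on a finite
    range (the variance of a truncated normal is bounded by the range).
    """

    def loss(p):
        mu, log_s = p
        s = float(np.exp(log_s))
        a, b = (m.lo - mu) / s, (m.hi - mu) / s
        mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [(mean - m.mean) / m.sd, 0.3 * (np.sqrt(var) - m.sd) / m.sd]

    sol = optimize.least_squares(loss, x0=[m.mean, np.log(m.sd)], method="lm")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped, diagonal-renormalized PSD repair of a correlation matrix."""
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-8, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


def _latent_correlation(spec: CohortSpec, names: Sequence[str], repair: bool) -> np.ndarray:
    R = np.eye(len(names))
    for (a, b), rho in spec.spearman_targets.items():
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = 2.0 * np.sin(np.pi * rho / 6.0)
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-10:
        if not repair:
            raise ValueError(
                f"completed correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g}); pass repair=True to project onto "
                "the nearest PSD correlation matrix"
            )
        R = _nearest_psd(R)
    elif eigmin < 1e-10:
        R = _nearest_psd(R)  # harmless ridge for the Cholesky factor
    return R


def generate_frame(
    spec: CohortSpec, seed: int | None = None, repair: bool = False
) -> pd.DataFrame:
    """Draw ``spec.n`` rows of the generated variables as a DataFrame.

    Deterministic for a fixed seed (``seed`` overrides ``spec.seed``).  Values
    respect the (grid-snapped) range limits and the measurement granularity
    exactly.
    """
    spec.validate()
    names = list(spec.marginals)
    R = _latent_correlation(spec, names, repair)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((spec.n, len(names))) @ L.T
    u = stats.norm.cdf(z)
    out = {}
    for j, name in enumerate(names):
        m = spec.marginals[name]
        mu, s = _calibrate_parent(m)
        a, b = (m.lo - mu) / s, (m.hi - mu) / s
        v = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=s)
        v = np.round(v / m.step) * m.step
        out[name] = np.clip(v, m.grid_lo, m.grid_hi)
    return pd.DataFrame(out)


def _round_step(values: np.ndarray, step: float, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.round(values / step) * step, lo, hi)


def _spread_pta4(target: float) -> dict[float, float]:
    """Four 5 dB-step thresholds whose mean equals ``target`` (a 1.25 dB multiple)."""
    quarters = int(round(target / 1.25))
    base = (quarters // 4) * 5.0
    extra = quarters % 4
    thr = {}
    for i, f in enumerate(PTA4_FREQS):
        thr[f] = base + (5.0 if i < extra else 0.0)
    return thr


def _to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for i, row in frame.iterrows():
        rec = PatientRecord(
            id=f"S{int(i) + 1:03d}",
            age=float(row["age"]),
            sex="F" if int(i) % 2 == 0 else "M",
            etiology="synthetic",
            coupling_site="RW",
            coupler="RWSC",
            bc=_spread_pta4(float(row["bc_pta4"])),
            vib=_spread_pta4(float(row["vib_pta4"])),
            wrs_max=float(row["wrs_max"]),
            wrs_65=float(row["wrs_65"]),
        )
        records.append(rec)
    return records


def generate(
    spec: CohortSpec = STUDY_SPEC, seed: int | None = None, repair: bool = False
) -> list[PatientRecord]:
    """Generate a synthetic cohort as patient records (see module docstring)."""
    return _to_records(generate_frame(spec, seed=seed, repair=repair))


def generate_planted(
    spec: CohortSpec,
    truth: PlantedModel,
    seed: int | None = None,
    repair: bool = False,
) -> list[PatientRecord]:
    """Generate predictors as in :func:`generate`, then overwrite the outcome
    with ``sigmoid(linear predictor) + N(0, noise_sd)``, clipped to [0, 100]
    and rounded to 5 % steps."""
    frame = generate_frame(spec, seed=seed, repair=repair)
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    y = sigmoid_predict(truth.linear_predictor(frame), truth.sigmoid)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=len(frame))
    frame["wrs_65"] = _round_step(np.asarray(y, dtype=float), 5.0, 0.0, 100.0)
    return _to_records(frame)


def reference_cohort(seed: int = 0) -> list[PatientRecord]:
    """A 20-patient stand-in for the development cohort (synthetic).

    Ages are the study's published per-patient values; every other column is a
    copula draw under the study conditions, with the drawn ages replaced by
    the published ones *rank for rank* so the joint rank structure of the draw
    is preserved.  Patient ids follow the study's 1–20 numbering.
    """
    frame = generate_frame(STUDY_SPEC, seed=seed)
    ages = np.asarray(REFERENCE_AGES, dtype=float)
    order = np.argsort(np.argsort(frame["age"].to_numpy()))
    frame["age"] = np.sort(ages)[order]
    records = _to_records(frame)
    for i, rec in enumerate(records):
        rec.id = str(i + 1)
        rec.etiology = "synthetic stand-in"
    return records
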