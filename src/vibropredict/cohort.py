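"""Patient cohort containers, delimited-text I/O and audiometric derived parameters.

A cohort is a list of :class:`PatientRecord` objects, one per implanted ear.
Thresholds are stored as frequency→dB HL maps keyed in kHz; word recognition
scores (WRS) are percentages on the 0–100 scale.  Derived quantities follow the
conventions of active-middle-ear-implant audiology:

* ``PTA4`` — arithmetic mean of thresholds at 0.5, 1, 2 and 4 kHz;
  ``PTA3`` drops 0.5 kHz.
* effective gain ``EG = FF_PTA − BC_PTA`` (how completely the device
  compensates the cochlear component; more negative is better),
* coupling efficiency ``CE = VIB_PTA − BC_PTA`` (in-situ Vibrogram threshold
  relative to bone conduction; 0 dB means ideal energy transfer),
* dynamic range ``DR = MPO_PTA − FF_PTA`` (usable headroom between the aided
  free-field threshold and the transducer's maximum power output).

The sign convention for DR is chosen so that a positive number means usable
headroom; the MPO entering DR is averaged over the same frequencies as the
corresponding PTA so every derived quantity lives on the PTA scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "DerivedAudiometry",
    "CohortError",
    "PTA4_FREQS",
    "PTA3_FREQS",
    "MPO_DEFAULT",
    "pta",
    "derive_audiometry",
    "load_cohort",
    "write_cohort",
    "cohort_to_frame",
]

log = logging.getLogger(__name__)

#: frequencies (kHz) entering the four- and three-frequency pure-tone averages
PTA4_FREQS: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
PTA3_FREQS: tuple[float, ...] = (1.0, 2.0, 4.0)

#: maximum power output of the Vibrant Soundbridge per frequency [dB]
MPO_DEFAULT: dict[float, float] = {0.5: 75.0, 1.0: 83.0, 2.0: 90.0, 4.0: 80.0}

COUPLING_SITES = ("RW", "OW", "stapes", "incus-SP")
COUPLERS = ("RWSC", "RWTC", "SClip", "SSH", "OWC", "SP")


class CohortError(ValueError):
    """Raised for invalid cohort files or records."""


@dataclass
class PatientRecord:
    """One subject: demographics, per-frequency thresholds and word scores.

    Threshold maps (``bc``, ``ff``, ``ac``, ``vib``) are keyed by frequency in
    kHz.  Maps may be partial; only the frequencies needed for a requested PTA
    are mandatory.
    """

    id: str
    age: float
    sex: str = ""
    etiology: str = ""
    coupling_site: str = ""
    coupler: str = ""
    bc: dict[float, float] = field(default_factory=dict)
    ff: dict[float, float] = field(default_factory=dict)
    ac: dict[float, float] = field(default_factory=dict)
    vib: dict[float, float] = field(default_factory=dict)
    wrs_max: float = float("nan")
    wrs_65: float = float("nan")

    def validate(self) -> None:
        if not self.age > 0:
            raise CohortError(f"patient {self.id!r}: age must be positive, got {self.age}")
        if self.age < 18:
            raise CohortError(
                f"patient {self.id!r}: age {self.age} violates the adult inclusion criterion (≥ 18 y)"
            )
        for name, score in (("wrs_max", self.wrs_max), ("wrs_65", self.wrs_65)):
            if score == score and not 0.0 <= score <= 100.0:  # NaN-safe
                raise CohortError(
                    f"patient {self.id!r}: {name} = {score} outside the [0, 100] percent range"
                )


@dataclass(frozen=True)
class DerivedAudiometry:
    """PTA-level derived parameters for one patient (all in dB)."""

    bc_pta4: float
    bc_pta3: float
    ff_pta4: float
    ff_pta3: float
    vib_pta4: float
    vib_pta3: float
    eg_pta4: float
    eg_pta3: float
    ce_pta4: float
    ce_pta3: float
    dr_pta4: float
    dr_pta3: float


def pta(thresholds: Mapping[float, float], frequencies: Sequence[float]) -> float:
    """Arithmetic mean of ``thresholds`` at the requested ``frequencies`` (kHz).

    Raises :class:`CohortError` naming the first missing frequency.
    """
    values = []
    for f in frequencies:
        if f not in thresholds:
            raise CohortError(f"missing threshold at {f} kHz (have {sorted(thresholds)})")
        values.append(float(thresholds[f]))
    if not values:
        raise CohortError("pta requested over an empty frequency list")
    return sum(values) / len(values)


def derive_audiometry(
    p: PatientRecord, mpo: Mapping[float, float] | None = None
) -> DerivedAudiometry:
    """Compute PTA4/PTA3 and the derived parameters EG, CE and DR.

    ``mpo`` defaults to the device's printed maximum power output
    (75/83/90/80 dB at 0.5/1/2/4 kHz).  DR is reported as MPO_PTA − FF_PTA so
    that positive values mean usable headroom.
    """
    mpo = MPO_DEFAULT if mpo is None else dict(mpo)
    out: dict[str, float] = {}
    for tag, freqs in (("pta4", PTA4_FREQS), ("pta3", PTA3_FREQS)):
        bc = pta(p.bc, freqs)
        ff = pta(p.ff, freqs)
        vib = pta(p.vib, freqs)
        out[f"bc_{tag}"] = bc
        out[f"ff_{tag}"] = ff
        out[f"vib_{tag}"] = vib
        out[f"eg_{tag}"] = ff - bc
        out[f"ce_{tag}"] = vib - bc
        out[f"dr_{tag}"] = pta(mpo, freqs) - ff
    return DerivedAudiometry(**out)


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Column schema: id, age, sex, etiology, coupling_site, coupler, wrs_max,
# wrs_65 plus threshold columns "<map>_<hz>" (e.g. bc_500, vib_4000) for the
# four maps bc/ff/ac/vib.  Frequencies are written in Hz in the header and
# stored in kHz on the record.

_THRESHOLD_PREFIXES = ("bc", "ff", "ac", "vib")
_META_COLUMNS = ("id", "age", "sex", "etiology", "coupling_site", "coupler", "wrs_max", "wrs_65")


def _threshold_columns(columns: Iterable[str]) -> dict[str, tuple[str, float]]:
    """Map column name → (map name, frequency in kHz) for threshold columns."""
    out: dict[str, tuple[str, float]] = {}
    for col in columns:
        if "_" not in col:
            continue
        prefix, _, tail = col.partition("_")
        if prefix in _THRESHOLD_PREFIXES:
            try:
                hz = float(tail)
            except ValueError:
                continue
            out[col] = (prefix, hz / 1000.0)
    return out


def load_cohort(
    path: str | Path,
    sep: str = ",",
    decimal: str = ".",
) -> list[PatientRecord]:
    """Read a cohort from delimited text (UTF-8, header row).

    ``decimal`` selects the decimal-mark dialect (``"."`` default, ``","`` for
    continental exports).  Every row is validated; failures report the
    offending row index and column.
    """
    df = pd.read_csv(path, sep=sep, decimal=decimal, dtype={"id": str})
    if "id" not in df.columns or "age" not in df.columns:
        raise CohortError(f"{path}: cohort file must contain at least 'id' and 'age' columns")
    if df.empty:
        log.warning("%s: cohort file contains a header but no rows", path)
        return []
    dup = df["id"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise CohortError(f"{path}: duplicate patient id {df['id'][row]!r} at row {row}")
    thr_cols = _threshold_columns(df.columns)
    records: list[PatientRecord] = []
    for row_idx, row in df.iterrows():
        rec = PatientRecord(
            id=str(row["id"]),
            age=_numeric(row, "age", row_idx),
            sex=_text(row, "sex"),
            etiology=_text(row, "etiology"),
            coupling_site=_text(row, "coupling_site"),
            coupler=_text(row, "coupler"),
            wrs_max=_numeric(row, "wrs_max", row_idx, optional=True),
            wrs_65=_numeric(row, "wrs_65", row_idx, optional=True),
        )
        for col, (prefix, khz) in thr_cols.items():
            val = row.get(col)
            if pd.notna(val):
                getattr(rec, prefix)[khz] = float(val)
        try:
            rec.validate()
        except CohortError as exc:
            raise CohortError(f"{path}: row {row_idx}: {exc}") from exc
        records.append(rec)
    return records


def _text(row: pd.Series, col: str) -> str:
    val = row.get(col, "")
    return "" if pd.isna(val) else str(val)


def _numeric(row: pd.Series, col: str, row_idx, optional: bool = False) -> float:
    val = row.get(col)
    if val is None or (isinstance(val, float) and val != val) or pd.isna(val):
        if optional:
            return float("nan")
        raise CohortError(f"row {row_idx}: required column {col!r} is missing or empty")
    try:
        return float(val)
    except (TypeError, ValueError):
        raise CohortError(f"row {row_idx}: column {col!r} is not numeric: {val!r}") from None


def write_cohort(records: Sequence[PatientRecord], path: str | Path, sep: str = ",") -> None:
    """Write a cohort as delimited text; numeric fields round-trip exactly."""
    freqs: dict[str, set[float]] = {p: set() for p in _THRESHOLD_PREFIXES}
    for rec in records:
        for prefix in _THRESHOLD_PREFIXES:
            freqs[prefix].update(getattr(rec, prefix))
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.id,
            "age": rec.age,
            "sex": rec.sex,
            "etiology": rec.etiology,
            "coupling_site": rec.coupling_site,
            "coupler": rec.coupler,
        }
        for prefix in _THRESHOLD_PREFIXES:
            for khz in sorted(freqs[prefix]):
                row[f"{prefix}_{int(round(khz * 1000))}"] = getattr(rec, prefix).get(khz)
        row["wrs_max"] = rec.wrs_max
        row["wrs_65"] = rec.wrs_65
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def cohort_to_frame(records: Sequence[PatientRecord], derived: bool = True) -> pd.DataFrame:
    """Modelling table: one row per patient with age, word scores and, when the
    threshold maps allow it, the PTA-level derived parameters."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.id,
            "age": rec.age,
            "wrs_max": rec.wrs_max,
            "wrs_65": rec.wrs_65,
        }
        if derived:
            try:
                der = derive_audiometry(rec)
            except CohortError:
                # fall back to the quantities computable without FF thresholds
                for name, thr in (("bc", rec.bc), ("vib", rec.vib)):
                    for tag, fr in (("pta4", PTA4_FREQS), ("pta3", PTA3_FREQS)):
                        try:
                            row[f"{name}_{tag}"] = pta(thr, fr)
                        except CohortError:
                            pass
                if "bc_pta4" in row and "vib_pta4" in row:
                    row["ce_pta4"] = row["vib_pta4"] - row["bc_pta4"]
            else:
                row.update(vars(der))
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")
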