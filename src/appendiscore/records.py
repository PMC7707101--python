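"""Patient-level records for pediatric abdominal-pain cohorts.

A :class:`PatientRecord` carries the raw clinical history, examination
findings, laboratory values, ultrasound result and histology-based outcome
for one child hospitalized with suspected appendicitis.  Clinical yes/no
findings are tri-state (``True`` / ``False`` / ``None`` for not recorded);
laboratory and ultrasound values may be missing jointly when the work-up was
not completed.  Missingness is always represented explicitly — nothing is
imputed at this layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import pandas as pd

NO_APPENDICITIS = "no_appendicitis"
SIMPLE = "simple"
PERFORATED = "perforated"
OUTCOMES = (NO_APPENDICITIS, SIMPLE, PERFORATED)

#: tri-state clinical findings recorded on history / examination
TRISTATE_FIELDS = (
    "continuous_pain",
    "nausea_vomiting",
    "anorexia",
    "migration_of_pain",
    "tenderness_rlq",
    "rebound_tenderness",
    "cough_hop_tenderness",
    "us_appendicitis",
)

_TRUE = {"yes", "true", "1", "y"}
_FALSE = {"no", "false", "0", "n"}


def is_appendicitis(outcome: Optional[str]) -> Optional[bool]:
    """Dichotomize an outcome label as appendicitis (simple or perforated) vs none."""
    if outcome is None:
        return None
    return outcome in (SIMPLE, PERFORATED)


@dataclass
class PatientRecord:
    """One patient's raw clinical, laboratory and imaging values plus outcome.

    Units: ``age`` in years, ``duration_h`` in hours of abdominal pain,
    ``temperature_c`` in degrees Celsius, ``wbc`` and ``neutrophils_abs`` in
    10^9 cells/L, ``neutrophils_pct`` in percent, ``crp`` in mg/L.
    """

    id: str
    age: float
    sex: str
    duration_h: float
    continuous_pain: Optional[bool] = None
    nausea_vomiting: Optional[bool] = None
    anorexia: Optional[bool] = None
    migration_of_pain: Optional[bool] = None
    tenderness_rlq: Optional[bool] = None
    rebound_tenderness: Optional[bool] = None
    cough_hop_tenderness: Optional[bool] = None
    temperature_c: Optional[float] = None
    wbc: Optional[float] = None
    neutrophils_abs: Optional[float] = None
    neutrophils_pct: Optional[float] = None
    crp: Optional[float] = None
    us_appendicitis: Optional[bool] = None
    outcome: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 < self.age <= 18):
            raise ValueError(f"age must lie in (0, 18], got {self.age!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.duration_h < 0:
            raise ValueError("duration_h must be >= 0")
        for name in ("wbc", "crp", "neutrophils_abs"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0 when present")
        if self.neutrophils_pct is not None and not (0 <= self.neutrophils_pct <= 100):
            raise ValueError("neutrophils_pct must lie in [0, 100] when present")
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def appendicitis(self) -> Optional[bool]:
        return is_appendicitis(self.outcome)


def _parse_tristate(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text == "":
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"cannot parse tri-state value {value!r}")


def _parse_float(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    result = float(value)
    if math.isnan(result):
        return None
    return result


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV (one row per patient, empty cells = missing)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = [f.name for f in fields(PatientRecord)]
    missing_cols = set(expected) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing_cols)}")
    cohort = []
    for row in frame.itertuples(index=False):
        values = {name: getattr(row, name) for name in expected}
        record = PatientRecord(
            id=str(values["id"]),
            age=float(values["age"]),
            sex=str(values["sex"]).strip().lower(),
            duration_h=float(values["duration_h"]),
            temperature_c=_parse_float(values["temperature_c"]),
            wbc=_parse_float(values["wbc"]),
            neutrophils_abs=_parse_float(values["neutrophils_abs"]),
            neutrophils_pct=_parse_float(values["neutrophils_pct"]),
            crp=_parse_float(values["crp"]),
            outcome=(values["outcome"].strip() or None),
            **{name: _parse_tristate(values[name]) for name in TRISTATE_FIELDS},
        )
        cohort.append(record)
    return cohort


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate a cohort; tri-state fields become yes/no/empty strings."""
    rows = []
    for patient in cohort:
        row = {}
        for f in fields(PatientRecord):
            value = getattr(patient, f.name)
            if f.name in TRISTATE_FIELDS:
                value = "" if value is None else ("yes" if value else "no")
            elif value is None:
                value = ""
            row[f.name] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=[f.name for f in fields(PatientRecord)])


def write_cohort_csv(cohort: Iterable[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
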