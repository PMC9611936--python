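"""Event-dataset reading and writing.

The interchange format is a single flat CSV in the pharmacometric event
style: one row per dose or observation, with the patient's covariates
repeated on each row.  Columns (case-insensitive header):

    ID, TIME, EVENT, AMT, DUR, DV, DVUNIT, BW, HT, AGE, SEX

* dose rows:        EVENT=dose, AMT (mg) and DUR (h) set, DV empty
* observation rows: EVENT=obs,  DV set (DVUNIT ng/mL by default), AMT empty

Concentrations are converted to mg/L internally (1 mg/L = 1000 ng/mL);
ng/mL is the default external unit because that is how busulfan assays
report.  Covariates are taken from a patient's first row; conflicting
values on later rows are logged and ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .models import PatientCovariates
from .pk import DoseEvent, Observation, Regimen

__all__ = ["Patient", "read_dataset", "write_dataset", "COLUMNS"]

logger = logging.getLogger(__name__)

COLUMNS = ["ID", "TIME", "EVENT", "AMT", "DUR", "DV", "DVUNIT", "BW", "HT", "AGE", "SEX"]
_MANDATORY = ["ID", "TIME", "EVENT", "AMT", "DUR", "DV", "BW"]
_DOSE = "dose"
_OBS = "obs"


@dataclass(frozen=True)
class Patient:
    """A patient record: covariates, dosing history, observations."""

    id: str
    covariates: PatientCovariates
    regimen: Regimen
    observations: tuple[Observation, ...]


def _to_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)


def read_dataset(path: str | Path) -> list[Patient]:
    """Parse an event CSV into validated patients.

    Raises with the offending column name if a mandatory column is
    missing, and with the 1-based data row number on invalid rows
    (negative AMT/DV, a dose row carrying a DV, an observation row
    carrying an AMT, unknown event type).
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().upper() for c in df.columns]
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"dataset {path} is missing mandatory column {col!r}")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = None

    patients: list[Patient] = []
    for pid, group in df.groupby("ID", sort=False):
        events: list[DoseEvent] = []
        observations: list[Observation] = []
        cov: PatientCovariates | None = None
        for idx, row in group.iterrows():
            rowno = idx + 1  # 1-based data row, matching the CSV body
            time = _to_float(row["TIME"])
            if time is None or time < 0:
                raise ValueError(f"row {rowno}: TIME must be a number >= 0")
            kind = str(row["EVENT"]).strip().lower()
            amt = _to_float(row["AMT"])
            dur = _to_float(row["DUR"])
            dv = _to_float(row["DV"])

            row_cov = PatientCovariates(
                body_weight=_require(row, "BW", rowno),
                height=_to_float(row["HT"]),
                age=_to_float(row["AGE"]),
                sex=None if _is_blank(row["SEX"])
                else str(row["SEX"]).strip().lower(),
            )
            if cov is None:
                cov = row_cov
            elif row_cov != cov:
                logger.warning(
                    "patient %s row %d: covariates differ from the first row; "
                    "first row wins", pid, rowno,
                )

            if kind == _DOSE:
                if dv is not None:
                    raise ValueError(f"row {rowno}: dose row must not carry a DV")
                if amt is None or dur is None:
                    raise ValueError(f"row {rowno}: dose row needs AMT and DUR")
                if amt < 0:
                    raise ValueError(f"row {rowno}: negative AMT {amt}")
                events.append(DoseEvent(amount=amt, start=time, duration=dur))
            elif kind in (_OBS, "observation"):
                if amt is not None:
                    raise ValueError(
                        f"row {rowno}: observation row must not carry an AMT"
                    )
                if dv is None:
                    raise ValueError(f"row {rowno}: observation row needs a DV")
                if dv < 0:
                    raise ValueError(f"row {rowno}: negative DV {dv}")
                unit = (str(row["DVUNIT"]).strip() or "ng/mL") \
                    if not _is_blank(row["DVUNIT"]) else "ng/mL"
                if unit.lower() in ("ng/ml", "ng per ml"):
                    observations.append(Observation.from_ng_per_ml(time, dv))
                elif unit.lower() in ("mg/l", "mg per l", "ug/ml", "µg/ml"):
                    observations.append(
                        Observation(time=time, concentration=dv, source_unit="mg/L")
                    )
                else:
                    raise ValueError(f"row {rowno}: unknown DV unit {unit!r}")
            else:
                raise ValueError(
                    f"row {rowno}: unknown event type {kind!r} "
                    f"(expected '{_DOSE}' or '{_OBS}')"
                )

        if not events:
            raise ValueError(f"patient {pid}: no dose events")
        events.sort(key=lambda e: e.start)
        patients.append(
            Patient(
                id=str(pid),
                covariates=cov,
                regimen=Regimen(events=tuple(events)),
                observations=tuple(observations),
            )
        )
    return patients


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


def _require(row, col: str, rowno: int) -> float:
    value = _to_float(row[col])
    if value is None:
        raise ValueError(f"row {rowno}: {col} is required")
    return value


def _fmt(value) -> str:
    if value is None:
        return ""
    return format(float(value), ".10g")


def write_dataset(patients: Sequence[Patient], path: str | Path) -> None:
    """Write patients back to the event CSV (DV in ng/mL).

    Numbers are rendered at 10 significant digits, enough to round-trip
    every quantity the engine produces through ``read_dataset`` exactly
    at the file level.
    """
    rows = []
    for p in patients:
        c = p.covariates
        base = {
            "BW": _fmt(c.body_weight),
            "HT": _fmt(c.height) if c.height is not None else "",
            "AGE": _fmt(c.age) if c.age is not None else "",
            "SEX": c.sex or "",
        }
        for e in p.regimen.events:
            rows.append(
                {
                    "ID": p.id, "TIME": _fmt(e.start), "EVENT": _DOSE,
                    "AMT": _fmt(e.amount), "DUR": _fmt(e.duration),
                    "DV": "", "DVUNIT": "", **base,
                }
            )
        for o in p.observations:
            rows.append(
                {
                    "ID": p.id, "TIME": _fmt(o.time), "EVENT": _OBS,
                    "AMT": "", "DUR": "",
                    "DV": _fmt(o.concentration * 1000.0), "DVUNIT": "ng/mL",
                    **base,
                }
            )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
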