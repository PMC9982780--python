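"""Reading and writing the tabular event dataset.

The format follows the NONMEM convention: one row per dose (EVID=1, with
AMT mg and RATE mg/h or DUR h) or observation (EVID=0, with DV mg/L and
DVID 1=total / 2=unbound), plus per-patient covariate columns (WT kg, ALB
g/L, CLCR mL/min/1.73 m2 or SCR umol/L with AGE and SEX).  Times are hours
since the first dose; the reader rejects files that do not follow these
units conventions rather than converting silently.
"""

from __future__ import annotations

import math
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .covariates import CovariateSet
from .estimation import Observation, PatientRecord
from .pk import DoseEvent

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "patients_to_frame", "frame_to_patients"]

COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "RATE", "DUR", "DV", "DVID",
    "WT", "ALB", "CLCR", "SCR", "AGE", "SEX",
]

_DVID_CHANNEL = {1: "total", 2: "unbound"}
_CHANNEL_DVID = {v: k for k, v in _DVID_CHANNEL.items()}


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""


def _err(row_no: int, msg: str):
    raise ValueError(f"dataset row {row_no}: {msg}")


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    """Validate an event table and build patient records.

    Row numbers in error messages refer to the data rows (header = row 0).
    """
    missing = [c for c in ("ID", "TIME", "EVID") if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    for col in ("UNIT", "UNITS"):
        if col in df.columns:
            raise ValueError(
                f"dataset carries a {col!r} column; units are fixed (h, mg, mg/L) "
                "and unit columns are rejected rather than converted"
            )
    df = df.reset_index(drop=True)
    patients = []
    for pid, sub in df.groupby("ID", sort=False):
        doses: list[DoseEvent] = []
        obs: list[Observation] = []
        cov_row = sub.iloc[0]
        for idx, row in sub.iterrows():
            row_no = int(idx) + 1
            evid = int(row["EVID"])
            t = float(row["TIME"])
            if evid == 1:
                if _is_missing(row.get("AMT")):
                    _err(row_no, "dose row lacks AMT")
                amt = float(row["AMT"])
                rate = row.get("RATE")
                dur = row.get("DUR")
                if not _is_missing(rate) and float(rate) > 0:
                    duration = amt / float(rate)
                elif not _is_missing(dur):
                    duration = float(dur)
                else:
                    _err(row_no, "dose row needs RATE > 0 or DUR")
                try:
                    doses.append(DoseEvent(t, amt, duration))
                except ValueError as e:
                    _err(row_no, str(e))
            elif evid == 0:
                if _is_missing(row.get("DV")):
                    _err(row_no, "observation row lacks DV")
                if _is_missing(row.get("DVID")):
                    _err(row_no, "observation row lacks DVID")
                dvid = int(row["DVID"])
                if dvid not in _DVID_CHANNEL:
                    _err(row_no, f"DVID must be 1 (total) or 2 (unbound), got {dvid}")
                try:
                    obs.append(Observation(t, _DVID_CHANNEL[dvid], float(row["DV"])))
                except ValueError as e:
                    _err(row_no, str(e))
            else:
                _err(row_no, f"EVID must be 0 or 1, got {evid}")
        first_row_no = int(sub.index[0]) + 1
        for col in ("WT", "ALB"):
            if col not in sub.columns or _is_missing(cov_row.get(col)):
                _err(first_row_no, f"patient {pid} lacks covariate {col}")
        clcr = cov_row.get("CLCR")
        scr = cov_row.get("SCR")
        if _is_missing(clcr) and (
            _is_missing(scr) or _is_missing(cov_row.get("AGE")) or _is_missing(cov_row.get("SEX"))
        ):
            _err(first_row_no, f"patient {pid} needs CLCR or (SCR, AGE, SEX)")
        cov = CovariateSet(
            weight=float(cov_row["WT"]),
            albumin=float(cov_row["ALB"]),
            clcr=None if _is_missing(clcr) else float(clcr),
            serum_creatinine=None if _is_missing(scr) else float(scr),
            age=None if _is_missing(cov_row.get("AGE")) else float(cov_row["AGE"]),
            sex=None if _is_missing(cov_row.get("SEX")) else str(cov_row["SEX"]),
        )
        if not doses:
            _err(first_row_no, f"patient {pid} has no dose row")
        obs.sort(key=lambda o: o.time)
        patients.append(PatientRecord(str(pid), doses, obs, cov))
    return patients


def read_dataset(path_or_buf) -> list[PatientRecord]:
    """Read a CSV event dataset into validated patient records.

    Creatinine clearance is resolved from SCR/AGE/SEX via CKD-EPI downstream
    when the CLCR column is absent.
    """
    df = pd.read_csv(path_or_buf)
    return frame_to_patients(df)


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    """Serialize patient records to the canonical event table."""
    rows = []
    for p in patients:
        c = p.covariates
        cov = {
            "WT": c.weight,
            "ALB": c.albumin,
            "CLCR": c.clcr if c.clcr is not None else np.nan,
            "SCR": c.serum_creatinine if c.serum_creatinine is not None else np.nan,
            "AGE": c.age if c.age is not None else np.nan,
            "SEX": {"male": "M", "female": "F"}.get(str(c.sex).lower(), c.sex)
            if c.sex is not None
            else "",
        }
        events = [("dose", d.start_time, d) for d in p.dose_events] + [
            ("obs", o.time, o) for o in p.observations
        ]
        events.sort(key=lambda e: (e[1], e[0] == "obs"))
        for kind, t, ev in events:
            row = {"ID": p.id, "TIME": t, **cov}
            if kind == "dose":
                row.update(
                    EVID=1, AMT=ev.amount, RATE=ev.rate, DUR=ev.duration, DV=np.nan, DVID=np.nan
                )
            else:
                row.update(
                    EVID=0, AMT=np.nan, RATE=np.nan, DUR=np.nan,
                    DV=ev.value, DVID=_CHANNEL_DVID[ev.channel],
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def write_dataset(patients: Iterable[PatientRecord], path_or_buf) -> None:
    """Write patient records as a CSV event dataset."""
    patients_to_frame(patients).to_csv(path_or_buf, index=False)
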