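"""Domain types and CSV (de)serialization for hemodialysis (HD) sessions.

A maintenance HD session lasts about four hours.  The dialysis machine logs a
new record only when venous or transmembranous pressure changes, so machine
series are irregularly sampled; staff vitals (blood pressures, pulse rate)
arrive every 30-60 minutes.  Each session additionally carries four
time-invariant patient fields and zero or more timed intradialytic adverse
events drawn from a closed 27-category vocabulary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENTS",
    "MEASUREMENT_IDS",
    "EVENT_EPISODES",
    "EVENT_VOCABULARY",
    "MeasurementRecord",
    "StaticFields",
    "AdverseEvent",
    "HDSession",
    "SessionValidationError",
    "read_sessions",
    "write_sessions",
]

# The nine time-varying measurements, keyed by their fixed id.  Ids 1-4 are
# staff-recorded vitals, 5-9 are machine readouts.
MEASUREMENTS: dict[int, str] = {
    1: "systolic_bp",            # mmHg
    2: "diastolic_bp",           # mmHg
    3: "pulse_pressure",         # mmHg
    4: "pulse_rate",             # bpm
    5: "blood_flow_rate",        # mL/min
    6: "venous_pressure",        # mmHg
    7: "transmembranous_pressure",  # mmHg
    8: "uf_rate",                # mL/h
    9: "uf_volume",              # mL, cumulative
}
MEASUREMENT_IDS: dict[str, int] = {name: mid for mid, name in MEASUREMENTS.items()}

VITALS_IDS = frozenset({1, 2, 3, 4})
MACHINE_IDS = frozenset({5, 6, 7, 8, 9})

BLOOD_FLOW_RATE = 5
VENOUS_PRESSURE = 6
TRANSMEMBRANOUS_PRESSURE = 7
UF_RATE = 8
UF_VOLUME = 9

# Closed adverse-event vocabulary with documented episode counts, used both
# for validation and as the empirical type distribution of the simulator.
EVENT_EPISODES: dict[str, int] = {
    "muscle_cramps": 138,
    "blood_pressure_elevation": 108,
    "low_blood_pressure": 64,
    "miscellaneous": 45,
    "headache": 28,
    "lightheadedness": 26,
    "chest_tightness": 23,
    "vascular_access_thrombosis": 23,
    "cold_sweating": 22,
    "nausea_vomiting": 12,
    "fever": 10,
    "tachycardia": 10,
    "dyspnea": 8,
    "hoarseness": 8,
    "chills": 5,
    "leg_pain": 5,
    "low_back_pain": 5,
    "shoulder_pain": 5,
    "altered_mental_status": 4,
    "chest_discomfort": 3,
    "numb_hands": 3,
    "tinnitus": 3,
    "vascular_access_occlusion": 3,
    "abdominal_pain": 2,
    "hypersomnia": 1,
    "palpitation": 1,
    "pruritus": 1,
}
EVENT_VOCABULARY = frozenset(EVENT_EPISODES)


class SessionValidationError(ValueError):
    """Raised when input tables or session objects violate the data model."""


@dataclass(frozen=True, slots=True)
class MeasurementRecord:
    """One timed observation Y at time T of measurement j."""

    measurement_id: int
    time_min: float
    value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_min", float(self.time_min))
        object.__setattr__(self, "value", float(self.value))
        if self.measurement_id not in MEASUREMENTS:
            raise SessionValidationError(
                f"unknown measurement id {self.measurement_id!r}"
            )
        if not math.isfinite(self.time_min) or self.time_min < 0:
            raise SessionValidationError(
                f"time_min must be finite and >= 0, got {self.time_min!r}"
            )


@dataclass(frozen=True, slots=True)
class StaticFields:
    """Time-invariant patient fields used as demographic features."""

    age: float
    gender: str  # "male" | "female"
    vintage_years: float
    predialytic_weight: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise SessionValidationError(f"age must be > 0, got {self.age}")
        if self.gender not in ("male", "female"):
            raise SessionValidationError(f"gender must be male/female, got {self.gender!r}")
        if self.vintage_years < 0:
            raise SessionValidationError("vintage_years must be >= 0")
        if self.predialytic_weight <= 0:
            raise SessionValidationError("predialytic_weight must be > 0")

    @property
    def gender_code(self) -> int:
        """Modeling encoding: male=1, female=0."""
        return 1 if self.gender == "male" else 0


@dataclass(frozen=True, slots=True)
class AdverseEvent:
    event_type: str
    time_min: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_VOCABULARY:
            raise SessionValidationError(
                f"event_type {self.event_type!r} outside the adverse-event vocabulary"
            )
        if not math.isfinite(self.time_min) or self.time_min <= 0:
            raise SessionValidationError(
                f"event time must be finite and > 0, got {self.time_min!r}"
            )


@dataclass(slots=True)
class HDSession:
    """One dialysis session: records, static patient fields, timed events."""

    session_id: str
    patient_id: str
    records: list[MeasurementRecord]
    static: StaticFields
    events: list[AdverseEvent] = field(default_factory=list)
    scheduled_length_min: float = 240.0

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.time_min, r.measurement_id))
        self.events = sorted(self.events, key=lambda e: e.time_min)

    def series(self, measurement_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Time-sorted (t, y) arrays for one measurement.

        Duplicate timestamps are collapsed to the last value recorded at that
        time, so downstream differencing never sees a zero time step.
        """
        t, y = [], []
        for r in self.records:
            if r.measurement_id != measurement_id:
                continue
            if t and r.time_min == t[-1]:
                y[-1] = r.value
            else:
                t.append(r.time_min)
                y.append(r.value)
        return np.asarray(t, dtype=float), np.asarray(y, dtype=float)

    @property
    def first_event_time(self) -> float | None:
        return self.events[0].time_min if self.events else None

    @property
    def last_record_time(self) -> float:
        if not self.records:
            raise SessionValidationError(f"session {self.session_id} has no records")
        return self.records[-1].time_min

    def with_records(self, records: Iterable[MeasurementRecord]) -> "HDSession":
        return replace(self, records=list(records))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionValidationError(f"{table} is missing required column(s) {missing}")


def _as_frame(obj: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    # round_trip parsing so serialized floats reproduce exactly
    return pd.read_csv(obj, float_precision="round_trip")


def read_sessions(
    session_table: pd.DataFrame | str | Path,
    metadata_table: pd.DataFrame | str | Path,
    event_table: pd.DataFrame | str | Path | None = None,
) -> list[HDSession]:
    """Assemble HDSession objects from long-format CSV tables.

    ``session_table``: session_id, patient_id, time_min, measurement, value.
    ``metadata_table``: session_id, patient_id, age, gender, vintage_years,
    predialytic_weight, scheduled_length_min.
    ``event_table``: session_id, time_min, event_type (optional/empty allowed).
    """
    rec_df = _as_frame(session_table)
    meta_df = _as_frame(metadata_table)
    _require_columns(rec_df, ["session_id", "patient_id", "time_min", "measurement", "value"], "session table")
    _require_columns(
        meta_df,
        ["session_id", "patient_id", "age", "gender", "vintage_years", "predialytic_weight"],
        "metadata table",
    )
    if event_table is not None:
        ev_df = _as_frame(event_table)
        _require_columns(ev_df, ["session_id", "time_min", "event_type"], "event table")
    else:
        ev_df = pd.DataFrame(columns=["session_id", "time_min", "event_type"])

    unknown = set(rec_df["measurement"]) - set(MEASUREMENT_IDS)
    if unknown:
        raise SessionValidationError(f"unknown measurement name(s) {sorted(unknown)}")

    events_by_sid: dict[str, list[AdverseEvent]] = {}
    for row in ev_df.itertuples(index=False):
        sid = str(row.session_id)
        if row.event_type not in EVENT_VOCABULARY:
            raise SessionValidationError(
                f"event_type {row.event_type!r} for session {sid} is outside the vocabulary"
            )
        if pd.isna(row.time_min):
            raise SessionValidationError(f"event for session {sid} lacks a time")
        events_by_sid.setdefault(sid, []).append(
            AdverseEvent(event_type=row.event_type, time_min=float(row.time_min))
        )

    recs_by_sid: dict[str, list[MeasurementRecord]] = {}
    for row in rec_df.itertuples(index=False):
        recs_by_sid.setdefault(str(row.session_id), []).append(
            MeasurementRecord(
                measurement_id=MEASUREMENT_IDS[row.measurement],
                time_min=float(row.time_min),
                value=float(row.value),
            )
        )

    sessions: list[HDSession] = []
    for row in meta_df.itertuples(index=False):
        sid = str(row.session_id)
        static = StaticFields(
            age=float(row.age),
            gender=str(row.gender),
            vintage_years=float(row.vintage_years),
            predialytic_weight=float(row.predialytic_weight),
        )
        scheduled = float(getattr(row, "scheduled_length_min", 240.0) or 240.0)
        sessions.append(
            HDSession(
                session_id=sid,
                patient_id=str(row.patient_id),
                records=recs_by_sid.get(sid, []),
                static=static,
                events=events_by_sid.get(sid, []),
                scheduled_length_min=scheduled,
            )
        )
    return sessions


def write_sessions(
    sessions: Sequence[HDSession], out_dir: str | Path
) -> dict[str, Path]:
    """Write sessions.csv / metadata.csv / events.csv into ``out_dir``.

    Values round-trip exactly through :func:`read_sessions` (floats are
    written with shortest round-trippable repr).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rec_rows, meta_rows, ev_rows = [], [], []
    for s in sessions:
        meta_rows.append(
            {
                "session_id": s.session_id,
                "patient_id": s.patient_id,
                "age": s.static.age,
                "gender": s.static.gender,
                "vintage_years": s.static.vintage_years,
                "predialytic_weight": s.static.predialytic_weight,
                "scheduled_length_min": s.scheduled_length_min,
            }
        )
        for r in s.records:
            rec_rows.append(
                {
                    "session_id": s.session_id,
                    "patient_id": s.patient_id,
                    "time_min": r.time_min,
                    "measurement": MEASUREMENTS[r.measurement_id],
                    "value": r.value,
                }
            )
        for e in s.events:
            ev_rows.append(
                {"session_id": s.session_id, "time_min": e.time_min, "event_type": e.event_type}
            )

    paths = {
        "sessions": out / "sessions.csv",
        "metadata": out / "metadata.csv",
        "events": out / "events.csv",
    }
    pd.DataFrame(
        rec_rows, columns=["session_id", "patient_id", "time_min", "measurement", "value"]
    ).to_csv(paths["sessions"], index=False)
    pd.DataFrame(
        meta_rows,
        columns=[
            "session_id",
            "patient_id",
            "age",
            "gender",
            "vintage_years",
            "predialytic_weight",
            "scheduled_length_min",
        ],
    ).to_csv(paths["metadata"], index=False)
    pd.DataFrame(ev_rows, columns=["session_id", "time_min", "event_type"]).to_csv(
        paths["events"], index=False
    )
    return paths
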