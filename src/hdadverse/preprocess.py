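"""Session cleaning, LOCF value assignment, truncation and cutoff rules.

Cleaning removes session-start artifacts and dialysis interruptions:

* the first data point of every measurement is dropped when the blood flow
  rate differs between the first two blood-flow records (setup artifact);
* every record taken while the contemporaneous blood flow rate (by last
  observation carried forward) is <= 0 is dropped;
* a maximal contiguous run of such zero-flow record times counts as one
  interruption, and a session interrupted more than once is rejected;
* a surviving session must keep at least ``MIN_RECORDS`` records for every
  measurement so that slope / R^2 / derivative features remain defined.

Truncation rules implement the analysis endpoints: features for a session
with adverse events use only data strictly before the first event; cutoff
variants stop collection 0/5/10/15/20/60 minutes before that anchor (or
before session end for event-free sessions); event-free sessions can also be
truncated to fixed or uniformly drawn endpoints to probe session-length
effects.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .session_model import (
    BLOOD_FLOW_RATE,
    MACHINE_IDS,
    MEASUREMENTS,
    HDSession,
    MeasurementRecord,
    SessionValidationError,
)

__all__ = [
    "MIN_RECORDS",
    "CleanReport",
    "clean_session",
    "clean_cohort",
    "value_at",
    "record_floor_ok",
    "truncate_before_first_event",
    "apply_cutoff",
    "truncate_negative",
]

#: minimum surviving records per measurement for downstream features
MIN_RECORDS = 3


@dataclass(slots=True)
class CleanReport:
    session_id: str
    dropped_first_point: bool = False
    n_points_dropped_nonpositive_flow: int = 0
    n_interruptions: int = 0
    rejected: bool = False
    reason: str | None = None  # "multiple_interruptions" | "too_few_records"


def _bfr_locf(bfr_t: np.ndarray, bfr_v: np.ndarray, t: float) -> float:
    """Blood flow rate at time t by LOCF; before the first record, its value."""
    i = bisect.bisect_right(bfr_t.tolist(), t) - 1
    return float(bfr_v[max(i, 0)])


def clean_session(session: HDSession) -> tuple[HDSession | None, CleanReport]:
    """Apply the cleaning rules; returns (cleaned session or None, report)."""
    report = CleanReport(session_id=session.session_id)
    if not session.records:
        raise SessionValidationError(f"session {session.session_id} is empty")

    records = list(session.records)
    bfr_t, bfr_v = session.series(BLOOD_FLOW_RATE)
    if bfr_t.size < 2:
        report.rejected = True
        report.reason = "too_few_records"
        return None, report

    # Session-start artifact: drop all measurements' first point when the
    # blood flow rate changes between the first two blood-flow records.
    if bfr_v[0] != bfr_v[1]:
        t_first = records[0].time_min
        records = [r for r in records if r.time_min != t_first]
        report.dropped_first_point = True
        keep = bfr_t != t_first
        bfr_t, bfr_v = bfr_t[keep], bfr_v[keep]
        if bfr_t.size == 0:
            report.rejected = True
            report.reason = "too_few_records"
            return None, report

    # Zero-flow removal.  Machine records are dropped whenever LOCF blood
    # flow is <= 0; staff vitals only when they fall inside such a run.
    zero_runs: list[tuple[float, float]] = []  # [start, resume)
    run_start: float | None = None
    for t in sorted({r.time_min for r in records if r.measurement_id in MACHINE_IDS}):
        flow = _bfr_locf(bfr_t, bfr_v, t)
        if flow <= 0:
            if run_start is None:
                run_start = t
        else:
            if run_start is not None:
                zero_runs.append((run_start, t))
                run_start = None
    if run_start is not None:
        zero_runs.append((run_start, np.inf))
    report.n_interruptions = len(zero_runs)

    def in_run(t: float) -> bool:
        return any(a <= t < b for a, b in zero_runs)

    kept: list[MeasurementRecord] = []
    for r in records:
        if r.measurement_id in MACHINE_IDS:
            drop = _bfr_locf(bfr_t, bfr_v, r.time_min) <= 0
        else:
            drop = in_run(r.time_min)
        if drop:
            report.n_points_dropped_nonpositive_flow += 1
        else:
            kept.append(r)

    if report.n_interruptions >= 2:
        report.rejected = True
        report.reason = "multiple_interruptions"
        return None, report

    cleaned = session.with_records(kept)
    if not record_floor_ok(cleaned):
        report.rejected = True
        report.reason = "too_few_records"
        return None, report
    return cleaned, report


def clean_cohort(
    sessions: Iterable[HDSession],
) -> tuple[list[HDSession], list[CleanReport]]:
    kept, reports = [], []
    for s in sessions:
        c, rep = clean_session(s)
        reports.append(rep)
        if c is not None:
            kept.append(c)
    return kept, reports


def record_floor_ok(session: HDSession, min_records: int = MIN_RECORDS) -> bool:
    """True when every measurement keeps at least ``min_records`` records."""
    counts = dict.fromkeys(MEASUREMENTS, 0)
    seen_t: dict[int, float] = {}
    for r in session.records:
        # duplicate timestamps collapse to one point, mirror series()
        if seen_t.get(r.measurement_id) == r.time_min:
            continue
        seen_t[r.measurement_id] = r.time_min
        counts[r.measurement_id] += 1
    return all(c >= min_records for c in counts.values())


def value_at(session: HDSession, measurement_id: int, t: float) -> float:
    """Last observation carried forward: most recent value at or before t."""
    times, values = session.series(measurement_id)
    if times.size == 0:
        raise SessionValidationError(
            f"session {session.session_id} has no records for measurement {measurement_id}"
        )
    if t < times[0]:
        raise ValueError(
            f"t={t} precedes the first record ({times[0]}) of measurement {measurement_id}"
        )
    i = int(np.searchsorted(times, t, side="right")) - 1
    return float(values[i])


def truncate_before_first_event(
    session: HDSession, in_scope_types: set[str] | None = None
) -> HDSession:
    """Keep only records strictly before the first (in-scope) event.

    The events list is retained for labeling.  No-op with a warning when the
    session has no in-scope event.
    """
    anchor = _first_event_time(session, in_scope_types)
    if anchor is None:
        warnings.warn(
            f"session {session.session_id} has no in-scope event; truncation is a no-op",
            stacklevel=2,
        )
        return session
    return session.with_records(r for r in session.records if r.time_min < anchor)


def _first_event_time(session: HDSession, in_scope_types: set[str] | None) -> float | None:
    for e in session.events:
        if in_scope_types is None or e.event_type in in_scope_types:
            return e.time_min
    return None


def apply_cutoff(
    session: HDSession,
    minutes_before: float,
    in_scope_types: set[str] | None = None,
) -> HDSession:
    """Stop feature collection ``minutes_before`` minutes before the anchor.

    Anchor is the first (in-scope) event time for event sessions, otherwise
    the last record time.  At 0 minutes on an event session this reproduces
    :func:`truncate_before_first_event` exactly (strictly-before semantics);
    at 0 minutes on an event-free session the session is unchanged.
    """
    if minutes_before < 0:
        raise ValueError("minutes_before must be >= 0")
    anchor = _first_event_time(session, in_scope_types)
    has_event = anchor is not None
    if anchor is None:
        anchor = session.last_record_time
    threshold = anchor - minutes_before
    if has_event and minutes_before == 0:
        keep = lambda r: r.time_min < threshold  # noqa: E731
    else:
        keep = lambda r: r.time_min <= threshold  # noqa: E731
    return session.with_records(r for r in session.records if keep(r))


def truncate_negative(
    session: HDSession,
    mode: str,
    window_or_point: float | tuple[float, float],
    rng: np.random.Generator | int | None = None,
) -> HDSession:
    """Truncate an event-free session to an assigned endpoint T_end.

    ``mode="fixed"`` cuts at the stated point (minutes); ``mode="uniform"``
    draws T_end ~ U(window) per session.  Records after T_end are removed and
    an LOCF endpoint record at T_end is appended for every measurement whose
    first record precedes T_end, so the endpoint is defined the same way as
    the value at an arbitrary time T_p.
    """
    if session.events:
        raise SessionValidationError(
            f"truncate_negative applied to event session {session.session_id}"
        )
    if mode == "fixed":
        t_end = float(window_or_point)  # type: ignore[arg-type]
    elif mode == "uniform":
        lo, hi = window_or_point  # type: ignore[misc]
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        t_end = float(gen.uniform(lo, hi))
    else:
        raise ValueError(f"unknown truncation mode {mode!r}")

    kept = [r for r in session.records if r.time_min <= t_end]
    have_at_end = {r.measurement_id for r in kept if r.time_min == t_end}
    endpoint: list[MeasurementRecord] = []
    for mid in MEASUREMENTS:
        if mid in have_at_end:
            continue
        times, values = session.series(mid)
        if times.size and times[0] <= t_end:
            i = int(np.searchsorted(times, t_end, side="right")) - 1
            endpoint.append(MeasurementRecord(mid, t_end, float(values[i])))
    return session.with_records(kept + endpoint)
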