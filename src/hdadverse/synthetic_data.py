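"""Synthetic hemodialysis cohorts with a known event-generating mechanism.

The generator reproduces the statistical structure the downstream analysis
assumes, not physiology: ~4-hour sessions; machine channels (blood flow,
venous and transmembranous pressure, ultrafiltration rate and cumulative
volume) logged only when either pressure has moved by more than a trigger
threshold since the last record, so inter-record gaps are irregular; staff
vitals (systolic/diastolic/pulse pressure, pulse rate) every 30-60 minutes;
a nondecreasing cumulative ultrafiltration volume that is the exact integral
of the stepwise rate program; and a configurable logistic event hazard on
latent per-session quantities (drift slopes, mean ultrafiltration rate) so
that signal recovery is testable against ground truth.

Latent trajectories follow patient baseline + session-level linear drift +
Ornstein-Uhlenbeck jitter, discretized by the trigger rule.  Events are
per-session Bernoulli draws from the logistic hazard; the event time is then
drawn from a triangular law biased toward the second half of the session,
because the analysis only ever uses the first event's time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .session_model import (
    EVENT_EPISODES,
    MEASUREMENT_IDS,
    AdverseEvent,
    HDSession,
    MeasurementRecord,
    StaticFields,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_interruptions",
]

_SBP = MEASUREMENT_IDS["systolic_bp"]
_DBP = MEASUREMENT_IDS["diastolic_bp"]
_PP = MEASUREMENT_IDS["pulse_pressure"]
_PR = MEASUREMENT_IDS["pulse_rate"]
_BFR = MEASUREMENT_IDS["blood_flow_rate"]
_VP = MEASUREMENT_IDS["venous_pressure"]
_TMP = MEASUREMENT_IDS["transmembranous_pressure"]
_UFR = MEASUREMENT_IDS["uf_rate"]
_UFV = MEASUREMENT_IDS["uf_volume"]

#: latent quantities usable as hazard covariates, by measurement name
SIGNAL_QUANTITIES = {
    "systolic_bp": "session drift slope (mmHg/min)",
    "diastolic_bp": "session drift slope (mmHg/min)",
    "pulse_rate": "session drift slope (bpm/min)",
    "venous_pressure": "session drift slope (mmHg/min)",
    "transmembranous_pressure": "session drift slope (mmHg/min)",
    "uf_rate": "session mean programmed rate (mL/h)",
    "blood_flow_rate": "session blood-flow setting (mL/min)",
}


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Cohort-level knobs; the seed fully determines the output."""

    n_patients: int = 108
    sessions_per_patient: tuple[int, int] = (39, 40)
    seed: int = 0
    event_session_fraction: float = 0.096
    #: (measurement name, effect direction +-1, effect size on the logit per SD)
    signal_features: tuple[tuple[str, float, float], ...] = (
        ("systolic_bp", -1.0, 1.2),
        ("uf_rate", 1.0, 0.8),
    )
    vitals_interval_min: tuple[float, float] = (30.0, 60.0)
    machine_trigger_sd: float = 5.0
    second_half_event_bias: float = 0.8
    scheduled_length_min: float = 240.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.sessions_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("sessions_per_patient must be a nondecreasing pair >= 1")
        if not 0.0 <= self.event_session_fraction <= 1.0:
            raise ValueError("event_session_fraction must be in [0, 1]")
        if not 0.0 <= self.second_half_event_bias <= 1.0:
            raise ValueError("second_half_event_bias must be in [0, 1]")
        for name, _, _ in self.signal_features:
            if name not in SIGNAL_QUANTITIES:
                raise ValueError(f"no hazard covariate for measurement {name!r}")


@dataclass(slots=True)
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    config: SimulationConfig
    intercept: float
    signal_values: dict[str, dict[str, float]]   # session_id -> covariate values
    event_prob: dict[str, float]                 # session_id -> hazard probability
    latent_drifts: dict[str, dict[str, float]]   # session_id -> drift slopes
    interruptions: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                "n_patients": self.config.n_patients,
                "sessions_per_patient": list(self.config.sessions_per_patient),
                "seed": self.config.seed,
                "event_session_fraction": self.config.event_session_fraction,
                "signal_features": [list(s) for s in self.config.signal_features],
                "vitals_interval_min": list(self.config.vitals_interval_min),
                "machine_trigger_sd": self.config.machine_trigger_sd,
                "second_half_event_bias": self.config.second_half_event_bias,
                "scheduled_length_min": self.config.scheduled_length_min,
            },
            "intercept": self.intercept,
            "signal_values": self.signal_values,
            "event_prob": self.event_prob,
            "latent_drifts": self.latent_drifts,
            "interruptions": self.interruptions,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(slots=True)
class _LatentSession:
    session_id: str
    patient_id: str
    static: StaticFields
    records: list[MeasurementRecord]
    drifts: dict[str, float]
    signal_raw: dict[str, float]


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, lo: float) -> float:
    while True:
        x = rng.normal(mu, sd)
        if x > lo:
            return float(x)


def _simulate_session_records(
    rng: np.random.Generator, cfg: SimulationConfig, base: dict[str, float]
) -> tuple[list[MeasurementRecord], dict[str, float], dict[str, float]]:
    length = cfg.scheduled_length_min
    grid = np.arange(0.0, length + 1.0)

    drifts = {
        "systolic_bp": rng.normal(-0.02, 0.04),
        "diastolic_bp": None,  # tied to SBP below
        "pulse_rate": rng.normal(0.01, 0.02),
        "venous_pressure": rng.normal(0.02, 0.04),
        "transmembranous_pressure": rng.normal(0.03, 0.05),
    }
    drifts["diastolic_bp"] = 0.6 * drifts["systolic_bp"] + rng.normal(0.0, 0.015)

    # ultrafiltration program: stepwise rate, exact cumulative integral
    target = float(np.clip(rng.normal(2400.0, 500.0), 500.0, 4000.0))
    base_rate = target / (length / 60.0)
    n_changes = int(min(rng.poisson(1.2), 4))
    change_t = np.sort(rng.uniform(20.0, length - 20.0, size=n_changes))
    seg_start = np.concatenate(([0.0], change_t))
    seg_rate = base_rate * np.concatenate(
        ([1.0], rng.uniform(0.75, 1.3, size=n_changes))
    )

    def rate_at(t: float) -> float:
        return float(seg_rate[np.searchsorted(seg_start, t, side="right") - 1])

    def volume_at(t: float) -> float:
        ends = np.concatenate((seg_start[1:], [length]))
        lo = seg_start
        dur = np.clip(np.minimum(ends, t) - lo, 0.0, None)
        return float(np.sum(seg_rate * dur / 60.0))

    # Ornstein-Uhlenbeck jitter on the pressure channels (dt = 1 min)
    def ou(sd_step: float, theta: float = 0.08) -> np.ndarray:
        x = np.empty(grid.size)
        x[0] = 0.0
        noise = rng.normal(0.0, sd_step, size=grid.size - 1)
        for i in range(1, grid.size):
            x[i] = x[i - 1] - theta * x[i - 1] + noise[i - 1]
        return x

    vp_lat = base["vp"] + drifts["venous_pressure"] * grid + ou(2.2)
    tmp_lat = base["tmp"] + drifts["transmembranous_pressure"] * grid + ou(2.2)

    # machine-triggered record times: a new record when either pressure has
    # moved by more than the trigger threshold since the last record
    trig = cfg.machine_trigger_sd
    times = [0]
    vp_ref, tmp_ref = vp_lat[0], tmp_lat[0]
    for i in range(1, grid.size):
        if abs(vp_lat[i] - vp_ref) > trig or abs(tmp_lat[i] - tmp_ref) > trig:
            times.append(i)
            vp_ref, tmp_ref = vp_lat[i], tmp_lat[i]
    if times[-1] != grid.size - 1:
        times.append(grid.size - 1)  # end-of-session snapshot

    bfr_setting = base["bfr"]
    ramp = rng.random() < 0.5  # setup artifact: lower blood flow on the first record
    bfr_first = round(bfr_setting - rng.uniform(40.0, 90.0)) if ramp else bfr_setting

    records: list[MeasurementRecord] = []
    for i in times:
        t = float(grid[i])
        bfr = bfr_first if i == 0 else bfr_setting
        records.append(MeasurementRecord(_BFR, t, float(bfr)))
        records.append(MeasurementRecord(_VP, t, round(float(vp_lat[i]), 1)))
        records.append(MeasurementRecord(_TMP, t, round(float(tmp_lat[i]), 1)))
        records.append(MeasurementRecord(_UFR, t, round(rate_at(t), 1)))
        records.append(MeasurementRecord(_UFV, t, round(volume_at(t), 1)))

    # staff vitals every 30-60 minutes
    lo, hi = cfg.vitals_interval_min
    t = 0.0
    while t <= length:
        sbp = base["sbp"] + drifts["systolic_bp"] * t + rng.normal(0.0, 6.0)
        dbp = base["dbp"] + drifts["diastolic_bp"] * t + rng.normal(0.0, 4.0)
        dbp = min(dbp, sbp - 10.0)
        pr = base["pr"] + drifts["pulse_rate"] * t + rng.normal(0.0, 3.0)
        records.append(MeasurementRecord(_SBP, t, round(sbp)))
        records.append(MeasurementRecord(_DBP, t, round(dbp)))
        records.append(MeasurementRecord(_PP, t, round(sbp) - round(dbp)))
        records.append(MeasurementRecord(_PR, t, round(pr)))
        t += float(rng.uniform(lo, hi))

    mean_rate = volume_at(length) / (length / 60.0)
    signal_raw = {
        "systolic_bp": drifts["systolic_bp"],
        "diastolic_bp": drifts["diastolic_bp"],
        "pulse_rate": drifts["pulse_rate"],
        "venous_pressure": drifts["venous_pressure"],
        "transmembranous_pressure": drifts["transmembranous_pressure"],
        "uf_rate": mean_rate,
        "blood_flow_rate": float(bfr_setting),
    }
    return records, drifts, signal_raw


def _calibrate_intercept(logit_terms: np.ndarray, fraction: float) -> float:
    """Bisection for the intercept giving mean sigmoid == fraction."""
    if fraction <= 0.0:
        return -np.inf
    if fraction >= 1.0:
        return np.inf
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + logit_terms)))) < fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[HDSession], GroundTruth]:
    """Generate a deterministic cohort of sessions plus its ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_cohort, rng_events = (np.random.default_rng(c) for c in ss.spawn(2))

    latents: list[_LatentSession] = []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        static = StaticFields(
            age=round(_truncated_normal(rng_cohort, 64.0, 12.0, 18.0), 1),
            gender="male" if rng_cohort.random() < 0.56 else "female",
            vintage_years=round(float(rng_cohort.gamma(2.0, 3.85)), 1),
            predialytic_weight=round(_truncated_normal(rng_cohort, 62.0, 12.0, 35.0), 1),
        )
        base = {
            "sbp": float(np.clip(rng_cohort.normal(140.0, 15.0), 95.0, 200.0)),
            "pr": float(rng_cohort.normal(75.0, 8.0)),
            "vp": float(rng_cohort.normal(120.0, 15.0)),
            "tmp": float(np.clip(rng_cohort.normal(110.0, 25.0), 40.0, 250.0)),
            "bfr": float(np.round(np.clip(rng_cohort.normal(250.0, 25.0), 150.0, 350.0) / 5.0) * 5.0),
        }
        base["dbp"] = base["sbp"] - float(np.clip(rng_cohort.normal(55.0, 12.0), 25.0, 90.0))
        n_sessions = int(rng_cohort.integers(config.sessions_per_patient[0],
                                             config.sessions_per_patient[1] + 1))
        for s in range(n_sessions):
            sid = f"{pid}-S{s:02d}"
            records, drifts, signal_raw = _simulate_session_records(rng_cohort, config, base)
            latents.append(_LatentSession(sid, pid, static, records, drifts, signal_raw))

    # logistic hazard on cohort-standardized covariates
    n = len(latents)
    logit_terms = np.zeros(n)
    for name, direction, size in config.signal_features:
        vals = np.array([ls.signal_raw[name] for ls in latents])
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
        logit_terms += direction * size * z
    intercept = _calibrate_intercept(logit_terms, config.event_session_fraction)
    with np.errstate(over="ignore"):
        probs = 1.0 / (1.0 + np.exp(-(intercept + logit_terms)))

    event_types = list(EVENT_EPISODES)
    type_p = np.array([EVENT_EPISODES[t] for t in event_types], dtype=float)
    type_p /= type_p.sum()

    sessions: list[HDSession] = []
    truth = GroundTruth(
        config=config, intercept=float(intercept),
        signal_values={}, event_prob={}, latent_drifts={},
    )
    length = config.scheduled_length_min
    for ls, p_event in zip(latents, probs):
        events: list[AdverseEvent] = []
        if rng_events.random() < p_event:
            if rng_events.random() < config.second_half_event_bias:
                lo, hi = length / 2.0, length
            else:
                lo, hi = 70.0, length / 2.0
            # triangular with mode at the window's right edge: later is likelier
            t_event = lo + (hi - lo) * float(np.sqrt(rng_events.random()))
            t_event = min(round(t_event, 1), length)
            events.append(
                AdverseEvent(str(rng_events.choice(event_types, p=type_p)), t_event)
            )
            if rng_events.random() < 0.25 and t_event < length - 10.0:
                t2 = round(float(rng_events.uniform(t_event + 5.0, length)), 1)
                events.append(
                    AdverseEvent(str(rng_events.choice(event_types, p=type_p)), t2)
                )
        sessions.append(
            HDSession(
                session_id=ls.session_id,
                patient_id=ls.patient_id,
                records=ls.records,
                static=ls.static,
                events=events,
                scheduled_length_min=length,
            )
        )
        truth.signal_values[ls.session_id] = dict(ls.signal_raw)
        truth.event_prob[ls.session_id] = float(p_event)
        truth.latent_drifts[ls.session_id] = dict(ls.drifts)
    return sessions, truth


def simulate_interruptions(
    sessions: Sequence[HDSession],
    fraction_single: float,
    fraction_multiple: float,
    seed: int,
    ground_truth: GroundTruth | None = None,
) -> tuple[list[HDSession], dict[str, int]]:
    """Inject zero-blood-flow intervals for exercising the cleaning rules.

    ``fraction_single`` of sessions get exactly one interruption,
    ``fraction_multiple`` get two (so cleaning must reject them).  Returns
    (new session list, {session_id: injected interruption count}).
    """
    if fraction_single + fraction_multiple > 1.0:
        raise ValueError("interruption fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n = len(sessions)
    n_single = int(round(fraction_single * n))
    n_multi = int(round(fraction_multiple * n))
    chosen = rng.choice(n, size=n_single + n_multi, replace=False)
    plan = {int(i): 1 for i in chosen[:n_single]}
    plan.update({int(i): 2 for i in chosen[n_single:]})

    out: list[HDSession] = []
    counts: dict[str, int] = {}
    for i, s in enumerate(sessions):
        k = plan.get(i, 0)
        counts[s.session_id] = k
        if k == 0:
            out.append(s)
            continue
        bfr_t, bfr_v = s.series(_BFR)
        resume_value = float(bfr_v[-1])
        # non-integer start times avoid colliding with machine timestamps
        intervals: list[tuple[float, float]] = []
        while len(intervals) < k:
            t0 = float(rng.uniform(30.0, 200.0)) + 0.5
            dur = float(rng.uniform(5.0, 12.0))
            if all(t0 + dur + 5.0 < a or b + 5.0 < t0 for a, b in intervals):
                intervals.append((t0, t0 + dur))
        extra = []
        for a, b in intervals:
            extra.append(MeasurementRecord(_BFR, a, 0.0))
            extra.append(MeasurementRecord(_BFR, b, resume_value))
        out.append(s.with_records(list(s.records) + extra))
    if ground_truth is not None:
        ground_truth.interruptions = dict(counts)
    return out, counts
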