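import numpy as np
import pytest

from hdadverse.preprocess import clean_cohort
from hdadverse.session_model import (
    MEASUREMENT_IDS,
    AdverseEvent,
    HDSession,
    MeasurementRecord,
    StaticFields,
)
from hdadverse.synthetic_data import SimulationConfig, simulate_cohort

DEFAULT_STATIC = StaticFields(age=60.0, gender="male", vintage_years=5.0,
                              predialytic_weight=62.0)


def make_session(
    session_id="S1",
    patient_id="P1",
    bfr=None,
    times=None,
    events=(),
    static=DEFAULT_STATIC,
    **series_overrides,
):
    """Hand-built session with full 9-measurement coverage.

    ``times`` are the machine record times (default 0,30,...,240); ``bfr``
    and any ``series_overrides`` (keyed by measurement name) give values at
    those times; unspecified machine series vary linearly, vitals are placed
    at 0/60/120/180/240.
    """
    if times is None:
        times = list(np.arange(0.0, 241.0, 30.0))
    n = len(times)
    defaults = {
        "blood_flow_rate": [250.0] * n if bfr is None else list(bfr),
        "venous_pressure": [120.0 + 0.1 * t for t in times],
        "transmembranous_pressure": [110.0 + 0.2 * t for t in times],
        "uf_rate": [600.0] * n,
        "uf_volume": [10.0 * t for t in times],
    }
    defaults.update(series_overrides)
    records = []
    for name in ("blood_flow_rate", "venous_pressure", "transmembranous_pressure",
                 "uf_rate", "uf_volume"):
        vals = defaults[name]
        assert len(vals) == n
        for t, v in zip(times, vals):
            records.append(MeasurementRecord(MEASUREMENT_IDS[name], float(t), float(v)))
    vit_times = defaults.get("vitals_times", [0.0, 60.0, 120.0, 180.0, 240.0])
    for name, base, slope in (
        ("systolic_bp", 140.0, -0.05),
        ("diastolic_bp", 80.0, -0.02),
        ("pulse_pressure", 60.0, -0.03),
        ("pulse_rate", 75.0, 0.01),
    ):
        vals = defaults.get(name, [base + slope * t for t in vit_times])
        for t, v in zip(vit_times, vals):
            records.append(MeasurementRecord(MEASUREMENT_IDS[name], float(t), float(v)))
    evs = [AdverseEvent(e[0], e[1]) if isinstance(e, tuple) else e for e in events]
    return HDSession(session_id=session_id, patient_id=patient_id, records=records,
                     static=static, events=evs)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(n_patients=12, sessions_per_patient=(8, 8), seed=101,
                           event_session_fraction=0.12)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cleaned_small(small_cohort):
    sessions, _truth = small_cohort
    cleaned, reports = clean_cohort(sessions)
    return cleaned, reports
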