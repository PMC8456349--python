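"""The 84-feature registry and extraction engine.

Each cleaned (and possibly truncated) session is summarized into exactly 84
features: per-measurement linear summaries (mean, standard deviation of the
mean i.e. the standard error, coefficient of variation, OLS slope and R^2 of
value on time, max, min), finite-difference first/second derivative
summaries of the pressure channels, ultrafiltration-rate change statistics,
and the four demographic fields.

The exact per-index composition is a documented canonical ordering: a small
set of indices is pinned by the analysis this package reproduces (the
ultrafiltration block occupies indices 70-83 with the rate-change count at
76, the mean rate change at 77, the maximal cumulative volume at 78 and the
volume slope at 82; the venous-pressure derivative block sits at 47-52; the
"top 21" index set is tagged as a group), and the remaining slots follow a
fixed order shipped here and exportable to ``registry.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .session_model import MEASUREMENT_IDS, MEASUREMENTS, HDSession
from .preprocess import MIN_RECORDS

__all__ = [
    "FeatureSpec",
    "FeatureRegistry",
    "FeatureExtractionError",
    "default_registry",
    "load_registry",
    "save_registry",
    "linear_summary",
    "regression_summary",
    "derivative_summary",
    "uf_rate_changes",
    "extract_features",
    "extract_matrix",
    "feature_subset",
    "subset_indices",
]

N_FEATURES = 84

LINEAR_KINDS = ("mean", "sd_of_mean", "cv", "slope", "r_squared", "max", "min")
DERIV_KINDS = ("d1_max", "d1_min", "d1_mean", "d2_max", "d2_min", "d2_mean")
CHANGE_KINDS = ("count_of_changes", "mean_of_changes")
STATIC_FIELDS = ("age", "gender", "vintage_years", "predialytic_weight")


class FeatureExtractionError(ValueError):
    """Raised when a session cannot supply a well-defined feature vector."""


@dataclass(frozen=True, slots=True)
class FeatureSpec:
    index: int          # 1-based registry index
    name: str
    source: str         # measurement name or static field name
    kind: str
    groups: frozenset[str]


# (index, name, source, kind, groups) — canonical 84-entry ordering.
_G = lambda *gs: frozenset(gs)  # noqa: E731
_TABLE: list[tuple[int, str, str, str, frozenset[str]]] = [
    (1, "gender", "gender", "static", _G("demographic")),
    (2, "age", "age", "static", _G("demographic", "top21")),
    (3, "vintage_years", "vintage_years", "static", _G("demographic")),
    (4, "predialytic_weight", "predialytic_weight", "static", _G("demographic")),
    (5, "tmp_max", "transmembranous_pressure", "max", _G("top21")),
    (6, "sbp_min", "systolic_bp", "min", _G("bp_related", "top21")),
    (7, "sbp_max", "systolic_bp", "max", _G("bp_related")),
    (8, "dbp_min", "diastolic_bp", "min", _G("bp_related", "top21")),
    (9, "dbp_max", "diastolic_bp", "max", _G("bp_related")),
    (10, "pp_max", "pulse_pressure", "max", _G("bp_related")),
    (11, "pp_min", "pulse_pressure", "min", _G("bp_related", "top21")),
    (12, "pr_max", "pulse_rate", "max", _G()),
    (13, "pr_min", "pulse_rate", "min", _G()),
    (14, "bfr_min", "blood_flow_rate", "min", _G("top21")),
    (15, "bfr_max", "blood_flow_rate", "max", _G()),
    (16, "vp_max", "venous_pressure", "max", _G()),
    (17, "sbp_mean", "systolic_bp", "mean", _G("bp_related", "top21")),
    (18, "dbp_mean", "diastolic_bp", "mean", _G("bp_related")),
    (19, "pp_mean", "pulse_pressure", "mean", _G("bp_related")),
    (20, "vp_mean", "venous_pressure", "mean", _G("top21")),
    (21, "tmp_mean", "transmembranous_pressure", "mean", _G("top21")),
    (22, "pr_mean", "pulse_rate", "mean", _G()),
    (23, "bfr_mean", "blood_flow_rate", "mean", _G()),
    (24, "vp_min", "venous_pressure", "min", _G()),
    (25, "tmp_min", "transmembranous_pressure", "min", _G()),
    (26, "sbp_slope", "systolic_bp", "slope", _G("bp_related", "top21")),
    (27, "sbp_r2", "systolic_bp", "r_squared", _G("bp_related")),
    (28, "dbp_r2", "diastolic_bp", "r_squared", _G("bp_related")),
    (29, "dbp_slope", "diastolic_bp", "slope", _G("bp_related", "top21")),
    (30, "pr_r2", "pulse_rate", "r_squared", _G()),
    (31, "pp_slope", "pulse_pressure", "slope", _G("bp_related", "top21")),
    (32, "vp_slope", "venous_pressure", "slope", _G()),
    (33, "vp_r2", "venous_pressure", "r_squared", _G()),
    (34, "tmp_slope", "transmembranous_pressure", "slope", _G()),
    (35, "tmp_r2", "transmembranous_pressure", "r_squared", _G()),
    (36, "pr_slope", "pulse_rate", "slope", _G("top21")),
    (37, "bfr_slope", "blood_flow_rate", "slope", _G()),
    (38, "bfr_r2", "blood_flow_rate", "r_squared", _G()),
    (39, "sbp_sem", "systolic_bp", "sd_of_mean", _G("bp_related")),
    (40, "sbp_cv", "systolic_bp", "cv", _G("bp_related")),
    (41, "dbp_sem", "diastolic_bp", "sd_of_mean", _G("bp_related")),
    (42, "dbp_cv", "diastolic_bp", "cv", _G("bp_related")),
    (43, "pp_sem", "pulse_pressure", "sd_of_mean", _G("bp_related")),
    (44, "pp_cv", "pulse_pressure", "cv", _G("bp_related")),
    (45, "pr_sem", "pulse_rate", "sd_of_mean", _G()),
    (46, "pr_cv", "pulse_rate", "cv", _G()),
    (47, "vp_d1_max", "venous_pressure", "d1_max", _G("derivative", "top21")),
    (48, "vp_d1_min", "venous_pressure", "d1_min", _G("derivative", "top21")),
    (49, "vp_d1_mean", "venous_pressure", "d1_mean", _G("derivative", "top21")),
    (50, "vp_d2_max", "venous_pressure", "d2_max", _G("derivative", "top21")),
    (51, "vp_d2_min", "venous_pressure", "d2_min", _G("derivative", "top21")),
    (52, "vp_d2_mean", "venous_pressure", "d2_mean", _G("derivative", "top21")),
    (53, "tmp_d1_max", "transmembranous_pressure", "d1_max", _G("derivative")),
    (54, "tmp_d1_min", "transmembranous_pressure", "d1_min", _G("derivative")),
    (55, "tmp_d1_mean", "transmembranous_pressure", "d1_mean", _G("derivative")),
    (56, "vp_sem", "venous_pressure", "sd_of_mean", _G()),
    (57, "bfr_sem", "blood_flow_rate", "sd_of_mean", _G("top21")),
    (58, "vp_cv", "venous_pressure", "cv", _G()),
    (59, "pp_r2", "pulse_pressure", "r_squared", _G("bp_related", "top21")),
    (60, "tmp_d2_max", "transmembranous_pressure", "d2_max", _G("derivative")),
    (61, "tmp_d2_min", "transmembranous_pressure", "d2_min", _G("derivative")),
    (62, "tmp_d2_mean", "transmembranous_pressure", "d2_mean", _G("derivative")),
    (63, "tmp_sem", "transmembranous_pressure", "sd_of_mean", _G()),
    (64, "tmp_cv", "transmembranous_pressure", "cv", _G()),
    (65, "bfr_cv", "blood_flow_rate", "cv", _G()),
    (66, "pp_d1_max", "pulse_pressure", "d1_max", _G("bp_related", "derivative")),
    (67, "pp_d1_min", "pulse_pressure", "d1_min", _G("bp_related", "derivative")),
    (68, "pp_d1_mean", "pulse_pressure", "d1_mean", _G("bp_related", "derivative")),
    (69, "bfr_d1_min", "blood_flow_rate", "d1_min", _G("derivative")),
    (70, "ufr_mean", "uf_rate", "mean", _G("uf_rate")),
    (71, "ufr_sem", "uf_rate", "sd_of_mean", _G("uf_rate")),
    (72, "ufr_cv", "uf_rate", "cv", _G("uf_rate")),
    (73, "ufr_slope", "uf_rate", "slope", _G("uf_rate")),
    (74, "ufr_max", "uf_rate", "max", _G("uf_rate")),
    (75, "ufr_min", "uf_rate", "min", _G("uf_rate")),
    (76, "ufr_n_changes", "uf_rate", "count_of_changes", _G("uf_rate")),
    (77, "ufr_mean_change", "uf_rate", "mean_of_changes", _G("uf_rate")),
    (78, "ufv_max", "uf_volume", "max", _G("uf_volume")),
    (79, "ufv_mean", "uf_volume", "mean", _G("uf_volume")),
    (80, "ufv_sem", "uf_volume", "sd_of_mean", _G("uf_volume")),
    (81, "ufv_cv", "uf_volume", "cv", _G("uf_volume")),
    (82, "ufv_slope", "uf_volume", "slope", _G("uf_volume")),
    (83, "ufv_min", "uf_volume", "min", _G("uf_volume")),
    (84, "bfr_d1_mean", "blood_flow_rate", "d1_mean", _G("derivative")),
]


class FeatureRegistry:
    """Ordered catalogue of the 84 features with index, source and groups."""

    def __init__(self, entries: Sequence[FeatureSpec]):
        entries = sorted(entries, key=lambda e: e.index)
        if [e.index for e in entries] != list(range(1, len(entries) + 1)):
            raise ValueError("registry indices must be 1..n without gaps")
        self.entries: tuple[FeatureSpec, ...] = tuple(entries)
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            raise ValueError("duplicate feature names in registry")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, index: int) -> FeatureSpec:
        return self.entries[index - 1]

    def by_name(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def group(self, tag: str) -> list[int]:
        """1-based indices carrying a group tag (see :func:`subset_indices`)."""
        return [e.index for e in self.entries if tag in e.groups]


def default_registry() -> FeatureRegistry:
    return FeatureRegistry(
        [FeatureSpec(i, n, s, k, g) for i, n, s, k, g in _TABLE]
    )


def save_registry(registry: FeatureRegistry, path: str | Path) -> None:
    data = [
        {
            "index": e.index,
            "name": e.name,
            "source": e.source,
            "kind": e.kind,
            "groups": sorted(e.groups),
        }
        for e in registry
    ]
    Path(path).write_text(yaml.safe_dump({"version": 1, "features": data}, sort_keys=False))


def load_registry(path: str | Path) -> FeatureRegistry:
    data = yaml.safe_load(Path(path).read_text())
    return FeatureRegistry(
        [
            FeatureSpec(
                index=int(d["index"]),
                name=d["name"],
                source=d["source"],
                kind=d["kind"],
                groups=frozenset(d.get("groups", [])),
            )
            for d in data["features"]
        ]
    )


# --------------------------------------------------------------------------
# summary primitives


def linear_summary(t: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Mean, standard error of the mean, CV, max and min of recorded values.

    ``sd_of_mean`` is the sample standard deviation (n-1 denominator) divided
    by sqrt(n); ``cv`` is sample SD over |mean| (0 for a constant series, NaN
    when the mean is exactly 0 with nonzero SD).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise FeatureExtractionError("linear_summary on an empty series")
    mean = float(np.mean(y))
    if y.size < 2:
        sd = 0.0
    else:
        sd = float(np.std(y, ddof=1))
    sem = sd / np.sqrt(y.size)
    if sd == 0.0:
        cv = 0.0
    elif mean == 0.0:
        cv = float("nan")
    else:
        cv = sd / abs(mean)
    return {
        "mean": mean,
        "sd_of_mean": float(sem),
        "cv": float(cv),
        "max": float(np.max(y)),
        "min": float(np.min(y)),
    }


def regression_summary(t: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """OLS slope of y on t (units per minute) and R^2 (squared Pearson r).

    A constant y has slope 0 and, by convention, R^2 = 0.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2 or np.ptp(t) == 0:
        raise FeatureExtractionError("regression needs >= 2 distinct time points")
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    syy = float(yc @ yc)
    sty = float(tc @ yc)
    slope = sty / stt
    r2 = 0.0 if syy == 0.0 else (sty * sty) / (stt * syy)
    return {"slope": slope, "r_squared": r2}


def derivative_summary(t: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Max/min/mean of first and second finite-difference derivatives.

    d1_k = (y_k - y_{k-1}) / (t_k - t_{k-1}) over consecutive records;
    d2_k = (d1_{k+1} - d1_k) / (t_{k+1} - t_k).  Requires >= 3 points with
    strictly increasing time (duplicate timestamps must be collapsed first).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise FeatureExtractionError("derivative summary needs >= 3 points")
    if np.any(np.diff(t) <= 0):
        raise FeatureExtractionError("time must be strictly increasing")
    d1 = np.diff(y) / np.diff(t)
    d2 = np.diff(d1) / np.diff(t)[:-1]
    return {
        "d1_max": float(d1.max()),
        "d1_min": float(d1.min()),
        "d1_mean": float(d1.mean()),
        "d2_max": float(d2.max()),
        "d2_min": float(d2.min()),
        "d2_mean": float(d2.mean()),
    }


def uf_rate_changes(t: np.ndarray, rate: np.ndarray) -> dict[str, float]:
    """Count and mean signed size of consecutive ultrafiltration-rate changes.

    A change is any pair of consecutive records with different rate values;
    the mean is over the signed differences of changed pairs (0 when the rate
    never changes).
    """
    rate = np.asarray(rate, dtype=float)
    if rate.size < 2:
        return {"count_of_changes": 0.0, "mean_of_changes": 0.0}
    diffs = np.diff(rate)
    changed = diffs[diffs != 0]
    return {
        "count_of_changes": float(changed.size),
        "mean_of_changes": float(changed.mean()) if changed.size else 0.0,
    }


# --------------------------------------------------------------------------
# extraction


def extract_features(
    session: HDSession, registry: FeatureRegistry | None = None
) -> np.ndarray:
    """Extract the registry's feature vector (length 84) from one session.

    The session must already be cleaned and truncated/cut off as intended;
    extraction sees only its surviving records.  Raises
    :class:`FeatureExtractionError` when any needed measurement has fewer
    than the record floor (reason ``too_few_records``).
    """
    registry = registry or default_registry()
    series = {name: session.series(mid) for mid, name in MEASUREMENTS.items()}

    needed = {e.source for e in registry if e.kind != "static"}
    for name in needed:
        if series[name][0].size < MIN_RECORDS:
            raise FeatureExtractionError(
                f"too_few_records: measurement {name!r} has "
                f"{series[name][0].size} < {MIN_RECORDS} records "
                f"in session {session.session_id}"
            )

    cache: dict[tuple[str, str], dict[str, float]] = {}

    def summaries(source: str, family: str) -> dict[str, float]:
        key = (source, family)
        if key not in cache:
            t, y = series[source]
            if family == "linear":
                cache[key] = linear_summary(t, y)
            elif family == "regression":
                cache[key] = regression_summary(t, y)
            elif family == "derivative":
                cache[key] = derivative_summary(t, y)
            elif family == "changes":
                cache[key] = uf_rate_changes(t, y)
        return cache[key]

    statics = {
        "age": session.static.age,
        "gender": float(session.static.gender_code),
        "vintage_years": session.static.vintage_years,
        "predialytic_weight": session.static.predialytic_weight,
    }

    out = np.empty(len(registry), dtype=float)
    for e in registry:
        if e.kind == "static":
            out[e.index - 1] = statics[e.source]
        elif e.kind in ("mean", "sd_of_mean", "cv", "max", "min"):
            out[e.index - 1] = summaries(e.source, "linear")[e.kind]
        elif e.kind in ("slope", "r_squared"):
            out[e.index - 1] = summaries(e.source, "regression")[e.kind]
        elif e.kind in DERIV_KINDS:
            out[e.index - 1] = summaries(e.source, "derivative")[e.kind]
        elif e.kind in CHANGE_KINDS:
            out[e.index - 1] = summaries(e.source, "changes")[e.kind]
        else:
            raise ValueError(f"unknown feature kind {e.kind!r}")
    return out


def extract_matrix(
    sessions: Iterable[HDSession], registry: FeatureRegistry | None = None
) -> tuple[np.ndarray, list[HDSession], list[tuple[str, str]]]:
    """Extract a (n_kept, 84) matrix; sessions failing the floor are excluded.

    Returns (matrix, kept sessions, [(session_id, reason), ...] exclusions).
    """
    registry = registry or default_registry()
    rows, kept, excluded = [], [], []
    for s in sessions:
        try:
            rows.append(extract_features(s, registry))
        except FeatureExtractionError as exc:
            excluded.append((s.session_id, str(exc)))
        else:
            kept.append(s)
    X = np.vstack(rows) if rows else np.empty((0, len(registry)))
    return X, kept, excluded


def subset_indices(registry: FeatureRegistry, group: str) -> list[int]:
    """Resolve a group name to sorted 1-based feature indices.

    Supported groups: any registry tag (``bp_related``, ``top21``,
    ``demographic``, ``derivative``, ``uf_rate``, ``uf_volume``), the union
    ``uf`` (rate + volume, 14 features), and complements spelled
    ``not_<group>`` (e.g. ``not_uf``, 70 features).
    """
    if group.startswith("not_"):
        inner = set(subset_indices(registry, group[len("not_"):]))
        return [e.index for e in registry if e.index not in inner]
    if group == "uf":
        return sorted(registry.group("uf_rate") + registry.group("uf_volume"))
    if group == "all":
        return [e.index for e in registry]
    idx = registry.group(group)
    if not idx:
        raise ValueError(f"unknown or empty feature group {group!r}")
    return sorted(idx)


def feature_subset(
    matrix: np.ndarray, registry: FeatureRegistry, group: str
) -> np.ndarray:
    """Column-filter a feature matrix by registry group."""
    idx = np.asarray(subset_indices(registry, group)) - 1
    return np.asarray(matrix)[:, idx]
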