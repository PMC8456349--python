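import numpy as np
import pytest

from hdadverse.features import (
    FeatureExtractionError,
    default_registry,
    derivative_summary,
    extract_features,
    extract_matrix,
    feature_subset,
    linear_summary,
    load_registry,
    regression_summary,
    save_registry,
    subset_indices,
    uf_rate_changes,
)
from hdadverse.preprocess import apply_cutoff, clean_cohort
from hdadverse.session_model import MEASUREMENT_IDS, MeasurementRecord

from conftest import make_session


# ---------------------------------------------------------------- registry


class TestRegistry:
    def test_exactly_84_entries_with_pinned_indices(self):
        reg = default_registry()
        assert len(reg) == 84
        assert reg.group("uf_rate") == list(range(70, 78))
        assert reg.group("uf_volume") == list(range(78, 84))
        assert reg[76].kind == "count_of_changes" and reg[76].source == "uf_rate"
        assert reg[77].kind == "mean_of_changes" and reg[77].source == "uf_rate"
        assert reg[78].kind == "max" and reg[78].source == "uf_volume"
        assert reg[82].kind == "slope" and reg[82].source == "uf_volume"

    def test_group_sizes(self):
        reg = default_registry()
        assert len(subset_indices(reg, "uf")) == 14
        assert len(subset_indices(reg, "not_uf")) == 70
        assert len(subset_indices(reg, "bp_related")) == 24
        assert len(subset_indices(reg, "top21")) == 21
        assert {reg[i].name for i in subset_indices(reg, "demographic")} == {
            "age", "gender", "vintage_years", "predialytic_weight"
        }

    def test_top21_disjoint_from_uf(self):
        reg = default_registry()
        assert not set(subset_indices(reg, "top21")) & set(subset_indices(reg, "uf"))

    def test_unknown_group_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            subset_indices(default_registry(), "astrology")

    def test_yaml_round_trip(self, tmp_path):
        reg = default_registry()
        save_registry(reg, tmp_path / "registry.yaml")
        back = load_registry(tmp_path / "registry.yaml")
        assert back.entries == reg.entries


# ------------------------------------------------------- summary primitives


class TestLinearSummary:
    def test_hand_arithmetic(self):
        out = linear_summary(np.arange(3.0), np.array([10.0, 20.0, 30.0]))
        assert out["mean"] == 20.0 and out["max"] == 30.0 and out["min"] == 10.0

    def test_constant_series(self):
        out = linear_summary(np.arange(4.0), np.full(4, 7.0))
        assert out["sd_of_mean"] == 0.0 and out["cv"] == 0.0

    def test_against_definition_oracle(self):
        y = np.array([2.0, 4, 4, 4, 5, 5, 7, 9])
        out = linear_summary(np.arange(8.0), y)
        # independent brute-force: n-1 sample SD by the definition
        m = sum(y) / len(y)
        sd = (sum((v - m) ** 2 for v in y) / (len(y) - 1)) ** 0.5
        assert out["sd_of_mean"] == pytest.approx(sd / len(y) ** 0.5, rel=1e-12)
        assert out["cv"] == pytest.approx(sd / abs(m), rel=1e-12)
        assert out["sd_of_mean"] == pytest.approx(0.755928946018454, rel=1e-10)

    def test_zero_mean_flags_cv(self):
        out = linear_summary(np.arange(2.0), np.array([-1.0, 1.0]))
        assert np.isnan(out["cv"])

    def test_empty_series_raises(self):
        with pytest.raises(FeatureExtractionError):
            linear_summary(np.array([]), np.array([]))


class TestRegressionSummary:
    def test_perfect_line(self):
        out = regression_summary(np.array([0.0, 60, 120]), np.array([0.0, 60, 120]))
        assert out["slope"] == pytest.approx(1.0) and out["r_squared"] == pytest.approx(1.0)

    def test_constant_y_convention(self):
        out = regression_summary(np.array([0.0, 30, 60]), np.full(3, 5.0))
        assert out["slope"] == 0.0 and out["r_squared"] == 0.0

    def test_against_normal_equation_oracle(self):
        t = np.array([0.0, 30, 60, 90])
        y = np.array([1.0, 3, 2, 5])
        out = regression_summary(t, y)
        # brute-force least squares via the normal equations
        A = np.column_stack([t, np.ones_like(t)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert out["slope"] == pytest.approx(beta[0], rel=1e-12)
        assert out["r_squared"] == pytest.approx(1 - resid @ resid / ss_tot, rel=1e-12)

    def test_degenerate_time_raises(self):
        with pytest.raises(FeatureExtractionError):
            regression_summary(np.array([5.0, 5.0]), np.array([1.0, 2.0]))


class TestDerivativeSummary:
    def test_linear_signal(self):
        t = np.array([0.0, 10, 25, 60])
        out = derivative_summary(t, 3.0 * t + 2)
        assert out["d1_max"] == pytest.approx(3.0)
        assert out["d1_min"] == pytest.approx(3.0)
        assert out["d2_max"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_finite_differences(self):
        out = derivative_summary(np.array([0.0, 1, 2]), np.array([0.0, 1, 4]))
        assert out["d1_min"] == 1.0 and out["d1_max"] == 3.0 and out["d1_mean"] == 2.0
        assert out["d2_max"] == out["d2_min"] == out["d2_mean"] == 2.0

    def test_monotone_series_has_nonnegative_d1_min(self):
        rng = np.random.default_rng(5)
        y = np.cumsum(rng.random(10))
        out = derivative_summary(np.arange(10.0), y)
        assert out["d1_min"] >= 0

    def test_needs_three_points(self):
        with pytest.raises(FeatureExtractionError):
            derivative_summary(np.array([0.0, 1]), np.array([0.0, 1]))


class TestUFRateChanges:
    def test_hand_count_and_mean(self):
        out = uf_rate_changes(np.arange(5.0), np.array([500.0, 500, 700, 700, 300]))
        assert out["count_of_changes"] == 2
        assert out["mean_of_changes"] == -100.0

    def test_constant_rate(self):
        out = uf_rate_changes(np.arange(3.0), np.full(3, 600.0))
        assert out["count_of_changes"] == 0 and out["mean_of_changes"] == 0.0

    def test_single_change(self):
        out = uf_rate_changes(np.arange(2.0), np.array([600.0, 750.0]))
        assert out["count_of_changes"] == 1 and out["mean_of_changes"] == 150.0


# -------------------------------------------------------------- extraction


class TestExtractFeatures:
    def test_valid_session_gives_84_finite_values(self, cleaned_small):
        cleaned, _ = cleaned_small
        v = extract_features(cleaned[0])
        assert v.shape == (84,)
        assert np.all(np.isfinite(v))

    def test_constant_session(self):
        n = 9
        s = make_session(
            venous_pressure=[120.0] * n, transmembranous_pressure=[110.0] * n,
            uf_rate=[600.0] * n, uf_volume=[100.0] * n,
            systolic_bp=[140.0] * 5, diastolic_bp=[80.0] * 5,
            pulse_pressure=[60.0] * 5, pulse_rate=[75.0] * 5,
        )
        reg = default_registry()
        v = extract_features(s, reg)
        by = {e.name: v[e.index - 1] for e in reg}
        assert by["vp_slope"] == 0.0 and by["sbp_cv"] == 0.0
        assert by["vp_d1_max"] == 0.0 and by["tmp_d2_mean"] == 0.0
        assert by["ufr_n_changes"] == 0.0
        assert by["age"] == 60.0 and by["gender"] == 1.0

    def test_depends_only_on_included_records(self, small_cohort):
        sessions, _ = small_cohort
        s = next(x for x in sessions if not x.events)
        cut = apply_cutoff(s, 60.0)
        v1 = extract_features(cut)
        # mutate everything after the cutoff in the parent; re-cut; compare
        anchor = s.last_record_time - 60.0
        mutated = s.with_records(
            r if r.time_min <= anchor
            else MeasurementRecord(r.measurement_id, r.time_min, r.value + 1e6)
            for r in s.records
        )
        v2 = extract_features(apply_cutoff(mutated, 60.0))
        np.testing.assert_array_equal(v1, v2)

    def test_scale_covariance(self, cleaned_small):
        cleaned, _ = cleaned_small
        s = cleaned[0]
        c = 3.5
        vp = MEASUREMENT_IDS["venous_pressure"]
        scaled = s.with_records(
            MeasurementRecord(r.measurement_id, r.time_min,
                              r.value * c if r.measurement_id == vp else r.value)
            for r in s.records
        )
        reg = default_registry()
        v0, v1 = extract_features(s, reg), extract_features(scaled, reg)
        for e in reg:
            if e.source != "venous_pressure":
                continue
            a, b = v0[e.index - 1], v1[e.index - 1]
            if e.kind in ("cv", "r_squared"):
                assert b == pytest.approx(a, rel=1e-9)
            else:
                assert b == pytest.approx(c * a, rel=1e-9)

    def test_record_floor_violation_excluded_with_reason(self, small_cohort):
        sessions, _ = small_cohort
        s = sessions[0].with_records(sessions[0].records[:8])
        with pytest.raises(FeatureExtractionError, match="too_few_records"):
            extract_features(s)
        X, kept, excluded = extract_matrix([s, sessions[1]])
        assert X.shape == (1, 84) and len(excluded) == 1

    def test_feature_subset_shapes(self, cleaned_small):
        cleaned, _ = cleaned_small
        X, _, _ = extract_matrix(cleaned[:10])
        reg = default_registry()
        assert feature_subset(X, reg, "uf").shape[1] == 14
        assert feature_subset(X, reg, "not_uf").shape[1] == 70
        assert feature_subset(X, reg, "bp_related").shape[1] == 24
        assert feature_subset(X, reg, "top21").shape[1] == 21
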