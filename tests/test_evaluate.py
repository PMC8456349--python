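import numpy as np
import pytest

from hdadverse.evaluate import (
    EvalConfig,
    build_dataset,
    confusion_metrics,
    cross_validate,
    probability_consistency,
    roc_auc,
    run_cutoff_experiment,
    run_truncation_experiment,
    _patient_folds,
    _stratified_folds,
)


def pairwise_auc(scores, labels):
    """Independent brute-force Mann-Whitney estimator (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestRocAuc:
    def test_perfect_ranking(self):
        a, _ = roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert a == 1.0

    def test_all_ties(self):
        a, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert a == 0.5

    def test_hand_example(self):
        a, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert a == pytest.approx(0.75)
        assert pairwise_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=80)
        y = (rng.random(80) < 0.4).astype(int)
        a1, _ = roc_auc(s, y)
        a2, _ = roc_auc(np.exp(3 * s) + 7, y)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert m["f1"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_all_negative_prediction(self):
        m = confusion_metrics([0, 0, 0, 0], [0, 1, 0, 1])
        assert m["sensitivity"] == 0.0 and m["f1"] == 0.0 and m["specificity"] == 1.0

    def test_hand_contingency_table(self):
        # TP=3, FP=1, FN=2, TN=10
        pred = [1] * 3 + [1] + [0] * 2 + [0] * 10
        truth = [1] * 3 + [0] + [1] * 2 + [0] * 10
        m = confusion_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(10 / 11)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [0, 1, 1])


@pytest.fixture(scope="module")
def signal_matrix():
    rng = np.random.default_rng(42)
    n = 400
    y = (rng.random(n) < 0.15).astype(int)
    X = rng.normal(size=(n, 6))
    X[:, 0] += 2.0 * y
    X[:, 1] -= 1.5 * y
    pids = [f"P{i % 25:02d}" for i in range(n)]
    return X, y, pids


class TestCrossValidate:
    def test_folds_are_a_partition(self, signal_matrix):
        X, y, _ = signal_matrix
        rng = np.random.default_rng(0)
        folds = _stratified_folds(y, 4, rng)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(y.size))

    def test_patient_partition_keeps_patients_whole(self, signal_matrix):
        X, y, pids = signal_matrix
        folds = _patient_folds(pids, 4, np.random.default_rng(1))
        seen = {}
        for j, idx in enumerate(folds):
            for i in idx:
                assert seen.setdefault(pids[i], j) == j

    def test_recovers_signal(self, signal_matrix):
        X, y, pids = signal_matrix
        res = cross_validate(X, y, "perceptron", EvalConfig(seed=3), groups=pids)
        assert res.mean_auc > 0.8
        assert len(res.per_fold) == 12  # 4 folds x 3 repeats
        assert res.sd_auc >= 0

    def test_patient_partition_runs(self, signal_matrix):
        X, y, pids = signal_matrix
        res = cross_validate(
            X, y, "perceptron",
            EvalConfig(partition="patient", seed=3), groups=pids,
        )
        assert res.mean_auc > 0.7

    def test_negative_control_chance_level(self, signal_matrix):
        from hdadverse.labeling import negative_control_relabel

        X, y, _ = signal_matrix
        yp = negative_control_relabel(y, 5)
        res = cross_validate(X, yp, "perceptron", EvalConfig(seed=3))
        assert 0.4 <= res.mean_auc <= 0.6


class TestExperiments:
    def test_cutoff_experiment_rows_and_cutoff_zero_consistency(self, cleaned_small):
        cleaned, _ = cleaned_small
        cutoffs = (0.0, 15.0, 60.0)
        rows = run_cutoff_experiment(
            cleaned, cutoffs=cutoffs, eval_config=EvalConfig(repeats=1, seed=6)
        )
        assert [m for m, _ in rows] == list(cutoffs)
        X, y, _, pids = build_dataset(cleaned, cutoff_min=0.0)
        direct = cross_validate(X, y, "perceptron", EvalConfig(repeats=1, seed=6),
                                groups=pids)
        assert rows[0][1].mean_auc == pytest.approx(direct.mean_auc)

    def test_truncation_modes_reproducible(self, cleaned_small):
        cleaned, _ = cleaned_small
        cfg = EvalConfig(repeats=1, seed=2)
        r1 = run_truncation_experiment(cleaned, ("fixed", 198.0), eval_config=cfg)
        r2 = run_truncation_experiment(cleaned, ("fixed", 198.0), eval_config=cfg)
        assert r1.mean_auc == r2.mean_auc
        r3 = run_truncation_experiment(cleaned, ("uniform", (180.0, 210.0)),
                                       eval_config=cfg, seed=5)
        assert 0.0 <= r3.mean_auc <= 1.0

    def test_truncation_none_equals_main_analysis(self, cleaned_small):
        cleaned, _ = cleaned_small
        cfg = EvalConfig(repeats=1, seed=2)
        r = run_truncation_experiment(cleaned, None, eval_config=cfg)
        X, y, _, pids = build_dataset(cleaned)
        direct = cross_validate(X, y, "perceptron", cfg, groups=pids)
        assert r.mean_auc == pytest.approx(direct.mean_auc)

    def test_matching_negative_endpoints_removes_length_leakage(self):
        """With a feature-independent hazard the only label signal is the
        event-time truncation of positives; truncating negatives into the
        same time window must pull the AUC back toward chance."""
        from hdadverse.preprocess import clean_cohort
        from hdadverse.synthetic_data import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_patients=30, sessions_per_patient=(12, 12),
                               seed=21, signal_features=())
        sessions, _ = simulate_cohort(cfg)
        cleaned, _ = clean_cohort(sessions)
        ec = EvalConfig(seed=3)
        leaky = run_truncation_experiment(cleaned, None, eval_config=ec)
        matched = run_truncation_experiment(
            cleaned, ("uniform", (150.0, 230.0)), eval_config=ec, seed=5
        )
        assert leaky.mean_auc > 0.75  # length leakage is real
        assert matched.mean_auc < leaky.mean_auc - 0.08


class TestProbabilityConsistency:
    def test_threshold_zero_all_consistent_and_strict_rule(self, cleaned_small):
        cleaned, _ = cleaned_small
        sids, mat, consistent = probability_consistency(
            cleaned, cutoffs=(0.0, 10.0), n_sample=60, seed=4,
            eval_config=EvalConfig(repeats=1, seed=1), threshold=0.0,
        )
        assert mat.shape == (len(sids), 2)
        finite_rows = [s for i, s in enumerate(sids) if np.all(np.isfinite(mat[i]))]
        assert set(consistent) == set(finite_rows)  # every finite row beats 0

    def test_oversampling_warns_and_uses_all(self, cleaned_small):
        cleaned, _ = cleaned_small
        with pytest.warns(UserWarning, match="using all"):
            sids, mat, _ = probability_consistency(
                cleaned[:30], cutoffs=(0.0,), n_sample=999, seed=1,
                eval_config=EvalConfig(repeats=1, seed=0), threshold=0.8,
            )
        assert len(sids) <= 30
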