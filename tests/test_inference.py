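"""Low-level encoding, NN/kNN classifiers and the LOSO harness."""
import numpy as np
import pytest

from ppgtherm.errors import InvalidInputError
from ppgtherm.inference import (
    CvReport,
    ModelSpec,
    build_feature_matrix,
    encode_low_level,
    fit_nn,
    knn1_classify,
    loso_cv,
)
from ppgtherm.signals import (
    MeasurementWindow,
    PPIntervalSeries,
    ThermalVariabilitySequence,
)
from ppgtherm.synthetic import RRParams, ThermalSimConfig, generate_rr, simulate_thermal
from ppgtherm.thermal_nose import extract_thermal


def make_window(pid, sid, intervals, tv_values, label=None):
    intervals = np.asarray(intervals, dtype=float)
    peaks = np.concatenate(([0.0], np.cumsum(intervals) / 1000.0))
    tv_values = np.asarray(tv_values, dtype=float)
    tv = ThermalVariabilitySequence(tv_values, 33.0 + tv_values)
    return MeasurementWindow(pid, sid, pp=PPIntervalSeries(intervals, peaks),
                             tv=tv, label=label)


def synthetic_label_cohort(n_participants=8, n_sessions=6, sep=3.0, seed=0):
    """Windows whose features differ by `sep` SDs between classes."""
    rng = np.random.default_rng(seed)
    windows = []
    for p in range(n_participants):
        for s in range(n_sessions):
            label = int(s % 2 == 1)
            base = 800.0 - sep * 20.0 * label
            iv = base + rng.normal(0, 20.0, 22)
            tv = np.clip(np.linspace(1.0, 1.0 - 0.4 * label, 20)
                         + rng.normal(0, 0.05, 20), 0, 1)
            windows.append(make_window(f"P{p}", f"S{s}", iv, tv, label))
    return windows


class TestEncodeLowLevel:
    def test_constant_intervals_encode_to_constant_row(self):
        w = make_window("P1", "S1", [800.0] * 20, np.linspace(0, 1, 20))
        row = encode_low_level(w, "ppg_only", pp_len=40)
        np.testing.assert_allclose(row, 800.0)
        assert len(row) == 40

    def test_matching_tv_length_is_identity(self):
        tv = np.linspace(0, 1, 20)
        w = make_window("P1", "S1", [800.0] * 10, tv)
        row = encode_low_level(w, "thermal_only", tv_len=20)
        np.testing.assert_allclose(row, tv)

    def test_ramp_intervals_interpolate_linearly(self):
        iv = np.linspace(700, 940, 25)  # arithmetic ramp
        w = make_window("P1", "S1", iv, np.linspace(0, 1, 20))
        row = encode_low_level(w, "ppg_only", pp_len=40)
        expected = np.interp(np.linspace(0, 24, 40), np.arange(25), iv)
        np.testing.assert_allclose(row, expected, atol=1e-9)

    def test_short_tv_edge_padded(self):
        w = make_window("P1", "S1", [800.0] * 10, np.linspace(0, 1, 12))
        row = encode_low_level(w, "thermal_only", tv_len=20)
        assert len(row) == 20
        np.testing.assert_allclose(row[12:], row[11])

    def test_multimodal_concatenates(self):
        w = make_window("P1", "S1", [800.0] * 10, np.linspace(0, 1, 20))
        row = encode_low_level(w, "multimodal", pp_len=40, tv_len=20)
        assert len(row) == 60

    def test_empty_pp_excludes_window(self):
        w = MeasurementWindow("P1", "S1", pp=PPIntervalSeries.empty(),
                              tv=ThermalVariabilitySequence(
                                  np.linspace(0, 1, 20),
                                  np.linspace(33, 34, 20)))
        assert encode_low_level(w, "ppg_only") is None
        assert encode_low_level(w, "multimodal") is None
        assert encode_low_level(w, "thermal_only") is not None


class TestFitNn:
    def _blobs(self, rng, n=100, d=60, sep=5.0):
        X = rng.standard_normal((n, d))
        y = (np.arange(n) % 2).astype(int)
        X[y == 1, 0] += sep
        return X, y

    def test_separable_blobs_learned(self, rng):
        X, y = self._blobs(rng)
        model = fit_nn(X, y, hidden_size=80, seed=1)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_training_is_deterministic(self, rng):
        X, y = self._blobs(rng, n=40)
        m1 = fit_nn(X, y, hidden_size=80, seed=7)
        m2 = fit_nn(X, y, hidden_size=80, seed=7)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(InvalidInputError):
            fit_nn(X, np.ones(10), hidden_size=80)

    def test_permuted_labels_do_not_generalize(self, rng):
        X, y = self._blobs(rng, n=80)
        y_perm = rng.permutation(y)
        model = fit_nn(X[:60], y_perm[:60], hidden_size=80, seed=3)
        held_out = (model.predict(X[60:]) == y_perm[60:]).mean()
        assert 0.2 <= held_out <= 0.8  # chance-level on fresh noise


class TestKnn1:
    def test_exact_match_returns_its_label(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.integers(0, 2, 10)
        pred = knn1_classify(X, y, X[4:5])
        assert pred[0] == y[4]

    def test_single_training_point(self, rng):
        pred = knn1_classify(np.zeros((1, 2)), np.array([1]),
                             rng.standard_normal((5, 2)))
        np.testing.assert_array_equal(pred, 1)

    def test_matches_brute_force_oracle(self, rng):
        train = rng.standard_normal((30, 5))
        y = rng.integers(0, 2, 30)
        test = rng.standard_normal((12, 5))
        pred = knn1_classify(train, y, test)
        for i, row in enumerate(test):
            dists = [np.sqrt(((row - tr) ** 2).sum()) for tr in train]
            assert pred[i] == y[int(np.argmin(dists))]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            knn1_classify(np.zeros((3, 4)), np.zeros(3), np.zeros((2, 5)))


class TestLosoCv:
    def test_folds_partition_windows_by_participant(self):
        windows = synthetic_label_cohort(n_participants=17)
        report = loso_cv(windows, ModelSpec("knn"), level="low", seed=0)
        assert len(report.fold_accuracies) == 17
        assert report.confusion.sum() == len(windows)

    def test_nearly_separable_labels_recovered(self):
        windows = synthetic_label_cohort(sep=6.0, seed=1)
        report = loso_cv(windows, ModelSpec("nn", 80), level="low", seed=1)
        assert report.mean_accuracy >= 0.95

    def test_confusion_trace_equals_weighted_accuracy(self):
        windows = synthetic_label_cohort(seed=2)
        report = loso_cv(windows, ModelSpec("knn"), level="low", seed=2)
        weighted = sum(a * 6 for a in report.fold_accuracies)
        assert np.trace(report.confusion) == pytest.approx(weighted, abs=1e-9)

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(3)
        accs = []
        for seed in range(3):
            windows = synthetic_label_cohort(n_participants=10, seed=seed)
            labels = [w.label for w in windows]
            for w, lab in zip(windows, rng.permutation(labels)):
                w.label = int(lab)
            rep = loso_cv(windows, ModelSpec("knn"), level="low", seed=seed)
            accs.append(rep.mean_accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_bit_reproducible(self):
        windows = synthetic_label_cohort(seed=4)
        r1 = loso_cv(windows, ModelSpec("nn", 80), level="low", seed=4)
        r2 = loso_cv(windows, ModelSpec("nn", 80), level="low", seed=4)
        assert r1.fold_accuracies == r2.fold_accuracies
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_exclude_sessions_drops_windows(self):
        windows = synthetic_label_cohort(seed=5)
        rep = loso_cv(windows, ModelSpec("knn"), level="low", seed=5,
                      exclude_sessions=("S0",))
        assert rep.confusion.sum() == len(windows) - 8

    def test_too_few_participants_rejected(self):
        windows = synthetic_label_cohort(n_participants=2)
        with pytest.raises(InvalidInputError):
            loso_cv(windows, ModelSpec("knn"), level="low")

    def test_high_level_feature_matrix_has_nine_columns(self):
        rng = np.random.default_rng(6)
        windows = []
        for p in range(4):
            for s in range(3):
                rr = generate_rr(RRParams(850, 40, 30, 20,
                                          seed=int(rng.integers(2**31))))
                tv = extract_thermal(simulate_thermal(ThermalSimConfig(
                    trend_slope=-0.02 * s, seed=int(rng.integers(2**31)))))
                windows.append(MeasurementWindow(f"P{p}", f"S{s}", pp=rr,
                                                 tv=tv, label=s % 2))
        X, y, groups = build_feature_matrix(windows, "multimodal", "high")
        assert X.shape[1] == 9
        assert not np.isnan(X).any()


class TestCvReport:
    def test_summary_mentions_means(self):
        rep = CvReport(["a", "b"], [0.5, 1.0], [0.4, 1.0],
                       np.array([[3, 1], [1, 3]]))
        text = rep.summary()
        assert "75.00%" in text
        assert rep.overall_accuracy == 0.75
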