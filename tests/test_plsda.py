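import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirfusion.plsda import (
    MODES,
    ModeRunConfig,
    ModeSpec,
    _pls1_coef,
    _pls1_decompose,
    choose_threshold,
    evaluate,
    fit_multiclass,
    fit_plsda,
    predict_scores,
    roc_curve,
    run_mode,
)

MODE_AB = ModeSpec("AB", frozenset({"A"}), frozenset({"B"}))


def labelled(n_a, n_b):
    return np.array(["A"] * n_a + ["B"] * n_b)


class TestModeSpec:
    def test_builtin_modes(self):
        assert MODES["mode1"].positive == {"Romina", "Sibilla"}
        assert MODES["mode2"].negative == {"Silvia"}
        assert MODES["mode3"].negative == {"Cristina"}

    def test_coding(self):
        y = MODES["mode1"].code(np.array(["Romina", "Silvia", "Sibilla"]))
        assert y.tolist() == [1, 0, 1]

    def test_unknown_cultivar_rejected(self):
        with pytest.raises(ValueError, match="neither class"):
            MODES["mode1"].code(np.array(["Elsanta"]))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ModeSpec("bad", frozenset({"A"}), frozenset({"A", "B"}))


class TestFitPLSDA:
    def test_perfect_fit_single_lv(self):
        # dummy y equals column 0; other columns orthogonal to centered y
        labels = labelled(2, 2)
        y = np.array([1.0, 1.0, 0.0, 0.0])
        X = np.column_stack([y, [1, -1, 1, -1], [1, -1, -1, 1]])
        model = fit_plsda(X, labels, MODE_AB, n_lv=1)
        pred = predict_scores(model, X)
        assert np.allclose(pred, y, atol=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(20, 5))
        labels = labelled(10, 10)
        y = MODE_AB.code(labels).astype(float)
        model = fit_plsda(X, labels, MODE_AB, n_lv=5)
        # independent oracle: ordinary least squares on the centered data
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        ols_pred = Xc @ beta + y.mean()
        assert np.allclose(predict_scores(model, X), ols_pred, atol=1e-8)

    def test_first_weight_is_normalized_xty(self, rng):
        X = rng.normal(size=(4, 3))
        labels = labelled(2, 2)
        y = MODE_AB.code(labels).astype(float)
        model = fit_plsda(X, labels, MODE_AB, n_lv=1)
        # hand-computed NIPALS step
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w1 = Xc.T @ yc
        w1 /= np.linalg.norm(w1)
        assert np.allclose(model.weights[:, 0], w1, atol=1e-10)

    def test_telescoping_deflation(self, rng):
        # k-LV decomposition restricted to k-1 LVs equals the k-1 fit
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        W3, P3, q3 = _pls1_decompose(Xc, yc, 3)
        W2, P2, q2 = _pls1_decompose(Xc, yc, 2)
        assert np.allclose(W3[:, :2], W2, atol=1e-12)
        assert np.allclose(_pls1_coef(W3, P3, q3, 2), _pls1_coef(W2, P2, q2, 2))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_plsda(X, np.array(["A"] * 5), MODE_AB, n_lv=1)

    def test_excess_lvs_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_plsda(X, labelled(3, 3), MODE_AB, n_lv=5)


class TestPredictScores:
    def test_training_data_reproduces_fit(self, rng):
        X = rng.normal(size=(15, 4))
        labels = labelled(8, 7)
        model = fit_plsda(X, labels, MODE_AB, n_lv=2)
        a = predict_scores(model, X)
        b = predict_scores(model, X)
        assert np.array_equal(a, b)

    def test_center_row_predicts_class_mean(self, rng):
        X = rng.normal(size=(12, 4))
        labels = labelled(7, 5)
        model = fit_plsda(X, labels, MODE_AB, n_lv=2)
        pred = predict_scores(model, X.mean(axis=0))
        assert np.isclose(pred[0], 7 / 12, atol=1e-12)

    def test_duplicated_row_duplicated_prediction(self, rng):
        X = rng.normal(size=(10, 3))
        model = fit_plsda(X, labelled(5, 5), MODE_AB, n_lv=2)
        row = X[3]
        pred = predict_scores(model, np.vstack([row, row]))
        assert pred[0] == pred[1]

    def test_no_leakage_through_test_shift(self, rng):
        X = rng.normal(size=(10, 3))
        model = fit_plsda(X, labelled(5, 5), MODE_AB, n_lv=2)
        x_mean_before = model.x_mean.copy()
        p0 = predict_scores(model, X)
        p1 = predict_scores(model, X + 2.0)
        assert np.array_equal(model.x_mean, x_mean_before)
        # shift propagates only through the fixed coefficient vector
        assert np.allclose(p1 - p0, 2.0 * model.coef.sum(), atol=1e-10)


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        *_, auc = roc_curve(y, s)
        assert auc == 1.0

    def test_reversed_scores_auc_zero(self):
        y = np.array([0, 0, 1, 1])
        s = 1 - np.array([0.1, 0.2, 0.8, 0.9])
        *_, auc = roc_curve(y, s)
        assert auc == 0.0

    def test_auc_equals_pair_counting_oracle(self):
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.8, 0.3, 0.5, 0.5, 0.2, 0.1])
        *_, auc = roc_curve(y, s)
        # exhaustive Mann-Whitney pair count
        pos = s[y == 1]
        neg = s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert np.isclose(auc, wins / (len(pos) * len(neg)), atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        s = r.normal(size=10)
        *_, auc1 = roc_curve(y, s)
        *_, auc2 = roc_curve(y, np.exp(3 * s))
        assert np.isclose(auc1, auc2, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.ones(4, int), np.arange(4.0))


class TestChooseThreshold:
    def test_separated_classes_midpoint_of_gap(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        assert choose_threshold(y, s) == pytest.approx(0.5)

    def test_matches_exhaustive_scan(self, rng):
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        s = rng.normal(size=30)
        thr = choose_threshold(y, s)
        err = np.mean((s >= thr).astype(int) != y)
        # oracle: try every midpoint between sorted scores
        u = np.sort(np.unique(s))
        cands = np.r_[u[0] - 1, (u[:-1] + u[1:]) / 2, u[-1] + 1]
        best = min(np.mean((s >= t).astype(int) != y) for t in cands)
        assert np.isclose(err, best)

    def test_gaussian_classes_threshold_near_midpoint(self):
        r = np.random.default_rng(0)
        s = np.r_[r.normal(0, 0.1, 500), r.normal(1, 0.1, 500)]
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        assert abs(choose_threshold(y, s) - 0.5) < 0.15


class TestEvaluate:
    def test_all_correct(self):
        m = evaluate([1, 1, 0, 0], [1, 1, 0, 0])
        assert (m.tpr, m.tnr, m.error) == (100.0, 100.0, 0.0)

    def test_arithmetic_example(self):
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1] * 2 + [0] * 8
        m = evaluate(y_true, y_pred)
        assert (m.tp, m.fn, m.fp, m.tn) == (9, 1, 2, 8)
        assert m.tpr == 90.0
        assert m.tnr == 80.0
        assert m.error == 15.0
        assert m.fpr == pytest.approx(100.0 - m.tnr)

    def test_random_labelings_match_recount_oracle(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        m = evaluate(y, p)
        tp = int(np.sum((y == 1) & (p == 1)))
        fn = int(np.sum((y == 1) & (p == 0)))
        fp = int(np.sum((y == 0) & (p == 1)))
        tn = int(np.sum((y == 0) & (p == 0)))
        assert (m.tp, m.fn, m.fp, m.tn) == (tp, fn, fp, tn)
        assert m.error == pytest.approx(100.0 * (fp + fn) / 50)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            evaluate([1, 0], [1])


class TestRunMode:
    def test_report_schema(self, cohort216):
        panel, spectra = cohort216
        cfg = ModeRunConfig(lv_grid=(1, 2, 3))
        rep = run_mode(spectra, panel, MODES["mode1"], "fused", cfg)
        assert rep.mode == "MODE1"
        assert rep.n_lv >= 1
        assert rep.n_train == 137 and rep.n_test == 60
        for m in (rep.cv, rep.test):
            assert 0 <= m.error <= 100
            assert 0 <= (m.auc or 0) <= 1
        d = rep.to_dict()
        assert set(d) >= {"mode", "n_lv", "threshold", "cv", "test"}

    def test_strong_separation_zero_test_error(self, separable_cohort):
        panel, spectra = separable_cohort
        rep = run_mode(spectra, panel, MODES["mode1"], "nir_only")
        assert rep.test.error == 0.0

    def test_stage_name_in_errors(self, cohort216):
        panel, spectra = cohort216
        bad = ModeRunConfig(cv_segments=1)
        with pytest.raises(RuntimeError, match="classification stage"):
            run_mode(spectra, panel, MODES["mode1"], "nir_only", bad)


class TestMulticlass:
    @staticmethod
    def _separated_classes(rng, n_per=30, sep=8.0):
        X, labels = [], []
        for k, name in enumerate(["a", "b", "c", "d"]):
            centre = np.zeros(6)
            centre[k] = sep
            X.append(rng.normal(size=(n_per, 6)) + centre)
            labels += [name] * n_per
        return np.vstack(X), np.array(labels)

    def test_separated_classes_high_accuracy(self, rng):
        X, labels = self._separated_classes(rng)
        model = fit_multiclass(X, labels, n_lv=5)
        pred = model.predict_class(X)
        for name in "abcd":
            acc = np.mean(pred[labels == name] == name)
            assert acc > 0.95

    def test_two_class_agrees_with_binary_plsda(self, rng):
        X = np.vstack([rng.normal(size=(20, 4)) + [5, 0, 0, 0],
                       rng.normal(size=(20, 4)) - [5, 0, 0, 0]])
        labels = labelled(20, 20)
        multi = fit_multiclass(X, labels, n_lv=2)
        binary = fit_plsda(X, labels, MODE_AB, n_lv=2)
        pred_m = multi.predict_class(X)
        pred_b = np.where(predict_scores(binary, X) >= 0.5, "A", "B")
        assert np.array_equal(pred_m, pred_b)

    def test_one_observation_per_class_memorized(self, rng):
        X = rng.normal(size=(4, 5))
        labels = np.array(["a", "b", "c", "d"])
        model = fit_multiclass(X, labels, n_lv=3)
        assert np.array_equal(model.predict_class(X), labels)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            fit_multiclass(rng.normal(size=(5, 3)), np.array(["a"] * 5))
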