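import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oasig import (
    CASE,
    CONTROL,
    ConfusionMatrix,
    SVMParams,
    SyntheticSpec,
    confusion,
    generate_cohort,
    loocv_predict,
    metrics,
    train_svm,
)


def _clusters(n=10, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(sep, 1, n), rng.normal(-sep, 1, n)])[:, None]
    y = np.array([CASE] * n + [CONTROL] * n)
    return X, y


class TestTrainSvm:
    def test_separated_clusters_fit_perfectly(self):
        X, y = _clusters()
        model = train_svm(X, y)
        assert (model.predict(X) == y).all()

    def test_training_is_deterministic(self):
        X, y = _clusters(seed=3)
        grid = np.linspace(-5, 5, 50)[:, None]
        p1 = train_svm(X, y).predict(grid)
        p2 = train_svm(X, y).predict(grid)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_set_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_svm(X, np.array([CASE] * 4))

    def test_params_validated(self):
        with pytest.raises(ValueError):
            SVMParams(C=0.0)
        with pytest.raises(ValueError):
            SVMParams(gamma=-1.0)
        assert SVMParams().resolve_gamma(23) == pytest.approx(1 / 23)


class TestLoocv:
    def test_one_prediction_per_sample(self):
        X, y = _clusters(n=5)
        assert loocv_predict(X, y).shape == y.shape

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_separable_cohort_predicted_perfectly(self, seed):
        spec = SyntheticSpec(
            n_case=30, n_control=30, n_informative=5,
            n_redundant_per_informative=0, n_null=0, effect_size=3.0, seed=seed,
        )
        em, _ = generate_cohort(spec)
        y = em.labels.to_numpy()
        assert (loocv_predict(em.values.to_numpy(), y) == y).all()

    def test_pure_noise_features_score_near_zero_mcc(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 10))
            y = np.array([CASE] * 50 + [CONTROL] * 50)
            mcc = metrics(confusion(loocv_predict(X, y), y)).mcc
            assert abs(mcc) < 0.3

    def test_singleton_class_rejected_by_name(self):
        X = np.zeros((3, 1))
        y = np.array([CASE, CASE, CONTROL])
        with pytest.raises(ValueError, match="control"):
            loocv_predict(X, y)

    def test_repeated_runs_identical(self):
        X, y = _clusters(n=6, sep=0.5, seed=9)
        np.testing.assert_array_equal(loocv_predict(X, y), loocv_predict(X, y))


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        actual = np.array([CASE] * 10 + [CONTROL] * 5)
        cm = confusion(actual, actual)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 5, 0, 0)
        flipped = np.where(actual == CASE, CONTROL, CASE)
        cm2 = confusion(flipped, actual)
        assert (cm2.tp, cm2.tn) == (0, 0) and (cm2.fn, cm2.fp) == (10, 5)

    def test_hand_tally(self):
        actual = [CASE, CASE, CASE, CASE, CONTROL, CONTROL, CONTROL, CONTROL]
        pred = [CASE, CASE, CONTROL, CASE, CASE, CONTROL, CONTROL, CASE]
        cm = confusion(pred, actual)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 1, 2, 2)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["maybe"], [CASE])


class TestMetrics:
    def test_study_confusion_matrix_reproduces_reported_statistics(self):
        m = metrics(ConfusionMatrix(tp=105, fn=1, fp=3, tn=30))
        assert round(m.sn, 3) == 0.991
        assert round(m.sp, 3) == 0.909
        assert round(m.acc, 3) == 0.971
        assert round(m.mcc, 3) == 0.920

    def test_perfect_prediction(self):
        m = metrics(ConfusionMatrix(tp=5, fn=0, fp=0, tn=5))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_all_predicted_case_uses_zero_denominator_convention(self):
        m = metrics(ConfusionMatrix(tp=5, fn=0, fp=5, tn=0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 0.0, 0.5, 0.0)

    def test_missing_class_reports_missing_rate(self):
        m = metrics(ConfusionMatrix(tp=3, fn=1, fp=0, tn=0))
        assert m.sp is None and m.sn == pytest.approx(0.75)

    @settings(deadline=None, max_examples=300)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        fp=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_identities_hold_on_arbitrary_tables(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
        m = metrics(cm)
        assert -1.0 <= m.mcc <= 1.0
        # ACC is the class-size weighted mean of Sn and Sp
        if m.sn is not None and m.sp is not None:
            P, N = cm.n_case, cm.n_control
            assert m.acc == pytest.approx((m.sn * P + m.sp * N) / (P + N))
        # MCC = 1 exactly when there are no errors and both classes appear
        if fp == 0 and fn == 0 and tp > 0 and tn > 0:
            assert m.mcc == pytest.approx(1.0)
        # swapping the predicted labels negates MCC
        m_swap = metrics(ConfusionMatrix(tp=fn, fn=tp, fp=tn, tn=fp))
        if m.mcc != 0.0 or m_swap.mcc != 0.0:
            assert m_swap.mcc == pytest.approx(-m.mcc, abs=1e-12)
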