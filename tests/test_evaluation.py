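import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slesurv.evaluation import (
    MetricsReport,
    baseline_suite,
    classification_metrics,
    reclassification_metrics,
    roc_auc,
)


def _pair_count_auc(labels, probs):
    """Independent AUC oracle: concordant-pair probability with tie credit."""
    pos = [p for y, p in zip(labels, probs) if y == 1]
    neg = [p for y, p in zip(labels, probs) if y == 0]
    total = conc = 0.0
    for pp in pos:
        for pn in neg:
            total += 1
            if pp > pn:
                conc += 1
            elif pp == pn:
                conc += 0.5
    return conc / total


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        rep = classification_metrics(y, y)
        assert rep.sensitivity == rep.specificity == rep.accuracy == rep.f1 == 1.0

    def test_hand_confusion_case(self):
        # TP=8 FN=2 TN=6 FP=4
        y = np.array([1] * 10 + [0] * 10)
        p = np.array([1] * 8 + [0] * 2 + [1] * 4 + [0] * 6)
        rep = classification_metrics(y, p)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.6)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.f1 == pytest.approx(2 * 8 / (2 * 8 + 4 + 2))

    def test_degenerate_all_negative_predictor(self):
        y = np.array([1, 1, 0, 0])
        rep = classification_metrics(y, np.zeros(4, dtype=int))
        assert rep.sensitivity == 0.0

    def test_no_positives_sensitivity_undefined(self):
        rep = classification_metrics(np.zeros(4, dtype=int), np.zeros(4, dtype=int))
        assert rep.sensitivity is None

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_counts_conserve(self, pairs):
        y = np.array([a for a, _ in pairs])
        p = np.array([b for _, b in pairs])
        rep = classification_metrics(y, p)
        assert rep.counts.n == len(pairs)


class TestRocAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        _, auc = roc_auc(y, y.astype(float))
        assert auc == 1.0

    def test_four_point_hand_case(self):
        _, auc = roc_auc(np.array([1, 1, 0, 0]), np.array([0.9, 0.4, 0.6, 0.1]))
        assert auc == pytest.approx(0.75)

    def test_null_ranking_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        _, auc = roc_auc(y, rng.random(4000))
        assert auc == pytest.approx(0.5, abs=0.04)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.integers(0, 5, n) / 4.0  # coarse grid: exercises ties
            _, auc = roc_auc(y, p)
            assert auc == pytest.approx(_pair_count_auc(y, p), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5, dtype=int), np.linspace(0, 1, 5))


class TestReclassification:
    def test_identity_comparison_is_zero(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        p = rng.random(20)
        nri, idi = reclassification_metrics(y, p, p)
        assert nri == 0.0 and idi == 0.0

    def test_hand_nri_case(self):
        # 10 events: 2 up, 0 down; 10 nonevents: 1 down, 0 up -> NRI = 0.2 + 0.1
        y = np.array([1] * 10 + [0] * 10)
        ref = np.array([0.4] * 10 + [0.6] * 10)
        new = ref.copy()
        new[0] = new[1] = 0.7  # two events cross up
        new[10] = 0.3  # one nonevent crosses down
        nri, _ = reclassification_metrics(y, ref, new)
        assert nri == pytest.approx(0.3)

    def test_idi_direct_evaluation(self):
        # new probs = labels, reference = constant 0.5 on a 6-record fixture
        y = np.array([1, 1, 0, 0, 0, 1])
        ref = np.full(6, 0.5)
        new = y.astype(float)
        _, idi = reclassification_metrics(y, ref, new)
        # (1 - 0.5) - (0 - 0.5) = 1.0
        assert idi == pytest.approx(1.0)

    def test_idi_antisymmetric(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 15)
        a, b = rng.random(30), rng.random(30)
        _, idi_ab = reclassification_metrics(y, a, b)
        _, idi_ba = reclassification_metrics(y, b, a)
        assert idi_ab == pytest.approx(-idi_ba)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            reclassification_metrics(np.ones(4, dtype=int), np.ones(4) / 2, np.ones(4) / 2)


class TestBaselineSuite:
    @pytest.fixture(scope="class")
    def separable_split(self):
        rng = np.random.default_rng(0)
        n = 200
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 5)) * 0.3
        x[:, 2] += y * 3.0
        idx = rng.permutation(n)
        return x[idx[:150]], y[idx[:150]], x[idx[150:]], y[idx[150:]]

    def test_all_classifiers_learn_separable_fixture(self, separable_split):
        out = baseline_suite(*separable_split, seed=0)
        assert set(out) == {
            "decision_tree", "random_forest", "gradient_boosting",
            "knn", "svm", "logistic_regression",
        }
        for name, rep in out.items():
            assert isinstance(rep, MetricsReport), name
            assert rep.accuracy > 0.9, name

    def test_same_seed_identical_reports(self, separable_split):
        a = baseline_suite(*separable_split, seed=3)
        b = baseline_suite(*separable_split, seed=3)
        for name in a:
            assert a[name].accuracy == b[name].accuracy
            assert a[name].auc == b[name].auc

    def test_dominant_feature_ranks_first_in_tree_importances(self, separable_split):
        out = baseline_suite(*separable_split, seed=0)
        for name in ("random_forest", "gradient_boosting"):
            imp = out[name].feature_importances
            assert int(np.argmax(imp)) == 2, name

    def test_degenerate_train_set_recorded_not_raised(self):
        x = np.zeros((10, 3))
        y = np.zeros(10, dtype=int)  # single class: some classifiers fail
        out = baseline_suite(x, y, x, y, seed=0)
        assert len(out) == 6  # suite completes regardless
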