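import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slesurv.cssnn import (
    LossConfig,
    NetConfig,
    TrainedModel,
    batch_mse,
    class_weights,
    combined_loss,
    delay_coefficient,
    dyn_weight_mse,
    one_hot_targets,
    per_sample_weights,
    pseudo_label,
    train_cost_sensitive,
    train_initial,
)

# ---------------------------------------------------------------------------
# independent scalar-loop oracle for the full loss
# ---------------------------------------------------------------------------


def _oracle_weights(labels):
    n = len(labels)
    n_dead = sum(1 for y in labels if y == 1)
    n_surv = n - n_dead
    zero_w, one_w = n_dead / n, n_surv / n
    return [zero_w if y == 0 else one_w for y in labels]


def _oracle_dyn_weight_mse(targets, outputs, weights):
    total = 0.0
    for i in range(len(targets)):
        sq = 0.0
        for k in range(len(targets[i])):
            sq += (targets[i][k] - outputs[i][k]) ** 2
        total += weights[i] * sq
    return total / (2 * len(targets))


def _oracle_alpha(t, alpha_f, t1, t2):
    if t < t1:
        return 0.0
    if t <= t2:
        return alpha_f * (t - t1) / (t2 - t1)
    return alpha_f


def _oracle_combined(true_y, true_out, true_lab, ps_y, ps_out, ps_lab, t, cfg):
    loss = _oracle_dyn_weight_mse(true_y, true_out, _oracle_weights(true_lab))
    if ps_y is not None and len(ps_y) > 0:
        a = _oracle_alpha(t, cfg.alpha_f, cfg.t1, cfg.t2)
        loss += a * _oracle_dyn_weight_mse(ps_y, ps_out, _oracle_weights(ps_lab))
    return loss


class TestClassWeights:
    @pytest.mark.parametrize(
        "labels,zero_w,one_w",
        [
            ([0, 1, 0, 1], 0.5, 0.5),
            ([0, 0, 0, 1], 0.25, 0.75),
            ([0, 0], 0.0, 1.0),  # degenerate all-survivor batch
            ([1, 1, 1], 1.0, 0.0),  # degenerate all-death batch
        ],
    )
    def test_weight_formula(self, labels, zero_w, one_w):
        w = class_weights(np.array(labels))
        assert w.zero_weight == pytest.approx(zero_w)
        assert w.one_weight == pytest.approx(one_w)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=64))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one(self, labels):
        w = class_weights(np.array(labels))
        assert w.zero_weight + w.one_weight == pytest.approx(1.0)

    def test_minority_class_gets_larger_weight(self):
        w = class_weights(np.array([0] * 30 + [1] * 2))
        assert w.one_weight > w.zero_weight

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            class_weights(np.array([]))


class TestLossPieces:
    def test_batch_mse_perfect_fit(self):
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert batch_mse(t, t) == 0.0

    def test_batch_mse_hand_case(self):
        # one sample, target (1,0), output (0.5,0.5): (0.25+0.25)/2
        assert batch_mse(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]])) == pytest.approx(0.25)

    def test_batch_mse_duplication_invariance(self):
        rng = np.random.default_rng(0)
        t, o = rng.random((5, 2)), rng.random((5, 2))
        doubled = batch_mse(np.vstack([t, t]), np.vstack([o, o]))
        assert doubled == pytest.approx(batch_mse(t, o))

    def test_dyn_weight_reduces_to_plain_mse_at_unit_weights(self):
        rng = np.random.default_rng(1)
        t, o = rng.random((8, 2)), rng.random((8, 2))
        assert dyn_weight_mse(t, o, np.ones(8)) == pytest.approx(batch_mse(t, o))

    def test_dyn_weight_zero_annihilates(self):
        rng = np.random.default_rng(2)
        t, o = rng.random((4, 2)), rng.random((4, 2))
        assert dyn_weight_mse(t, o, np.zeros(4)) == 0.0

    def test_dyn_weight_hand_case(self):
        # 2 samples, weights (0.25, 0.75), squared-error sums (0.5, 0.5)
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        o = np.array([[0.5, 0.5], [0.5, 0.5]])  # each row's squared-error sum = 0.5
        got = dyn_weight_mse(t, o, np.array([0.25, 0.75]))
        assert got == pytest.approx((0.25 * 0.5 + 0.75 * 0.5) / 4)
        assert got == pytest.approx(0.125)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            dyn_weight_mse(np.ones((1, 2)), np.ones((1, 2)), np.array([-0.1]))


class TestDelayCoefficient:
    @pytest.mark.parametrize("t,expected", [(0, 0.0), (50, 0.0), (350, 1.5), (700, 3.0), (601, 3.0)])
    def test_default_ramp(self, t, expected):
        assert delay_coefficient(t, LossConfig()) == pytest.approx(expected)

    def test_continuity_at_breakpoints(self):
        cfg = LossConfig(alpha_f=2.5, t1=17, t2=93)
        # both adjacent branch formulas agree at T1 and T2
        assert delay_coefficient(cfg.t1, cfg) == pytest.approx(0.0)
        assert delay_coefficient(cfg.t2, cfg) == pytest.approx(cfg.alpha_f)
        assert delay_coefficient(cfg.t1 - 1, cfg) == 0.0
        assert delay_coefficient(cfg.t2 + 1, cfg) == cfg.alpha_f

    def test_invalid_ramp_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(t1=600, t2=100)


class TestCombinedLoss:
    def test_matches_scalar_oracle_on_random_batches(self):
        rng = np.random.default_rng(0)
        cfg = LossConfig()
        for _ in range(50):
            nt = int(rng.integers(1, 9))
            npseudo = int(rng.integers(0, 9))
            yl = rng.integers(0, 2, nt)
            yp = rng.integers(0, 2, npseudo)
            tt, to = one_hot_targets(yl), rng.random((nt, 2))
            pt, po = one_hot_targets(yp), rng.random((npseudo, 2))
            t = int(rng.integers(0, 900))
            got = combined_loss(tt, to, yl, pt, po, yp, t, cfg)
            want = _oracle_combined(
                tt.tolist(), to.tolist(), yl.tolist(), pt.tolist(), po.tolist(),
                yp.tolist(), t, cfg,
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_pseudo_term_annihilated_before_t1(self):
        rng = np.random.default_rng(3)
        yl, yp = np.array([0, 1]), np.array([1, 0])
        tt, pt = one_hot_targets(yl), one_hot_targets(yp)
        to, po = rng.random((2, 2)), rng.random((2, 2))
        cfg = LossConfig()
        sup_only = dyn_weight_mse(tt, to, per_sample_weights(yl))
        assert combined_loss(tt, to, yl, pt, po, yp, 50, cfg) == pytest.approx(sup_only)

    def test_empty_pseudo_batch_reduces_to_supervised(self):
        yl = np.array([0, 1, 1])
        tt = one_hot_targets(yl)
        to = np.full((3, 2), 0.5)
        cfg = LossConfig()
        got = combined_loss(tt, to, yl, None, None, None, 700, cfg)
        assert got == pytest.approx(dyn_weight_mse(tt, to, per_sample_weights(yl)))


class TestTraining:
    def test_separable_data_learned(self, separable_xy):
        x, y = separable_xy
        cfg = NetConfig(input_dim=4, hidden=(16,), epochs=150, learning_rate=0.02, seed=0)
        model = train_initial(x, y, cfg)
        assert (model.predict(x) == y).mean() > 0.95

    def test_loss_history_decreases_and_is_deterministic(self, separable_xy):
        x, y = separable_xy
        cfg = NetConfig(input_dim=4, hidden=(16,), epochs=60, seed=7)
        a = train_initial(x, y, cfg)
        b = train_initial(x, y, cfg)
        assert a.history == b.history
        assert a.history[-1]["loss"] < a.history[0]["loss"]

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            train_initial(np.random.default_rng(0).random((10, 4)), np.zeros(10, dtype=int),
                          NetConfig(input_dim=4, epochs=2))

    def test_predictions_are_simplex_points(self, separable_xy):
        x, y = separable_xy
        model = train_initial(x, y, NetConfig(input_dim=4, hidden=(8,), epochs=10, seed=0))
        p = model.predict_proba(np.random.default_rng(1).normal(size=(50, 4)) * 10)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_feature_dim_mismatch_raises(self, separable_xy):
        x, y = separable_xy
        model = train_initial(x, y, NetConfig(input_dim=4, hidden=(8,), epochs=2, seed=0))
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 7)))

    def test_checkpoint_round_trip(self, separable_xy, tmp_path):
        x, y = separable_xy
        model = train_initial(x, y, NetConfig(input_dim=4, hidden=(8,), epochs=5, seed=0))
        model.save(tmp_path / "m.json")
        back = TrainedModel.load(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict_proba(x), model.predict_proba(x))


class TestPseudoLabel:
    def test_every_censored_record_labeled(self, separable_xy):
        x, y = separable_xy
        model = train_initial(x, y, NetConfig(input_dim=4, hidden=(8,), epochs=30, seed=0))
        cen = np.random.default_rng(0).normal(size=(37, 4))
        ps = pseudo_label(model, cen)
        assert len(ps.labels) == 37
        assert ps.n_death + ps.n_survival == 37

    def test_death_distributed_censored_mostly_labeled_death(self, separable_xy):
        x, y = separable_xy
        model = train_initial(
            x, y, NetConfig(input_dim=4, hidden=(16,), epochs=150, learning_rate=0.02, seed=0)
        )
        rng = np.random.default_rng(5)
        cen = rng.normal(size=(60, 4)) * 0.3
        cen[:, 0] += 3.0  # drawn from the death-group distribution
        ps = pseudo_label(model, cen)
        assert ps.n_death > 0.8 * 60


class TestCostSensitiveTraining:
    def test_pseudo_term_zero_before_t1(self, separable_xy, fast_loss_cfg):
        x, y = separable_xy
        cfg = NetConfig(input_dim=4, hidden=(8,), epochs=25, seed=1)
        model0 = train_initial(x, y, cfg)
        ps = pseudo_label(model0, x[:20])
        model = train_cost_sensitive(x, y, x[:20], ps, cfg, fast_loss_cfg, rebalance=False)
        for rec in model.history:
            if rec["epoch"] < fast_loss_cfg.t1:
                assert rec["pseudo_loss"] == 0.0
                assert rec["alpha"] == 0.0
        assert model.history[-1]["alpha"] > 0.0

    def test_invalid_loss_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(t1=40, t2=40)

    def test_alpha_zero_equals_supervised_training(self, separable_xy):
        # with the pseudo term disabled the training path sees only the
        # supervised gradient, so accuracy matches supervised-only training
        x, y = separable_xy
        cfg = NetConfig(input_dim=4, hidden=(16,), epochs=150, learning_rate=0.02, seed=2)
        sup = train_initial(x, y, cfg)
        ps = pseudo_label(sup, x[:30])
        off = train_cost_sensitive(
            x, y, x[:30], ps, cfg, LossConfig(alpha_f=0.0, t1=1, t2=2), rebalance=False
        )
        assert (off.predict(x) == y).mean() > 0.95
        assert all(rec["pseudo_loss"] == 0.0 for rec in off.history)
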