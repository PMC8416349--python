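"""Tests for fold construction and the Levenberg-Marquardt trainer."""
import numpy as np
import pytest

from gaitnarx.errors import FoldError, LengthError
from gaitnarx.narx import (
    MinMaxNormalizer,
    NarxConfig,
    fit_normalizer,
    predict_trial,
)
from gaitnarx.synthetic import teacher_generate
from gaitnarx.training import (
    FoldPartition,
    TrainingConfig,
    _assemble,
    _jacobian,
    _loss_and_state,
    _pack,
    _unpack,
    make_folds,
    moment_variance_error_goal,
    normalized_mse,
    train_network,
    train_with_restarts,
)
from gaitnarx.trials import CONDITIONS, ProcessedTrial

from conftest import random_weights


class TestMakeFolds:
    def test_partition_properties(self, full_session):
        folds = make_folds(full_session, n_folds=10, seed=0)
        assert len(folds) == 10
        test_ids = {c: set() for c in CONDITIONS}
        for f in folds:
            for cond in CONDITIONS:
                tr, va, te = set(f.train[cond]), set(f.val[cond]), set(f.test[cond])
                assert len(tr) == 8 and len(va) == 2 and len(te) == 1
                assert not (tr & va or tr & te or va & te)
                assert len(tr | va | te) == 11
                test_ids[cond] |= te
        for cond in CONDITIONS:
            assert len(test_ids[cond]) == 10  # distinct test trial per fold

    def test_same_seed_identical(self, full_session):
        f1 = make_folds(full_session, n_folds=5, seed=3)
        f2 = make_folds(full_session, n_folds=5, seed=3)
        assert f1 == f2

    def test_fold0_counts_three_conditions(self, full_session):
        folds = make_folds(full_session, n_folds=10, seed=1)
        f = folds[0]
        assert len(f.ids("train")) == 24
        assert len(f.ids("val")) == 6
        assert len(f.ids("test")) == 3

    def test_insufficient_trials(self, full_session):
        short = [t for t in full_session if not t.trial_id.endswith("10")]
        with pytest.raises(FoldError, match="8 train"):
            make_folds(short, n_folds=10, seed=0)


def _toy_trial(trial_id, cond, n=60, seed=0):
    r = np.random.default_rng(seed)
    return ProcessedTrial(
        trial_id, cond, r.normal(0, 1, (n, 2)), r.normal(0, 1, (n, 2)), ()
    )


class TestNormalizedMse:
    def _normalizer(self):
        return MinMaxNormalizer(
            x_min=np.zeros(2),
            x_max=np.ones(2),
            y_min=np.array([-10.0, 0.0]),
            y_max=np.array([10.0, 2.0]),
        )

    def test_perfect_prediction_zero(self):
        nm = self._normalizer()
        y = np.random.default_rng(0).normal(0, 1, (30, 2))
        assert normalized_mse(y, y, nm) == 0.0

    def test_midpoint_predictor_equals_mean_normalized_variance(self):
        nm = self._normalizer()
        r = np.random.default_rng(1)
        y = np.column_stack([r.uniform(-10, 10, 200), r.uniform(0, 2, 200)])
        mid = np.tile([0.0, 1.0], (200, 1))  # channel midpoints
        yn = nm.norm_y(y)
        expect = np.mean(np.mean(yn**2, axis=0) - np.mean(yn, axis=0) ** 2 + np.mean(yn, axis=0) ** 2)
        # constant-at-midpoint MSE = E[yn^2] per channel, averaged
        assert normalized_mse(mid, y, nm) == pytest.approx(expect, rel=1e-12)

    def test_full_range_error_contributes_four(self):
        nm = self._normalizer()
        target = np.array([[10.0, 1.0]])
        pred = np.array([[-10.0, 1.0]])  # angle off by full range
        # angle channel error = 2 -> squared 4; moment channel 0; mean = 2
        assert normalized_mse(pred, target, nm) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(LengthError):
            normalized_mse(np.zeros((0, 2)), np.zeros((0, 2)), self._normalizer())


class TestMomentVarianceGoal:
    def test_matches_independent_two_pass_variance(self, lw_session):
        nm = fit_normalizer(lw_session[:8])
        goal = moment_variance_error_goal(lw_session, nm)
        pooled = np.concatenate([nm.norm_y(t.y)[:, 1] for t in lw_session])
        mean = pooled.sum() / pooled.size
        var = ((pooled - mean) ** 2).sum() / pooled.size
        assert goal == pytest.approx(0.01 * var, rel=1e-12)

    def test_scalar_arithmetic(self):
        nm = MinMaxNormalizer(
            x_min=np.zeros(2), x_max=np.ones(2),
            y_min=np.array([0.0, -1.0]), y_max=np.array([1.0, 1.0]),
        )
        r = np.random.default_rng(0)
        trial = ProcessedTrial("t", "LW", r.normal(0, 1, (100, 2)), r.normal(0, 0.3, (100, 2)), ())
        goal = moment_variance_error_goal([trial], nm)
        assert goal == pytest.approx(0.01 * np.var(nm.norm_y(trial.y)[:, 1]))


def _teacher_session(n_trials=11, n=140, seed=5):
    """Session of trials whose targets come from a known teacher network."""
    cfg = NarxConfig(m=1, d=2, n_hidden=4)
    teacher = random_weights(cfg, seed=99, scale=0.4)
    r = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        drive = r.normal(0, 1, (n, 2))
        from scipy.signal import sosfiltfilt, butter

        sos = butter(2, 8, fs=120, output="sos")
        x = np.column_stack([sosfiltfilt(sos, drive[:, 0]), sosfiltfilt(sos, drive[:, 1])])
        x += r.normal(0, 0.01, x.shape)  # mild exogenous noise
        y = teacher_generate(teacher, cfg, x, r.normal(0, 0.1, (3, 2)))
        trials.append(ProcessedTrial(f"LW{i:02d}", "LW", x, y, ()))
    return cfg, teacher, trials


class TestLmTraining:
    def test_teacher_student_recovery(self):
        cfg, _, trials = _teacher_session()
        folds = make_folds(trials, n_folds=1, seed=0)
        tconfig = TrainingConfig(error_goal=1e-4, max_epochs=60, restarts=1, seed=0)
        model = train_network(trials, folds[0], cfg, tconfig, restart_seed=2)
        assert model.history.train_mse[-1] < 1e-3

    def test_infinite_error_goal_stops_epoch_one(self, lw_session):
        folds = make_folds(lw_session, n_folds=1, seed=0)
        cfg = NarxConfig(m=2, d=2, n_hidden=2)
        tconfig = TrainingConfig(error_goal=np.inf, max_epochs=50, restarts=1, seed=0)
        model = train_network(lw_session, folds[0], cfg, tconfig)
        assert model.history.stop_reason == "error_goal"
        assert len(model.history.train_mse) == 1

    def test_determinism(self, lw_session):
        folds = make_folds(lw_session, n_folds=1, seed=0)
        cfg = NarxConfig(m=2, d=2, n_hidden=3)
        tconfig = TrainingConfig(error_goal=0.0, max_epochs=5, restarts=1, seed=0)
        m1 = train_network(lw_session, folds[0], cfg, tconfig, restart_seed=7)
        m2 = train_network(lw_session, folds[0], cfg, tconfig, restart_seed=7)
        assert m1.history.train_mse == m2.history.train_mse
        assert np.array_equal(m1.weights.a, m2.weights.a)

    def test_accepted_steps_monotone(self, lw_session):
        folds = make_folds(lw_session, n_folds=1, seed=0)
        cfg = NarxConfig(m=3, d=3, n_hidden=4)
        tconfig = TrainingConfig(error_goal=0.0, max_epochs=15, restarts=1, seed=0)
        model = train_network(lw_session, folds[0], cfg, tconfig)
        mse = model.history.train_mse
        assert all(b < a for a, b in zip(mse, mse[1:]))

    def test_returned_weights_are_best_validation_epoch(self, lw_session):
        folds = make_folds(lw_session, n_folds=1, seed=0)
        cfg = NarxConfig(m=3, d=3, n_hidden=4)
        tconfig = TrainingConfig(error_goal=0.0, max_epochs=20, restarts=1, seed=0)
        model = train_network(lw_session, folds[0], cfg, tconfig)
        h = model.history
        assert h.best_epoch == int(np.argmin(h.val_mse))
        # recompute validation MSE of the returned weights: must equal the min
        val_trials = folds[0].trials(lw_session, "val")
        features, targets = _assemble(val_trials, cfg, model.normalizer)
        from gaitnarx.narx import forward_batch

        _, yhat = forward_batch(model.weights, features)
        assert float(np.mean((yhat - targets) ** 2)) == pytest.approx(min(h.val_mse))

    def test_no_leakage_from_test_trial(self, lw_session):
        """Scrambling the held-out test trial's content must not change the
        trained weights bitwise."""
        folds = make_folds(lw_session, n_folds=1, seed=0)
        cfg = NarxConfig(m=2, d=2, n_hidden=3)
        tconfig = TrainingConfig(error_goal=0.0, max_epochs=4, restarts=1, seed=0)
        m1 = train_network(lw_session, folds[0], cfg, tconfig, restart_seed=3)
        test_id = folds[0].test["LW"][0]
        scrambled = []
        r = np.random.default_rng(0)
        for t in lw_session:
            if t.trial_id == test_id:
                scrambled.append(
                    ProcessedTrial(t.trial_id, t.condition, r.normal(0, 9, t.x.shape),
                                   r.normal(0, 9, t.y.shape), t.events)
                )
            else:
                scrambled.append(t)
        m2 = train_network(scrambled, folds[0], cfg, tconfig, restart_seed=3)
        assert np.array_equal(m1.weights.a, m2.weights.a)
        assert np.array_equal(m1.weights.w, m2.weights.w)

    def test_jacobian_matches_finite_differences(self):
        """LM Jacobian vs central finite differences on a tiny network."""
        cfg = NarxConfig(m=1, d=1, n_hidden=2)
        r = np.random.default_rng(0)
        features = r.normal(0, 0.5, (12, cfg.n_features))
        targets = r.normal(0, 0.5, (12, 2))
        theta = _pack(random_weights(cfg, seed=4, scale=0.3))
        _, resid, v, weights = _loss_and_state(theta, cfg, features, targets)
        jac = _jacobian(weights, features, v)
        eps = 1e-6
        for p in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[p] += eps
            tm[p] -= eps
            _, rp, _, _ = _loss_and_state(tp, cfg, features, targets)
            _, rm, _, _ = _loss_and_state(tm, cfg, features, targets)
            fd = np.concatenate([(rp - rm)[:, 0], (rp - rm)[:, 1]]) / (2 * eps)
            denom = max(np.max(np.abs(fd)), 1e-8)
            assert np.max(np.abs(jac[:, p] - fd)) / denom < 1e-5

    def test_pack_unpack_round_trip(self):
        cfg = NarxConfig(m=2, d=3, n_hidden=4)
        w = random_weights(cfg, seed=6)
        w2 = _unpack(_pack(w), cfg)
        for name in ("a", "c", "w", "b1", "b2"):
            assert np.array_equal(getattr(w, name), getattr(w2, name))


class TestRestarts:
    def test_single_restart_equals_train_network(self, lw_session):
        folds = make_folds(lw_session, n_folds=1, seed=0)
        cfg = NarxConfig(m=2, d=2, n_hidden=2)
        tconfig = TrainingConfig(error_goal=0.0, max_epochs=4, restarts=1, seed=5)
        best = train_with_restarts(lw_session, folds[0], cfg, tconfig)
        solo = train_network(lw_session, folds[0], cfg, tconfig, restart_seed=(5, 0, 0))
        assert np.array_equal(best.weights.a, solo.weights.a)

    def test_argmin_selection(self, lw_session):
        folds = make_folds(lw_session, n_folds=1, seed=0)
        cfg = NarxConfig(m=2, d=2, n_hidden=3)
        tconfig = TrainingConfig(error_goal=0.0, max_epochs=4, restarts=4, seed=1)
        best = train_with_restarts(lw_session, folds[0], cfg, tconfig)
        assert best.restart_scores
        chosen = min(best.restart_scores)
        assert all(chosen <= s for s in best.restart_scores)

    def test_best_of_restarts_beats_median(self):
        """Order-statistics check on the teacher-student task."""
        cfg, _, trials = _teacher_session(n=100)
        folds = make_folds(trials, n_folds=1, seed=0)
        tconfig = TrainingConfig(error_goal=0.0, max_epochs=8, restarts=5, seed=2)
        best = train_with_restarts(trials, folds[0], cfg, tconfig)
        scores = sorted(best.restart_scores)
        assert min(scores) <= scores[len(scores) // 2]
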