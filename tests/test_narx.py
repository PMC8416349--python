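"""Unit and property tests for the NARX core: forward equations, delay-line
windows, normalization, initialization and serialization."""
import json

import numpy as np
import pytest

from gaitnarx.errors import (
    ConfigError,
    DegenerateRangeError,
    LengthError,
    StructureError,
)
from gaitnarx.narx import (
    MinMaxNormalizer,
    NarxConfig,
    NarxWeights,
    build_design,
    fit_normalizer,
    forward_batch,
    forward_step,
    init_weights,
    model_from_dict,
    model_to_dict,
    predict_trial,
    steps_from_ms,
)
from gaitnarx.trials import ProcessedTrial

from conftest import random_weights


def brute_force_step(weights, config, x_window, y_window):
    """Independent nested-loop evaluation of the printed forward equations."""
    n, d = config.n_hidden, config.d
    v = np.zeros(n)
    for ni in range(n):
        z = weights.b1[ni]
        for q in range(d + 1):
            for i in range(2):
                z += weights.a[ni, i, q] * x_window[i, q]
        for q in range(1, d + 1):
            for j in range(2):
                z -= weights.c[ni, j, q - 1] * y_window[j, q - 1]
        v[ni] = np.tanh(z)
    yhat = np.zeros(2)
    for j in range(2):
        s = weights.b2[j]
        for ni in range(n):
            s += weights.w[j, ni] * v[ni]
        yhat[j] = s
    return v, yhat


class TestStepsFromMs:
    def test_58ms_is_7_steps(self):
        assert steps_from_ms(58) == 7

    def test_8ms_floors_to_1(self):
        assert steps_from_ms(8) == 1

    def test_142ms_rounds_to_17(self):
        assert steps_from_ms(142) == 17

    @pytest.mark.parametrize(
        "ms,steps", [(33, 4), (42, 5), (50, 6), (67, 8), (75, 9), (83, 10), (108, 13)]
    )
    def test_grid_values(self, ms, steps):
        assert steps_from_ms(ms) == steps

    def test_nonpositive_rejected(self):
        with pytest.raises(ConfigError):
            steps_from_ms(0)


class TestConfig:
    def test_derived_intervals(self):
        cfg = NarxConfig(m=7, d=10, n_hidden=6)
        assert cfg.tau_s == pytest.approx(7 / 120)
        assert cfg.window_s == pytest.approx(10 / 120)

    def test_invalid(self):
        with pytest.raises(ConfigError):
            NarxConfig(m=0, d=1, n_hidden=1)


class TestForwardStep:
    def test_all_zero_weights(self):
        cfg = NarxConfig(m=1, d=2, n_hidden=3)
        w = NarxWeights(
            a=np.zeros((3, 2, 3)),
            c=np.zeros((3, 2, 2)),
            w=np.zeros((2, 3)),
            b1=np.zeros(3),
            b2=np.zeros(2),
        )
        v, yhat = forward_step(w, cfg, np.ones((2, 3)), np.ones((2, 2)))
        assert np.all(v == 0.0) and np.all(yhat == 0.0)

    def test_bias_passthrough(self):
        cfg = NarxConfig(m=1, d=1, n_hidden=2)
        w = NarxWeights(
            a=np.zeros((2, 2, 2)),
            c=np.zeros((2, 2, 1)),
            w=np.zeros((2, 2)),
            b1=np.zeros(2),
            b2=np.array([0.5, -0.5]),
        )
        _, yhat = forward_step(w, cfg, np.zeros((2, 2)), np.zeros((2, 1)))
        assert yhat == pytest.approx([0.5, -0.5])

    def test_oracle_equivalence_100_instances(self):
        r = np.random.default_rng(7)
        for k in range(100):
            n = int(r.integers(1, 6))
            d = int(r.integers(1, 5))
            cfg = NarxConfig(m=int(r.integers(1, 4)), d=d, n_hidden=n)
            w = random_weights(cfg, seed=k)
            xw = r.normal(0, 1, (2, d + 1))
            yw = r.normal(0, 1, (2, d))
            v, yhat = forward_step(w, cfg, xw, yw)
            v0, yhat0 = brute_force_step(w, cfg, xw, yw)
            assert np.max(np.abs(v - v0)) <= 1e-12
            assert np.max(np.abs(yhat - yhat0)) <= 1e-12

    def test_shape_mismatch(self):
        cfg = NarxConfig(m=1, d=2, n_hidden=2)
        w = random_weights(cfg)
        with pytest.raises(StructureError):
            forward_step(w, cfg, np.zeros((2, 2)), np.zeros((2, 2)))

    def test_sign_absorption_regression(self):
        """Negating c and flipping the c-term sign must reproduce outputs:
        proves the printed minus sign is implemented, not silently absorbed."""
        cfg = NarxConfig(m=1, d=3, n_hidden=4)
        w = random_weights(cfg, seed=3)
        r = np.random.default_rng(3)
        xw = r.normal(0, 1, (2, 4))
        yw = r.normal(0, 1, (2, 3))
        _, yhat = forward_step(w, cfg, xw, yw)
        flipped = NarxWeights(a=w.a, c=-w.c, w=w.w, b1=w.b1, b2=w.b2)
        # with negated c, feeding -y through the + convention must agree
        z = (
            np.einsum("niq,iq->n", flipped.a, xw)
            + np.einsum("njq,jq->n", flipped.c, yw)  # explicit plus on -c
            + flipped.b1
        )
        yhat2 = flipped.w @ np.tanh(z) + flipped.b2
        assert np.allclose(yhat, yhat2, atol=1e-14)


class TestBatchAndDesign:
    def test_batch_matches_stepwise(self):
        cfg = NarxConfig(m=2, d=3, n_hidden=5)
        w = random_weights(cfg, seed=11)
        r = np.random.default_rng(11)
        xn = r.normal(0, 1, (40, 2))
        yn = r.normal(0, 1, (40, 2))
        features, idx, targets = build_design(xn, yn, cfg)
        _, yhat = forward_batch(w, features)
        for row, t_pred in enumerate(idx):
            t = t_pred - cfg.m
            xw = xn[t - cfg.d : t + 1][::-1].T
            yw = yn[t - cfg.d : t][::-1].T
            _, expect = forward_step(w, cfg, xw, yw)
            assert np.allclose(yhat[row], expect, atol=1e-12)

    def test_too_short(self):
        cfg = NarxConfig(m=3, d=4, n_hidden=2)
        with pytest.raises(LengthError):
            build_design(np.zeros((7, 2)), np.zeros((7, 2)), cfg)


class TestNormalizer:
    def _trial(self, x, y):
        return ProcessedTrial(trial_id="t", condition="LW", x=x, y=y, events=())

    def test_affine_endpoints(self):
        x = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        y = np.column_stack([np.linspace(-10, 20, 50), np.linspace(0, 1, 50)])
        nm = fit_normalizer([self._trial(x, y)])
        mapped = nm.norm_y(np.array([[-10.0, 0.0], [20.0, 1.0], [5.0, 0.5]]))
        assert mapped[:, 0] == pytest.approx([-1.0, 1.0, 0.0])

    def test_union_of_two_trials(self):
        x1 = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 1, 10)])
        y1 = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 1, 10)])
        y2 = np.column_stack([np.linspace(5, 9, 10), np.linspace(2, 3, 10)])
        nm = fit_normalizer([self._trial(x1, y1), self._trial(x1, y2)])
        assert nm.y_min[0] == 0.0 and nm.y_max[0] == 9.0

    def test_round_trip_1000_samples(self, rng):
        x = rng.normal(0, 5, (500, 2))
        y = rng.normal(0, 5, (500, 2))
        nm = fit_normalizer([self._trial(x, y)])
        samples = rng.normal(0, 20, (1000, 2))
        assert np.max(np.abs(nm.denorm_y(nm.norm_y(samples)) - samples)) < 1e-12
        assert np.max(np.abs(nm.denorm_x(nm.norm_x(samples)) - samples)) < 1e-12

    def test_degenerate_channel(self):
        x = np.column_stack([np.ones(10), np.linspace(0, 1, 10)])
        y = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 1, 10)])
        with pytest.raises(DegenerateRangeError):
            fit_normalizer([self._trial(x, y)])


def _identity_normalizer():
    return MinMaxNormalizer(
        x_min=np.array([-1.0, -1.0]),
        x_max=np.array([1.0, 1.0]),
        y_min=np.array([-1.0, -1.0]),
        y_max=np.array([1.0, 1.0]),
    )


class TestPredictTrial:
    def test_single_valid_prediction(self):
        cfg = NarxConfig(m=2, d=3, n_hidden=2)
        w = random_weights(cfg, seed=1, scale=0.1)
        r = np.random.default_rng(0)
        n = cfg.d + cfg.m + 1
        trial = ProcessedTrial(
            trial_id="t",
            condition="LW",
            x=r.normal(0, 0.5, (n, 2)),
            y=r.normal(0, 0.5, (n, 2)),
            events=(),
        )
        trace = predict_trial(w, cfg, _identity_normalizer(), trial)
        assert len(trace.valid_index) == 1
        assert np.isfinite(trace.predictions[trace.valid_index]).all()
        assert np.isnan(trace.predictions[: cfg.d + cfg.m]).all()

    def test_open_loop_no_future_leakage(self):
        """Altering targets beyond the designed windows must not change the
        prediction at a given time."""
        cfg = NarxConfig(m=3, d=2, n_hidden=4)
        w = random_weights(cfg, seed=5, scale=0.2)
        r = np.random.default_rng(5)
        y = r.normal(0, 0.5, (60, 2))
        x = r.normal(0, 0.5, (60, 2))
        trial = ProcessedTrial("t", "LW", x, y, ())
        trace = predict_trial(w, cfg, _identity_normalizer(), trial)
        t_check = 30  # prediction index; built from inputs up to t_check - m
        y2 = y.copy()
        y2[t_check - cfg.m :] += r.normal(0, 5, y2[t_check - cfg.m :].shape)
        trial2 = ProcessedTrial("t", "LW", x, y2, ())
        trace2 = predict_trial(w, cfg, _identity_normalizer(), trial2)
        assert trace2.predictions[t_check] == pytest.approx(
            trace.predictions[t_check], abs=1e-12
        )

    def test_too_short_trial(self):
        cfg = NarxConfig(m=2, d=3, n_hidden=2)
        w = random_weights(cfg)
        trial = ProcessedTrial("t", "LW", np.zeros((5, 2)), np.zeros((5, 2)), ())
        with pytest.raises(LengthError):
            predict_trial(w, cfg, _identity_normalizer(), trial)


class TestInitWeights:
    def test_deterministic(self):
        cfg = NarxConfig(m=7, d=4, n_hidden=6)
        w1, w2 = init_weights(cfg, 3), init_weights(cfg, 3)
        assert np.array_equal(w1.a, w2.a) and np.array_equal(w1.w, w2.w)

    def test_ten_distinct_seeds(self):
        cfg = NarxConfig(m=7, d=4, n_hidden=6)
        mats = [init_weights(cfg, s).a for s in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                assert not np.array_equal(mats[i], mats[j])

    def test_preactivations_in_active_region(self, full_session):
        """On normalized data, >= 95% of initial hidden pre-activations should
        sit inside tanh's active region (|z| < 3)."""
        cfg = NarxConfig(m=7, d=10, n_hidden=8)
        nm = fit_normalizer(full_session[:8])
        trial = full_session[0]
        features, _, _ = build_design(nm.norm_x(trial.x), nm.norm_y(trial.y), cfg)
        frac = []
        for seed in range(5):
            w = init_weights(cfg, seed)
            z = features @ w.hidden_matrix().T + w.b1
            frac.append(np.mean(np.abs(z) < 3.0))
        assert np.mean(frac) >= 0.95


class TestSerialization:
    def test_bit_exact_round_trip(self):
        cfg = NarxConfig(m=7, d=5, n_hidden=4)
        w = random_weights(cfg, seed=9)
        nm = MinMaxNormalizer(
            x_min=np.array([0.0, 0.1]),
            x_max=np.array([1.0, 0.9]),
            y_min=np.array([-20.0, -0.2]),
            y_max=np.array([15.0, 1.5]),
        )
        doc = json.loads(json.dumps(model_to_dict(w, cfg, nm)))
        w2, cfg2, nm2 = model_from_dict(doc)
        assert cfg2 == cfg
        for name in ("a", "c", "w", "b1", "b2"):
            assert np.array_equal(getattr(w, name), getattr(w2, name))
        assert np.array_equal(nm.y_min, nm2.y_min)

    def test_unknown_schema_rejected(self):
        with pytest.raises(ConfigError):
            model_from_dict({"schema_version": 99})
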