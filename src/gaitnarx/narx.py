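"""Feedforward (open-loop) multiple-input multiple-output NARX network.

The network maps tapped-delay-line windows of two exogenous EMG envelopes
``x_i`` and two measured targets ``y_j`` (angle, moment) onto predictions of
both targets ``m`` time steps ahead:

    v_n(t+m)    = tanh( sum_{q=0..d} sum_i a[n,i,q] x_i(t-q)
                        - sum_{q=1..d} sum_j c[n,j,q] y_j(t-q) + b1[n] )
    yhat_j(t+m) = sum_n w[j,n] v_n(t+m) + b2[j]

Note the deliberate asymmetry: the exogenous window includes the current
sample (q = 0) while the feedback window holds past targets only (q = 1..d),
and the feedback term enters with a minus sign.  Both are preserved exactly;
see the sign-absorption regression test.

"Open loop" means the fed-back targets are always the *measured* series, never
the network's own predictions.  All training and inference happens in a
min-max normalized space mapping each channel to [-1, 1].
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    ConfigError,
    DegenerateRangeError,
    LengthError,
    NumericError,
    StructureError,
)
from .trials import FS, ProcessedTrial

__all__ = [
    "NarxConfig",
    "NarxWeights",
    "MinMaxNormalizer",
    "PredictionTrace",
    "steps_from_ms",
    "init_weights",
    "fit_normalizer",
    "forward_step",
    "forward_batch",
    "build_design",
    "predict_trial",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

MODEL_SCHEMA_VERSION = 1

#: Channel labels in normalizer order.
X_CHANNELS = ("emg_ta", "emg_gm")
Y_CHANNELS = ("angle", "moment")


def steps_from_ms(interval_ms: float, dt: float = 1.0 / FS) -> int:
    """Convert a millisecond interval to discrete time steps at ``dt``.

    Nearest-integer rounding with a floor of one step; 58 ms at 120 Hz maps
    to 7 steps and the shortest 8 ms sampling window maps to 1 step.
    """
    if interval_ms <= 0:
        raise ConfigError(f"interval must be positive, got {interval_ms} ms")
    return max(1, int(round(interval_ms / 1000.0 / dt)))


@dataclass(frozen=True)
class NarxConfig:
    """Structural hyperparameters of the network.

    Parameters
    ----------
    m : int
        Prediction interval in time steps (tau = m * dt).
    d : int
        Sampling window length in time steps (D = d * dt).
    n_hidden : int
        Number of tanh units in the hidden layer.
    dt : float
        Sample period in seconds (1/120 by default).
    """

    m: int
    d: int
    n_hidden: int
    dt: float = 1.0 / FS

    def __post_init__(self) -> None:
        if self.m < 1 or self.d < 1 or self.n_hidden < 1:
            raise ConfigError(
                f"m, d and n_hidden must all be >= 1 (got m={self.m}, "
                f"d={self.d}, n_hidden={self.n_hidden})"
            )
        if self.dt <= 0:
            raise ConfigError("dt must be positive")

    @property
    def tau_s(self) -> float:
        """Prediction interval in seconds."""
        return self.m * self.dt

    @property
    def window_s(self) -> float:
        """Sampling window span in seconds."""
        return self.d * self.dt

    @property
    def n_features(self) -> int:
        """Length of one flattened delay-line feature row."""
        return 2 * (self.d + 1) + 2 * self.d


@dataclass
class NarxWeights:
    """All trainable parameters.

    Index order follows the forward equations: ``a[n, i, q]`` with q = 0..d,
    ``c[n, j, q-1]`` with q = 1..d, ``w[j, n]``, ``b1[n]``, ``b2[j]``.
    """

    a: np.ndarray
    c: np.ndarray
    w: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def validate(self, config: NarxConfig) -> None:
        n, d = config.n_hidden, config.d
        shapes = {
            "a": (self.a.shape, (n, 2, d + 1)),
            "c": (self.c.shape, (n, 2, d)),
            "w": (self.w.shape, (2, n)),
            "b1": (self.b1.shape, (n,)),
            "b2": (self.b2.shape, (2,)),
        }
        for name, (got, want) in shapes.items():
            if got != want:
                raise StructureError(f"weight {name}: shape {got}, expected {want}")
        for name in shapes:
            if not np.all(np.isfinite(getattr(self, name))):
                raise NumericError(f"weight {name} contains non-finite values")

    def hidden_matrix(self) -> np.ndarray:
        """Hidden-layer weights as (N, K) with the feedback sign baked into
        the feature layout (features carry -y)."""
        n = self.a.shape[0]
        return np.hstack([self.a.reshape(n, -1), self.c.reshape(n, -1)])

    def copy(self) -> "NarxWeights":
        return NarxWeights(
            self.a.copy(), self.c.copy(), self.w.copy(), self.b1.copy(), self.b2.copy()
        )


def init_weights(config: NarxConfig, seed) -> NarxWeights:
    """Seeded layer-wise scaled uniform initialization.

    Uniform in +-sqrt(3 / fan_in) per layer so that, on [-1, 1] normalized
    inputs, hidden pre-activations land mostly in tanh's active region.
    ``seed`` may be an int or a tuple of ints.
    """
    rng = np.random.default_rng(seed)
    n, d = config.n_hidden, config.d
    lim_h = np.sqrt(3.0 / config.n_features)
    a = rng.uniform(-lim_h, lim_h, (n, 2, d + 1))
    c = rng.uniform(-lim_h, lim_h, (n, 2, d))
    b1 = rng.uniform(-lim_h, lim_h, n)
    lim_o = np.sqrt(3.0 / n)
    w = rng.uniform(-lim_o, lim_o, (2, n))
    b2 = rng.uniform(-lim_o, lim_o, 2)
    return NarxWeights(a=a, c=c, w=w, b1=b1, b2=b2)


@dataclass(frozen=True)
class MinMaxNormalizer:
    """Per-channel min-max map to [-1, 1], fitted on a pooled training set.

    Validation/test samples are mapped with the same affine map and may fall
    outside [-1, 1]; they are passed through unclipped (tanh saturates
    gracefully).
    """

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: np.ndarray
    y_max: np.ndarray

    @classmethod
    def from_trials(cls, trials: list[ProcessedTrial]) -> "MinMaxNormalizer":
        if not trials:
            raise LengthError("need at least one trial to fit the normalizer")
        x = np.concatenate([t.x for t in trials], axis=0)
        y = np.concatenate([t.y for t in trials], axis=0)
        x_min, x_max = x.min(axis=0), x.max(axis=0)
        y_min, y_max = y.min(axis=0), y.max(axis=0)
        for names, lo, hi in ((X_CHANNELS, x_min, x_max), (Y_CHANNELS, y_min, y_max)):
            for k, name in enumerate(names):
                if not hi[k] > lo[k]:
                    raise DegenerateRangeError(
                        f"channel {name!r} is constant across the training set"
                    )
        return cls(x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max)

    @staticmethod
    def _fwd(v: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return 2.0 * (v - lo) / (hi - lo) - 1.0

    @staticmethod
    def _inv(v: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return (v + 1.0) * (hi - lo) / 2.0 + lo

    def norm_x(self, x: np.ndarray) -> np.ndarray:
        return self._fwd(np.asarray(x, dtype=float), self.x_min, self.x_max)

    def norm_y(self, y: np.ndarray) -> np.ndarray:
        return self._fwd(np.asarray(y, dtype=float), self.y_min, self.y_max)

    def denorm_y(self, yn: np.ndarray) -> np.ndarray:
        return self._inv(np.asarray(yn, dtype=float), self.y_min, self.y_max)

    def denorm_x(self, xn: np.ndarray) -> np.ndarray:
        return self._inv(np.asarray(xn, dtype=float), self.x_min, self.x_max)


def fit_normalizer(training_trials: list[ProcessedTrial]) -> MinMaxNormalizer:
    """Fit the [-1, 1] min-max map on pooled training trials only."""
    return MinMaxNormalizer.from_trials(training_trials)


def forward_step(
    weights: NarxWeights,
    config: NarxConfig,
    x_window: np.ndarray,
    y_window: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the network for one time step in normalized space.

    Parameters
    ----------
    x_window : ndarray, shape (2, d+1)
        ``x_window[i, q] = x_i(t - q)`` for q = 0..d (current sample included).
    y_window : ndarray, shape (2, d)
        ``y_window[j, q-1] = y_j(t - q)`` for q = 1..d (past targets only).

    Returns
    -------
    v : ndarray, shape (N,)
        Hidden unit outputs.
    yhat : ndarray, shape (2,)
        Normalized predictions for time t + m.
    """
    weights.validate(config)
    x_window = np.asarray(x_window, dtype=float)
    y_window = np.asarray(y_window, dtype=float)
    if x_window.shape != (2, config.d + 1):
        raise StructureError(
            f"x_window shape {x_window.shape}, expected (2, {config.d + 1})"
        )
    if y_window.shape != (2, config.d):
        raise StructureError(f"y_window shape {y_window.shape}, expected (2, {config.d})")
    if not (np.all(np.isfinite(x_window)) and np.all(np.isfinite(y_window))):
        raise NumericError("non-finite values in input windows")
    z = (
        np.einsum("niq,iq->n", weights.a, x_window)
        - np.einsum("njq,jq->n", weights.c, y_window)
        + weights.b1
    )
    v = np.tanh(z)
    yhat = weights.w @ v + weights.b2
    return v, yhat


def forward_batch(
    weights: NarxWeights, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward pass over pre-built feature rows.

    ``features`` rows are laid out as ``[x windows | -y windows]`` (see
    :func:`build_design`), so the printed minus sign on the feedback term is
    realized by the feature sign, not by negated weights.
    """
    z = features @ weights.hidden_matrix().T + weights.b1
    v = np.tanh(z)
    yhat = v @ weights.w.T + weights.b2
    return v, yhat


def build_design(
    xn: np.ndarray, yn: np.ndarray, config: NarxConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build delay-line feature rows for every valid prediction time.

    Valid base times are t = d .. T-1-m; the prediction produced from the
    window at t scores against the target at t + m.  Windows never extend
    across the ends of the series, so callers that concatenate trials must
    build one design per trial.

    Returns
    -------
    features : ndarray, shape (S, 2*(d+1) + 2*d)
        Row r corresponds to base time t = r + d; layout
        ``[x_0(t..t-d), x_1(t..t-d), -y_0(t-1..t-d), -y_1(t-1..t-d)]``.
    predict_index : ndarray, shape (S,)
        Target/sample indices t + m of each row's prediction.
    targets : ndarray, shape (S, 2)
        ``yn`` at ``predict_index``.
    """
    xn = np.asarray(xn, dtype=float)
    yn = np.asarray(yn, dtype=float)
    n = len(xn)
    d, m = config.d, config.m
    s = n - d - m
    if s < 1:
        raise LengthError(
            f"trial of length {n} too short for d={d}, m={m} (needs > d + m samples)"
        )
    xw = sliding_window_view(xn, d + 1, axis=0)[:s, :, ::-1]  # (S, 2, d+1), q=0..d
    yw = sliding_window_view(yn, d, axis=0)[:s, :, ::-1]  # (S, 2, d), q=1..d
    features = np.concatenate(
        [xw.reshape(s, -1), -yw.reshape(s, -1)], axis=1
    )
    predict_index = np.arange(d + m, n)
    return features, predict_index, yn[predict_index]


@dataclass
class PredictionTrace:
    """Open-loop predictions over one trial, on the target time base.

    ``predictions[t]`` is the network output for sample t computed from
    inputs up to t - m; entries outside ``valid_index`` (the first d + m
    samples) are NaN.  Scoring is a same-index comparison against the trial's
    measured targets at ``valid_index``.
    """

    predictions: np.ndarray
    valid_index: np.ndarray
    hidden: np.ndarray | None = None


def predict_trial(
    weights: NarxWeights,
    config: NarxConfig,
    normalizer: MinMaxNormalizer,
    trial: ProcessedTrial,
    return_hidden: bool = False,
) -> PredictionTrace:
    """Run the open-loop network over a trial; outputs in physical units.

    The feedback windows are drawn from the *measured* target history of the
    trial (open-loop contract) after mapping through ``normalizer``.
    """
    weights.validate(config)
    xn = normalizer.norm_x(trial.x)
    yn = normalizer.norm_y(trial.y)
    features, predict_index, _ = build_design(xn, yn, config)
    v, yhat_n = forward_batch(weights, features)
    predictions = np.full((trial.n_samples, 2), np.nan)
    predictions[predict_index] = normalizer.denorm_y(yhat_n)
    return PredictionTrace(
        predictions=predictions,
        valid_index=predict_index,
        hidden=v if return_hidden else None,
    )


# ---------------------------------------------------------------------------
# Serialization: one versioned JSON document holding config + normalizer +
# weights with explicit index order.  json round-trips Python floats exactly
# (repr-based), so the round trip is bit-exact.
# ---------------------------------------------------------------------------


def model_to_dict(
    weights: NarxWeights,
    config: NarxConfig,
    normalizer: MinMaxNormalizer,
    extra: dict | None = None,
) -> dict:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": {
            "m": config.m,
            "d": config.d,
            "n_hidden": config.n_hidden,
            "dt": config.dt,
        },
        "normalizer": {
            "x_min": normalizer.x_min.tolist(),
            "x_max": normalizer.x_max.tolist(),
            "y_min": normalizer.y_min.tolist(),
            "y_max": normalizer.y_max.tolist(),
        },
        "weights": {
            # index order: a[n][i][q], c[n][j][q-1], w[j][n]
            "a": weights.a.tolist(),
            "c": weights.c.tolist(),
            "w": weights.w.tolist(),
            "b1": weights.b1.tolist(),
            "b2": weights.b2.tolist(),
        },
    }
    if extra:
        doc["meta"] = extra
    return doc


def model_from_dict(doc: dict) -> tuple[NarxWeights, NarxConfig, MinMaxNormalizer]:
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    cfg = doc["config"]
    config = NarxConfig(m=cfg["m"], d=cfg["d"], n_hidden=cfg["n_hidden"], dt=cfg["dt"])
    nrm = doc["normalizer"]
    normalizer = MinMaxNormalizer(
        x_min=np.asarray(nrm["x_min"], dtype=float),
        x_max=np.asarray(nrm["x_max"], dtype=float),
        y_min=np.asarray(nrm["y_min"], dtype=float),
        y_max=np.asarray(nrm["y_max"], dtype=float),
    )
    wts = doc["weights"]
    weights = NarxWeights(
        a=np.asarray(wts["a"], dtype=float),
        c=np.asarray(wts["c"], dtype=float),
        w=np.asarray(wts["w"], dtype=float),
        b1=np.asarray(wts["b1"], dtype=float),
        b2=np.asarray(wts["b2"], dtype=float),
    )
    weights.validate(config)
    return weights, config, normalizer


def save_model(path, weights, config, normalizer, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(weights, config, normalizer, extra), fh, indent=1)


def load_model(path) -> tuple[NarxWeights, NarxConfig, MinMaxNormalizer]:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
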