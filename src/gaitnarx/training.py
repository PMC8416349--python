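"""Levenberg-Marquardt supervised training with the trial-blocked fold protocol.

Training minimizes the mean squared error between network predictions and
targets with both channels mapped to [-1, 1] (errors bounded to [-2, 2]), so
angle and moment are fitted equally.  Trials form a concurrent set of
sequences: delay-line windows never cross trial boundaries, avoiding the
artificial discontinuities that concatenation would introduce.

The LM loop runs on the full training batch with an analytic Jacobian and the
classic damping schedule (lambda x10 on a rejected step, /10 on an accepted
one, identity-scaled).  Stopping: error goal reached, validation patience
exhausted, lambda overflow (recorded as ``converged``), or the epoch cap.
The returned weights are those of the epoch with the best validation MSE,
never simply the last epoch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .errors import FoldError, LengthError, NumericError, TrainingError
from .narx import (
    MinMaxNormalizer,
    NarxConfig,
    NarxWeights,
    build_design,
    fit_normalizer,
    forward_batch,
    init_weights,
    predict_trial,
)
from .trials import CONDITIONS, ProcessedTrial, group_by_condition

__all__ = [
    "TrainingConfig",
    "FoldPartition",
    "TrainingHistory",
    "TrainedModel",
    "make_folds",
    "normalized_mse",
    "moment_variance_error_goal",
    "train_network",
    "train_with_restarts",
]

_TRAIN_PER_CONDITION = 8
_VAL_PER_CONDITION = 2


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and protocol controls.

    ``error_goal`` is either a normalized-MSE threshold (0 trains to
    patience/max_epochs) or the string ``"moment1pct"`` selecting 1% of the
    pooled normalized moment variance of the fold's non-test trials.
    """

    error_goal: float | str = 0.0
    max_epochs: int = 1000
    restarts: int = 10
    val_patience: int = 6
    lm_lambda_init: float = 1e-3
    lm_lambda_up: float = 10.0
    lm_lambda_down: float = 10.0
    lm_lambda_max: float = 1e10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.max_epochs < 1:
            raise FoldError("restarts and max_epochs must be >= 1")
        if min(self.lm_lambda_init, self.lm_lambda_up, self.lm_lambda_down) <= 0:
            raise FoldError("LM damping controls must be positive")


@dataclass(frozen=True)
class FoldPartition:
    """Whole-trial split for one fold: per condition 8 train / 2 val / 1 test."""

    fold_index: int
    train: dict
    val: dict
    test: dict

    def ids(self, part: str) -> list[str]:
        mapping = getattr(self, part)
        out: list[str] = []
        for cond in CONDITIONS:
            out.extend(mapping.get(cond, ()))
        return out

    def trials(self, session, part: str) -> list[ProcessedTrial]:
        wanted = set(self.ids(part))
        return [t for t in session if t.trial_id in wanted]


@dataclass
class TrainingHistory:
    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    lm_lambda: list = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1


@dataclass
class TrainedModel:
    """A trained network with everything needed to run and audit it."""

    weights: NarxWeights
    config: NarxConfig
    normalizer: MinMaxNormalizer
    history: TrainingHistory
    fold_index: int
    seed: object
    restart_scores: list = field(default_factory=list)


def make_folds(session, n_folds: int = 10, seed: int = 0) -> list[FoldPartition]:
    """Trial-blocked leave-one-out folds.

    Per condition, ``n_folds`` designated trials each serve as the held-out
    novel test trial in exactly one fold; the remaining 10 trials are
    shuffled once per fold (seeded) and split into contiguous blocks of
    8 training and 2 validation trials.  Splits always operate on whole
    trials, never on samples.
    """
    by_cond = group_by_condition(session)
    if not by_cond:
        raise FoldError("empty session")
    for cond, trials in by_cond.items():
        if len(trials) < 11:
            raise FoldError(
                f"condition {cond}: {len(trials)} trials < 11 needed for the "
                "8 train / 2 validation / 1 test per-condition split"
            )
        if n_folds > len(trials) - 1:
            raise FoldError(
                f"condition {cond}: cannot designate {n_folds} test trials "
                f"from {len(trials)} while keeping 10 for the 8/2 split"
            )
    rng = np.random.default_rng(seed)
    test_pool: dict[str, list[str]] = {}
    for cond in CONDITIONS:
        if cond not in by_cond:
            continue
        ids = [t.trial_id for t in by_cond[cond]]
        perm = rng.permutation(len(ids))
        test_pool[cond] = [ids[i] for i in perm[:n_folds]]
    folds = []
    for f in range(n_folds):
        train: dict[str, tuple] = {}
        val: dict[str, tuple] = {}
        test: dict[str, tuple] = {}
        for ci, cond in enumerate(CONDITIONS):
            if cond not in by_cond:
                continue
            ids = [t.trial_id for t in by_cond[cond]]
            test_id = test_pool[cond][f]
            remaining = [i for i in ids if i != test_id]
            rng_f = np.random.default_rng((seed, f, ci))
            order = [remaining[i] for i in rng_f.permutation(len(remaining))]
            train[cond] = tuple(order[:_TRAIN_PER_CONDITION])
            val[cond] = tuple(
                order[_TRAIN_PER_CONDITION : _TRAIN_PER_CONDITION + _VAL_PER_CONDITION]
            )
            test[cond] = (test_id,)
        folds.append(FoldPartition(fold_index=f, train=train, val=val, test=test))
    return folds


def normalized_mse(
    predictions: np.ndarray,
    targets: np.ndarray,
    normalizer: MinMaxNormalizer,
) -> float:
    """MSE on [-1, 1]-mapped values, averaged over both output channels."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape or predictions.size == 0:
        raise LengthError("predictions and targets must be non-empty and aligned")
    err = normalizer.norm_y(predictions) - normalizer.norm_y(targets)
    return float(np.mean(err**2))


def moment_variance_error_goal(trials, normalizer: MinMaxNormalizer) -> float:
    """1% of the pooled normalized moment variance over the given trials."""
    if not trials:
        raise LengthError("need at least one trial")
    pooled = np.concatenate([normalizer.norm_y(t.y)[:, 1] for t in trials])
    return 0.01 * float(np.var(pooled))


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core
# ---------------------------------------------------------------------------


def _assemble(trials, config: NarxConfig, normalizer: MinMaxNormalizer):
    """Per-trial delay-line designs concatenated into one batch."""
    feats, targs = [], []
    for t in trials:
        f, _, y = build_design(normalizer.norm_x(t.x), normalizer.norm_y(t.y), config)
        feats.append(f)
        targs.append(y)
    return np.concatenate(feats, axis=0), np.concatenate(targs, axis=0)


def _pack(weights: NarxWeights) -> np.ndarray:
    return np.concatenate(
        [
            weights.hidden_matrix().ravel(),
            weights.w.ravel(),
            weights.b1,
            weights.b2,
        ]
    )


def _unpack(theta: np.ndarray, config: NarxConfig) -> NarxWeights:
    n, d = config.n_hidden, config.d
    k = config.n_features
    kx = 2 * (d + 1)
    hidden = theta[: n * k].reshape(n, k)
    off = n * k
    w = theta[off : off + 2 * n].reshape(2, n)
    off += 2 * n
    b1 = theta[off : off + n]
    b2 = theta[off + n : off + n + 2]
    return NarxWeights(
        a=hidden[:, :kx].reshape(n, 2, d + 1).copy(),
        c=hidden[:, kx:].reshape(n, 2, d).copy(),
        w=w.copy(),
        b1=b1.copy(),
        b2=b2.copy(),
    )


def _loss_and_state(theta, config, features, targets):
    weights = _unpack(theta, config)
    v, yhat = forward_batch(weights, features)
    resid = yhat - targets  # (S, 2)
    loss = float(np.mean(resid**2))
    return loss, resid, v, weights


def _jacobian(weights: NarxWeights, features, v):
    """Analytic Jacobian of the stacked residual vector [r_j=0; r_j=1].

    Column order matches :func:`_pack`: hidden matrix (N*K), output weights
    (w[0], w[1]), hidden biases, output biases.
    """
    s, k = features.shape
    n = v.shape[1]
    g = 1.0 - v**2  # tanh'
    p = n * k + 2 * n + n + 2
    jac = np.zeros((2 * s, p))
    for j in range(2):
        wg = g * weights.w[j]  # (S, N)
        block = slice(j * s, (j + 1) * s)
        jac[block, : n * k] = np.einsum("sn,sk->snk", wg, features).reshape(s, n * k)
        jac[block, n * k + j * n : n * k + (j + 1) * n] = v
        jac[block, n * k + 2 * n : n * k + 3 * n] = wg
        jac[block, n * k + 3 * n + j] = 1.0
    return jac


def _lm_fit(
    config: NarxConfig,
    features,
    targets,
    val_features,
    val_targets,
    tconfig: TrainingConfig,
    seed,
    error_goal: float,
) -> tuple[NarxWeights, TrainingHistory]:
    theta = _pack(init_weights(config, seed))
    history = TrainingHistory()
    loss, resid, v, weights = _loss_and_state(theta, config, features, targets)
    if not np.isfinite(loss):
        raise NumericError("non-finite loss at initialization")
    lam = tconfig.lm_lambda_init
    best_val = np.inf
    best_theta = theta.copy()
    since_best = 0
    stop = ""
    n_params = len(theta)
    eye = np.eye(n_params)
    for epoch in range(tconfig.max_epochs):
        jac = _jacobian(weights, features, v)
        r_flat = np.concatenate([resid[:, 0], resid[:, 1]])
        grad = jac.T @ r_flat
        hess = jac.T @ jac
        accepted = False
        while lam <= tconfig.lm_lambda_max:
            try:
                cho = cho_factor(hess + lam * eye, lower=True)
                delta = cho_solve(cho, -grad)
            except LinAlgError:
                lam *= tconfig.lm_lambda_up
                continue
            loss_new, resid_new, v_new, weights_new = _loss_and_state(
                theta + delta, config, features, targets
            )
            if np.isfinite(loss_new) and loss_new < loss:
                theta = theta + delta
                loss, resid, v, weights = loss_new, resid_new, v_new, weights_new
                lam = max(lam / tconfig.lm_lambda_down, 1e-15)
                accepted = True
                break
            lam *= tconfig.lm_lambda_up
        if not accepted:
            stop = "converged"
            break
        _, val_yhat = forward_batch(weights, val_features)
        val_loss = float(np.mean((val_yhat - val_targets) ** 2))
        history.train_mse.append(loss)
        history.val_mse.append(val_loss)
        history.lm_lambda.append(lam)
        if val_loss < best_val:
            best_val = val_loss
            best_theta = theta.copy()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if loss <= error_goal:
            stop = "error_goal"
            break
        if since_best >= tconfig.val_patience:
            stop = "patience"
            break
    history.stop_reason = stop or "max_epochs"
    if history.best_epoch < 0:  # no epoch recorded (immediate convergence)
        best_theta = theta
    return _unpack(best_theta, config), history


def _resolve_error_goal(tconfig: TrainingConfig, trials, normalizer) -> float:
    if tconfig.error_goal == "moment1pct":
        return moment_variance_error_goal(trials, normalizer)
    goal = float(tconfig.error_goal)  # type: ignore[arg-type]
    if goal < 0:
        raise FoldError("error_goal must be >= 0")
    return goal


def train_network(
    session,
    fold: FoldPartition,
    config: NarxConfig,
    tconfig: TrainingConfig,
    restart_seed=None,
) -> TrainedModel:
    """Train one network on a fold's training trials.

    The normalizer is fitted on the fold's training trials only; the error
    goal (when the 1%-of-moment-variance rule is selected) is computed from
    the fold's train + validation trials, so the held-out test trial touches
    nothing.
    """
    train_trials = fold.trials(session, "train")
    val_trials = fold.trials(session, "val")
    if not train_trials or not val_trials:
        raise FoldError(f"fold {fold.fold_index}: empty train or validation set")
    normalizer = fit_normalizer(train_trials)
    goal = _resolve_error_goal(tconfig, train_trials + val_trials, normalizer)
    features, targets = _assemble(train_trials, config, normalizer)
    val_features, val_targets = _assemble(val_trials, config, normalizer)
    seed = restart_seed if restart_seed is not None else (tconfig.seed, fold.fold_index)
    weights, history = _lm_fit(
        config, features, targets, val_features, val_targets, tconfig, seed, goal
    )
    return TrainedModel(
        weights=weights,
        config=config,
        normalizer=normalizer,
        history=history,
        fold_index=fold.fold_index,
        seed=seed,
    )


def _selection_score(model: TrainedModel, session, fold: FoldPartition) -> float:
    """Mean over conditions of the normalized MSE on train + validation
    trials (the novel test trial stays untouched until evaluation)."""
    by_cond: dict[str, list[float]] = {}
    for part in ("train", "val"):
        for trial in fold.trials(session, part):
            trace = predict_trial(model.weights, model.config, model.normalizer, trial)
            idx = trace.valid_index
            err = model.normalizer.norm_y(trace.predictions[idx]) - model.normalizer.norm_y(
                trial.y[idx]
            )
            by_cond.setdefault(trial.condition, []).extend((err**2).ravel())
    return float(np.mean([np.mean(v) for v in by_cond.values()]))


def train_with_restarts(
    session,
    fold: FoldPartition,
    config: NarxConfig,
    tconfig: TrainingConfig,
) -> TrainedModel:
    """Train ``tconfig.restarts`` networks from different seeded initial
    weights and return the one with the lowest per-condition-averaged MSE."""
    models, scores = [], []
    for r in range(tconfig.restarts):
        try:
            model = train_network(
                session, fold, config, tconfig, restart_seed=(tconfig.seed, fold.fold_index, r)
            )
        except NumericError:
            models.append(None)
            scores.append(np.inf)
            continue
        models.append(model)
        scores.append(_selection_score(model, session, fold))
    if not np.isfinite(np.min(scores)):
        raise TrainingError(
            f"fold {fold.fold_index}: all {tconfig.restarts} restarts failed"
        )
    best = int(np.argmin(scores))
    chosen = models[best]
    assert chosen is not None
    chosen.restart_scores = [float(s) for s in scores]
    return chosen
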