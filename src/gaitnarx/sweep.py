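"""Hyperparameter characterization over prediction interval, sampling window
and hidden-unit count, optimal (window, hidden) selection at a fixed
prediction interval, and the zero-error-goal re-training that produces the
optimized subject-specific networks.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigError, GaitNarxError, LengthError
from .narx import NarxConfig, predict_trial, steps_from_ms
from .trials import CONDITIONS
from .training import (
    TrainedModel,
    TrainingConfig,
    make_folds,
    train_with_restarts,
)

__all__ = [
    "SweepGrid",
    "DEFAULT_GRID",
    "REDUCED_GRID",
    "SweepResult",
    "run_sweep",
    "collapse_rmse",
    "regress_marginal",
    "select_optimal",
    "finalize_model",
]

_AXES = ("tau", "window", "hidden")


@dataclass(frozen=True)
class SweepGrid:
    """Grid of prediction intervals (ms), sampling windows (ms) and hidden
    unit counts; each list must be non-empty and strictly increasing."""

    tau_ms: tuple = (33, 42, 50, 58, 67, 75, 83, 108, 142)
    window_ms: tuple = (8, 17, 33, 50, 67, 83)
    hidden: tuple = (2, 4, 6, 8, 10, 12, 14, 16)

    def __post_init__(self) -> None:
        for name in ("tau_ms", "window_ms", "hidden"):
            vals = getattr(self, name)
            if not vals or any(b <= a for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"{name} must be non-empty and strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.tau_ms) * len(self.window_ms) * len(self.hidden)


DEFAULT_GRID = SweepGrid()
#: Desk-scale grid; the full 432-cell grid stays available behind a flag.
REDUCED_GRID = SweepGrid(tau_ms=(33, 58, 142), window_ms=(8, 33, 83), hidden=(2, 6, 12))


@dataclass
class SweepResult:
    """Per-cell test-trial errors, averaged across folds.

    ``rmse`` is indexed [tau][window][hidden][condition][output] in physical
    units (degrees, N*m/kg); ``test_mse`` is the normalized test MSE used for
    optimal-parameter selection.  Failed cells hold NaN and are listed in
    ``failures``.
    """

    grid: SweepGrid
    conditions: tuple
    rmse: np.ndarray
    test_mse: np.ndarray
    n_folds: int
    seed: int
    failures: list = field(default_factory=list)


def run_sweep(
    session,
    grid: SweepGrid,
    tconfig: TrainingConfig,
    n_folds: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Train (with restarts) and evaluate every grid cell on novel test trials.

    Deterministic under ``seed``: folds and every restart's initial weights
    derive from it.  A cell whose training fails is recorded in place and the
    sweep continues.
    """
    folds = make_folds(session, n_folds=n_folds, seed=seed)
    conditions = tuple(c for c in CONDITIONS if any(t.condition == c for t in session))
    shape = (len(grid.tau_ms), len(grid.window_ms), len(grid.hidden))
    rmse = np.full(shape + (len(conditions), 2), np.nan)
    test_mse = np.full(shape, np.nan)
    failures: list = []
    for it, tau in enumerate(grid.tau_ms):
        for iw, window in enumerate(grid.window_ms):
            for ih, hidden in enumerate(grid.hidden):
                config = NarxConfig(
                    m=steps_from_ms(tau), d=steps_from_ms(window), n_hidden=hidden
                )
                cell_t = replace(tconfig, seed=(seed, it, iw, ih))
                try:
                    cell_rmse, cell_mse = _evaluate_cell(
                        session, folds, config, cell_t, conditions
                    )
                except GaitNarxError as exc:
                    failures.append((tau, window, hidden, str(exc)))
                    continue
                rmse[it, iw, ih] = cell_rmse
                test_mse[it, iw, ih] = cell_mse
    return SweepResult(
        grid=grid,
        conditions=conditions,
        rmse=rmse,
        test_mse=test_mse,
        n_folds=n_folds,
        seed=seed,
        failures=failures,
    )


def _evaluate_cell(session, folds, config, tconfig, conditions):
    """Mean over folds of per-condition test RMSE and normalized test MSE."""
    rmse_acc = np.zeros((len(conditions), 2))
    mse_acc = 0.0
    for fold in folds:
        model = train_with_restarts(session, fold, config, tconfig)
        for ci, cond in enumerate(conditions):
            for trial in fold.trials(session, "test"):
                if trial.condition != cond:
                    continue
                trace = predict_trial(model.weights, model.config, model.normalizer, trial)
                idx = trace.valid_index
                err = trace.predictions[idx] - trial.y[idx]
                rmse_acc[ci] += np.sqrt(np.mean(err**2, axis=0)) / len(folds)
                err_n = model.normalizer.norm_y(trace.predictions[idx]) - model.normalizer.norm_y(
                    trial.y[idx]
                )
                mse_acc += float(np.mean(err_n**2)) / (len(folds) * len(conditions))
    return rmse_acc, mse_acc


def collapse_rmse(result: SweepResult, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Marginal RMSE curve along one parameter axis.

    Returns the axis values and an array of shape (len(axis), n_conditions, 2)
    holding the arithmetic mean across the two non-selected parameter axes.
    """
    if axis not in _AXES:
        raise ConfigError(f"axis must be one of {_AXES}")
    if np.isnan(result.rmse).any():
        missing = np.argwhere(np.isnan(result.rmse[..., 0, 0]))
        raise LengthError(f"sweep tensor incomplete; missing cells at {missing.tolist()}")
    keep = _AXES.index(axis)
    other = tuple(i for i in range(3) if i != keep)
    values = {
        "tau": result.grid.tau_ms,
        "window": result.grid.window_ms,
        "hidden": result.grid.hidden,
    }[axis]
    return np.asarray(values, dtype=float), result.rmse.mean(axis=other)


def regress_marginal(param_values, mean_rmse):
    """Ordinary least squares of mean RMSE on a parameter value.

    Returns (slope, intercept, r_squared, slope_p) where ``slope_p`` is the
    p-value of the zero-slope F-test (identical to the slope t-test in simple
    regression).
    """
    x = np.asarray(param_values, dtype=float)
    y = np.asarray(mean_rmse, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise LengthError("need at least 3 aligned points for the marginal fit")
    if np.ptp(y) == 0.0:  # constant response: zero slope, no explained variance
        return 0.0, float(y[0]), 0.0, 1.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(fit.pvalue)


def select_optimal(result: SweepResult, fixed_tau_ms: float = 58) -> tuple[int, int]:
    """(window_ms, hidden) minimizing normalized test MSE at the fixed
    prediction interval; ties break toward fewer hidden units, then the
    shorter window."""
    if fixed_tau_ms not in result.grid.tau_ms:
        raise ConfigError(
            f"fixed tau {fixed_tau_ms} ms not in sweep grid {result.grid.tau_ms}"
        )
    it = result.grid.tau_ms.index(fixed_tau_ms)
    best = None
    best_val = np.inf
    for hidden in sorted(result.grid.hidden):
        ih = result.grid.hidden.index(hidden)
        for window in sorted(result.grid.window_ms):
            iw = result.grid.window_ms.index(window)
            val = result.test_mse[it, iw, ih]
            if np.isfinite(val) and val < best_val:
                best_val = val
                best = (window, hidden)
    if best is None:
        raise LengthError("no finite cells at the fixed prediction interval")
    return best


def finalize_model(
    session,
    window_ms: int,
    n_hidden: int,
    tconfig: TrainingConfig,
    tau_ms: float = 58,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[list[TrainedModel], list]:
    """Re-train per fold at the fixed prediction interval and the selected
    (window, hidden) with an error goal of zero, so training runs to the
    validation-patience or epoch-cap stop to maximize performance."""
    config = NarxConfig(
        m=steps_from_ms(tau_ms), d=steps_from_ms(window_ms), n_hidden=n_hidden
    )
    folds = make_folds(session, n_folds=n_folds, seed=seed)
    tconfig0 = replace(tconfig, error_goal=0.0)
    models = [train_with_restarts(session, fold, config, tconfig0) for fold in folds]
    return models, folds
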