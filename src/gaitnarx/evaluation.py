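"""Performance measurement and statistics.

RMSE in physical units, cross-correlation-peak R-squared, instantaneous RMSE
over common-length trials, the constant-EMG ablation, critical-point
extraction with Shapiro-Wilk-gated paired tests, and the Benjamini-Hochberg
step-up correction.

Sign convention (configurable, recorded in every report): dorsiflexion
positive, so "maximum plantarflexion" is the angle minimum, and the
plantarflexion (push-off) moment peak is the moment maximum.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import DegenerateRangeError, EventError, LengthError
from .narx import predict_trial
from .sigproc import COMMON_LENGTHS, resample_to_length
from .trials import CONDITIONS, ProcessedTrial

__all__ = [
    "rmse",
    "xcorr_r2",
    "instantaneous_rmse",
    "constant_emg_inputs",
    "CriticalPointSpec",
    "default_critical_specs",
    "extract_critical_points",
    "critical_point_test",
    "benjamini_hochberg",
    "EvaluationReport",
    "build_report",
]

SIGN_CONVENTION = "dorsiflexion positive; plantarflexion moment positive"


def rmse(pred: np.ndarray, target: np.ndarray) -> float:
    """Root mean square error, in the channel's physical units."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.size == 0:
        raise LengthError("pred and target must be non-empty and the same shape")
    return float(np.sqrt(np.mean((pred - target) ** 2)))


def xcorr_r2(
    pred: np.ndarray, target: np.ndarray, max_lag: int | None = None
) -> tuple[float, int]:
    """Squared peak of the normalized cross-correlation, plus its lag.

    The correlation at lag k is the Pearson correlation between the
    overlapping segments after shifting ``pred`` by k samples (k > 0 means
    the prediction lags the target).  Each lag re-centers on its own overlap,
    so offsets and shapes are not conflated.  The peak is selected by
    magnitude before squaring.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    n = len(pred)
    if pred.shape != target.shape or n < 4:
        raise LengthError("pred and target must be equal-length 1-D with n >= 4")
    if max_lag is None:
        max_lag = n // 4
    if not 0 <= max_lag < n / 2:
        raise LengthError(f"max_lag={max_lag} must satisfy 0 <= max_lag < n/2")
    if np.ptp(pred) == 0.0 or np.ptp(target) == 0.0:
        raise DegenerateRangeError("correlation undefined for a constant series")
    best_r, best_lag = 0.0, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = pred[lag:], target[: n - lag]
        else:
            a, b = pred[: n + lag], target[-lag:]
        if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if abs(r) > abs(best_r):
            best_r, best_lag = r, lag
    return best_r**2, best_lag


def instantaneous_rmse(
    pred_trials, target_trials, common_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial RMSE at every common-time index.

    Trials are interpolated to ``common_length`` points first.  The mean
    curve is sqrt(mean across trials of squared error); the band curve is the
    across-trial sample standard deviation of the absolute error.
    """
    if len(pred_trials) < 2 or len(pred_trials) != len(target_trials):
        raise LengthError("need >= 2 aligned (pred, target) trial pairs")
    errs = []
    for p, t in zip(pred_trials, target_trials):
        errs.append(
            resample_to_length(np.asarray(p, float), common_length)
            - resample_to_length(np.asarray(t, float), common_length)
        )
    err = np.vstack(errs)
    mean_curve = np.sqrt(np.mean(err**2, axis=0))
    sd_curve = np.std(np.abs(err), axis=0, ddof=1)
    return mean_curve, sd_curve


def constant_emg_inputs(trial: ProcessedTrial) -> ProcessedTrial:
    """Replace each EMG channel by its own temporal mean over the trial,
    preserving average signal power while omitting time-varying information.
    Targets are untouched.  Idempotent."""
    if np.all(trial.x == trial.x[:1]):
        return replace(trial, x=trial.x.copy(), percent_trial=trial.percent_trial)
    x_const = np.tile(trial.x.mean(axis=0), (trial.n_samples, 1))
    return replace(trial, x=x_const, percent_trial=trial.percent_trial)


# ---------------------------------------------------------------------------
# Critical performance points
# ---------------------------------------------------------------------------

_STANCE_EVENTS = (
    "TO",
    "max_dorsiflexion",
    "max_plantarflexion",
    "max_plantarflexion_moment",
)


@dataclass(frozen=True)
class CriticalPointSpec:
    """One critical performance point.

    ``kind`` is ``stance_event`` (a single target-defined instant) or
    ``clearance_interval`` (all samples within a fractional time interval).
    ``window`` restricts the extremum search to a fractional sub-span of the
    trial.  ``interval`` gives the clearance interval bounds as trial
    fractions.
    """

    name: str
    kind: str
    channel: str  # "angle" | "moment"
    event: str | None = None
    window: tuple = (0.0, 1.0)
    interval: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stance_event", "clearance_interval"):
            raise EventError(f"unknown critical point kind {self.kind!r}")
        if self.kind == "stance_event" and self.event not in _STANCE_EVENTS:
            raise EventError(f"unknown stance event {self.event!r}")
        if self.kind == "clearance_interval" and self.interval is None:
            raise EventError("clearance_interval spec needs interval bounds")


def default_critical_specs() -> list[CriticalPointSpec]:
    """Stance critical points at toe off and the angle/moment extrema, plus a
    swing-phase clearance interval around the minimum-clearance angle."""
    return [
        CriticalPointSpec("toe_off_angle", "stance_event", "angle", event="TO"),
        CriticalPointSpec("max_dorsiflexion", "stance_event", "angle", event="max_dorsiflexion"),
        CriticalPointSpec(
            "max_plantarflexion", "stance_event", "angle", event="max_plantarflexion"
        ),
        CriticalPointSpec(
            "max_plantarflexion_moment",
            "stance_event",
            "moment",
            event="max_plantarflexion_moment",
        ),
        CriticalPointSpec(
            "swing_clearance",
            "clearance_interval",
            "angle",
            interval=(0.60, 0.72),
        ),
    ]


def extract_critical_points(
    pred: np.ndarray,
    target: np.ndarray,
    spec: CriticalPointSpec,
    events=(),
    moment_pf_sign: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (prediction, target) samples for one spec on one trial.

    Stance events are located on the *target* series; both series are then
    sampled at that index.  ``pred``/``target`` are (T, 2) arrays with angle
    in column 0 and moment in column 1.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    n = len(target)
    ch = 0 if spec.channel == "angle" else 1
    if spec.kind == "clearance_interval":
        lo, hi = spec.interval  # type: ignore[misc]
        idx = np.arange(int(np.floor(lo * (n - 1))), int(np.ceil(hi * (n - 1))) + 1)
        return pred[idx, ch], target[idx, ch]
    i0, i1 = (int(np.floor(f * (n - 1))) for f in spec.window)
    if i1 <= i0:
        raise EventError(f"spec {spec.name}: empty search window")
    seg = target[i0 : i1 + 1, ch]
    if spec.event == "TO":
        for name, idx in events:
            if name == "TO" and i0 <= idx <= i1:
                return pred[[idx], ch], target[[idx], ch]
        raise EventError(f"spec {spec.name}: no TO event in the search window")
    if spec.event == "max_dorsiflexion":
        i = int(np.argmax(seg))
    elif spec.event == "max_plantarflexion":
        i = int(np.argmin(seg))
    else:  # max_plantarflexion_moment
        i = int(np.argmax(moment_pf_sign * seg))
    idx = i0 + i
    return pred[[idx], ch], target[[idx], ch]


def critical_point_test(
    pred_vals: np.ndarray, target_vals: np.ndarray, alpha: float = 0.05
) -> tuple[str, float, float]:
    """Shapiro-Wilk-gated paired test on prediction-target differences.

    Normal differences (Shapiro-Wilk p > alpha) get a paired-samples t-test;
    otherwise an exact two-sided binomial sign test on the nonzero
    differences.  Identical samples report ("identical", 0, 1) by convention.
    """
    pred_vals = np.asarray(pred_vals, dtype=float)
    target_vals = np.asarray(target_vals, dtype=float)
    if pred_vals.shape != target_vals.shape or len(pred_vals) < 3:
        raise LengthError("need >= 3 aligned pairs")
    diff = pred_vals - target_vals
    if np.allclose(diff, 0.0):
        return "identical", 0.0, 1.0
    if np.ptp(diff) == 0.0:  # constant nonzero difference: normality degenerate
        return _sign_test(diff)
    sw = stats.shapiro(diff)
    if sw.pvalue > alpha:
        t = stats.ttest_rel(pred_vals, target_vals)
        return "paired_t", float(t.statistic), float(t.pvalue)
    return _sign_test(diff)


def _sign_test(diff: np.ndarray) -> tuple[str, float, float]:
    nonzero = diff[diff != 0.0]
    if nonzero.size == 0:
        return "identical", 0.0, 1.0
    k = int(np.sum(nonzero > 0))
    res = stats.binomtest(k, n=nonzero.size, p=0.5, alternative="two-sided")
    return "sign", float(k), float(res.pvalue)


def benjamini_hochberg(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR adjustment with enforced monotonicity.

    Returns (adjusted p-values, reject flags); rejection where adjusted
    p <= q.  Adjusted values dominate the raw ones elementwise.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise LengthError("pvals must be a non-empty 1-D array")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise LengthError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty_like(p)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


# ---------------------------------------------------------------------------
# Session-level report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Aggregated per-condition metrics, ablation and critical-point tables."""

    conditions: dict
    ablation: dict
    critical_points: list
    instantaneous: dict
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "conditions": self.conditions,
            "ablation": self.ablation,
            "critical_points": self.critical_points,
            "instantaneous": {
                cond: {k: np.asarray(v).tolist() for k, v in curves.items()}
                for cond, curves in self.instantaneous.items()
            },
            "meta": self.meta,
        }


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def build_report(
    session,
    models,
    folds,
    specs: list[CriticalPointSpec] | None = None,
    with_ablation: bool = True,
    fdr_q: float = 0.05,
    max_lag: int | None = None,
) -> EvaluationReport:
    """Evaluate per-fold optimized models on their novel test trials.

    Metrics are computed per test trial, aggregated to fold level and then to
    session means and standard deviations.  When ``with_ablation`` is set the
    same models are re-run with constant (trial-mean) EMG inputs and the
    instantaneous-RMSE comparison is included.  Critical-point samples are
    pooled across folds per spec x condition and tested, with
    Benjamini-Hochberg adjustment across the whole table.
    """
    if len(models) != len(folds) or not models:
        raise LengthError("need one trained model per fold")
    if specs is None:
        specs = default_critical_specs()
    out_names = ("angle", "moment")
    per_cond: dict[str, dict] = {}
    inst: dict[str, dict] = {}
    crit_samples: dict[tuple, list] = {}
    raw_metrics: dict[str, dict] = {
        c: {o: {"rmse": [], "r2": [], "lag": [], "rmse_const": []} for o in out_names}
        for c in CONDITIONS
    }
    inst_errs: dict[str, dict] = {}
    for model, fold in zip(models, folds):
        for trial in fold.trials(session, "test"):
            trace = predict_trial(model.weights, model.config, model.normalizer, trial)
            idx = trace.valid_index
            pred = trace.predictions[idx]
            targ = trial.y[idx]
            cond = trial.condition
            for o, name in enumerate(out_names):
                raw_metrics[cond][name]["rmse"].append(rmse(pred[:, o], targ[:, o]))
                r2, lag = xcorr_r2(pred[:, o], targ[:, o], max_lag=max_lag)
                raw_metrics[cond][name]["r2"].append(r2)
                raw_metrics[cond][name]["lag"].append(lag)
            if with_ablation:
                const_trace = predict_trial(
                    model.weights,
                    model.config,
                    model.normalizer,
                    constant_emg_inputs(trial),
                )
                pred_c = const_trace.predictions[idx]
                for o, name in enumerate(out_names):
                    raw_metrics[cond][name]["rmse_const"].append(
                        rmse(pred_c[:, o], targ[:, o])
                    )
                store = inst_errs.setdefault(
                    cond, {"pred": [], "pred_const": [], "target": []}
                )
                store["pred"].append(pred)
                store["pred_const"].append(pred_c)
                store["target"].append(targ)
            # critical points located relative to the scored segment
            events = tuple((n, i - idx[0]) for n, i in trial.events if i >= idx[0])
            for spec in specs:
                try:
                    pv, tv = extract_critical_points(pred, targ, spec, events=events)
                except EventError:
                    continue
                key = (cond, spec.name)
                crit_samples.setdefault(key, ([], []))
                crit_samples[key][0].extend(pv)
                crit_samples[key][1].extend(tv)

    for cond in list(raw_metrics):
        if not raw_metrics[cond]["angle"]["rmse"]:
            del raw_metrics[cond]
            continue
        per_cond[cond] = {}
        for name in out_names:
            m = raw_metrics[cond][name]
            entry = {}
            entry["rmse_mean"], entry["rmse_sd"] = _mean_sd(m["rmse"])
            entry["r2_mean"], entry["r2_sd"] = _mean_sd(m["r2"])
            entry["lags"] = [int(v) for v in m["lag"]]
            if with_ablation:
                entry["rmse_const_mean"], entry["rmse_const_sd"] = _mean_sd(
                    m["rmse_const"]
                )
            per_cond[cond][name] = entry

    if with_ablation:
        for cond, store in inst_errs.items():
            length = COMMON_LENGTHS.get(cond, 200)
            curves = {}
            for o, name in enumerate(out_names):
                preds = [p[:, o] for p in store["pred"]]
                preds_c = [p[:, o] for p in store["pred_const"]]
                targs = [t[:, o] for t in store["target"]]
                if len(preds) >= 2:
                    mean_tv, sd_tv = instantaneous_rmse(preds, targs, length)
                    mean_c, sd_c = instantaneous_rmse(preds_c, targs, length)
                    curves[f"{name}_rmse_tv"] = mean_tv
                    curves[f"{name}_rmse_tv_sd"] = sd_tv
                    curves[f"{name}_rmse_const"] = mean_c
                    curves[f"{name}_rmse_const_sd"] = sd_c
            if curves:
                inst[cond] = curves

    table = []
    for (cond, spec_name), (pv, tv) in sorted(crit_samples.items()):
        if len(pv) < 3:
            continue
        test_name, statistic, p = critical_point_test(np.asarray(pv), np.asarray(tv))
        pm, ps = _mean_sd(pv)
        tm, ts = _mean_sd(tv)
        table.append(
            {
                "condition": cond,
                "point": spec_name,
                "n": len(pv),
                "pred_mean": pm,
                "pred_sd": ps,
                "target_mean": tm,
                "target_sd": ts,
                "test": test_name,
                "statistic": statistic,
                "p": p,
            }
        )
    if table:
        adjusted, reject = benjamini_hochberg([row["p"] for row in table], q=fdr_q)
        for row, ap, rej in zip(table, adjusted, reject):
            row["p_adjusted"] = float(ap)
            row["reject"] = bool(rej)

    ablation_summary = {}
    if with_ablation:
        for cond, metrics in per_cond.items():
            ablation_summary[cond] = {
                name: {
                    "rmse_time_varying": metrics[name]["rmse_mean"],
                    "rmse_constant": metrics[name].get("rmse_const_mean", float("nan")),
                }
                for name in out_names
            }

    return EvaluationReport(
        conditions=per_cond,
        ablation=ablation_summary,
        critical_points=table,
        instantaneous=inst,
        meta={"sign_convention": SIGN_CONVENTION, "fdr_q": fdr_q, "n_folds": len(folds)},
    )
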