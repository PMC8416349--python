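"""Seeded generator of multi-condition gait sessions.

Trials are built from hand-crafted per-condition templates (sums of Gaussian
bumps over the gait-cycle phase) for the dorsiflexor/plantarflexor EMG
envelopes, ankle angle and ankle moment, with trial-to-trial variability in
amplitude (lognormal per-burst jitter), timing (smooth monotone time warp)
and additive smoothed noise.  Level walking trials span one gait cycle; stair
trials span three continuous cycles whose first and last cycles carry reduced
amplitudes, standing in for the level-to-stair and stair-to-level transition
segments.

When ``emg_coupling`` > 0, a fraction of the angle and moment signal is driven
by the trial's *own* EMG envelopes through a fixed causal smoothing-and-lag
operator (EMG leads mechanics), so the envelopes carry trial-specific
information about the targets and EMG informativeness is testable.  The
coupled component is expressed as a delta against the same operator applied to
the noise-free envelope, so a zero-variability trial reproduces the template
exactly regardless of coupling.

A teacher generator (closed-loop roll-out of the forward equations from known
weights) supports exact parameter-recovery tests of the training machinery.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigError, StructureError
from .narx import NarxConfig, NarxWeights, forward_step
from .trials import CONDITIONS, DECIM, FS, FS_RAW, GaitEvent, RawTrial

__all__ = [
    "Bump",
    "GaitTemplate",
    "VariabilityModel",
    "default_templates",
    "template_curve",
    "trial_time_grid",
    "generate_trial",
    "generate_session",
    "teacher_generate",
]

CHANNELS = ("emg_ta", "emg_gm", "angle", "moment")

#: Pre/post padding around the analysis core (seconds).  The pre-pad exceeds
#: the 225 ms pre-roll the truncation stage needs.
PRE_PAD_S = 0.5
POST_PAD_S = 0.2

#: Fixed smoothing-and-lag operator tying EMG envelopes to mechanics: a causal
#: 2nd-order 6 Hz low-pass followed by a pure delay (EMG leads mechanics).
COUPLING_LAG_SAMPLES = 8  # ~67 ms at 120 Hz
COUPLING_SMOOTH_HZ = 6.0

#: Cutoff for smoothing additive channel noise (keeps it band-limited).
NOISE_SMOOTH_HZ = 5.0

# Gait events within one cycle, as fractions of the cycle.  Heel strike opens
# the cycle; toe off at ~62% stance/swing split; contralateral events offset
# by roughly half a cycle; ON/OFF are force-plate contact bounds.
_CYCLE_EVENTS = (
    ("HS", 0.0),
    ("ON", 0.02),
    ("cTO", 0.12),
    ("cHS", 0.50),
    ("cON", 0.52),
    ("OFF", 0.60),
    ("TO", 0.64),
)


@dataclass(frozen=True)
class Bump:
    """One Gaussian bump in cycle phase: amp * exp(-((p-center)/width)^2/2)."""

    center: float
    width: float
    amp: float


@dataclass(frozen=True)
class GaitTemplate:
    """Noise-free per-condition trial morphology.

    ``bumps`` maps each channel to its per-cycle Gaussian bumps (in cycle
    phase); ``cycle_scales`` modulates bump amplitudes per cycle, which is how
    the stair conditions express their transition (first/last) cycles.
    """

    condition: str
    n_cycles: int
    core_duration_s: float
    baselines: dict
    bumps: dict
    cycle_scales: dict
    event_phases: tuple = _CYCLE_EVENTS

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        for ch in CHANNELS:
            if ch not in self.bumps or ch not in self.baselines:
                raise ConfigError(f"template missing channel {ch!r}")
            if len(self.cycle_scales[ch]) != self.n_cycles:
                raise ConfigError(f"cycle_scales[{ch!r}] must have n_cycles entries")
        phases = [p for _, p in self.event_phases]
        if any(b <= a for a, b in zip(phases, phases[1:])) or not all(
            0.0 <= p < 1.0 for p in phases
        ):
            raise ConfigError("event phases must be strictly increasing in [0, 1)")
        # Envelopes must be non-negative everywhere on the core.
        grid = np.linspace(-0.2, 1.2, 2001)
        for ch in ("emg_ta", "emg_gm"):
            if template_curve(self, ch, grid).min() < 0.0:
                raise ConfigError(f"envelope channel {ch!r} goes negative")

    @property
    def global_event_phases(self) -> tuple:
        """Events of all cycles plus the terminal heel strike, in trial phase."""
        out = []
        for k in range(self.n_cycles):
            for name, p in self.event_phases:
                out.append((name, (k + p) / self.n_cycles))
        out.append(("HS", 1.0))
        return tuple(out)


def template_curve(
    template: GaitTemplate, channel: str, phase: np.ndarray, amp_jitter=None
) -> np.ndarray:
    """Evaluate one template channel at trial-phase values (may lie outside
    [0, 1]; Gaussian tails extend naturally into the padding)."""
    phase = np.asarray(phase, dtype=float)
    out = np.full(phase.shape, float(template.baselines[channel]))
    nc = template.n_cycles
    for k in range(nc):
        scale = template.cycle_scales[channel][k]
        for bi, b in enumerate(template.bumps[channel]):
            amp = b.amp * scale
            if amp_jitter is not None:
                amp *= amp_jitter[k, bi]
            out += amp * np.exp(-0.5 * ((phase - (k + b.center) / nc) / (b.width / nc)) ** 2)
    return out


def _make_template(condition, n_cycles, core_s, angle_scale, moment_scale, cycle_scales):
    bumps = {
        "emg_ta": (
            Bump(0.03, 0.045, 0.32),
            Bump(0.66, 0.060, 0.16),
            Bump(0.93, 0.050, 0.28),
        ),
        "emg_gm": (Bump(0.15, 0.080, 0.10), Bump(0.42, 0.090, 0.45)),
        "angle": (
            Bump(0.07, 0.050, -5.0 * angle_scale),
            Bump(0.40, 0.140, 13.0 * angle_scale),
            Bump(0.63, 0.100, -20.0 * angle_scale),
            Bump(0.82, 0.110, 8.0 * angle_scale),
        ),
        "moment": (
            Bump(0.06, 0.035, -0.10 * moment_scale),
            Bump(0.45, 0.110, 1.35 * moment_scale),
            Bump(0.80, 0.120, -0.08 * moment_scale),
        ),
    }
    baselines = {"emg_ta": 0.02, "emg_gm": 0.015, "angle": 0.0, "moment": 0.0}
    return GaitTemplate(
        condition=condition,
        n_cycles=n_cycles,
        core_duration_s=core_s,
        baselines=baselines,
        bumps=bumps,
        cycle_scales=cycle_scales,
    )


def default_templates() -> dict:
    """Hand-built templates: LW one cycle, AS/DS three continuous cycles with
    damped transition (first/last) cycles; stair-descent angle excursions are
    the widest of the three conditions."""
    ones3 = (0.85, 1.0, 0.9)
    return {
        "LW": _make_template("LW", 1, 1.20, 1.0, 1.0, {ch: (1.0,) for ch in CHANNELS}),
        "AS": _make_template(
            "AS",
            3,
            3.30,
            1.15,
            0.95,
            {"emg_ta": ones3, "emg_gm": ones3, "angle": (0.9, 1.0, 0.9), "moment": (0.9, 1.0, 0.95)},
        ),
        "DS": _make_template(
            "DS",
            3,
            3.10,
            1.35,
            0.90,
            {"emg_ta": ones3, "emg_gm": ones3, "angle": (0.92, 1.0, 0.92), "moment": (0.9, 1.0, 0.95)},
        ),
    }


@dataclass(frozen=True)
class VariabilityModel:
    """Trial-to-trial variability controls; the seed fully determines output.

    ``amplitude_jitter_sd`` is the lognormal sigma of per-burst EMG amplitude
    jitter (target bumps jitter at 0.4x that sigma).  ``time_warp_sd`` scales
    a smooth monotone warp of the phase axis.  Additive noise SDs are in
    channel units and band-limited below ~5 Hz.  ``emg_coupling`` in [0, 1]
    sets the fraction of angle/moment driven by the trial's own envelopes.
    """

    amplitude_jitter_sd: float = 0.15
    time_warp_sd: float = 0.10
    emg_noise_sd: float = 0.006
    angle_noise_sd: float = 0.4
    moment_noise_sd: float = 0.018
    emg_coupling: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "amplitude_jitter_sd",
            "time_warp_sd",
            "emg_noise_sd",
            "angle_noise_sd",
            "moment_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.emg_coupling <= 1.0:
            raise ConfigError("emg_coupling must lie in [0, 1]")


def zero_variability(coupling: float = 0.0, seed: int = 0) -> VariabilityModel:
    """Convenience: a fully deterministic, noise-free variability model."""
    return VariabilityModel(0.0, 0.0, 0.0, 0.0, 0.0, coupling, seed)


def trial_time_grid(template: GaitTemplate) -> tuple[np.ndarray, np.ndarray]:
    """Sample times (s) and trial-phase values of a generated trial's grid."""
    n_pre = int(round(PRE_PAD_S * FS))
    n_core = int(round(template.core_duration_s * FS))
    n_post = int(round(POST_PAD_S * FS))
    n_total = n_pre + n_core + n_post
    t = np.arange(n_total) / FS
    phase = (t - n_pre / FS) / template.core_duration_s
    return t, phase


def _smooth_noise(rng, sd, n, cutoff_hz=NOISE_SMOOTH_HZ):
    """Band-limited Gaussian noise with standard deviation ~sd."""
    white = rng.standard_normal(n)
    if sd == 0.0:
        return np.zeros(n)
    sos = signal.butter(2, cutoff_hz, fs=FS, output="sos")
    smooth = signal.sosfiltfilt(sos, white)
    smooth /= max(smooth.std(), 1e-12)
    return sd * smooth


def _mech_features(env_ta, env_gm):
    """Fixed causal smoothing-and-lag operator from envelopes to mechanics."""
    sos = signal.butter(2, COUPLING_SMOOTH_HZ, fs=FS, output="sos")
    out = []
    for e in (env_ta, env_gm):
        f = signal.sosfilt(sos, e)
        lag = COUPLING_LAG_SAMPLES
        out.append(np.concatenate([np.full(lag, f[0]), f[:-lag]]))
    return np.column_stack(out)


def generate_trial(
    template: GaitTemplate,
    variability: VariabilityModel,
    trial_index: int,
    include_raw: bool = False,
) -> RawTrial:
    """Generate one trial from a template under a variability model.

    The per-trial RNG stream is derived from (seed, condition, trial_index),
    so trials are independent and reorderable; identical arguments reproduce
    the trial bitwise.
    """
    if trial_index < 0:
        raise ConfigError("trial_index must be >= 0")
    cond = template.condition
    rng = np.random.default_rng(
        (int(variability.seed), CONDITIONS.index(cond), int(trial_index))
    )
    t, phase = trial_time_grid(template)
    n_total = len(t)
    t0 = int(round(PRE_PAD_S * FS)) / FS

    # --- monotone time warp: cumulative integral of a positive jittered rate
    if variability.time_warp_sd > 0:
        k = np.arange(1, 7)
        coef_sin = rng.normal(0.0, 1.0, k.size)
        coef_cos = rng.normal(0.0, 1.0, k.size)
        g = (
            np.sin(2 * np.pi * np.outer(phase, k)) @ coef_sin
            + np.cos(2 * np.pi * np.outer(phase, k)) @ coef_cos
        ) * (variability.time_warp_sd / np.sqrt(k.size))
        rate = np.exp(g)
        cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0)]) / FS
        c0 = np.interp(0.0, phase, cum)
        c1 = np.interp(1.0, phase, cum)
        warped = (cum - c0) / (c1 - c0)
    else:
        warped = phase

    # --- per-burst amplitude jitter (EMG strong, targets weak) + EMG gains
    def jitter(ch, sd):
        shape = (template.n_cycles, len(template.bumps[ch]))
        if sd == 0.0:
            return np.ones(shape)
        return np.exp(rng.normal(0.0, sd, shape))

    sd = variability.amplitude_jitter_sd
    jit = {
        "emg_ta": jitter("emg_ta", sd),
        "emg_gm": jitter("emg_gm", sd),
        "angle": jitter("angle", 0.4 * sd),
        "moment": jitter("moment", 0.4 * sd),
    }
    gain_ta, gain_gm = (
        np.exp(rng.normal(0.0, sd / 2.0, 2)) if sd > 0 else np.ones(2)
    )

    # --- EMG envelopes (jittered template + band-limited noise, clipped >= 0)
    env_ta = template_curve(template, "emg_ta", warped, jit["emg_ta"]) * gain_ta
    env_gm = template_curve(template, "emg_gm", warped, jit["emg_gm"]) * gain_gm
    env_ta = np.clip(env_ta + _smooth_noise(rng, variability.emg_noise_sd, n_total, 8.0), 0.0, None)
    env_gm = np.clip(env_gm + _smooth_noise(rng, variability.emg_noise_sd, n_total, 8.0), 0.0, None)

    # --- targets: warped template plus an EMG-driven delta component
    angle = template_curve(template, "angle", warped, jit["angle"])
    moment = template_curve(template, "moment", warped, jit["moment"])
    coupling = variability.emg_coupling
    if coupling > 0.0:
        ref_ta = template_curve(template, "emg_ta", warped)
        ref_gm = template_curve(template, "emg_gm", warped)
        feat_ref = _mech_features(ref_ta, ref_gm)
        feat_trial = _mech_features(env_ta, env_gm)
        design = np.column_stack([feat_ref, np.ones(n_total)])
        # least-squares map from reference features to the template mechanics;
        # only the slope part matters because the delta cancels the intercept
        coef_angle, *_ = np.linalg.lstsq(design, angle, rcond=None)
        coef_moment, *_ = np.linalg.lstsq(design, moment, rcond=None)
        dfeat = feat_trial - feat_ref
        angle = angle + coupling * (dfeat @ coef_angle[:2])
        moment = moment + coupling * (dfeat @ coef_moment[:2])
    angle = angle + _smooth_noise(rng, variability.angle_noise_sd, n_total)
    moment = moment + _smooth_noise(rng, variability.moment_noise_sd, n_total)

    # --- events at warped template phases
    events = []
    for name, p_event in template.global_event_phases:
        p_star = np.interp(p_event, warped, phase)
        events.append(GaitEvent(name=name, time_s=t0 + p_star * template.core_duration_s))
    events.sort(key=lambda e: e.time_s)

    emg_raw = None
    if include_raw:
        # raw EMG = envelope-modulated band-limited noise carrier at 1,200 Hz,
        # scaled so the linear-envelope chain recovers ~the modulating envelope
        n_raw = n_total * DECIM
        carrier = rng.standard_normal(n_raw)
        sos = signal.butter(4, (20.0, 450.0), btype="bandpass", fs=FS_RAW, output="sos")
        carrier = signal.sosfiltfilt(sos, carrier)
        carrier /= carrier.std()
        t_raw = np.arange(n_raw) / FS_RAW
        emg_raw = np.column_stack(
            [
                np.interp(t_raw, t, env_ta) * carrier / np.sqrt(2.0 / np.pi),
                np.interp(t_raw, t, env_gm) * carrier[::-1] / np.sqrt(2.0 / np.pi),
            ]
        )

    return RawTrial(
        trial_id=f"{cond}{trial_index:02d}",
        condition=cond,
        emg_envelope=np.column_stack([env_ta, env_gm]),
        angle=angle,
        moment=moment,
        events=tuple(events),
        emg_raw=emg_raw,
    )


def generate_session(
    templates: dict,
    variability: VariabilityModel,
    n_trials_per_condition: int,
    include_raw: bool = False,
) -> list[RawTrial]:
    """Generate ``n_trials_per_condition`` trials for every template.

    At least 11 trials per condition are required to support the trial-blocked
    folds (8 training + 2 validation + 1 held-out test trial per condition).
    """
    if n_trials_per_condition < 11:
        raise ConfigError(
            f"n_trials_per_condition={n_trials_per_condition} < 11: each "
            "condition needs 8 training + 2 validation + 1 test trial per fold"
        )
    trials = []
    for cond in CONDITIONS:
        if cond not in templates:
            continue
        for idx in range(n_trials_per_condition):
            trials.append(
                generate_trial(templates[cond], variability, idx, include_raw=include_raw)
            )
    return trials


def teacher_generate(
    weights: NarxWeights,
    config: NarxConfig,
    exogenous: np.ndarray,
    y_init: np.ndarray,
) -> np.ndarray:
    """Closed-loop roll-out of the forward equations from known weights.

    Starting from ``y_init`` (the first d + m target samples; the roll-out at
    base time t writes sample t + m, so the first un-generated index is
    d + m), each subsequent target sample is produced by the network from the
    exogenous window and previously generated targets.  Exact and
    deterministic; used to manufacture data with known generative parameters.
    """
    exogenous = np.asarray(exogenous, dtype=float)
    y_init = np.asarray(y_init, dtype=float)
    d, m = config.d, config.m
    n = len(exogenous)
    if n <= d + m:
        raise StructureError(f"exogenous length {n} must exceed d + m = {d + m}")
    if exogenous.shape != (n, 2):
        raise StructureError("exogenous must have shape (T, 2)")
    if y_init.shape != (d + m, 2):
        raise StructureError(
            f"y_init shape {y_init.shape}, expected ({d + m}, 2) "
            "(the first d + m target samples)"
        )
    weights.validate(config)
    y = np.zeros((n, 2))
    y[: d + m] = y_init
    for t in range(d, n - m):
        xw = exogenous[t - d : t + 1][::-1].T  # (2, d+1): x_i(t-q), q=0..d
        yw = y[t - d : t][::-1].T  # (2, d): y_j(t-q), q=1..d
        _, yhat = forward_step(weights, config, xw, yw)
        y[t + m] = yhat
    return y
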