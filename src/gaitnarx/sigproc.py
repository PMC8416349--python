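"""Signal-conditioning chains: EMG linear envelope, kinetic/kinematic
filtering, trial truncation and common-length resampling.

Every filter is a 4th-order Butterworth design applied forward-backward
(zero phase, effective order 8).  Downsampling from the 1,200 Hz acquisition
rate to the 120 Hz working rate is plain decimation by 10, taken after a
low-pass whose cutoff (5.5 Hz for EMG envelopes, 15 Hz for kinetics) sits far
below the 60 Hz post-decimation Nyquist, so no extra anti-alias stage is
needed.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import EventError, LengthError, RateError
from .trials import (
    DECIM,
    FS,
    FS_RAW,
    PRE_ROLL_SAMPLES,
    GaitEvent,
    ProcessedTrial,
    RawTrial,
)

__all__ = [
    "emg_linear_envelope",
    "filter_kinetics",
    "filter_kinematics",
    "truncate_trial",
    "preprocess_trial",
    "resample_to_length",
    "COMMON_LENGTHS",
]

#: Common-length interpolation targets per condition for reporting.
COMMON_LENGTHS = {"LW": 145, "AS": 430, "DS": 400}

_FILTER_ORDER = 4
_EMG_BAND_HZ = (20.0, 499.5)
_EMG_ENVELOPE_HZ = 5.5
_KINETIC_LOWPASS_HZ = 15.0
_NOTCH_BAND_HZ = (59.0, 61.0)
_KINEMATIC_LOWPASS_HZ = 15.0

# Minimum input lengths: generous multiples of the slowest filter's settling
# span so zero-phase edge padding is well conditioned.
_MIN_RAW_SAMPLES = 360  # 0.3 s at 1,200 Hz
_MIN_WORKING_SAMPLES = 36  # 0.3 s at 120 Hz


def _sos(kind: str, cutoffs, fs: float):
    return signal.butter(_FILTER_ORDER, cutoffs, btype=kind, fs=fs, output="sos")


def _zero_phase(sos, x: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, x)


def _check(x: np.ndarray, fs: float, expected_fs: float, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise LengthError("expected a 1-D series")
    if fs != expected_fs:
        raise RateError(f"expected a {expected_fs:g} Hz series, got {fs:g} Hz")
    if len(x) < min_len:
        raise LengthError(f"series of length {len(x)} too short (need >= {min_len})")
    return x


def emg_linear_envelope(raw: np.ndarray, fs: float = FS_RAW) -> np.ndarray:
    """EMG linear envelope at 120 Hz from raw EMG at 1,200 Hz.

    Chain order is fixed: 20-499.5 Hz band-pass (4th-order zero-phase
    Butterworth) -> full-wave rectification -> 5.5 Hz low-pass (same design)
    -> decimation by 10.  The smoothed rectified signal can undershoot zero
    slightly at the edges; envelopes are physically non-negative so the
    output is clipped at 0.
    """
    raw = _check(raw, fs, FS_RAW, _MIN_RAW_SAMPLES)
    band = _zero_phase(_sos("bandpass", _EMG_BAND_HZ, FS_RAW), raw)
    rectified = np.abs(band)
    envelope = _zero_phase(_sos("lowpass", _EMG_ENVELOPE_HZ, FS_RAW), rectified)
    return np.clip(envelope[::DECIM], 0.0, None)


def filter_kinetics(raw: np.ndarray, fs: float = FS_RAW) -> np.ndarray:
    """Kinetic conditioning: 15 Hz low-pass + 59-61 Hz band-stop (both
    4th-order zero-phase Butterworth) at 1,200 Hz, then decimation to 120 Hz."""
    raw = _check(raw, fs, FS_RAW, _MIN_RAW_SAMPLES)
    low = _zero_phase(_sos("lowpass", _KINETIC_LOWPASS_HZ, FS_RAW), raw)
    notched = _zero_phase(_sos("bandstop", _NOTCH_BAND_HZ, FS_RAW), low)
    return notched[::DECIM]


def filter_kinematics(series: np.ndarray, fs: float = FS) -> np.ndarray:
    """15 Hz zero-phase low-pass for 120 Hz kinematic/kinetic time series."""
    series = _check(series, fs, FS, _MIN_WORKING_SAMPLES)
    return _zero_phase(_sos("lowpass", _KINEMATIC_LOWPASS_HZ, FS), series)


def truncate_trial(
    x: np.ndarray,
    y: np.ndarray,
    events,
    condition: str,
    trial_id: str = "",
) -> ProcessedTrial:
    """Cut 120 Hz channels to the analysis window and re-index events.

    The window runs from 225 ms (27 samples) before the first heel strike to
    the terminal (last) heel strike, inclusive.  Events are re-indexed to
    window samples; a percent-trial axis spans 0-100 over the window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hs = [ev for ev in events if ev.name == "HS"]
    if len(hs) < 2:
        raise EventError(
            f"trial {trial_id or '<anon>'}: need the first and the terminal "
            "heel strike to truncate"
        )
    i_first = int(round(hs[0].time_s * FS))
    i_last = int(round(hs[-1].time_s * FS))
    start = i_first - PRE_ROLL_SAMPLES
    if start < 0:
        raise LengthError(
            f"trial {trial_id or '<anon>'}: only {i_first} samples before the "
            f"first heel strike; {PRE_ROLL_SAMPLES} (225 ms) required"
        )
    if i_last >= len(x) or i_last <= i_first:
        raise EventError(
            f"trial {trial_id or '<anon>'}: terminal heel strike at sample "
            f"{i_last} outside the usable record"
        )
    window_events = []
    for ev in events:
        idx = int(round(ev.time_s * FS))
        if start <= idx <= i_last:
            window_events.append((ev.name, idx - start))
    return ProcessedTrial(
        trial_id=trial_id,
        condition=condition,
        x=x[start : i_last + 1],
        y=y[start : i_last + 1],
        events=tuple(window_events),
    )


def preprocess_trial(trial: RawTrial) -> ProcessedTrial:
    """Full conditioning of one raw trial.

    If raw-rate EMG is present the linear-envelope chain is run per channel;
    otherwise the supplied 120 Hz envelopes are used as-is.  Angle and moment
    get the 15 Hz zero-phase low-pass, then the trial is truncated to the
    analysis window.
    """
    if trial.emg_raw is not None:
        env = np.column_stack(
            [emg_linear_envelope(trial.emg_raw[:, i]) for i in range(2)]
        )
        n = min(len(env), trial.n_samples)
        env = env[:n]
    else:
        env = trial.emg_envelope
        n = trial.n_samples
    angle = filter_kinematics(trial.angle[:n])
    moment = filter_kinematics(trial.moment[:n])
    return truncate_trial(
        x=env,
        y=np.column_stack([angle, moment]),
        events=trial.events,
        condition=trial.condition,
        trial_id=trial.trial_id,
    )


def preprocess_session(trials) -> list[ProcessedTrial]:
    """Condition every trial of a session."""
    return [preprocess_trial(t) for t in trials]


def resample_to_length(series: np.ndarray, length: int) -> np.ndarray:
    """Endpoint-preserving linear interpolation onto ``length`` uniform points."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise LengthError("input series must be 1-D with length >= 2")
    if length < 2:
        raise LengthError(f"target length must be >= 2, got {length}")
    if length == len(series):
        return series.copy()
    old = np.arange(len(series), dtype=float)
    new = np.linspace(0.0, len(series) - 1.0, length)
    return np.interp(new, old, series)


def common_length_for(condition: str) -> int:
    """Default common reporting length for a condition."""
    return COMMON_LENGTHS[condition]


def events_from_indices(trial: ProcessedTrial) -> tuple[GaitEvent, ...]:
    """Convert a processed trial's sample-index events back to timestamps
    (useful for idempotence checks and serialization)."""
    return tuple(GaitEvent(name=n, time_s=i / FS) for n, i in trial.events)
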