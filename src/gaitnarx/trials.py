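"""Trial containers shared by the generator, signal processing and modelling layers.

All modelling happens at the working rate of 120 Hz.  Raw surface EMG, when
present, is carried at 1,200 Hz (10x the working rate).  Angle is expressed in
degrees (dorsiflexion positive), moment in N*m/kg (plantarflexion moment
positive by the package-wide sign convention, recorded in every report).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError

#: Working sample rate for all modelled channels.
FS = 120.0
#: Raw EMG sample rate.
FS_RAW = 1200.0
#: Decimation factor from raw to working rate.
DECIM = 10
#: Canonical condition labels: level walking, stair ascent, stair descent.
CONDITIONS = ("LW", "AS", "DS")
#: Samples kept before the first heel strike (225 ms at 120 Hz).
PRE_ROLL_SAMPLES = 27


@dataclass(frozen=True)
class GaitEvent:
    """A labelled gait event located in trial time (seconds)."""

    name: str
    time_s: float


@dataclass
class RawTrial:
    """One recorded (or simulated) walking trial before conditioning.

    Attributes
    ----------
    emg_envelope : ndarray, shape (T, 2)
        EMG linear envelopes at 120 Hz; column 0 dorsiflexor (TA), column 1
        plantarflexor (GM).
    angle, moment : ndarray, shape (T,)
        Sagittal ankle angle (degrees) and mass-normalized ankle moment
        (N*m/kg) at 120 Hz.
    emg_raw : ndarray, shape (10*T, 2), optional
        Raw-rate EMG; used to exercise the full envelope front end.
    """

    trial_id: str
    condition: str
    emg_envelope: np.ndarray
    angle: np.ndarray
    moment: np.ndarray
    events: tuple[GaitEvent, ...]
    emg_raw: np.ndarray | None = None
    fs: float = FS
    fs_raw: float = FS_RAW

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        self.emg_envelope = np.asarray(self.emg_envelope, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        n = len(self.angle)
        if self.emg_envelope.shape != (n, 2) or self.moment.shape != (n,):
            raise DataError(
                f"trial {self.trial_id}: 120 Hz channels disagree in length"
            )
        duration = n / self.fs
        for ev in self.events:
            if not (0.0 <= ev.time_s <= duration):
                raise DataError(
                    f"trial {self.trial_id}: event {ev.name} at {ev.time_s:.3f}s "
                    f"outside trial duration {duration:.3f}s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.angle)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ProcessedTrial:
    """Conditioned, truncated trial ready for modelling.

    ``x`` holds the two exogenous EMG envelopes, ``y`` the two targets
    (column 0 angle in degrees, column 1 moment in N*m/kg).  The first sample
    sits 225 ms (27 samples) before the first heel strike; the last sample is
    the terminal heel strike.  ``events`` are re-indexed to window samples.
    """

    trial_id: str
    condition: str
    x: np.ndarray
    y: np.ndarray
    events: tuple[tuple[str, int], ...]
    dt: float = 1.0 / FS
    percent_trial: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 2 or self.x.shape[1] != 2 or self.x.shape != self.y.shape:
            raise DataError(
                f"trial {self.trial_id}: x and y must both have shape (T, 2)"
            )
        if self.percent_trial is None:
            self.percent_trial = np.linspace(0.0, 100.0, len(self.x))

    @property
    def n_samples(self) -> int:
        return len(self.x)

    def event_index(self, name: str) -> int:
        """Sample index of the first event called ``name``."""
        for ev_name, idx in self.events:
            if ev_name == name:
                return idx
        from .errors import EventError

        raise EventError(f"trial {self.trial_id}: no event named {name!r}")


def group_by_condition(trials) -> dict[str, list]:
    """Group a session's trials by condition, preserving canonical order."""
    out: dict[str, list] = {}
    for cond in CONDITIONS:
        members = [t for t in trials if t.condition == cond]
        if members:
            out[cond] = members
    return out
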