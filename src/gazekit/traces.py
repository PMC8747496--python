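"""Core in-memory containers for eye and head time series.

All traces live on a uniform clock with time in seconds from session start.
Horizontal eye position is in degrees, rightward-positive (nasal for the
left eye, temporal for the right eye).  The attempted-head-movement signal
is the conditioned load-cell voltage in session Z-score units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, TimingError

__all__ = ["EyeTrace", "HeadTrace", "velocity"]


def velocity(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Velocity by central difference over one sample interval.

    Endpoints use one-sided differences so the output has the same length
    as the input.  Units are input-units per second.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.zeros_like(x)
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (rate_hz / 2.0)
    v[0] = (x[1] - x[0]) * rate_hz
    v[-1] = (x[-1] - x[-2]) * rate_hz
    return v


def _check_uniform(time_s: np.ndarray, rate_hz: float, tol: float = 1e-6) -> None:
    if time_s.size >= 2:
        dt = np.diff(time_s)
        if np.any(np.abs(dt - 1.0 / rate_hz) > tol):
            raise TimingError("trace is not uniformly sampled at the declared rate")


@dataclass
class EyeTrace:
    """Uniformly sampled horizontal angular eye position.

    Parameters
    ----------
    time_s : array
        Sample times in seconds from session start.
    position_deg : array
        Horizontal position, degrees, rightward-positive.
    rate_hz : float
        Nominal sampling rate (100 Hz for the camera-based tracker).
    valid : bool array, optional
        Per-sample quality mask; invalid samples break saccades that span
        them.  Defaults to all-valid.
    """

    time_s: np.ndarray
    position_deg: np.ndarray
    rate_hz: float = 100.0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_deg = np.asarray(self.position_deg, dtype=float)
        if self.time_s.shape != self.position_deg.shape:
            raise AlignmentError("time and position arrays differ in length")
        if self.valid is None:
            self.valid = np.ones(self.time_s.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        _check_uniform(self.time_s, self.rate_hz)

    def __len__(self) -> int:
        return self.time_s.size

    def velocity_dps(self) -> np.ndarray:
        """Angular velocity in deg/s (central difference)."""
        return velocity(self.position_deg, self.rate_hz)

    def centered(self) -> "EyeTrace":
        """Return a copy with the session-mean position (over valid
        samples) subtracted, the convention used before pooling sessions."""
        mean = float(np.mean(self.position_deg[self.valid]))
        return EyeTrace(self.time_s, self.position_deg - mean, self.rate_hz, self.valid.copy())

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t``."""
        return int(round((t - self.time_s[0]) * self.rate_hz))


@dataclass
class HeadTrace:
    """Conditioned attempted-head-rotation signal on the eye clock.

    ``signal_z`` is in session Z-score units after low-pass filtering,
    resampling and standardization (see ``kinematics.condition_head_signal``).
    """

    time_s: np.ndarray
    signal_z: np.ndarray
    rate_hz: float = 100.0
    raw_volts: np.ndarray = None  # original DAQ samples, if retained

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal_z = np.asarray(self.signal_z, dtype=float)
        if self.time_s.shape != self.signal_z.shape:
            raise AlignmentError("time and signal arrays differ in length")
        _check_uniform(self.time_s, self.rate_hz)

    def __len__(self) -> int:
        return self.time_s.size

    def velocity_zps(self) -> np.ndarray:
        """Signal derivative in Z/s (central difference)."""
        return velocity(self.signal_z, self.rate_hz)

    def index_at(self, t: float) -> int:
        return int(round((t - self.time_s[0]) * self.rate_hz))

    def covers(self, t0: float, t1: float) -> bool:
        return t0 >= self.time_s[0] - 1e-9 and t1 <= self.time_s[-1] + 1e-9
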