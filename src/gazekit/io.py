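"""Readers and writers for session inputs and analysis outputs.

Inputs
------
* Pose tables in the three-header-row pose-estimation dialect
  (``scorer`` / ``bodyparts`` / ``coords`` header rows, then one row per
  frame with x, y, likelihood per tracked point).  The eye tracker follows
  four points: the left and right edges of the pupil and of the corneal
  reflection.
* Head-sensor (load cell) traces as two-column CSV (time_s, volts),
  nominally 2000 Hz from the DAQ.
* Stimulus logs as CSV (time_s, modality, side).

Outputs
-------
* Per-saccade event tables (one CSV row per detected saccade with its
  attempted-head-movement metrics), schema-versioned.
* Ground truth and fitted results as JSON.

All files are comma-separated, '.'-decimal, UTF-8, header mandatory; times
are float64 seconds with session start at 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, TimingError

__all__ = [
    "REQUIRED_PARTS",
    "PoseTable",
    "StimulusLog",
    "read_pose_table",
    "write_pose_table",
    "read_head_trace",
    "write_head_trace",
    "read_stimulus_log",
    "write_stimulus_log",
    "write_event_tables",
    "read_event_tables",
    "write_json",
    "read_json",
]

#: Tracked points required for the angular-position conversion.
REQUIRED_PARTS = (
    "pupil_left_edge",
    "pupil_right_edge",
    "cr_left_edge",
    "cr_right_edge",
)

EVENT_TABLE_SCHEMA_VERSION = 1

#: Event tables round-trip at 9 significant digits; raw traces and pose
#: tables use 12 so write-read is an identity at float-noise level.
_FLOAT_FMT = "%.9g"
_TRACE_FMT = "%.12g"


@dataclass
class PoseTable:
    """Tracked eye landmarks, one (x, y, likelihood) triple per point per frame."""

    points: dict  # part name -> float array of shape (n_frames, 3)
    rate_hz: float = 100.0
    valid: np.ndarray = None  # set by likelihood filtering

    def __post_init__(self):
        n = {p: a.shape[0] for p, a in self.points.items()}
        if len(set(n.values())) > 1:
            raise SchemaError(f"tracked points disagree on frame count: {n}")
        for part in REQUIRED_PARTS:
            if part not in self.points:
                raise SchemaError(f"required tracked point missing: {part!r}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.points.values())).shape[0]

    def likelihood(self, part: str) -> np.ndarray:
        return self.points[part][:, 2]

    def x(self, part: str) -> np.ndarray:
        return self.points[part][:, 0]

    def y(self, part: str) -> np.ndarray:
        return self.points[part][:, 1]


@dataclass
class StimulusLog:
    """Ordered stimulus events: time (s), modality, side ('left'/'right'/'n/a')."""

    times: np.ndarray
    modalities: np.ndarray
    sides: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.modalities = np.asarray(self.modalities, dtype=object)
        self.sides = np.asarray(self.sides, dtype=object)
        if not (self.times.shape == self.modalities.shape == self.sides.shape):
            raise SchemaError("stimulus log columns differ in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise SchemaError("stimulus times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def conditions(self) -> list:
        """Distinct (modality, side) pairs in log order."""
        seen, out = set(), []
        for m, s in zip(self.modalities, self.sides):
            if (m, s) not in seen:
                seen.add((m, s))
                out.append((m, s))
        return out

    def select(self, modality=None, side=None) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        if modality is not None:
            mask &= self.modalities == modality
        if side is not None:
            mask &= self.sides == side
        return self.times[mask]


# ---------------------------------------------------------------------------
# Pose tables


def read_pose_table(path, rate_hz: float = 100.0) -> PoseTable:
    """Read a pose table in the three-header-row dialect.

    Missing likelihood columns are treated as likelihood 1 (hand-made
    fixtures); missing cells map to likelihood 0 for that frame.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: not a three-header-row pose table ({exc})") from exc
    bodyparts = [c[1] for c in df.columns]
    points: dict[str, np.ndarray] = {}
    for part in sorted(set(bodyparts)):
        sub = df.loc[:, [c for c in df.columns if c[1] == part]]
        coords = {c[2]: np.asarray(sub[c]) for c in sub.columns}
        if "x" not in coords or "y" not in coords:
            raise SchemaError(f"{path}: point {part!r} lacks x/y columns")
        n = len(df)
        arr = np.empty((n, 3), dtype=float)
        for j, key in enumerate(("x", "y")):
            col = coords[key]
            try:
                arr[:, j] = pd.to_numeric(col, errors="raise")
            except (ValueError, TypeError) as exc:
                bad = np.where(pd.to_numeric(col, errors="coerce") != pd.to_numeric(col, errors="coerce"))[0]
                row = int(bad[0]) if bad.size else -1
                raise ParseError(f"{path}: non-numeric {key} for {part!r} at row {row}") from exc
        arr[:, 2] = pd.to_numeric(coords["likelihood"], errors="coerce") if "likelihood" in coords else 1.0
        # cells the tracker left empty carry no information: likelihood 0
        nan_xy = np.isnan(arr[:, 0]) | np.isnan(arr[:, 1])
        arr[nan_xy, 2] = 0.0
        arr[np.isnan(arr[:, 2]), 2] = 0.0
        points[part] = arr
    pose = PoseTable(points=points, rate_hz=rate_hz)
    if pose.n_frames == 0:
        raise SchemaError(f"{path}: pose table has no frames")
    for part in REQUIRED_PARTS:
        col = pose.points[part]
        if np.all(np.isnan(col[:, 0])):
            raise SchemaError(f"{path}: point {part!r} is all-NaN")
    return pose


def write_pose_table(pose: PoseTable, path, scorer: str = "gazekit-synth") -> None:
    """Write ``pose`` in the three-header-row dialect (inverse of the reader)."""
    parts = list(pose.points)
    cols = pd.MultiIndex.from_tuples(
        [(scorer, p, c) for p in parts for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.hstack([pose.points[p] for p in parts])
    df = pd.DataFrame(data, columns=cols)
    df.to_csv(path, float_format=_TRACE_FMT, index_label=None)


# ---------------------------------------------------------------------------
# Head traces and stimulus logs


def read_head_trace(path, raw_rate_hz: float = 2000.0):
    """Read a two-column (time_s, volts) trace and validate its clock.

    The declared rate is checked against the median sample interval within
    1%, and any gap larger than 1.5 sample intervals (a dropped chunk) is a
    timing error.

    Returns ``(time_s, volts)`` float arrays.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns (time_s, volts)")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(t)) or np.any(np.isnan(v)):
        raise ParseError(f"{path}: non-numeric sample in head trace")
    if t.size < 2:
        raise TimingError(f"{path}: too few samples to validate timing")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TimingError(f"{path}: time is not strictly increasing")
    nominal = 1.0 / raw_rate_hz
    med = float(np.median(dt))
    if abs(med - nominal) > 0.01 * nominal:
        raise TimingError(
            f"{path}: median sample interval {med:.6g}s disagrees with declared "
            f"rate {raw_rate_hz:g} Hz by more than 1%"
        )
    if float(np.max(dt)) > 1.5 * nominal:
        raise TimingError(f"{path}: gap of {np.max(dt):.6g}s in a {raw_rate_hz:g} Hz trace")
    return t, v


def write_head_trace(time_s: np.ndarray, volts: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": time_s, "volts": volts}).to_csv(
        path, index=False, float_format=_TRACE_FMT
    )


def read_stimulus_log(path) -> StimulusLog:
    df = pd.read_csv(path)
    for col in ("time_s", "modality", "side"):
        if col not in df.columns:
            raise SchemaError(f"{path}: stimulus log lacks column {col!r}")
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise ParseError(f"{path}: non-numeric stimulus time")
    return StimulusLog(t, df["modality"].to_numpy(object), df["side"].to_numpy(object))


def write_stimulus_log(log: StimulusLog, path) -> None:
    pd.DataFrame(
        {"time_s": log.times, "modality": log.modalities, "side": log.sides}
    ).to_csv(path, index=False, float_format=_TRACE_FMT)


# ---------------------------------------------------------------------------
# Event tables

_EVENT_COLUMNS = [
    "onset_s",
    "offset_s",
    "start_deg",
    "end_deg",
    "amplitude_deg",
    "peak_vel_dps",
    "direction",
    "class",
    "stimulus_index",
    "stimulus_modality",
    "stimulus_side",
    "head_disp_z_150",
    "head_vel_z_60",
    "head_latency_ms",
    "head_direction",
    "schema_version",
]


def write_event_tables(gaze_shifts: Sequence, path) -> None:
    """One CSV row per saccade with its head-coupling metrics.

    Floats are written with 9 significant digits so a read-back reproduces
    them; the writer is byte-stable for identical input.
    """
    rows = []
    for gs in gaze_shifts:
        s = gs.saccade
        rows.append(
            {
                "onset_s": s.onset_s,
                "offset_s": s.offset_s,
                "start_deg": s.start_deg,
                "end_deg": s.end_deg,
                "amplitude_deg": s.amplitude_deg,
                "peak_vel_dps": s.peak_vel_dps,
                "direction": s.direction,
                "class": s.klass,
                "stimulus_index": "" if s.stimulus_index is None else s.stimulus_index,
                "stimulus_modality": s.stimulus_modality or "",
                "stimulus_side": s.stimulus_side or "",
                "head_disp_z_150": _opt(gs.head_disp_z),
                "head_vel_z_60": _opt(gs.head_vel_z_s),
                "head_latency_ms": _opt(gs.head_latency_ms),
                "head_direction": gs.head_direction,
                "schema_version": EVENT_TABLE_SCHEMA_VERSION,
            }
        )
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _opt(x):
    return "" if x is None else x


def read_event_tables(path):
    """Read an event table back into ``GazeShift`` objects."""
    from .detection import GazeShift, Saccade  # local import: avoid cycle

    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        sac = Saccade(
            onset_s=float(r["onset_s"]),
            offset_s=float(r["offset_s"]),
            start_deg=float(r["start_deg"]),
            end_deg=float(r["end_deg"]),
            amplitude_deg=float(r["amplitude_deg"]),
            peak_vel_dps=float(r["peak_vel_dps"]),
            klass=str(r["class"]),
            stimulus_index=None if pd.isna(r["stimulus_index"]) else int(r["stimulus_index"]),
            stimulus_modality=None if pd.isna(r["stimulus_modality"]) else str(r["stimulus_modality"]),
            stimulus_side=None if pd.isna(r["stimulus_side"]) else str(r["stimulus_side"]),
        )
        out.append(
            GazeShift(
                saccade=sac,
                head_disp_z=None if pd.isna(r["head_disp_z_150"]) else float(r["head_disp_z_150"]),
                head_vel_z_s=None if pd.isna(r["head_vel_z_60"]) else float(r["head_vel_z_60"]),
                head_latency_ms=None if pd.isna(r["head_latency_ms"]) else float(r["head_latency_ms"]),
                head_direction=str(r["head_direction"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# JSON helpers


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
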