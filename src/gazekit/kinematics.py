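"""From tracked pixels and raw volts to calibrated, aligned traces.

Eye: the horizontal angular position of each eye is recovered from the
pupil and corneal-reflection edge tracks with the arcsine projection model
of Sakatani & Isa (2004):

    E = asin((pupil_center_x - cr_center_x - offset) / R)

where ``R`` is the effective projection radius of the eyeball in pixels (a
per-setup calibration) and ``offset`` maps the session-mean displacement
to 0 deg.  Frames whose tracking likelihood falls below 0.90 for any
required point are discarded; short gaps (<= 3 frames) are linearly
interpolated, longer gaps stay invalid and break any saccade spanning
them.  Analyses use the average of the two eyes, which cancels the small
nasal/temporal amplitude asymmetry of each eye, and each session is
mean-centered before pooling.

Head: the load-cell voltage recorded at 2000 Hz is low-pass filtered at
80 Hz with a zero-phase (forward-backward) second-order Butterworth
filter, resampled onto the 100 Hz eye clock, and Z-scored per session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    AlignmentError,
    CalibrationError,
    DegenerateSignalError,
    QualityError,
)
from .io import REQUIRED_PARTS, PoseTable
from .traces import EyeTrace, HeadTrace

__all__ = [
    "EyeCalibration",
    "filter_pose_likelihood",
    "compute_angular_position",
    "eye_trace_from_pose",
    "average_eyes",
    "condition_head_signal",
]

LIKELIHOOD_THRESHOLD = 0.90
GAP_LIMIT_FRAMES = 3


@dataclass(frozen=True)
class EyeCalibration:
    """Arcsine-model calibration for one camera/eye.

    ``effective_radius_px`` is the projection radius of the rotating eye in
    image pixels.  It depends on eyeball geometry and camera optics and is
    a per-setup input; the default corresponds to a ~1.25 mm effective
    rotation radius imaged at ~0.5x telecentric magnification on typical
    machine-vision pixels, and should be replaced by a measured value for
    real rigs.  ``rightward_positive`` fixes the sign convention (positions
    right of center positive); set False for a camera whose x axis is
    mirrored.
    """

    effective_radius_px: float = 128.0
    rightward_positive: bool = True

    def __post_init__(self):
        if self.effective_radius_px <= 0:
            raise CalibrationError("effective_radius_px must be > 0")


def filter_pose_likelihood(
    pose: PoseTable,
    threshold: float = LIKELIHOOD_THRESHOLD,
    gap_limit_frames: int = GAP_LIMIT_FRAMES,
    max_invalid_frac: float = 0.5,
) -> PoseTable:
    """Mask frames with low tracking confidence and bridge short gaps.

    A frame is invalid when any required point has likelihood below
    ``threshold``.  Runs of at most ``gap_limit_frames`` invalid frames
    flanked by valid frames are linearly interpolated (x and y, per point)
    but remain flagged in ``valid`` only as interpolated-valid; longer
    runs stay invalid.  More than ``max_invalid_frac`` invalid frames is a
    quality error.

    Returns a new :class:`PoseTable` with interpolated coordinates and a
    ``valid`` mask attached.
    """
    n = pose.n_frames
    bad = np.zeros(n, dtype=bool)
    for part in REQUIRED_PARTS:
        bad |= pose.likelihood(part) < threshold
    if bad.mean() > max_invalid_frac:
        raise QualityError(
            f"{bad.mean():.0%} of frames fail the likelihood threshold "
            f"{threshold:g}; session not analyzable"
        )
    valid = ~bad
    fill = np.zeros(n, dtype=bool)  # short gaps to interpolate
    if bad.any() and valid.any():
        # enumerate maximal bad runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            interior = start > 0 and stop < n
            if interior and (stop - start) <= gap_limit_frames:
                fill[start:stop] = True
    points = {}
    good = valid.copy()
    idx = np.arange(n)
    for part, arr in pose.points.items():
        out = arr.copy()
        if fill.any():
            for j in (0, 1):
                out[fill, j] = np.interp(idx[fill], idx[good], arr[good, j])
        points[part] = out
    return PoseTable(points=points, rate_hz=pose.rate_hz, valid=valid | fill)


def compute_angular_position(
    pose: PoseTable,
    cal: EyeCalibration,
    offset_px: float | None = None,
) -> np.ndarray:
    """Horizontal angular eye position (deg) from tracked edges.

    Pupil and corneal-reflection centers are the midpoints of their edge
    pairs; the angular position is the arcsine of their normalized
    horizontal displacement.  ``offset_px=None`` (default) centers the
    displacement on its session mean over valid frames, so the mean
    displacement maps to 0 deg; pass an explicit offset (e.g. 0) to skip
    centering.  A displacement outside the arcsine domain on a valid frame
    is a calibration error.
    """
    pupil = 0.5 * (pose.x("pupil_left_edge") + pose.x("pupil_right_edge"))
    cr = 0.5 * (pose.x("cr_left_edge") + pose.x("cr_right_edge"))
    dx = pupil - cr
    valid = pose.valid if pose.valid is not None else np.ones(dx.shape, bool)
    if offset_px is None:
        offset_px = float(np.mean(dx[valid]))
    arg = (dx - offset_px) / cal.effective_radius_px
    if np.any(np.abs(arg[valid]) > 1.0):
        worst = float(np.max(np.abs(arg[valid])))
        raise CalibrationError(
            f"normalized displacement {worst:.3f} outside the arcsine domain; "
            "check effective_radius_px"
        )
    pos = np.degrees(np.arcsin(np.clip(arg, -1.0, 1.0)))
    if not cal.rightward_positive:
        pos = -pos
    return pos


def eye_trace_from_pose(
    pose: PoseTable,
    cal: EyeCalibration,
    offset_px: float | None = None,
) -> EyeTrace:
    """Convenience: angular conversion plus clock construction."""
    pos = compute_angular_position(pose, cal, offset_px=offset_px)
    t = np.arange(pose.n_frames) / pose.rate_hz
    valid = pose.valid if pose.valid is not None else np.ones(pos.shape, bool)
    return EyeTrace(t, pos, pose.rate_hz, valid)


def average_eyes(left: EyeTrace, right: EyeTrace) -> EyeTrace:
    """Sample-wise mean of the two eyes' positions.

    Both traces must share the clock and the rightward-positive sign
    convention.  The output is valid only where both inputs are valid.
    Averaging cancels each eye's nasal/temporal amplitude asymmetry.
    """
    if len(left) != len(right) or left.rate_hz != right.rate_hz:
        raise AlignmentError("eye traces differ in length or rate")
    if np.any(np.abs(left.time_s - right.time_s) > 1e-9):
        raise AlignmentError("eye traces are on different clocks")
    return EyeTrace(
        left.time_s.copy(),
        0.5 * (left.position_deg + right.position_deg),
        left.rate_hz,
        left.valid & right.valid,
    )


def condition_head_signal(
    raw_time_s: np.ndarray,
    raw_volts: np.ndarray,
    eye_time_s: np.ndarray,
    butterworth_order: int = 2,
    butterworth_cutoff_hz: float = 80.0,
    zscore: bool = True,
    keep_raw: bool = False,
) -> HeadTrace:
    """Filter, resample and standardize the load-cell signal.

    Zero-phase (``filtfilt``) Butterworth low-pass at the raw rate, linear
    interpolation onto the eye clock, then per-session Z-scoring (mean 0,
    SD 1).  Z-scoring makes sessions comparable because each animal
    produces a different range of raw strain-gauge voltages.

    Set ``zscore=False`` to obtain the conditioned signal in volts (the
    conditioning is then linear in the input).
    """
    raw_time_s = np.asarray(raw_time_s, dtype=float)
    raw_volts = np.asarray(raw_volts, dtype=float)
    if raw_time_s.size < 2:
        raise DegenerateSignalError("head trace too short to condition")
    raw_rate = 1.0 / float(np.median(np.diff(raw_time_s)))
    if raw_time_s[-1] - raw_time_s[0] < 1.0:
        raise DegenerateSignalError("need at least 1 s of head samples")
    sos = sps.butter(
        butterworth_order, butterworth_cutoff_hz, btype="low", fs=raw_rate, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, raw_volts)
    eye_time_s = np.asarray(eye_time_s, dtype=float)
    resampled = np.interp(eye_time_s, raw_time_s, filtered)
    if zscore:
        sd = float(np.std(resampled))
        if sd == 0.0:
            raise DegenerateSignalError("head signal has zero variance; cannot Z-score")
        out = (resampled - float(np.mean(resampled))) / sd
    else:
        out = resampled
    rate = 1.0 / float(np.median(np.diff(eye_time_s))) if eye_time_s.size > 1 else 100.0
    return HeadTrace(
        eye_time_s,
        out,
        rate_hz=rate,
        raw_volts=raw_volts if keep_raw else None,
    )
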