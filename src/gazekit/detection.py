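"""Saccade detection, stimulus classification, and head-coupling metrics.

Saccades are eye movements whose speed exceeds 100 deg/s, with at least
3 deg amplitude, and not preceded by another saccade in the previous
100 ms.  Onset and offset are the first samples at which speed rises
above 30 deg/s and falls below 20 deg/s around the detection crossing.
A saccade is *evoked* if its onset falls within the 100 ms response
window after a stimulus, *spontaneous* if no stimulus occurs within
500 ms on either side, and *unclassified* otherwise.

Attempted-head-movement metrics attach to each saccade: displacement is
the conditioned load-cell value 150 ms after saccade onset, referenced to
the trace value 500 ms before onset so that the slow pre-saccadic phase
of spontaneous gaze shifts is included (reference configurable, e.g. 0 ms
to reference at onset); velocity is the signal derivative 60 ms after onset
(when the average load-cell velocity peaks), and latency is the first
crossing of 5 baseline standard deviations within +/-500 ms of onset,
with the baseline taken from -1.0 to -0.5 s on trials where the animal
held the head still there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import TimingError
from .io import StimulusLog
from .traces import EyeTrace, HeadTrace

__all__ = [
    "DetectionConfig",
    "Saccade",
    "GazeShift",
    "detect_saccades",
    "classify_saccades",
    "head_metrics",
    "attach_head_metrics",
    "stimulus_head_probability",
    "check_fixation",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and windows for detection, classification and coupling."""

    vel_detect_dps: float = 100.0
    min_amp_deg: float = 3.0
    refractory_ms: float = 100.0
    onset_vel_dps: float = 30.0
    offset_vel_dps: float = 20.0
    response_window_ms: float = 100.0
    spont_exclusion_ms: float = 500.0
    head_prob_threshold_z: float = 0.25
    head_disp_lag_ms: float = 150.0
    head_disp_ref_ms: float = -500.0  # reference time for displacement; 0 = saccade onset
    head_vel_lag_ms: float = 60.0
    latency_sd_mult: float = 5.0
    latency_search_ms: tuple = (-500.0, 500.0)
    head_baseline_ms: tuple = (-1000.0, -500.0)
    fixation_band_z: float = 0.25
    head_vel_max_over_window: bool = False  # alternative: max |velocity| on [0, 60] ms

    def __post_init__(self):
        import warnings

        if not (self.offset_vel_dps < self.onset_vel_dps < self.vel_detect_dps):
            warnings.warn(
                "velocity thresholds break the offset < onset < detect ordering",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Saccade:
    """One detected rapid eye movement."""

    onset_s: float
    offset_s: float
    start_deg: float
    end_deg: float
    amplitude_deg: float  # signed, end - start
    peak_vel_dps: float
    klass: str = "unclassified"
    stimulus_index: Optional[int] = None
    stimulus_modality: Optional[str] = None
    stimulus_side: Optional[str] = None

    @property
    def direction(self) -> str:
        return "right" if self.amplitude_deg > 0 else "left"


@dataclass(frozen=True)
class GazeShift:
    """A saccade paired with its attempted-head-movement metrics.

    Metrics are ``None`` when the head trace does not cover the required
    window around the saccade (or, for latency, when head fixation was not
    maintained during the baseline period).
    """

    saccade: Saccade
    head_disp_z: Optional[float] = None  # value at +150 ms minus reference value
    head_vel_z_s: Optional[float] = None  # derivative at +60 ms
    head_latency_ms: Optional[float] = None
    head_direction: str = "none"  # 'ipsiversive' | 'contraversive' | 'none'


def detect_saccades(eye: EyeTrace, cfg: DetectionConfig = DetectionConfig()) -> list:
    """Velocity-threshold saccade detection on a centered eye trace.

    For each maximal epoch with speed above ``vel_detect_dps``, the onset
    is found by walking backward to the first sample whose speed rises
    above ``onset_vel_dps`` and the offset forward to the first sample
    whose speed falls below ``offset_vel_dps``.  Candidates are kept when
    the onset-to-offset displacement reaches ``min_amp_deg``, the onset
    clears the refractory period after the previously accepted saccade,
    and no invalid frame falls inside the event.
    """
    dt = np.diff(eye.time_s)
    if dt.size and (np.max(dt) - np.min(dt)) > 1e-6:
        raise TimingError("saccade detection requires uniform sampling")
    x = eye.position_deg
    speed = np.abs(eye.velocity_dps())
    above = speed > cfg.vel_detect_dps
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    refractory_s = cfg.refractory_ms / 1000.0
    out: list[Saccade] = []
    last_onset = -np.inf
    n = x.size
    for e0, e1 in zip(edges[::2], edges[1::2]):
        # onset: last run of samples with speed >= onset threshold before the
        # detection crossing; walking back anchors "first rose above 30 deg/s"
        # to this event rather than to earlier drift
        i = e0
        while i > 0 and speed[i - 1] >= cfg.onset_vel_dps:
            i -= 1
        onset = i
        j = e1 - 1
        while j < n - 1 and speed[j + 1] >= cfg.offset_vel_dps:
            j += 1
        offset = min(j + 1, n - 1)  # first sample below the offset threshold
        if onset == 0 or offset == n - 1:
            continue  # event truncated by the trace edge
        if not eye.valid[onset : offset + 1].all():
            continue  # spans a tracking dropout
        amp = x[offset] - x[onset]
        if abs(amp) < cfg.min_amp_deg:
            continue
        t_on = eye.time_s[onset]
        if out and t_on == out[-1].onset_s:
            continue  # same event reached from a split epoch
        if t_on - last_onset < refractory_s:
            continue
        out.append(
            Saccade(
                onset_s=t_on,
                offset_s=eye.time_s[offset],
                start_deg=x[onset],
                end_deg=x[offset],
                amplitude_deg=amp,
                peak_vel_dps=float(np.max(speed[onset : offset + 1])),
            )
        )
        last_onset = t_on
    return out


def classify_saccades(
    saccades: Sequence[Saccade],
    stimuli: StimulusLog,
    cfg: DetectionConfig = DetectionConfig(),
) -> list:
    """Label each saccade evoked / spontaneous / unclassified.

    Evoked: onset in ``(t_stim, t_stim + response_window]`` for some
    stimulus, attributed to the nearest preceding stimulus.  Spontaneous:
    no stimulus within ``spont_exclusion_ms`` of onset.
    """
    win = cfg.response_window_ms / 1000.0
    excl = cfg.spont_exclusion_ms / 1000.0
    times = stimuli.times
    out = []
    for sac in saccades:
        t = sac.onset_s
        klass, idx, modality, side = "unclassified", None, None, None
        if times.size:
            j = int(np.searchsorted(times, t, side="left")) - 1
            if j >= 0 and 0.0 < t - times[j] <= win:
                klass, idx = "evoked", j
                modality, side = stimuli.modalities[j], stimuli.sides[j]
            else:
                dmin = float(np.min(np.abs(times - t)))
                if dmin > excl:
                    klass = "spontaneous"
        else:
            klass = "spontaneous"
        out.append(
            replace(
                sac,
                klass=klass,
                stimulus_index=idx,
                stimulus_modality=modality,
                stimulus_side=side,
            )
        )
    return out


def head_metrics(
    saccade: Saccade,
    head: HeadTrace,
    cfg: DetectionConfig = DetectionConfig(),
) -> GazeShift:
    """Attach attempted-head-movement metrics to one saccade."""
    t_on = saccade.onset_s
    b0, b1 = (v / 1000.0 for v in cfg.head_baseline_ms)
    s0, s1 = (v / 1000.0 for v in cfg.latency_search_ms)
    need_lo = t_on + min(b0, s0)
    need_hi = t_on + max(s1, cfg.head_disp_lag_ms / 1000.0)
    if not head.covers(need_lo, need_hi):
        return GazeShift(saccade=saccade)

    sig = head.signal_z
    i_ref = head.index_at(t_on + cfg.head_disp_ref_ms / 1000.0)
    i_disp = head.index_at(t_on + cfg.head_disp_lag_ms / 1000.0)
    disp = float(sig[i_disp] - sig[i_ref])

    i_vel = head.index_at(t_on + cfg.head_vel_lag_ms / 1000.0)
    vel_trace = head.velocity_zps()
    if cfg.head_vel_max_over_window:
        seg = vel_trace[i_on : i_vel + 1]
        vel = float(seg[np.argmax(np.abs(seg))])
    else:
        vel = float(vel_trace[i_vel])

    ib0, ib1 = head.index_at(t_on + b0), head.index_at(t_on + b1)
    baseline = sig[ib0:ib1]
    bmean = float(np.mean(baseline))
    bsd = float(np.std(baseline))
    latency = None
    fixated = bool(np.all(np.abs(baseline - bmean) < cfg.fixation_band_z))
    if fixated and bsd > 0:
        is0, is1 = head.index_at(t_on + s0), head.index_at(t_on + s1)
        dev = np.abs(sig[is0 : is1 + 1] - bmean)
        crossing = np.flatnonzero(dev > cfg.latency_sd_mult * bsd)
        if crossing.size:
            latency = float((head.time_s[is0 + crossing[0]] - t_on) * 1000.0)

    if disp == 0.0:
        direction = "none"
    elif (disp > 0) == (saccade.amplitude_deg > 0):
        direction = "ipsiversive"
    else:
        direction = "contraversive"
    return GazeShift(
        saccade=saccade,
        head_disp_z=disp,
        head_vel_z_s=vel,
        head_latency_ms=latency,
        head_direction=direction,
    )


def attach_head_metrics(
    saccades: Sequence[Saccade],
    head: HeadTrace,
    cfg: DetectionConfig = DetectionConfig(),
) -> list:
    """Vector convenience wrapper over :func:`head_metrics`."""
    return [head_metrics(s, head, cfg) for s in saccades]


def stimulus_head_probability(
    stimuli: StimulusLog,
    head: HeadTrace,
    cfg: DetectionConfig = DetectionConfig(),
    signed: bool = False,
):
    """Per-condition probability of a stimulus-evoked attempted head movement.

    A trial counts as a response when the head signal 150 ms after stimulus
    onset (referenced to its value at onset) exceeds the 0.25 Z threshold:
    in absolute value by default, or toward the stimulus side when
    ``signed`` (left stimuli count negative deflections, right positive).
    The baseline probability applies the same rule to the value at -350 ms
    referenced to -500 ms.  Results are stable across thresholds of
    roughly 0.1-2 Z when responses are strong.

    Returns ``{(modality, side): {"evoked": p, "baseline": p, "n": n}}``.
    """
    lag = cfg.head_disp_lag_ms / 1000.0
    thr = cfg.head_prob_threshold_z
    out = {}
    for modality, side in stimuli.conditions():
        times = stimuli.select(modality, side)
        hits = base_hits = 0
        n = 0
        for t in times:
            if not head.covers(t - 0.5, t + lag):
                continue
            n += 1
            d_ev = head.signal_z[head.index_at(t + lag)] - head.signal_z[head.index_at(t)]
            d_bl = (
                head.signal_z[head.index_at(t - 0.35)]
                - head.signal_z[head.index_at(t - 0.5)]
            )
            if signed and side in ("left", "right"):
                sign = -1.0 if side == "left" else 1.0
                hits += sign * d_ev > thr
                base_hits += sign * d_bl > thr
            else:
                hits += abs(d_ev) > thr
                base_hits += abs(d_bl) > thr
        out[(modality, side)] = {
            "evoked": hits / n if n else np.nan,
            "baseline": base_hits / n if n else np.nan,
            "n": n,
        }
    return out


def check_fixation(
    saccades: Sequence[Saccade],
    head: Optional[HeadTrace],
    t0: float,
    eye_window_s: tuple = (-0.5, 0.0),
    cfg: DetectionConfig = DetectionConfig(),
    eye_trace: Optional[EyeTrace] = None,
    position_gate_deg: Optional[tuple] = None,
) -> bool:
    """True when the animal held eyes and head still before ``t0``.

    No detected saccade onset may fall in ``t0 + eye_window_s`` and the
    head signal must stay within the fixation band around its window mean.
    ``position_gate_deg`` optionally additionally requires the eye
    position at ``t0`` to fall inside the given interval (the central
    -2..0 deg criterion used for optogenetic trials).
    """
    w0, w1 = (t0 + v for v in eye_window_s)
    for s in saccades:
        if w0 <= s.onset_s < w1:
            return False
    if head is not None and head.covers(w0, w1):
        seg = head.signal_z[head.index_at(w0) : head.index_at(w1) + 1]
        if seg.size and np.any(np.abs(seg - np.mean(seg)) >= cfg.fixation_band_z):
            return False
    if position_gate_deg is not None:
        if eye_trace is None:
            raise ValueError("position gate requires the eye trace")
        pos = eye_trace.position_deg[eye_trace.index_at(t0)]
        lo, hi = position_gate_deg
        if not (lo <= pos <= hi):
            return False
    return True
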