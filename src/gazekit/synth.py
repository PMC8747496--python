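"""Ground-truth-annotated synthetic head-fixed sessions.

The generator emulates the statistical structure of a head-fixed mouse
session: conjugate two-eye position traces built from fixations with
Gaussian jitter plus logistic (sigmoid) saccade waveforms obeying a linear
main sequence; a load-cell channel in which spontaneous gaze shifts carry
a slow attempted-head ramp starting 100-200 ms before saccade onset plus a
fast component coincident with onset, while stimulus-evoked gaze shifts
carry only the fast component; a stimulus schedule with 7-12 s uniform
inter-trial intervals (350 trials per session by default, ~55 min); and
evoked saccade amplitudes depending linearly on initial eye position.

Every event the generator plants is recorded in a :class:`GroundTruth`
object, so each downstream stage (detection, classification, coupling
statistics) can be scored against known truth without any data download.

Saccade waveform
----------------
Position follows a logistic sigmoid, ``x(t) = A / (1 + exp(-k (t - tc)))``
whose analytic peak velocity is ``A k / 4``.  ``k`` is chosen so the peak
velocity matches the main-sequence target ``V = gain * |A| + intercept``,
giving closed-form velocities for oracle checks.  Ground-truth onset is
the analytic time at which the waveform's speed rises above the 30 deg/s
onset criterion used downstream.

Head channel scaling
--------------------
Event amplitudes are specified in Z units, i.e. on the scale of the
conditioned (session-standardized) signal.  When background noise is
enabled, the generator budgets a slow Ornstein-Uhlenbeck "posture wander"
component so the synthesized session has unit variance, making the
downstream Z-scoring a near no-op and keeping the configured coupling
gains meaningful after conditioning.  With ``head_noise_sd = 0`` the
channel contains the noiseless event signal only (exact-arithmetic mode
for tests); session standardization would then rescale it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, GenerationError
from .io import PoseTable, StimulusLog
from .kinematics import EyeCalibration
from .traces import EyeTrace, HeadTrace

__all__ = [
    "StimulusClass",
    "SimulationConfig",
    "GroundTruthSaccade",
    "HeadEvent",
    "GroundTruth",
    "SyntheticSession",
    "generate_session",
    "emit_pose_tables",
    "sample_gaze_shift_population",
]


@dataclass(frozen=True)
class StimulusClass:
    """One stimulus condition and its evoked-saccade geometry.

    ``amp_slope`` / ``amp_intercept_{left,right}`` parameterize the linear
    dependence of evoked amplitude on initial eye position,
    ``amp = intercept_side + slope * position + noise``.  A slope of -1
    with intercept 0 is pure recentering (endpoints at center, the
    auditory regime); nonzero intercepts bias endpoints toward the
    stimulus side (the ear-airpuff regime, endpoints near +/-5.4 deg).
    """

    modality: str = "ear_airpuff"
    #: probability that a stimulus elicits an intended gaze shift; intents
    #: whose amplitude falls below the ~3.5 deg saccade floor produce no
    #: saccade, so the realized evoked-saccade probability is ~0.29 per
    #: trial (the ear-airpuff condition) at the 0.44 default
    evoked_prob: float = 0.44
    amp_slope: float = -1.0
    amp_intercept_left: float = -5.4
    amp_intercept_right: float = 5.4

    def intercept(self, side: str) -> float:
        return self.amp_intercept_left if side == "left" else self.amp_intercept_right


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic session.

    Defaults reproduce the study conditions: 350 stimuli per session at
    7-12 s uniform intervals (~55 min), 100 Hz eye sampling, 2000 Hz raw
    head sampling, a ~0.13 Hz spontaneous saccade rate (1.3% baseline
    probability per 100 ms window), head-eye coupling gains of 0.214 Z/deg
    for spontaneous and 0.162 Z/deg for evoked gaze shifts, and a slow
    attempted-head lead drawn uniformly from 100-200 ms before spontaneous
    saccades.
    """

    n_stimuli: int = 350
    iti_range_s: tuple = (7.0, 12.0)
    session_duration_s: Optional[float] = None  # None: ends 10 s after last stimulus
    eye_rate_hz: float = 100.0
    head_raw_rate_hz: float = 2000.0
    #: candidate Poisson rate; the intersaccadic dead time (mice rarely
    #: saccade in quick succession) and the stimulus guard zone thin this
    #: to ~0.13 Hz realized, i.e. a ~1.3% baseline probability per 100 ms
    #: quiet window
    spont_saccade_rate_hz: float = 0.19
    spont_dead_time_s: float = 1.6
    #: spontaneous events are cleared from this window around each stimulus
    #: so that a neighboring event's head response can never overlap an
    #: evoked trial's measurement points (the -500 ms reference and the
    #: +150 ms displacement); quiet-window statistics are unaffected
    spont_stimulus_guard_s: tuple = (1.5, 1.6)
    stimulus_classes: tuple = (StimulusClass(),)
    evoked_latency_range_ms: tuple = (30.0, 90.0)
    evoked_amp_noise_sd: float = 1.2
    spont_amp_range_deg: tuple = (3.5, 15.0)
    min_saccade_amp_deg: float = 3.5
    position_limit_deg: float = 12.0
    recenter_bias: float = 0.6  # P(spontaneous saccade heads toward center)
    main_sequence_gain: float = 45.0  # (deg/s)/deg
    main_sequence_intercept: float = 100.0  # deg/s
    coupling_gain_spont: float = 0.214  # Z/deg
    coupling_gain_evoked: float = 0.162  # Z/deg
    coupling_noise_sd: float = 0.9  # Z, per-event residual
    slow_head_lead_ms: tuple = (100.0, 200.0)
    head_pulse_rise_ms: float = 120.0
    head_pulse_hold_ms: float = 280.0
    head_pulse_decay_ms: float = 600.0
    eye_noise_sd: float = 0.2  # deg, per eye
    eye_asymmetry: float = 0.08  # fractional temporal-vs-nasal amplitude asymmetry
    head_noise_sd: float = 0.05  # Z, white background (0.05-0.1 Z baseline SD)
    head_wander_tau_s: float = 20.0  # slow posture-drift correlation time
    volt_scale: float = 0.5
    volt_offset: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.iti_range_s
        if not lo < hi:
            raise ConfigurationError("iti_range_s must satisfy low < high")
        if self.eye_rate_hz <= 0 or self.head_raw_rate_hz <= 0:
            raise ConfigurationError("sampling rates must be > 0")
        if self.spont_saccade_rate_hz < 0:
            raise ConfigurationError("spont_saccade_rate_hz must be >= 0")
        for cls in self.stimulus_classes:
            if not 0.0 <= cls.evoked_prob <= 1.0:
                raise ConfigurationError("evoked_prob must lie in [0, 1]")
        if self.n_stimuli < 0:
            raise ConfigurationError("n_stimuli must be >= 0")
        if self.main_sequence_gain <= 0:
            raise ConfigurationError("main_sequence_gain must be > 0")
        llo, lhi = self.evoked_latency_range_ms
        if not 0 <= llo < lhi:
            raise ConfigurationError("evoked_latency_range_ms must satisfy 0 <= low < high")
        if self.coupling_gain_spont < self.coupling_gain_evoked:
            # paper regime has spont > evoked; other orderings are legal but unusual
            import warnings

            warnings.warn(
                "coupling_gain_spont < coupling_gain_evoked inverts the "
                "slow-phase contribution observed in the data",
                stacklevel=2,
            )


@dataclass
class GroundTruthSaccade:
    """One planted saccade with everything needed to score the pipeline."""

    onset_s: float  # analytic 30 deg/s crossing
    amplitude_deg: float  # signed, in the 30/20 deg/s threshold convention
    full_step_deg: float  # signed asymptotic step of the waveform
    initial_pos_deg: float  # fixation position before the saccade (noise-free)
    peak_vel_dps: float  # analytic A*k/4
    klass: str  # 'evoked' | 'spontaneous' | 'unclassified'
    stimulus_index: Optional[int]
    head_disp_z: float  # total attempted-head displacement at onset + 150 ms
    slow_lead_s: Optional[float]  # slow-phase lead before onset (spontaneous only)


@dataclass
class HeadEvent:
    onset_s: float
    displacement_z: float
    phase: str  # 'slow' | 'fast'


@dataclass
class GroundTruth:
    saccades: list
    head_events: list

    def onsets(self, klass: Optional[str] = None) -> np.ndarray:
        return np.array(
            [s.onset_s for s in self.saccades if klass is None or s.klass == klass]
        )


@dataclass
class SyntheticSession:
    config: SimulationConfig
    eye_left: EyeTrace
    eye_right: EyeTrace
    head_z: HeadTrace  # generator-domain Z signal on the eye clock
    head_raw_time_s: Optional[np.ndarray]
    head_raw_volts: Optional[np.ndarray]
    stimuli: StimulusLog
    ground_truth: GroundTruth

    @property
    def eye_avg(self) -> EyeTrace:
        from .kinematics import average_eyes

        return average_eyes(self.eye_left, self.eye_right)


# ---------------------------------------------------------------------------
# waveform helpers


def _logistic_rate(amp: float, peak_vel: float) -> float:
    """Logistic rate constant k (1/s) giving analytic peak velocity A*k/4."""
    return 4.0 * peak_vel / abs(amp)


def _threshold_sigma(amp_abs: float, k: float, threshold_dps: float, rising: bool) -> float:
    """Logistic value at the speed-threshold crossing.

    The waveform speed is ``A k s (1 - s)`` for logistic value ``s``; the
    rising (onset) crossing has s < 1/2, the falling (offset) one s > 1/2.
    """
    r = threshold_dps / (amp_abs * k)
    if r >= 0.25:
        return 0.5
    root = math.sqrt(1.0 - 4.0 * r)
    return 0.5 * (1.0 - root) if rising else 0.5 * (1.0 + root)


def _solve_event_kinematics(
    amp_full: float,
    gain: float,
    intercept: float,
    onset_dps: float = 30.0,
    offset_dps: float = 20.0,
):
    """Peak velocity, logistic rate and threshold-convention amplitude.

    The observable amplitude of a saccade is the displacement between the
    30 deg/s onset and 20 deg/s offset speed crossings — the convention
    every downstream measurement uses — which excludes the waveform's
    sub-threshold tails.  The main sequence is planted on that observable
    amplitude, ``V = gain * A_obs + intercept``; because the crossings
    depend on V the pair is solved by fixed-point iteration (converges in
    a few steps).

    Returns ``(peak_vel, k, amp_obs_abs)`` for ``|amp_full|``.
    """
    a = abs(amp_full)
    a_obs = a
    for _ in range(6):
        peak_vel = gain * a_obs + intercept
        k = _logistic_rate(a, peak_vel)
        s_on = _threshold_sigma(a, k, onset_dps, rising=True)
        s_off = _threshold_sigma(a, k, offset_dps, rising=False)
        a_obs = a * (s_off - s_on)
    return peak_vel, k, a_obs


def _onset_lag_s(amp: float, k: float, threshold_dps: float = 30.0) -> float:
    """Time from the 30 deg/s speed crossing to the waveform center.

    Solves A*k*s*(1-s) = threshold for the logistic value s < 1/2; the
    crossing precedes the center by -logit(s)/k.
    """
    r = threshold_dps / (abs(amp) * k)
    if r >= 0.25:  # speed never drops to threshold; tiny event
        return 0.0
    s = 0.5 * (1.0 - math.sqrt(1.0 - 4.0 * r))
    return -math.log(s / (1.0 - s)) / k


_SUPPORT = 7.0  # waveform support half-width in units of 1/k


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0 at u<=0, 1 at u>=1, C2-continuous."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


# ---------------------------------------------------------------------------
# generator


@dataclass
class _PlannedSaccade:
    onset_s: float
    center_s: float
    amp: float  # full asymptotic step (position bookkeeping)
    amp_obs: float  # signed threshold-convention amplitude (observable)
    k: float
    peak_vel: float
    initial_pos: float
    klass: str
    stimulus_index: Optional[int]
    fast_z: float = 0.0
    slow_z: float = 0.0
    slow_lead_s: float = 0.0


def generate_session(config: SimulationConfig, raw_head: bool = True) -> SyntheticSession:
    """Generate one synthetic session.

    Deterministic for a fixed ``config.seed``.  ``raw_head=False`` skips
    synthesis of the 2000 Hz raw voltage channel (the 100 Hz Z-domain head
    signal is always produced), which is convenient for detector-only
    studies.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_sched, rng_events, rng_eye, rng_head = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    # -- stimulus schedule: uniform ITIs, random side, random class
    lead_in = 5.0
    itis = rng_sched.uniform(*config.iti_range_s, size=config.n_stimuli)
    stim_times = lead_in + np.cumsum(itis)
    sides = np.where(rng_sched.random(config.n_stimuli) < 0.5, "left", "right")
    cls_idx = rng_sched.integers(0, len(config.stimulus_classes), size=config.n_stimuli)
    modalities = np.array(
        [config.stimulus_classes[i].modality for i in cls_idx], dtype=object
    )
    if config.session_duration_s is not None:
        duration = float(config.session_duration_s)
        keep = stim_times < duration - 1.0
        stim_times, sides, cls_idx, modalities = (
            stim_times[keep],
            sides[keep],
            cls_idx[keep],
            modalities[keep],
        )
    else:
        duration = (stim_times[-1] if stim_times.size else lead_in) + 10.0
    stimuli = StimulusLog(stim_times, modalities, sides)

    # -- spontaneous onset process: Poisson candidates thinned to an
    #    intersaccadic dead time and cleared from the guard zone around
    #    each stimulus (see SimulationConfig.spont_stimulus_guard_s)
    spont_times: list[float] = []
    guard_pre, guard_post = config.spont_stimulus_guard_s
    if config.spont_saccade_rate_hz > 0:
        n_exp = rng_events.poisson(config.spont_saccade_rate_hz * (duration - 3.0))
        cand = np.sort(rng_events.uniform(1.0, duration - 2.0, size=n_exp))
        last = -np.inf
        for t in cand:
            if t - last < config.spont_dead_time_s:
                continue
            if stim_times.size:
                j = np.searchsorted(stim_times, t)
                near_next = j < stim_times.size and stim_times[j] - t < guard_pre
                near_prev = j > 0 and t - stim_times[j - 1] < guard_post
                if near_next or near_prev:
                    continue
            spont_times.append(float(t))
            last = t

    # -- build the chronological event list, tracking fixation position
    planned: list[_PlannedSaccade] = []
    pos = 0.0
    lat_lo, lat_hi = (v / 1000.0 for v in config.evoked_latency_range_ms)
    events = [(t, "spont", None) for t in spont_times] + [
        (stim_times[j], "stim", j) for j in range(stim_times.size)
    ]
    events.sort(key=lambda e: e[0])
    for t, kind, j in events:
        if kind == "spont":
            a = rng_events.uniform(*config.spont_amp_range_deg)
            toward = -math.copysign(1.0, pos) if pos != 0 else rng_events.choice((-1.0, 1.0))
            if rng_events.random() < config.recenter_bias:
                direction = toward
            else:
                direction = -toward
            if abs(pos + direction * a) > config.position_limit_deg:
                direction = toward
                a = min(a, abs(pos) + config.position_limit_deg)
            amp = direction * a
            if abs(amp) < config.min_saccade_amp_deg:
                continue
            onset = t
            klass = "spontaneous"
            if stim_times.size:
                dmin = float(np.min(np.abs(stim_times - onset)))
                if dmin <= 0.5:
                    klass = "unclassified"
            stim_index = None
        else:
            cls = config.stimulus_classes[cls_idx[j]]
            if rng_events.random() >= cls.evoked_prob:
                continue
            amp = (
                cls.intercept(sides[j])
                + cls.amp_slope * pos
                + rng_events.normal(0.0, config.evoked_amp_noise_sd)
            )
            if abs(amp) < config.min_saccade_amp_deg:
                continue
            onset = t + rng_events.uniform(lat_lo, lat_hi)
            klass = "evoked"
            stim_index = int(j)
        if planned and onset - planned[-1].onset_s < 0.25:
            continue
        peak_vel, k, a_obs = _solve_event_kinematics(
            amp, config.main_sequence_gain, config.main_sequence_intercept
        )
        center = onset + _onset_lag_s(amp, k)
        p = _PlannedSaccade(
            onset_s=onset,
            center_s=center,
            amp=amp,
            amp_obs=math.copysign(a_obs, amp),
            k=k,
            peak_vel=peak_vel,
            initial_pos=pos,
            klass=klass,
            stimulus_index=stim_index,
        )
        planned.append(p)
        pos += amp

    # -- head-event amplitudes (Z units)
    for p in planned:
        eps = rng_events.normal(0.0, config.coupling_noise_sd) if config.coupling_noise_sd else 0.0
        p.fast_z = config.coupling_gain_evoked * p.amp_obs + eps
        if p.klass != "evoked":
            p.slow_z = (config.coupling_gain_spont - config.coupling_gain_evoked) * p.amp_obs
            p.slow_lead_s = rng_events.uniform(*config.slow_head_lead_ms) / 1000.0

    # -- render the noiseless eye trace
    n_eye = int(round(duration * config.eye_rate_hz)) + 1
    t_eye = np.arange(n_eye) / config.eye_rate_hz
    base = np.zeros(n_eye)
    steps = np.zeros(n_eye)
    rate = config.eye_rate_hz
    for p in planned:
        half = _SUPPORT / p.k
        i0 = max(0, int(math.ceil((p.center_s - half) * rate)))
        i1 = min(n_eye, int(math.floor((p.center_s + half) * rate)) + 1)
        tt = t_eye[i0:i1]
        base[i0:i1] += p.amp / (1.0 + np.exp(-p.k * (tt - p.center_s)))
        if i1 < n_eye:
            steps[i1] += p.amp
    # each saccade's asymptotic level takes over where its waveform window ends
    base += np.cumsum(steps)

    # -- per-eye asymmetry: each saccade nudges the eyes apart by
    #    +/- asym * |A| (temporal amplitudes exceed nasal ones), relaxing
    #    back over ~1.5 s so vergence stays bounded.
    asym_l = np.zeros(n_eye)
    asym_r = np.zeros(n_eye)
    if config.eye_asymmetry:
        tau = 1.5
        decay_n = int(5 * tau * rate)
        kernel = np.exp(-np.arange(decay_n) / (tau * rate))
        for p in planned:
            i0 = int(round(p.center_s * rate))
            if i0 >= n_eye:
                continue
            seg = min(decay_n, n_eye - i0)
            bump = config.eye_asymmetry * abs(p.amp)
            asym_l[i0 : i0 + seg] += -bump * kernel[:seg]
            asym_r[i0 : i0 + seg] += bump * kernel[:seg]

    noise_l = rng_eye.normal(0.0, config.eye_noise_sd, n_eye) if config.eye_noise_sd else 0.0
    noise_r = rng_eye.normal(0.0, config.eye_noise_sd, n_eye) if config.eye_noise_sd else 0.0
    eye_left = EyeTrace(t_eye, base + asym_l + noise_l, rate)
    eye_right = EyeTrace(t_eye, base + asym_r + noise_r, rate)

    # -- render the head channel in Z units on the eye clock
    head = np.zeros(n_eye)
    rise = config.head_pulse_rise_ms / 1000.0
    hold = config.head_pulse_hold_ms / 1000.0
    decay = config.head_pulse_decay_ms / 1000.0
    head_events: list[HeadEvent] = []
    for p in planned:
        t_on = p.onset_s
        # fast phase: smoothstep rise to fast_z, plateau, smoothstep decay
        _add_pulse(head, t_eye, rate, t_on, rise, hold, decay, p.fast_z)
        if p.fast_z:
            head_events.append(HeadEvent(t_on, p.fast_z, "fast"))
        if p.slow_z:
            # slow phase: linear ramp from t_on - lead to t_on, then a plateau
            # and the shared decay envelope
            _add_ramp_pulse(
                head, t_eye, rate, t_on, p.slow_lead_s, rise + hold, decay, p.slow_z
            )
            head_events.append(HeadEvent(t_on - p.slow_lead_s, p.slow_z, "slow"))

    if config.head_noise_sd > 0:
        white = rng_head.normal(0.0, config.head_noise_sd, n_eye)
        g = head + white
        g0 = g - g.mean()
        v_g = float(np.mean(g0**2))
        if v_g < 1.0 and config.head_wander_tau_s > 0:
            # slow posture wander, scaled so the session has unit variance
            rho = math.exp(-1.0 / (rate * config.head_wander_tau_s))
            innov = rng_head.normal(0.0, 1.0, n_eye)
            w = np.empty(n_eye)
            w[0] = innov[0]
            fac = math.sqrt(1.0 - rho * rho)
            for i in range(1, n_eye):
                w[i] = rho * w[i - 1] + fac * innov[i]
            w -= w.mean()
            # orthogonalize against the event+noise signal, then scale the
            # remainder to the exact variance budget
            denom = float(np.dot(g0, g0))
            if denom > 0:
                w -= (np.dot(w, g0) / denom) * g0
            w_sd = float(np.sqrt(np.mean(w**2)))
            if w_sd > 0:
                w *= math.sqrt(1.0 - v_g) / w_sd
            head = g + w
        else:
            head = g
    head_trace = HeadTrace(t_eye, head, rate)

    raw_t = raw_v = None
    if raw_head:
        n_raw = int(round(duration * config.head_raw_rate_hz)) + 1
        raw_t = np.arange(n_raw) / config.head_raw_rate_hz
        raw_v = config.volt_scale * np.interp(raw_t, t_eye, head) + config.volt_offset

    gt = GroundTruth(
        saccades=[
            GroundTruthSaccade(
                onset_s=p.onset_s,
                amplitude_deg=p.amp_obs,
                full_step_deg=p.amp,
                initial_pos_deg=p.initial_pos,
                peak_vel_dps=p.peak_vel,
                klass=p.klass,
                stimulus_index=p.stimulus_index,
                head_disp_z=p.fast_z + p.slow_z,
                slow_lead_s=p.slow_lead_s if p.slow_z else None,
            )
            for p in planned
        ],
        head_events=head_events,
    )
    return SyntheticSession(
        config=config,
        eye_left=eye_left,
        eye_right=eye_right,
        head_z=head_trace,
        head_raw_time_s=raw_t,
        head_raw_volts=raw_v,
        stimuli=stimuli,
        ground_truth=gt,
    )


def _add_pulse(out, t, rate, t_on, rise, hold, decay, amp):
    """Smoothstep rise over ``rise`` s, plateau, smoothstep decay."""
    if amp == 0.0:
        return
    i0 = max(0, int(math.floor(t_on * rate)))
    i1 = min(out.size, int(math.ceil((t_on + rise + hold + decay) * rate)) + 1)
    tt = t[i0:i1] - t_on
    env = np.where(
        tt < rise,
        _smoothstep(tt / rise),
        np.where(tt < rise + hold, 1.0, 1.0 - _smoothstep((tt - rise - hold) / decay)),
    )
    env[tt < 0] = 0.0
    out[i0:i1] += amp * env


def _add_ramp_pulse(out, t, rate, t_on, lead, hold, decay, amp):
    """Linear ramp over [t_on - lead, t_on], plateau, smoothstep decay."""
    if amp == 0.0 or lead <= 0:
        return
    t0 = t_on - lead
    i0 = max(0, int(math.floor(t0 * rate)))
    i1 = min(out.size, int(math.ceil((t_on + hold + decay) * rate)) + 1)
    tt = t[i0:i1] - t0
    env = np.where(
        tt < lead,
        tt / lead,
        np.where(tt < lead + hold, 1.0, 1.0 - _smoothstep((tt - lead - hold) / decay)),
    )
    env[tt < 0] = 0.0
    out[i0:i1] += amp * env


# ---------------------------------------------------------------------------
# pose-table emission (inverse of the angular conversion)


def emit_pose_tables(
    eye: EyeTrace,
    cal: EyeCalibration,
    dropout_frac: float = 0.0,
    dropout_likelihood: float = 0.5,
    seed: int = 0,
) -> PoseTable:
    """Render an eye trace as a tracked-point table.

    The pupil center is placed at ``cr_center + R * sin(E)`` so that
    :func:`~gazekit.kinematics.compute_angular_position` (with
    ``offset_px=0``) reproduces the input trace to float precision.
    Likelihoods are 1.0 except at ``dropout_frac`` randomly chosen frames,
    which receive ``dropout_likelihood`` (< 0.90, hence discarded
    downstream).
    """
    pos = eye.position_deg
    if np.any(np.abs(pos) >= 90.0):
        raise GenerationError("angular position outside the arcsine domain (|E| >= 90 deg)")
    n = pos.size
    cr_x, cr_y = 300.0, 200.0
    pupil_y = 200.0
    dx = cal.effective_radius_px * np.sin(np.radians(pos))
    if not cal.rightward_positive:
        dx = -dx
    pupil_x = cr_x + dx
    lik = np.ones(n)
    if dropout_frac > 0:
        rng = np.random.default_rng(seed)
        drop = rng.random(n) < dropout_frac
        lik[drop] = dropout_likelihood
    pupil_half, cr_half = 25.0, 8.0
    ones = np.ones(n)

    def pt(x, y, like):
        return np.column_stack([x, y * ones, like])

    points = {
        "pupil_left_edge": pt(pupil_x - pupil_half, pupil_y, lik),
        "pupil_right_edge": pt(pupil_x + pupil_half, pupil_y, lik),
        "cr_left_edge": pt(cr_x - cr_half * ones, cr_y, ones),
        "cr_right_edge": pt(cr_x + cr_half * ones, cr_y, ones),
    }
    return PoseTable(points=points, rate_hz=eye.rate_hz)


# ---------------------------------------------------------------------------
# light-weight event sampler for statistical calibration


def sample_gaze_shift_population(
    n: int,
    gain: float,
    rng: np.random.Generator,
    amp_range: tuple = (3.5, 15.0),
    noise_sd: float = 0.9,
):
    """Sample (amplitude, head displacement) pairs from the coupling model.

    Amplitudes are signed-uniform over ``amp_range`` magnitudes;
    displacements are ``gain * amp`` plus Gaussian residual.  Used for
    permutation-test calibration studies where full time-series synthesis
    would be wasteful.
    """
    amps = rng.uniform(*amp_range, size=n) * rng.choice((-1.0, 1.0), size=n)
    disps = gain * amps + rng.normal(0.0, noise_sd, size=n)
    return amps, disps
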