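"""Saccade detection, classification, and head-coupling metrics."""

import numpy as np
import pytest

from gazekit.detection import (
    DetectionConfig,
    check_fixation,
    classify_saccades,
    detect_saccades,
    head_metrics,
    stimulus_head_probability,
)
from gazekit.io import StimulusLog
from gazekit.traces import EyeTrace, HeadTrace

from conftest import make_saccade_trace


def _stimlog(times, side="left", modality="ear_airpuff"):
    times = np.asarray(times, float)
    return StimulusLog(
        times, np.array([modality] * times.size), np.array([side] * times.size)
    )


def test_constant_trace_has_no_saccades():
    t = np.arange(1000) / 100.0
    assert detect_saccades(EyeTrace(t, np.full(1000, 3.0))) == []


def test_single_sigmoid_event_is_detected_accurately():
    trace, onset = make_saccade_trace(amp_deg=8.0, t_event=5.0)
    sacs = detect_saccades(trace)
    assert len(sacs) == 1
    s = sacs[0]
    assert s.onset_s == pytest.approx(onset, abs=0.0101)
    assert s.amplitude_deg == pytest.approx(8.0, abs=0.3)
    assert s.offset_s > s.onset_s
    assert s.direction == "right"
    assert s.peak_vel_dps > 100.0


def test_sub_threshold_amplitude_is_rejected():
    # 2.9 deg movement at ~150 deg/s peak: fast enough, too small
    trace, _ = make_saccade_trace(amp_deg=2.9, gain=0.0, intercept=150.0)
    assert detect_saccades(trace) == []


def test_refractory_period_suppresses_the_second_of_a_close_pair():
    t = np.arange(1000) / 100.0
    x = np.zeros(1000)
    for t0 in (5.0, 5.08):  # onsets 80 ms apart
        k = 4.0 * 460.0 / 8.0
        x += 8.0 / (1.0 + np.exp(np.clip(-k * (t - t0), -700, 700)))
    sacs = detect_saccades(EyeTrace(t, x))
    assert len(sacs) == 1
    assert sacs[0].onset_s < 5.05


def test_detection_is_invariant_to_a_constant_offset():
    trace, _ = make_saccade_trace(amp_deg=-6.0, noise_sd=0.2, seed=3)
    shifted = EyeTrace(trace.time_s, trace.position_deg + 40.0, trace.rate_hz)
    a = detect_saccades(trace)
    b = detect_saccades(shifted)
    assert [s.onset_s for s in a] == [s.onset_s for s in b]
    assert [s.amplitude_deg for s in a] == [s.amplitude_deg for s in b]


def test_events_spanning_invalid_frames_are_dropped():
    trace, onset = make_saccade_trace(amp_deg=8.0, t_event=5.0)
    valid = np.ones(len(trace), bool)
    valid[int(5.0 * 100)] = False
    masked = EyeTrace(trace.time_s, trace.position_deg, trace.rate_hz, valid)
    assert detect_saccades(masked) == []


def test_no_two_accepted_onsets_within_the_refractory_period(default_session):
    sacs = detect_saccades(default_session.eye_avg.centered())
    onsets = np.array([s.onset_s for s in sacs])
    assert np.all(np.diff(onsets) >= 0.1)


@pytest.mark.parametrize(
    "lag_s, expected",
    [(0.06, "evoked"), (0.101, "unclassified"), (0.6, "spontaneous")],
)
def test_classification_windows(lag_s, expected):
    trace, onset = make_saccade_trace(amp_deg=8.0, t_event=5.0)
    sacs = detect_saccades(trace)
    detected_onset = sacs[0].onset_s
    log = _stimlog([detected_onset - lag_s])
    out = classify_saccades(sacs, log)
    assert out[0].klass == expected
    if expected == "evoked":
        assert out[0].stimulus_index == 0
        assert out[0].stimulus_side == "left"


def test_classification_labels_are_consistent_on_rescan(default_session):
    sacs = detect_saccades(default_session.eye_avg.centered())
    out = classify_saccades(sacs, default_session.stimuli)
    times = default_session.stimuli.times
    for s in out:
        dmin = np.min(np.abs(times - s.onset_s))
        if s.klass == "evoked":
            lag = s.onset_s - times[s.stimulus_index]
            assert 0.0 < lag <= 0.1
        elif s.klass == "spontaneous":
            assert dmin > 0.5
        else:
            assert dmin <= 0.5


# ---------------------------------------------------------------------------
# head metrics


def _head_with_step(step_z=1.0, step_at=0.1, onset=3.0, noise_sd=0.01, seed=0, dur=6.0):
    t = np.arange(int(dur * 100)) / 100.0
    rng = np.random.default_rng(seed)
    sig = rng.normal(0.0, noise_sd, t.size)
    sig[t >= onset + step_at] += step_z
    return HeadTrace(t, sig)


def _saccade_at(onset, amp=10.0):
    from gazekit.detection import Saccade

    return Saccade(
        onset_s=onset,
        offset_s=onset + 0.05,
        start_deg=0.0,
        end_deg=amp,
        amplitude_deg=amp,
        peak_vel_dps=500.0,
        klass="evoked",
    )


def test_step_input_yields_the_step_latency():
    head = _head_with_step(step_z=1.0, step_at=0.1)
    gs = head_metrics(_saccade_at(3.0), head)
    assert gs.head_latency_ms == pytest.approx(100.0, abs=11.0)
    assert gs.head_disp_z == pytest.approx(1.0, abs=0.1)
    assert gs.head_direction == "ipsiversive"


def test_gaussian_noise_rarely_crosses_five_sigma():
    """Null simulation: with a stationary Gaussian baseline, 5-sigma
    latency crossings occur in under 1% of trials."""
    crossings = 0
    n_trials = 1000
    for seed in range(n_trials):
        head = _head_with_step(step_z=0.0, noise_sd=0.05, seed=seed, dur=4.5)
        gs = head_metrics(_saccade_at(3.0), head)
        if gs.head_latency_ms is not None:
            crossings += 1
    assert crossings / n_trials < 0.01


def test_insufficient_coverage_returns_none_metrics():
    head = _head_with_step(dur=2.0)
    gs = head_metrics(_saccade_at(0.7), head)  # needs onset-1 s .. onset+0.5 s
    assert gs.head_disp_z is None and gs.head_latency_ms is None
    assert gs.head_direction == "none"


def test_generator_coupling_arithmetic_reaches_head_metrics(noiseless_config):
    """Zero-noise simulator: measured displacement equals the configured
    evoked gain times the measured amplitude (0.16 Z/deg regime)."""
    import dataclasses

    from gazekit.synth import StimulusClass, generate_session

    cfg = dataclasses.replace(
        noiseless_config,
        coupling_gain_evoked=0.16,
        coupling_gain_spont=0.214,
        stimulus_classes=(
            StimulusClass(
                evoked_prob=1.0,
                amp_slope=0.0,
                amp_intercept_left=-10.25,
                amp_intercept_right=10.25,
            ),
        ),
        spont_saccade_rate_hz=0.0,
        n_stimuli=40,
    )
    s = generate_session(cfg, raw_head=False)
    # exact arithmetic against the planted events
    gt_evoked = [g for g in s.ground_truth.saccades if g.klass == "evoked"]
    assert len(gt_evoked) >= 30
    for g in gt_evoked[:10]:
        gs = head_metrics(_saccade_at(g.onset_s, g.amplitude_deg), s.head_z)
        assert gs.head_disp_z == pytest.approx(0.16 * g.amplitude_deg, abs=1e-9)
        assert abs(gs.head_disp_z) == pytest.approx(1.6, abs=0.05)
    # the detected path agrees up to the sub-sample jitter of onset/offset
    sacs = classify_saccades(detect_saccades(s.eye_avg.centered()), s.stimuli)
    evoked = [x for x in sacs if x.klass == "evoked"]
    for sac in evoked[:10]:
        gs = head_metrics(sac, s.head_z)
        assert gs.head_disp_z == pytest.approx(0.16 * sac.amplitude_deg, rel=0.08)


def test_stimulus_head_probability_counts_threshold_exceedances():
    t = np.arange(1200 * 100) / 100.0
    sig = np.zeros(t.size)
    stim_times = 5.0 + 10.0 * np.arange(100)
    # responses on the first 29 trials only
    for st_ in stim_times[:29]:
        sig[(t >= st_ + 0.05) & (t <= st_ + 0.4)] = 1.0
    head = HeadTrace(t, sig)
    log = _stimlog(stim_times)
    out = stimulus_head_probability(log, head)
    res = out[("ear_airpuff", "left")]
    assert res["evoked"] == pytest.approx(0.29)
    assert res["baseline"] == 0.0
    # threshold stability on a strong-response fixture
    for thr in (0.1, 0.5, 0.9):
        cfg = DetectionConfig(head_prob_threshold_z=thr)
        assert stimulus_head_probability(log, head, cfg)[("ear_airpuff", "left")][
            "evoked"
        ] == pytest.approx(0.29)


def test_all_zero_head_trace_has_zero_probability():
    t = np.arange(3000) / 100.0
    head = HeadTrace(t, np.zeros(t.size))
    out = stimulus_head_probability(_stimlog([5.0, 15.0]), head)
    assert out[("ear_airpuff", "left")]["evoked"] == 0.0


# ---------------------------------------------------------------------------
# fixation checks


def test_quiet_period_passes_fixation():
    t = np.arange(1000) / 100.0
    head = HeadTrace(t, np.zeros(1000))
    assert check_fixation([], head, t0=5.0)


def test_recent_saccade_fails_fixation():
    sac = _saccade_at(4.8)
    assert not check_fixation([sac], None, t0=5.0)


def test_central_position_gate():
    t = np.arange(1000) / 100.0
    eye = EyeTrace(t, np.full(1000, -1.0))
    assert check_fixation([], None, 5.0, eye_trace=eye, position_gate_deg=(-2.0, 0.0))
    eye2 = EyeTrace(t, np.full(1000, 3.0))
    assert not check_fixation([], None, 5.0, eye_trace=eye2, position_gate_deg=(-2.0, 0.0))
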