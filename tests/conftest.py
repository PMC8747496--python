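"""Shared fixtures and scoring helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gazekit.synth import SimulationConfig, generate_session
from gazekit.traces import EyeTrace


@pytest.fixture(scope="session")
def default_session():
    """One full synthetic session at default (study) conditions."""
    return generate_session(SimulationConfig(seed=11), raw_head=False)


@pytest.fixture(scope="session")
def noiseless_config():
    """Exact-arithmetic generator configuration: no noise anywhere."""
    return SimulationConfig(
        seed=3,
        eye_noise_sd=0.0,
        head_noise_sd=0.0,
        coupling_noise_sd=0.0,
        evoked_amp_noise_sd=0.0,
        eye_asymmetry=0.0,
    )


def score_detection(gt_saccades, detected, tol_s=0.05):
    """Match ground-truth saccades to detections by onset proximity.

    Returns (matched pairs, precision, recall).
    """
    det_onsets = np.array([s.onset_s for s in detected])
    used = np.zeros(det_onsets.size, dtype=bool)
    matched = []
    for g in gt_saccades:
        if det_onsets.size == 0:
            break
        d = np.abs(det_onsets - g.onset_s)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol_s:
            used[i] = True
            matched.append((g, detected[i]))
    tp = len(matched)
    precision = tp / det_onsets.size if det_onsets.size else 1.0
    recall = tp / len(gt_saccades) if gt_saccades else 1.0
    return matched, precision, recall


def make_saccade_trace(
    amp_deg=8.0,
    t_event=5.0,
    duration_s=10.0,
    rate_hz=100.0,
    gain=45.0,
    intercept=100.0,
    noise_sd=0.0,
    seed=0,
):
    """A flat trace with one logistic saccade; returns (trace, analytic onset).

    The waveform obeys the main sequence (peak velocity = gain*|A| +
    intercept); the analytic onset is the 30 deg/s speed crossing.
    """
    n = int(duration_s * rate_hz) + 1
    t = np.arange(n) / rate_hz
    peak_vel = gain * abs(amp_deg) + intercept
    k = 4.0 * peak_vel / abs(amp_deg)
    x = amp_deg / (1.0 + np.exp(np.clip(-k * (t - t_event), -700, 700)))
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    # analytic 30 deg/s crossing (rising): logistic value s solves A k s(1-s)=30
    r = 30.0 / (abs(amp_deg) * k)
    s = 0.5 * (1.0 - math.sqrt(1.0 - 4.0 * r))
    onset = t_event + math.log(s / (1.0 - s)) / k
    return EyeTrace(t, x, rate_hz), onset
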