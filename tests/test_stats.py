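"""Coupling regressions, permutation tests, matching, conditioned stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from gazekit.detection import GazeShift, Saccade
from gazekit.errors import DegenerateSignalError, InsufficientDataError
from gazekit.io import StimulusLog
from gazekit.stats import (
    coupling_regression,
    endpoint_stats,
    evoked_probability,
    ipsiversive_timecourse,
    match_trials,
    ols_fit,
    percent_gain_reduction,
    permutation_mean_test,
    permutation_slope_test,
    position_conditioned_stats,
    saccade_psth,
    spontaneous_rate_windows,
)
from gazekit.synth import sample_gaze_shift_population
from gazekit.traces import EyeTrace, HeadTrace


def _gs(amp, disp, onset=0.0, klass="spontaneous", end=None):
    sac = Saccade(
        onset_s=onset,
        offset_s=onset + 0.05,
        start_deg=0.0,
        end_deg=amp if end is None else end,
        amplitude_deg=amp,
        peak_vel_dps=400.0,
        klass=klass,
    )
    return GazeShift(sac, head_disp_z=disp)


# ---------------------------------------------------------------------------
# regression


def test_exact_line_is_fit_exactly():
    x = np.arange(10.0)
    fit = ols_fit(x, 0.2 * x)
    assert fit.slope == pytest.approx(0.2, abs=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_ols_matches_the_reference_implementation():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = 0.7 * x + rng.normal(size=200)
    fit = ols_fit(x, y)
    ref = sstats.linregress(x, y)
    assert fit.slope == pytest.approx(ref.slope, rel=1e-10)
    assert fit.intercept == pytest.approx(ref.intercept, rel=1e-10)
    assert fit.p_slope == pytest.approx(ref.pvalue, rel=1e-6)
    assert fit.stderr == pytest.approx(ref.stderr, rel=1e-10)


def test_degenerate_x_raises():
    with pytest.raises(DegenerateSignalError):
        ols_fit(np.ones(10), np.arange(10.0))
    with pytest.raises(InsufficientDataError):
        ols_fit(np.arange(2.0), np.arange(2.0))


def test_coupling_regression_recovers_the_generating_gain():
    rng = np.random.default_rng(7)
    amps, disps = sample_gaze_shift_population(500, 0.2, rng, noise_sd=0.3)
    shifts = [_gs(a, d) for a, d in zip(amps, disps)]
    fit = coupling_regression(shifts)
    lo, hi = fit.slope_ci()
    assert lo <= 0.2 <= hi
    assert fit.n == 500


def test_percent_gain_reduction_of_the_reported_slopes():
    assert round(percent_gain_reduction(0.214, 0.162)) == 24


# ---------------------------------------------------------------------------
# permutation tests


def test_identical_groups_give_p_one():
    x = np.arange(20.0)
    y = 0.3 * x + np.sin(x)
    r = permutation_slope_test(x, y, x, y, n_shuffles=99, seed=0)
    assert r.observed_stat == 0.0
    assert r.p_value == 1.0
    m = permutation_mean_test(y, y, n_shuffles=99, seed=0)
    assert m.observed_stat == 0.0 and m.p_value == 1.0


def test_separated_gains_drive_slope_p_to_the_floor():
    rng = np.random.default_rng(3)
    xa, ya = sample_gaze_shift_population(2000, 0.214, rng, noise_sd=0.3)
    xb, yb = sample_gaze_shift_population(2000, 0.162, rng, noise_sd=0.3)
    r = permutation_slope_test(xa, ya, xb, yb, n_shuffles=500, seed=1)
    assert r.p_value == pytest.approx(1.0 / 501.0)


def test_two_sd_mean_shift_drives_p_to_the_floor():
    rng = np.random.default_rng(4)
    a = rng.normal(2.0, 1.0, 200)
    b = rng.normal(0.0, 1.0, 200)
    r = permutation_mean_test(a, b, n_shuffles=400, seed=2)
    assert r.p_value == pytest.approx(1.0 / 401.0)


def test_permutation_p_is_super_uniform_under_the_null():
    """Exchangeable null: p-values are (discretely) uniform, checked with a
    KS statistic over repeated draws at reduced shuffle counts."""
    rng = np.random.default_rng(5)
    pvals = []
    for i in range(300):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        pvals.append(permutation_mean_test(a, b, n_shuffles=99, seed=1000 + i).p_value)
    pvals = np.asarray(pvals)
    assert pvals.min() >= 1.0 / 100.0
    # empirical CDF never exceeds the uniform by more than the KS band
    for q in (0.1, 0.25, 0.5, 0.75):
        assert np.mean(pvals <= q) <= q + 2.2 * np.sqrt(q * (1 - q) / 300)


# ---------------------------------------------------------------------------
# endpoints and probabilities


def test_identical_endpoint_samples_give_t_zero_p_one():
    a = [_gs(5.0, 0.0, end=2.0).saccade, _gs(5.0, 0.0, end=2.0).saccade]
    r = endpoint_stats(a, list(a))
    assert r.t_welch == 0.0 and r.p_welch == 1.0


def test_separated_endpoint_distributions_are_detected():
    rng = np.random.default_rng(6)
    a = [_gs(-5.0, 0.0, end=e).saccade for e in rng.normal(-5.0, 1.0, 200)]
    b = [_gs(5.0, 0.0, end=e).saccade for e in rng.normal(5.0, 1.0, 200)]
    r = endpoint_stats(a, b)
    assert r.p_welch < 1e-10
    assert r.mean_a == pytest.approx(-5.0, abs=0.3)
    assert r.frac_leftward_a == 1.0 and r.frac_leftward_b == 0.0
    # Welch oracle: direct formula
    ea = np.array([s.end_deg for s in a])
    eb = np.array([s.end_deg for s in b])
    t_direct = (ea.mean() - eb.mean()) / np.sqrt(ea.var(ddof=1) / 200 + eb.var(ddof=1) / 200)
    assert r.t_welch == pytest.approx(t_direct, rel=1e-10)


def test_evoked_probability_counting_fixture():
    stim_times = 10.0 * np.arange(1, 101)
    log = StimulusLog(
        stim_times, np.array(["ear_airpuff"] * 100), np.array(["left"] * 100)
    )
    # saccade 50 ms after the first 29 stimuli
    sacs = [
        Saccade(t + 0.05, t + 0.1, 0, 5, 5.0, 400.0) for t in stim_times[:29]
    ]
    out = evoked_probability(sacs, log)
    assert out[("ear_airpuff", "left")]["evoked"] == pytest.approx(0.29)
    assert out[("ear_airpuff", "left")]["baseline"] == 0.0
    assert evoked_probability([], log)[("ear_airpuff", "left")]["evoked"] == 0.0


# ---------------------------------------------------------------------------
# PSTH


def test_psth_is_zero_without_saccades():
    edges, prob = saccade_psth(np.array([]), np.arange(10.0))
    assert np.all(prob == 0.0)


def test_psth_concentrates_at_a_fixed_latency():
    stims = 10.0 * np.arange(1, 21)
    onsets = stims + 0.055
    edges, prob = saccade_psth(onsets, stims, bin_ms=10.0)
    i = int(np.flatnonzero(edges[:-1] == 50.0)[0])
    assert prob[i] == 1.0
    assert prob.sum() == 1.0


def test_psth_matches_the_poisson_closed_form():
    rng = np.random.default_rng(8)
    rate = 0.4  # Hz
    duration = 4000.0
    n = rng.poisson(rate * duration)
    onsets = np.sort(rng.uniform(0, duration, n))
    stims = np.arange(100.0, duration - 100.0, 25.0)
    edges, prob = saccade_psth(onsets, stims, bin_ms=50.0)
    expected = 1.0 - np.exp(-rate * 0.05)
    se = np.sqrt(expected * (1 - expected) / stims.size)
    assert np.mean(prob) == pytest.approx(expected, abs=4 * se / np.sqrt(prob.size) + 2e-3)


# ---------------------------------------------------------------------------
# matching


def brute_force_greedy(a, b, cutoff=3.0):
    a, b = np.atleast_2d(a.T).T if a.ndim == 1 else a, b
    pairs = []
    dists = [
        (float(np.linalg.norm(a[i] - b[j])), i, j)
        for i in range(a.shape[0])
        for j in range(b.shape[0])
    ]
    dists.sort()
    ua, ub = set(), set()
    for d, i, j in dists:
        if d > cutoff or i in ua or j in ub:
            continue
        ua.add(i)
        ub.add(j)
        pairs.append((i, j, d))
    return pairs


def test_identical_sets_pair_at_distance_zero():
    a = np.arange(5.0).reshape(-1, 1)
    m = match_trials(a, a.copy())
    assert len(m.pairs) == 5
    assert all(d == 0.0 for _, _, d in m.pairs)
    assert sorted(m.indices_a()) == sorted(m.indices_b()) == list(range(5))


def test_distant_sets_have_no_pairs():
    a = np.zeros((4, 2))
    b = np.full((4, 2), 10.0)
    assert match_trials(a, b, cutoff=3.0).pairs == []


@pytest.mark.parametrize("seed", range(8))
def test_matching_equals_the_exhaustive_greedy_oracle(seed):
    rng = np.random.default_rng(seed)
    na, nb = rng.integers(1, 7, size=2)
    a = rng.uniform(-5, 5, size=(na, 2))
    b = rng.uniform(-5, 5, size=(nb, 2))
    got = match_trials(a, b, cutoff=3.0).pairs
    want = brute_force_greedy(a, b, cutoff=3.0)
    assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in want]
    for _, _, d in got:
        assert d <= 3.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_matching_invariants_and_symmetry(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(-6, 6, size=(rng.integers(0, 8), 1))
    b = rng.uniform(-6, 6, size=(rng.integers(0, 8), 1))
    m = match_trials(a, b)
    assert len(set(m.indices_a())) == len(m.pairs)
    assert len(set(m.indices_b())) == len(m.pairs)
    swapped = match_trials(b, a)
    assert sorted((j, i) for i, j, _ in m.pairs) == sorted(
        (i, j) for i, j, _ in swapped.pairs
    )


# ---------------------------------------------------------------------------
# position-conditioned statistics


def test_pure_recentering_geometry_yields_slope_minus_one():
    pos = np.linspace(-9, 9, 200)
    amp = -pos
    hd = 0.2 * amp
    out = position_conditioned_stats(pos, amp, hd)
    assert out.amp_fit.slope == pytest.approx(-1.0, abs=1e-9)
    assert out.amp_fit.intercept == pytest.approx(0.0, abs=1e-9)


def test_endpoint_bias_shifts_the_intercept():
    pos = np.linspace(-9, 9, 200)
    amp = 5.0 - pos
    out = position_conditioned_stats(pos, amp, 0.2 * amp)
    assert out.amp_fit.slope == pytest.approx(-1.0, abs=1e-9)
    assert out.amp_fit.intercept == pytest.approx(5.0, abs=1e-9)


def test_empty_bins_are_missing_not_zero():
    pos = np.full(50, 1.0)  # all trials in one bin
    amp = np.full(50, -1.0) * np.nan
    out = position_conditioned_stats(pos, amp, np.full(50, np.nan))
    filled = out.n_trials > 0
    assert filled.sum() == 1
    assert np.isnan(out.p_saccade_left[~filled]).all()


def test_head_probability_minimum_sits_at_the_mean_endpoint():
    """With saccades only when |intended amplitude| clears the floor, the
    per-bin saccade probability dips where position equals the endpoint."""
    rng = np.random.default_rng(9)
    pos = rng.uniform(-10, 10, 4000)
    intended = 4.0 - pos  # endpoint bias +4 deg
    amp = np.where(np.abs(intended) >= 3.5, intended, np.nan)
    out = position_conditioned_stats(pos, amp, np.full(4000, np.nan))
    i_min = np.nanargmin(out.p_saccade_any)
    assert out.bin_centers[i_min] == pytest.approx(4.0, abs=1.0)


# ---------------------------------------------------------------------------
# time courses and baseline windows


def test_all_ipsiversive_fixture_is_one_everywhere():
    t = np.arange(3000) / 100.0
    sig = np.zeros(t.size)
    sig[t >= 14.8] = 1.0  # rightward head step after the -500 ms reference
    head = HeadTrace(t, sig)
    shifts = [_gs(5.0, 1.0, onset=15.0)]
    lags, frac = ipsiversive_timecourse(shifts, head)
    assert np.all(frac[lags >= -0.19] == 1.0)
    assert np.all(frac[lags <= -0.21] == 0.0)


def test_symmetric_noise_is_half_ipsiversive_before_onset():
    rng = np.random.default_rng(10)
    t = np.arange(200000) / 100.0
    head = HeadTrace(t, rng.normal(size=t.size))
    shifts = [
        _gs(5.0 if i % 2 else -5.0, 0.0, onset=10.0 + 1.9 * i) for i in range(1000)
    ]
    lags, frac = ipsiversive_timecourse(shifts, head)
    pre = frac[(lags > -0.4) & (lags < -0.1)]
    assert np.mean(pre) == pytest.approx(0.5, abs=0.03)


def test_spontaneous_windows_count_planted_saccades():
    t = np.arange(110000) / 100.0  # 1100 s
    eye = EyeTrace(t, np.zeros(t.size))
    stimuli = StimulusLog(np.array([1090.0]), np.array(["x"]), np.array(["left"]))
    # saccades placed in the probe sub-window of 13 of the first 1000 windows
    onsets = np.array([w + 0.55 for w in range(0, 13 * 40, 40)], dtype=float)
    out = spontaneous_rate_windows(onsets, stimuli, eye)
    assert out["n_windows"] >= 1000
    assert out["p_saccade_overall"] == pytest.approx(13 / out["n_windows"])
    empty = spontaneous_rate_windows(np.array([]), stimuli, eye)
    assert empty["p_saccade_overall"] == 0.0
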