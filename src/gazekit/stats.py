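"""Session and population statistics for gaze-shift analyses.

Covers peri-stimulus saccade histograms, evoked probabilities, endpoint
statistics, head-eye coupling regressions (ordinary least squares pooled
over trials, with per-mouse variants), label-shuffling permutation tests
for slope and mean differences (10,000 shuffles by default, add-one
two-sided p), greedy nearest-first trial matching with a 3 deg Euclidean
cutoff, eye-position-conditioned probabilities, and the spontaneous-rate
window analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, DegenerateSignalError, InsufficientDataError
from .io import StimulusLog
from .traces import EyeTrace, HeadTrace

__all__ = [
    "CouplingFit",
    "PermutationResult",
    "MatchedPairs",
    "ols_fit",
    "coupling_regression",
    "permutation_slope_test",
    "permutation_mean_test",
    "saccade_psth",
    "evoked_probability",
    "endpoint_stats",
    "match_trials",
    "position_conditioned_stats",
    "ipsiversive_timecourse",
    "spontaneous_rate_windows",
    "percent_gain_reduction",
]


@dataclass(frozen=True)
class CouplingFit:
    """Pooled OLS fit of head metric against saccade amplitude."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    p_slope: float
    stderr: float

    def slope_ci(self, level: float = 0.95) -> tuple:
        """Two-sided confidence interval for the slope."""
        tcrit = sstats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - tcrit * self.stderr, self.slope + tcrit * self.stderr)


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    null_mean: float
    null_sd: float
    p_value: float  # two-sided, add-one corrected
    n_shuffles: int
    seed: int


@dataclass(frozen=True)
class MatchedPairs:
    pairs: list  # (index_a, index_b, distance)
    cutoff: float

    def indices_a(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    def indices_b(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


# ---------------------------------------------------------------------------
# regression


def ols_fit(x: np.ndarray, y: np.ndarray) -> CouplingFit:
    """Unweighted least squares of y on x via the normal equations.

    Slope p-value from the standard t statistic with n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"regression needs n >= 3, got {n}")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise DegenerateSignalError("zero variance in x; regression undefined")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if n > 2 and ss_res > 0:
        s2 = ss_res / (n - 2)
        stderr = float(np.sqrt(s2 / sxx))
        tstat = slope / stderr
        p = 2.0 * float(sstats.t.sf(abs(tstat), n - 2))
    else:
        stderr, p = 0.0, 0.0
    return CouplingFit(slope, intercept, r2, n, p, stderr)


def coupling_regression(gaze_shifts: Sequence, metric: str = "disp") -> CouplingFit:
    """Head-eye coupling: OLS of a head metric on saccade amplitude.

    ``metric='disp'`` uses the attempted-head displacement 150 ms after
    saccade onset (Z per deg); ``metric='vel'`` the head velocity 60 ms
    after onset (Z/s per deg).  Shifts lacking the metric are dropped.
    """
    attr = {"disp": "head_disp_z", "vel": "head_vel_z_s"}[metric]
    pairs = [
        (gs.saccade.amplitude_deg, getattr(gs, attr))
        for gs in gaze_shifts
        if getattr(gs, attr) is not None
    ]
    if len(pairs) < 3:
        raise InsufficientDataError("too few gaze shifts with head metrics")
    x, y = map(np.asarray, zip(*pairs))
    return ols_fit(x, y)


def percent_gain_reduction(slope_ref: float, slope_other: float) -> float:
    """Percent reduction of ``slope_other`` relative to ``slope_ref``,
    100 * (1 - other/ref)."""
    return 100.0 * (1.0 - slope_other / slope_ref)


# ---------------------------------------------------------------------------
# permutation tests


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x.mean()
    return float(np.dot(x - xm, y - y.mean()) / np.dot(x - xm, x - xm))


def _permutation_p(observed: float, null: np.ndarray) -> float:
    # add-one estimator: avoids p = 0 and is exact under exchangeability
    return (1.0 + int(np.sum(np.abs(null) >= abs(observed)))) / (1.0 + null.size)


def permutation_slope_test(
    x_a: np.ndarray,
    y_a: np.ndarray,
    x_b: np.ndarray,
    y_b: np.ndarray,
    n_shuffles: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided permutation test for a slope difference between groups.

    Observed statistic: ``slope_A - slope_B``.  The null is built by
    shuffling group labels over the pooled (x, y) pairs and refitting both
    slopes for each shuffle.
    """
    x_a, y_a, x_b, y_b = map(np.asarray, (x_a, y_a, x_b, y_b))
    observed = _slope(x_a, y_a) - _slope(x_b, y_b)
    x = np.concatenate([x_a, x_b])
    y = np.concatenate([y_a, y_b])
    n_a = x_a.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(x.size)
        ia, ib = perm[:n_a], perm[n_a:]
        null[i] = _slope(x[ia], y[ia]) - _slope(x[ib], y[ib])
    return PermutationResult(
        observed_stat=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_value=_permutation_p(observed, null),
        n_shuffles=n_shuffles,
        seed=seed,
    )


def permutation_mean_test(
    a: np.ndarray,
    b: np.ndarray,
    n_shuffles: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided permutation test for ``mean(a) - mean(b)``."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(pooled.size)
        null[i] = pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean()
    return PermutationResult(
        observed_stat=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_value=_permutation_p(observed, null),
        n_shuffles=n_shuffles,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# event-probability analyses


def saccade_psth(
    saccade_onsets: np.ndarray,
    stimulus_times: np.ndarray,
    bin_ms: float = 10.0,
    range_ms: tuple = (-500.0, 500.0),
):
    """Peri-stimulus histogram of instantaneous saccade probability.

    For each bin, the fraction of trials containing at least one saccade
    onset in that bin.  Returns ``(bin_edges_ms, probability)``.
    """
    onsets = np.sort(np.asarray(saccade_onsets, float))
    stims = np.asarray(stimulus_times, float)
    lo, hi = range_ms
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    n_bins = edges.size - 1
    counts = np.zeros(n_bins)
    for t in stims:
        rel = (onsets - t) * 1000.0
        rel = rel[(rel >= lo) & (rel < hi)]
        if rel.size:
            bins = np.unique(np.floor((rel - lo) / bin_ms).astype(int))
            counts[bins[bins < n_bins]] += 1
    prob = counts / stims.size if stims.size else counts
    return edges, prob


def evoked_probability(
    saccades: Sequence,
    stimuli: StimulusLog,
    response_window_s: float = 0.1,
    baseline_window_s: tuple = (-0.5, -0.4),
):
    """Fraction of trials with a saccade in the response window, per
    (modality, side) condition, plus a matched-length baseline window
    before the stimulus.

    Returns ``{(modality, side): {"evoked": p, "baseline": p, "n": n}}``.
    """
    onsets = np.sort(np.array([s.onset_s for s in saccades]))
    out = {}
    b0, b1 = baseline_window_s
    for modality, side in stimuli.conditions():
        times = stimuli.select(modality, side)
        n = times.size
        ev = sum(
            1
            for t in times
            if np.any((onsets > t) & (onsets <= t + response_window_s))
        )
        bl = sum(1 for t in times if np.any((onsets >= t + b0) & (onsets < t + b1)))
        out[(modality, side)] = {
            "evoked": ev / n if n else np.nan,
            "baseline": bl / n if n else np.nan,
            "n": int(n),
        }
    return out


@dataclass(frozen=True)
class EndpointStats:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_welch: float
    p_welch: float
    frac_leftward_a: float
    frac_leftward_b: float


def endpoint_stats(saccades_a: Sequence, saccades_b: Sequence) -> EndpointStats:
    """Endpoint means/SDs for two conditions and Welch's t between them.

    Conditions are typically left-side vs right-side stimuli; endpoints
    are saccade end positions relative to the session-mean eye position.
    """
    ends_a = np.array([s.end_deg for s in saccades_a])
    ends_b = np.array([s.end_deg for s in saccades_b])
    if ends_a.size < 2 or ends_b.size < 2:
        raise InsufficientDataError("endpoint statistics need n >= 2 per condition")
    if np.ptp(ends_a) == 0 and np.ptp(ends_b) == 0 and ends_a.mean() == ends_b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sstats.ttest_ind(ends_a, ends_b, equal_var=False)
    frac_left_a = float(np.mean([s.amplitude_deg < 0 for s in saccades_a]))
    frac_left_b = float(np.mean([s.amplitude_deg < 0 for s in saccades_b]))
    return EndpointStats(
        float(ends_a.mean()),
        float(ends_a.std(ddof=1)),
        ends_a.size,
        float(ends_b.mean()),
        float(ends_b.std(ddof=1)),
        ends_b.size,
        float(t),
        float(p),
        frac_left_a,
        frac_left_b,
    )


# ---------------------------------------------------------------------------
# trial matching


def match_trials(
    features_a: np.ndarray,
    features_b: np.ndarray,
    cutoff: float = 3.0,
) -> MatchedPairs:
    """Greedy globally-nearest-first matching without replacement.

    Repeatedly pairs the closest remaining cross-set pair (Euclidean
    distance over the feature columns) with distance at most ``cutoff``,
    removing both members.  Ties break deterministically by
    ``(index_a, index_b)``.
    """
    a = np.asarray(features_a, float)
    b = np.asarray(features_b, float)
    if a.ndim == 1:
        a = a.reshape(-1, 1)
    if b.ndim == 1:
        b = b.reshape(-1, 1)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ConfigurationError("feature sets must be (n, k) with matching k")
    if a.shape[1] == 0:
        raise ConfigurationError("matching requires at least one feature")
    if a.shape[0] == 0 or b.shape[0] == 0:
        return MatchedPairs([], cutoff)
    d = cdist(a, b)
    ii, jj = np.nonzero(d <= cutoff)
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_a = np.zeros(a.shape[0], bool)
    used_b = np.zeros(b.shape[0], bool)
    pairs = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j, float(d[i, j])))
    return MatchedPairs(pairs, cutoff)


# ---------------------------------------------------------------------------
# eye-position-conditioned analyses


@dataclass(frozen=True)
class PositionBinnedStats:
    bin_centers: np.ndarray
    n_trials: np.ndarray
    p_saccade_left: np.ndarray
    p_saccade_right: np.ndarray
    p_head_left: np.ndarray
    p_head_right: np.ndarray
    p_saccade_any: np.ndarray
    amp_fit: Optional[CouplingFit]


def position_conditioned_stats(
    initial_pos_deg: np.ndarray,
    amplitude_deg: np.ndarray,
    head_disp_z: np.ndarray,
    bin_width_deg: float = 2.0,
    pos_range_deg: tuple = (-10.0, 10.0),
    head_threshold_z: float = 0.25,
) -> PositionBinnedStats:
    """Saccade/head-movement statistics binned by initial eye position.

    One entry per trial: ``amplitude_deg`` is NaN for trials without a
    saccade and ``head_disp_z`` NaN when the head metric is unavailable.
    Produces per-bin probabilities of left/right saccades and of left/
    right attempted head movements (signed exceedance of the threshold),
    plus the OLS fit of signed amplitude on initial position over trials
    with a saccade.  Bins with no trials are NaN (missing), not zero.
    """
    pos = np.asarray(initial_pos_deg, float)
    amp = np.asarray(amplitude_deg, float)
    hd = np.asarray(head_disp_z, float)
    edges = np.arange(pos_range_deg[0], pos_range_deg[1] + bin_width_deg / 2, bin_width_deg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = centers.size
    n_tr = np.zeros(nb, int)
    psl = np.full(nb, np.nan)
    psr = np.full(nb, np.nan)
    phl = np.full(nb, np.nan)
    phr = np.full(nb, np.nan)
    pany = np.full(nb, np.nan)
    which = np.digitize(pos, edges) - 1
    for b in range(nb):
        sel = which == b
        n = int(sel.sum())
        n_tr[b] = n
        if n == 0:
            continue
        a = amp[sel]
        psl[b] = float(np.mean(a < 0))  # NaN-amp trials compare False
        psr[b] = float(np.mean(a > 0))
        pany[b] = float(np.mean(~np.isnan(a)))
        h = hd[sel]
        h_ok = h[~np.isnan(h)]
        if h_ok.size:
            phl[b] = float(np.mean(h_ok < -head_threshold_z))
            phr[b] = float(np.mean(h_ok > head_threshold_z))
    has_sac = ~np.isnan(amp)
    fit = ols_fit(pos[has_sac], amp[has_sac]) if has_sac.sum() >= 3 else None
    return PositionBinnedStats(centers, n_tr, psl, psr, phl, phr, pany, fit)


def ipsiversive_timecourse(
    gaze_shifts: Sequence,
    head: HeadTrace,
    window_s: tuple = (-0.5, 0.5),
    baseline_at_s: float = -0.5,
):
    """Fraction of trials with ipsiversive attempted head displacement as a
    function of time around saccade onset.

    Each trial's head trace is referenced to its value ``baseline_at_s``
    before onset; at each lag the instantaneous displacement sign is
    compared with the saccade direction.  Returns ``(lags_s, fraction)``.
    """
    rate = head.rate_hz
    i0 = int(round(window_s[0] * rate))
    i1 = int(round(window_s[1] * rate))
    lags = np.arange(i0, i1 + 1) / rate
    num = np.zeros(lags.size)
    den = 0
    ib = int(round(baseline_at_s * rate))
    for gs in gaze_shifts:
        t_on = gs.saccade.onset_s
        if not head.covers(t_on + window_s[0], t_on + window_s[1]):
            continue
        c = head.index_at(t_on)
        seg = head.signal_z[c + i0 : c + i1 + 1] - head.signal_z[c + ib]
        if seg.size != lags.size:
            continue
        sign = 1.0 if gs.saccade.amplitude_deg > 0 else -1.0
        num += (np.sign(seg) == sign).astype(float)
        den += 1
    frac = num / den if den else np.full(lags.size, np.nan)
    return lags, frac


def spontaneous_rate_windows(
    saccade_onsets: np.ndarray,
    stimuli: StimulusLog,
    eye: EyeTrace,
    head: Optional[HeadTrace] = None,
    bin_width_deg: float = 2.0,
    pos_range_deg: tuple = (-10.0, 10.0),
    head_threshold_z: float = 0.25,
):
    """Baseline saccade/head probabilities from quiet 1 s windows.

    Non-overlapping 1 s windows containing no stimulus are enumerated; a
    window qualifies when no saccade onset falls in its first 500 ms.  The
    reported statistics are the probability of a saccade onset in the
    [500, 600) ms sub-window and of an attempted head movement (sensor
    value at 650 ms referenced to 500 ms, exceeding the threshold),
    binned by the eye position at 500 ms.

    Returns a dict with overall probabilities and per-bin arrays.
    """
    onsets = np.sort(np.asarray(saccade_onsets, float))
    t_end = eye.time_s[-1]
    starts = []
    t = float(eye.time_s[0])
    stim_t = stimuli.times
    while t + 1.0 <= t_end:
        if stim_t.size and np.any((stim_t >= t) & (stim_t < t + 1.0)):
            t += 1.0
            continue
        if np.any((onsets >= t) & (onsets < t + 0.5)):
            t += 1.0
            continue
        starts.append(t)
        t += 1.0
    starts = np.asarray(starts)
    edges = np.arange(pos_range_deg[0], pos_range_deg[1] + bin_width_deg / 2, bin_width_deg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = centers.size
    n_win = np.zeros(nb, int)
    sac_hit = np.zeros(nb)
    head_hit = np.zeros(nb)
    head_n = np.zeros(nb, int)
    total_hits = 0
    for t in starts:
        hit = bool(np.any((onsets >= t + 0.5) & (onsets < t + 0.6)))
        total_hits += hit
        pos = eye.position_deg[eye.index_at(t + 0.5)]
        b = int(np.digitize(pos, edges)) - 1
        if 0 <= b < nb:
            n_win[b] += 1
            sac_hit[b] += hit
            if head is not None and head.covers(t + 0.5, t + 0.65):
                d = head.signal_z[head.index_at(t + 0.65)] - head.signal_z[head.index_at(t + 0.5)]
                head_n[b] += 1
                head_hit[b] += abs(d) > head_threshold_z
    with np.errstate(invalid="ignore", divide="ignore"):
        p_sac = np.where(n_win > 0, sac_hit / np.maximum(n_win, 1), np.nan)
        p_head = np.where(head_n > 0, head_hit / np.maximum(head_n, 1), np.nan)
    return {
        "n_windows": int(starts.size),
        "p_saccade_overall": total_hits / starts.size if starts.size else np.nan,
        "bin_centers": centers,
        "n_windows_per_bin": n_win,
        "p_saccade_per_bin": p_sac,
        "p_head_per_bin": p_head,
    }
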