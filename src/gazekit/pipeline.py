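"""Reproducible runs: simulate -> preprocess -> detect -> analyze -> report.

Stages communicate only through on-disk artifacts inside the run
directory, so each stage can be re-run or tested in isolation:

    run/
      stimuli.csv, head_raw.csv, pose_left.csv, pose_right.csv   (simulate)
      ground_truth.json                                          (simulate)
      conditioned.csv                                            (preprocess)
      events.csv                                                 (detect)
      analysis.json, psth.csv, position_bins.csv                 (analyze)
      report.md                                                  (report)
      manifest.json                                              (always)

Identical config and seed produce identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import (
    DetectionConfig,
    attach_head_metrics,
    classify_saccades,
    detect_saccades,
)
from .errors import ConfigurationError, GazekitError, PipelineError, ReportError
from .io import (
    StimulusLog,
    read_head_trace,
    read_json,
    read_pose_table,
    read_stimulus_log,
    write_event_tables,
    write_head_trace,
    write_json,
    write_pose_table,
    write_stimulus_log,
    read_event_tables,
)
from .kinematics import (
    EyeCalibration,
    average_eyes,
    condition_head_signal,
    eye_trace_from_pose,
    filter_pose_likelihood,
)
from .stats import (
    coupling_regression,
    endpoint_stats,
    evoked_probability,
    percent_gain_reduction,
    permutation_mean_test,
    permutation_slope_test,
    position_conditioned_stats,
    saccade_psth,
    spontaneous_rate_windows,
)
from .synth import SimulationConfig, StimulusClass, emit_pose_tables, generate_session
from .traces import EyeTrace, HeadTrace

log = logging.getLogger("gazekit")

STAGES = ("simulate", "preprocess", "detect", "analyze", "report")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``simulation`` (generate a synthetic session) or
    ``inputs`` (paths to pose tables, head trace and stimulus log) must be
    present.
    """

    simulation: Optional[SimulationConfig] = None
    inputs: Optional[dict] = None  # pose_left, pose_right, head, stimuli paths
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    calibration: EyeCalibration = field(default_factory=EyeCalibration)
    n_shuffles: int = 10000
    seed: int = 0
    bin_width_deg: float = 2.0

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'simulation' or 'inputs' must be configured"
            )

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = None
        if "simulation" in raw:
            sim_raw = dict(raw["simulation"] or {})
            classes = sim_raw.pop("stimulus_classes", None)
            if classes is not None:
                sim_raw["stimulus_classes"] = tuple(
                    StimulusClass(**c) for c in classes
                )
            for key in ("iti_range_s", "evoked_latency_range_ms", "spont_amp_range_deg",
                        "slow_head_lead_ms"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimulationConfig(**sim_raw)
        det = DetectionConfig(**(raw.get("detection") or {}))
        cal = EyeCalibration(**(raw.get("calibration") or {}))
        cfg = cls(
            simulation=sim,
            inputs=raw.get("inputs"),
            detection=det,
            calibration=cal,
            n_shuffles=int(raw.get("n_shuffles", 10000)),
            seed=int(raw.get("seed", 0)),
            bin_width_deg=float(raw.get("bin_width_deg", 2.0)),
        )
        if seed is not None:
            cfg.seed = int(seed)
            if cfg.simulation is not None:
                cfg.simulation = dataclasses.replace(cfg.simulation, seed=int(seed))
        return cfg

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig, out_dir, stages=STAGES) -> Path:
    """Execute the requested stages, returning the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    done = []

    def _write_manifest():
        write_json(
            {
                "gazekit_version": __version__,
                "config_sha256": config.digest(),
                "seed": config.seed,
                "stages": done,
            },
            out / "manifest.json",
        )

    for stage in stages:
        if stage == "simulate" and config.simulation is None:
            continue
        log.info("stage %s", stage)
        _write_manifest()  # manifest reflects progress; report reads it
        try:
            _STAGE_FNS[stage](config, out)
        except GazekitError as exc:
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(stage, str(exc)) from exc
        done.append(stage)
    _write_manifest()
    return out


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path) -> None:
    sim = dataclasses.replace(config.simulation, seed=config.simulation.seed)
    session = generate_session(sim)
    write_stimulus_log(session.stimuli, out / "stimuli.csv")
    write_head_trace(session.head_raw_time_s, session.head_raw_volts, out / "head_raw.csv")
    for name, eye in (("left", session.eye_left), ("right", session.eye_right)):
        pose = emit_pose_tables(eye, config.calibration)
        write_pose_table(pose, out / f"pose_{name}.csv")
    gt = session.ground_truth
    write_json(
        {
            "saccades": [dataclasses.asdict(s) for s in gt.saccades],
            "head_events": [dataclasses.asdict(h) for h in gt.head_events],
        },
        out / "ground_truth.json",
    )


def _input_path(config: RunConfig, out: Path, key: str, default: str) -> Path:
    if config.inputs is not None and key in config.inputs:
        return Path(config.inputs[key])
    return out / default


def _stage_preprocess(config: RunConfig, out: Path) -> None:
    eyes = {}
    for name in ("left", "right"):
        path = _input_path(config, out, f"pose_{name}", f"pose_{name}.csv")
        pose = read_pose_table(path)
        pose = filter_pose_likelihood(pose)
        eyes[name] = eye_trace_from_pose(pose, config.calibration)
    avg = average_eyes(eyes["left"], eyes["right"]).centered()
    head_path = _input_path(config, out, "head", "head_raw.csv")
    raw_rate = config.simulation.head_raw_rate_hz if config.simulation else 2000.0
    t_raw, volts = read_head_trace(head_path, raw_rate)
    head = condition_head_signal(t_raw, volts, avg.time_s)
    df = pd.DataFrame(
        {
            "time_s": avg.time_s,
            "eye_deg": avg.position_deg,
            "eye_valid": avg.valid.astype(int),
            "head_z": head.signal_z,
        }
    )
    df.to_csv(out / "conditioned.csv", index=False, float_format="%.9g")


def _load_conditioned(out: Path):
    df = pd.read_csv(out / "conditioned.csv")
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / float(np.median(np.diff(t)))
    t = np.arange(t.size) / rate + t[0]  # regularize rounded timestamps
    eye = EyeTrace(t, df["eye_deg"].to_numpy(float), rate, df["eye_valid"].to_numpy(bool))
    head = HeadTrace(t, df["head_z"].to_numpy(float), rate)
    return eye, head


def _stage_detect(config: RunConfig, out: Path) -> None:
    eye, head = _load_conditioned(out)
    stim_path = _input_path(config, out, "stimuli", "stimuli.csv")
    stimuli = read_stimulus_log(stim_path)
    saccades = detect_saccades(eye, config.detection)
    saccades = classify_saccades(saccades, stimuli, config.detection)
    shifts = attach_head_metrics(saccades, head, config.detection)
    write_event_tables(shifts, out / "events.csv")


def _fixated(shifts):
    """Keep shifts with no prior saccade in the preceding 500 ms."""
    onsets = np.array([gs.saccade.onset_s for gs in shifts])
    keep = []
    for i, gs in enumerate(shifts):
        prior = onsets[(onsets < gs.saccade.onset_s) & (onsets >= gs.saccade.onset_s - 0.5)]
        if prior.size == 0:
            keep.append(gs)
    return keep


def _stage_analyze(config: RunConfig, out: Path) -> None:
    shifts = read_event_tables(out / "events.csv")
    eye, head = _load_conditioned(out)
    stimuli = read_stimulus_log(_input_path(config, out, "stimuli", "stimuli.csv"))
    fixated = _fixated(shifts)
    spont = [g for g in fixated if g.saccade.klass == "spontaneous"]
    evoked = [g for g in fixated if g.saccade.klass == "evoked"]
    results: dict = {"n_saccades": len(shifts), "n_spontaneous": len(spont), "n_evoked": len(evoked)}

    rng = np.random.default_rng(config.seed)

    def xy(group, attr):
        return (
            np.array([g.saccade.amplitude_deg for g in group if getattr(g, attr) is not None]),
            np.array([getattr(g, attr) for g in group if getattr(g, attr) is not None]),
        )

    if len(spont) >= 3 and len(evoked) >= 3:
        fit_s = coupling_regression(spont, "disp")
        fit_e = coupling_regression(evoked, "disp")
        xs, ys = xy(spont, "head_disp_z")
        xe, ye = xy(evoked, "head_disp_z")
        perm = permutation_slope_test(
            xs, ys, xe, ye, config.n_shuffles, seed=int(rng.integers(2**31))
        )
        mean_amp = permutation_mean_test(
            np.abs(xs), np.abs(xe), config.n_shuffles, seed=int(rng.integers(2**31))
        )
        results["coupling"] = {
            "spontaneous": dataclasses.asdict(fit_s),
            "evoked": dataclasses.asdict(fit_e),
            "gain_reduction_pct": percent_gain_reduction(fit_s.slope, fit_e.slope),
            "perm_slope": dataclasses.asdict(perm),
            "perm_mean_abs_amp": dataclasses.asdict(mean_amp),
        }
        try:
            fit_sv = coupling_regression(spont, "vel")
            fit_ev = coupling_regression(evoked, "vel")
            results["coupling_velocity"] = {
                "spontaneous": dataclasses.asdict(fit_sv),
                "evoked": dataclasses.asdict(fit_ev),
            }
        except GazekitError:
            pass

    # evoked probability per condition
    saccades = [g.saccade for g in shifts]
    probs = evoked_probability(saccades, stimuli)
    results["evoked_probability"] = {
        f"{m}|{s}": v for (m, s), v in probs.items()
    }

    # endpoints: left vs right stimuli, pooled over modalities
    left_ev = [g.saccade for g in evoked if g.saccade.stimulus_side == "left"]
    right_ev = [g.saccade for g in evoked if g.saccade.stimulus_side == "right"]
    if len(left_ev) >= 2 and len(right_ev) >= 2:
        results["endpoints_left_vs_right"] = dataclasses.asdict(
            endpoint_stats(left_ev, right_ev)
        )

    # PSTH
    edges, prob = saccade_psth(
        np.array([s.onset_s for s in saccades]), stimuli.times
    )
    pd.DataFrame({"bin_left_ms": edges[:-1], "p_saccade": prob}).to_csv(
        out / "psth.csv", index=False, float_format="%.9g"
    )

    # eye-position-conditioned statistics over trials
    trial_rows = _trial_table(stimuli, shifts, eye, head, config)
    if trial_rows is not None:
        pos, amp, hd = trial_rows
        pstats = position_conditioned_stats(pos, amp, hd, config.bin_width_deg)
        pd.DataFrame(
            {
                "bin_center_deg": pstats.bin_centers,
                "n": pstats.n_trials,
                "p_saccade_left": pstats.p_saccade_left,
                "p_saccade_right": pstats.p_saccade_right,
                "p_saccade_any": pstats.p_saccade_any,
                "p_head_left": pstats.p_head_left,
                "p_head_right": pstats.p_head_right,
            }
        ).to_csv(out / "position_bins.csv", index=False, float_format="%.9g")

    # amplitude vs initial position, fit per stimulus side (mixing sides
    # confounds the fit when endpoints are side-biased)
    from .stats import ols_fit

    fits = {}
    for side in ("left", "right"):
        sel = [g.saccade for g in evoked if g.saccade.stimulus_side == side]
        if len(sel) >= 3:
            f = ols_fit(
                np.array([s.start_deg for s in sel]),
                np.array([s.amplitude_deg for s in sel]),
            )
            fits[side] = dataclasses.asdict(f)
    if fits:
        results["amplitude_vs_position"] = fits

    # spontaneous-rate windows
    spont_windows = spontaneous_rate_windows(
        np.array([s.onset_s for s in saccades]), stimuli, eye, head,
        bin_width_deg=config.bin_width_deg,
    )
    results["baseline_windows"] = {
        "n_windows": spont_windows["n_windows"],
        "p_saccade_overall": spont_windows["p_saccade_overall"],
    }
    write_json(results, out / "analysis.json")


def _trial_table(stimuli: StimulusLog, shifts, eye: EyeTrace, head, config: RunConfig):
    """Per-trial (initial position, evoked amplitude or NaN, head disp)."""
    if len(stimuli) == 0:
        return None
    win = config.detection.response_window_ms / 1000.0
    by_stim = {}
    for g in shifts:
        if g.saccade.klass == "evoked" and g.saccade.stimulus_index is not None:
            by_stim.setdefault(g.saccade.stimulus_index, g)
    pos, amp, hd = [], [], []
    onsets = np.array([g.saccade.onset_s for g in shifts])
    for j, t in enumerate(stimuli.times):
        if np.any((onsets >= t - 0.5) & (onsets < t)):
            continue  # no pre-stimulus fixation
        pos.append(eye.position_deg[eye.index_at(t)])
        g = by_stim.get(j)
        amp.append(g.saccade.amplitude_deg if g else np.nan)
        if g is not None and g.head_disp_z is not None:
            hd.append(g.head_disp_z)
        elif head is not None and head.covers(t, t + win + 0.15):
            i_on = head.index_at(t)
            hd.append(head.signal_z[head.index_at(t + 0.15)] - head.signal_z[i_on])
        else:
            hd.append(np.nan)
    return np.array(pos), np.array(amp), np.array(hd)


def _stage_report(config: RunConfig, out: Path) -> None:
    make_report(out)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "detect": _stage_detect,
    "analyze": _stage_analyze,
    "report": _stage_report,
}


def make_report(run_dir) -> Path:
    """Render a human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    missing = [f for f in ("manifest.json",) if not (run_dir / f).exists()]
    lines = ["# gazekit run report", ""]
    if (run_dir / "manifest.json").exists():
        manifest = read_json(run_dir / "manifest.json")
        lines += [
            f"- gazekit version: {manifest['gazekit_version']}",
            f"- config sha256: {manifest['config_sha256'][:16]}...",
            f"- seed: {manifest['seed']}",
            "",
        ]
    if (run_dir / "events.csv").exists():
        df = pd.read_csv(run_dir / "events.csv")
        lines += ["## Detection", "", f"- saccades detected: {len(df)}"]
        if len(df):
            counts = df["class"].value_counts().to_dict()
            lines += [f"- by class: {counts}"]
        lines += [""]
    else:
        missing.append("events.csv")
    if (run_dir / "analysis.json").exists():
        a = read_json(run_dir / "analysis.json")
        lines += ["## Analysis", ""]
        if "coupling" in a:
            c = a["coupling"]
            lines += [
                "### Head-eye coupling (displacement at +150 ms vs amplitude)",
                "",
                f"- spontaneous: slope {c['spontaneous']['slope']:.3f} Z/deg, "
                f"R^2 {c['spontaneous']['r_squared']:.2f}, n {c['spontaneous']['n']}",
                f"- evoked: slope {c['evoked']['slope']:.3f} Z/deg, "
                f"R^2 {c['evoked']['r_squared']:.2f}, n {c['evoked']['n']}",
                f"- gain reduction: {c['gain_reduction_pct']:.1f}%",
                f"- permutation p (slope difference): {c['perm_slope']['p_value']:.2g}",
                "",
            ]
        if "evoked_probability" in a:
            lines += ["### Evoked saccade probability", ""]
            for cond, v in a["evoked_probability"].items():
                lines += [
                    f"- {cond}: {100 * v['evoked']:.1f}% "
                    f"(baseline {100 * v['baseline']:.1f}%, n={v['n']})"
                ]
            lines += [""]
        if "endpoints_left_vs_right" in a:
            e = a["endpoints_left_vs_right"]
            lines += [
                "### Saccade endpoints (left vs right stimuli)",
                "",
                f"- left: {e['mean_a']:.1f} +/- {e['sd_a']:.1f} deg (n={e['n_a']})",
                f"- right: {e['mean_b']:.1f} +/- {e['sd_b']:.1f} deg (n={e['n_b']})",
                f"- Welch t = {e['t_welch']:.2f}, p = {e['p_welch']:.2g}",
                "",
            ]
        if "amplitude_vs_position" in a:
            lines += ["### Evoked amplitude vs initial eye position", ""]
            for side, f in a["amplitude_vs_position"].items():
                lines += [
                    f"- {side} stimuli: slope {f['slope']:.3f}, "
                    f"intercept {f['intercept']:.2f} deg, R^2 {f['r_squared']:.2f}"
                ]
            lines += [""]
        if "baseline_windows" in a:
            b = a["baseline_windows"]
            lines += [
                "### Baseline saccade probability (quiet 1 s windows)",
                "",
                f"- {100 * b['p_saccade_overall']:.2f}% per 100 ms window "
                f"({b['n_windows']} windows)",
                "",
            ]
    else:
        lines += ["## Analysis", "", "- analysis outputs absent", ""]
        missing.append("analysis.json")
    if "manifest.json" in missing:
        raise ReportError(f"run directory incomplete, missing: {missing}")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
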