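# gazekit

Analysis of gaze shifts in head-fixed mice: saccade detection from
camera-based eye tracking, quantification of the *attempted* head
movements that accompany each saccade on a load-cell (strain gauge)
channel, classification of events relative to sensory stimuli, and the
population statistics that tie them together — head–eye coupling
regressions, permutation tests, peri-stimulus probabilities and
eye-position-conditioned analyses.  A synthetic session generator with
full ground-truth annotations exercises every stage, so the pipeline is
testable end-to-end without any data download.

It is written for oculomotor/behavioral-neuroscience labs that track the
eyes with pose-estimation software (pupil and corneal-reflection edges at
100 Hz) and record head torque against fixation with a load cell (2000 Hz
DAQ).

## The measurements

**Eye position.** Horizontal angular position follows the arcsine
projection model: E = asin((x_pupil − x_CR − offset)/R), with pupil and
corneal-reflection centers taken as midpoints of their tracked edge
pairs, R the effective projection radius (a per-setup calibration), and
the offset mapping the session-mean displacement to 0°.  Frames with
tracking likelihood < 0.90 are discarded (gaps ≤ 30 ms interpolated);
both eyes are averaged, which cancels the nasal/temporal amplitude
asymmetry of each eye; each session is mean-centered.

**Saccades.** Events whose speed exceeds 100°/s, with amplitude ≥ 3°,
and not preceded by another saccade within 100 ms.  Onset and offset are
the first samples at which speed rises above 30°/s and falls below
20°/s.  A saccade is *evoked* if its onset lies within 100 ms after a
stimulus, *spontaneous* if no stimulus occurs within ±500 ms, otherwise
unclassified.

**Attempted head movement.** The load-cell voltage is low-pass filtered
at 80 Hz (zero-phase second-order Butterworth), resampled onto the
100 Hz eye clock, and Z-scored per session.  Per gaze shift: the
displacement is the signal 150 ms after saccade onset (referenced 500 ms
before onset), the velocity is the derivative 60 ms after onset, and the
latency is the first crossing of 5 baseline SDs within ±500 ms of onset.

**Coupling statistics.** Head displacement regressed on saccade
amplitude (ordinary least squares pooled over trials) gives the coupling
gain in Z/deg; group differences in slope or mean are tested by
label-shuffling permutation (10,000 shuffles, two-sided add-one p).
Trials can be matched across conditions on initial eye position and/or
amplitude by greedy nearest-first Euclidean matching with a 3° cutoff.

The synthetic generator plants logistic saccade waveforms obeying a
linear main sequence, evoked amplitudes that depend linearly on initial
eye position, and a head channel with a biphasic (slow + fast) response
for spontaneous gaze shifts — the slow ramp starting 100–200 ms before
saccade onset — but a fast-only response for evoked ones.  Its defaults
reproduce the regime in which spontaneous gaze shifts couple at
0.214 Z/deg and evoked ones at 0.162 Z/deg, a 24% gain reduction.

## Worked example

```bash
cat > demo.yaml <<'EOF'
simulation:
  seed: 42
n_shuffles: 2000
EOF
gazekit all --config demo.yaml --seed 42 --out demo_full
cat demo_full/report.md
```

This simulates one ~55-minute session (350 ear-airpuff trials), writes
the pose tables / head trace / stimulus log, runs preprocessing,
detection and analysis, and prints (abridged):

```
## Detection

- saccades detected: 441
- by class: {'spontaneous': 339, 'evoked': 102}

### Head-eye coupling (displacement at +150 ms vs amplitude)

- spontaneous: slope 0.217 Z/deg, R^2 0.86, n 339
- evoked: slope 0.148 Z/deg, R^2 0.77, n 102
- gain reduction: 31.6%
- permutation p (slope difference): 0.0005

### Saccade endpoints (left vs right stimuli)

- left: -6.0 +/- 1.3 deg (n=51)
- right: 5.2 +/- 1.3 deg (n=51)

### Evoked amplitude vs initial eye position

- left stimuli: slope -0.981, intercept -6.07 deg, R^2 0.95
- right stimuli: slope -0.964, intercept 5.33 deg, R^2 0.95
```

Reading: spontaneous gaze shifts carry larger attempted head movements
per degree of saccade (0.217 vs 0.148 Z/deg here; single-session
estimates scatter around the generating 0.214/0.162), the slope
difference is significant by permutation, left and right stimuli drive
saccades to opposite eccentric endpoints, and evoked amplitude falls
off with initial eye position with unit slope — the eye travels to a
stimulus-specific endpoint regardless of where it started.

The library surface mirrors the pipeline: `gazekit.generate_session`,
`gazekit.detect_saccades`, `gazekit.classify_saccades`,
`gazekit.attach_head_metrics`, `gazekit.coupling_regression`,
`gazekit.permutation_slope_test`, `gazekit.match_trials`, and so on; see
the module docstrings.

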