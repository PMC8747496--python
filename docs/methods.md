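# Methods

This note documents the models, conventions and numerical choices behind
gazekit, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic tests do and do not
demonstrate about real data.

## Eye kinematics

Angular position uses the arcsine projection model,
`E = asin((Δx − offset)/R)` in degrees, where `Δx` is the horizontal
distance between the pupil center and the corneal-reflection center
(each the midpoint of its tracked edge pair).  `R`, the effective
projection radius in pixels, depends on eyeball geometry, camera
magnification and pixel pitch; it is a per-setup calibration input
(`EyeCalibration.effective_radius_px`, default 128 px, chosen to match a
~1.25 mm rotation radius under ~0.5× telecentric magnification at
typical sensor pitch).  The default `offset` maps the session-mean
displacement to 0°, and the averaged-eye trace is additionally
mean-centered in degrees; detection is invariant to these offsets.

Quality control discards frames whose pose-estimation likelihood falls
below 0.90 for any of the four required points.  Gaps of at most
3 frames (30 ms at 100 Hz, shorter than any saccade-relevant timescale)
are bridged by linear interpolation; longer gaps stay invalid and any
saccade spanning them is dropped.  A session with more than half its
frames invalid is rejected outright.

Velocity is the central difference over one sample interval (one-sided
at the ends).  At 100 Hz this is unbiased for smooth waveforms but
quantizes onset/offset placement to ±10 ms, which in turn jitters the
measured amplitude by a few tenths of a degree per event (see
"Detector fidelity" below).

## Head-signal conditioning

The load-cell voltage (2000 Hz) is low-pass filtered at 80 Hz with a
zero-phase second-order Butterworth filter (`sosfiltfilt`; the effective
magnitude response is the square of the single-pass response), linearly
interpolated onto the 100 Hz eye clock, and Z-scored per session.
Z-scoring is what makes sessions and animals comparable: raw voltage
ranges differ across mice.  Note that the digital (bilinear) Butterworth
design deviates from the continuous-time magnitude formula at
frequencies well above the cutoff — at 200 Hz the forward–backward gain
is 0.0223 rather than the analog 0.0250 — so the filter contract is
checked against the closed-form response of the digital filter itself.

## Saccade detection and classification

Detection thresholds follow the field-standard velocity criterion:
events exceed 100°/s, measure at least 3° from onset to offset, and
respect a 100 ms refractory period with respect to the previously
accepted saccade.  Onset is found by walking backward from the 100°/s
crossing to the first sample whose speed rises above 30°/s (anchoring
the onset to this event rather than to earlier drift), offset forward to
the first sample below 20°/s; amplitude is the signed onset-to-offset
displacement (not peak excursion).  Detection operates on speed;
direction comes from the amplitude sign (rightward positive).

Classification relative to the stimulus log: evoked within
`(t_stim, t_stim + 100 ms]` (attributed to the nearest preceding
stimulus — with ≥ 7 s inter-trial intervals double attribution cannot
occur), spontaneous when no stimulus falls within ±500 ms, otherwise
unclassified.

## Head-coupling metrics

Per gaze shift, the attempted-head displacement is the conditioned
signal 150 ms after saccade onset *referenced to the trace value 500 ms
before onset*.  The reference point matters: the slow component of
spontaneous gaze shifts rises during the 100–200 ms before saccade
onset, so referencing at onset would subtract it and collapse the
spontaneous coupling gain onto the evoked one.  The −500 ms reference
includes the slow phase; onset-referencing remains available via
`DetectionConfig.head_disp_ref_ms = 0` for analyses that deliberately
isolate the fast phase.  Head velocity is the instantaneous derivative
60 ms after onset (the time at which the average load-cell velocity
peaks); an alternative reading — the maximum over [0, 60] ms — is
available behind `head_vel_max_over_window`.

Latency uses a per-trial baseline over −1.0 to −0.5 s; trials qualify
only if the head stayed within a ±0.25 Z fixation band there, and the
latency is the first crossing of 5 baseline SDs within ±500 ms of
onset.  Head-movement probability thresholds (0.25 Z, shared with the
fixation band) are stable over roughly 0.1–2 Z for strong responses.

## Statistics

* Coupling regressions are unweighted OLS pooled over trials (per-mouse
  fits are available by fitting per session and averaging); slope p from
  the t statistic with n − 2 df.
* Permutation tests shuffle group labels over the pooled observations,
  refit the statistic per shuffle (10,000 by default), and report the
  add-one two-sided p, `(1 + #{|null| ≥ |obs|})/(1 + n_shuffles)`, which
  cannot return zero and is exactly calibrated at the achievable levels.
* Trial matching is greedy globally-nearest-first without replacement
  under a 3° Euclidean cutoff, with deterministic `(index_a, index_b)`
  tie-breaks; greedy order makes the pairing symmetric in A and B.
* Position-conditioned analyses bin initial eye position at 2° over
  [−10, 10]° by default; empty bins are reported missing, not zero.
  Amplitude-vs-position fits are computed per stimulus condition (side):
  pooling sides confounds the fit because the 3° amplitude floor
  removes different position ranges for left and right stimuli.
* Baseline ("spontaneous") rates use non-overlapping 1 s stimulus-free
  windows with a saccade-free first 500 ms, probing saccade occurrence
  in [500, 600) ms and the head sensor at 650 ms referenced to 500 ms.

## The synthetic session generator

The generator is the package's test bed: every event it plants is
recorded with its onset, amplitude, class and head displacement, so
precision/recall and parameter recovery are measurable exactly.

* **Schedule**: 350 stimuli at uniform 7–12 s intervals (~55 min),
  random left/right side.
* **Saccade waveform**: logistic sigmoid; the rate constant is set so
  the analytic peak velocity obeys the main sequence
  `V = 45 (deg/s)/deg × A + 100 deg/s`.  All planted event quantities
  (main-sequence velocity, coupling displacement) are expressed on the
  *observable* amplitude — the displacement between the 30°/s and 20°/s
  crossings — which is what the measurement convention reports; the
  asymptotic waveform step is kept separately in the ground truth.
* **Spontaneous process**: Poisson candidates at 0.19 Hz thinned by a
  1.6 s intersaccadic dead time (mice rarely saccade in quick
  succession) and cleared from a (−1.5, +1.6) s guard zone around
  stimuli; the realized rate gives the ~1.3% baseline probability per
  100 ms quiet window.  The guard zone exists so that the decaying head
  pulse of a neighboring event can never overlap an evoked trial's
  −500 ms reference or +150 ms measurement point; its side effect is
  that synthetic peri-stimulus histograms have an artificially clean
  pre-stimulus baseline — baseline rates should be read from quiet
  windows, as the analysis does.  Amplitudes are uniform 3.5–15°
  (the distribution is not constrained by data; no fidelity claimed),
  directed toward the orbital center with probability 0.6 and bounded
  to ±12°.
* **Evoked events**: with probability 0.44 per stimulus an intended
  amplitude `intercept_side + slope × position + N(0, 1.2°)` is drawn
  (defaults: slope −1, intercepts ±5.4°); intents below the 3.5°
  saccade floor produce no saccade, which both yields the realized
  ~29% evoked-saccade probability and reproduces the dip of saccade
  probability at positions matching the condition's mean endpoint.
  Latency is uniform in 30–90 ms.
* **Head channel**: each saccade contributes a fast pulse (quintic
  smoothstep rise over 120 ms, plateau to 400 ms, 600 ms decay) scaled
  to `0.162 Z/deg × amplitude`; spontaneous saccades add a slow linear
  ramp starting 100–200 ms before onset that brings the total at
  +150 ms to `0.214 Z/deg × amplitude`.  A per-event Gaussian residual
  (0.9 Z) models trial-to-trial coupling variability.  Background =
  white noise (0.05 Z, matching the ~0.05–0.1 Z baseline SD of real
  trials) plus a slow Ornstein–Uhlenbeck posture wander (τ = 20 s)
  whose variance is budgeted so the session has exactly unit variance —
  making the downstream Z-scoring a near no-op and keeping the
  configured gains meaningful in conditioned units.  With zero noise
  the channel is the bare event signal (exact-arithmetic mode).
* **Two eyes**: both eyes share the common trace plus independent 0.2°
  white jitter; each saccade additionally pushes the eyes apart by
  8% of its amplitude (temporal amplitudes exceed nasal ones), relaxing
  over ~1.5 s, so per-eye directional amplitudes are asymmetric while
  the averaged trace is not.
* Randomness flows from one seed through named sub-streams (schedule,
  events, eye noise, head noise), so sessions are bit-reproducible.

### What the synthetic tests do not show

The generator understates real trial-to-trial scatter (endpoint SDs of
~1.2–1.4° versus 3.4–4.5° in recordings, coupling R² of ~0.8 versus
~0.6): the geometry checks need tight within-condition noise, so passing
them demonstrates correctness of the machinery, not robustness to the
full biological variance.  It also omits slow ocular drift, optokinetic
nystagmus, blinks beyond likelihood dropouts, pupil-size changes,
vertical eye motion and any stimulus-rate modulation of the spontaneous
process.  Detector scores on synthetic sessions are therefore upper
bounds for real data.

## Problem sizes

Test-suite and acceptance-script simulations use 4–20 full-length
sessions per check (chosen to put ~1,500–2,000 gaze shifts in each
regression group, matching the scale at which the coupling contrasts are
resolvable) and reduced shuffle counts (199–2,000) for permutation
calibration; these sizes keep a complete run in the low minutes on one
CPU while leaving every confidence interval comfortably narrower than
the effects under test.

## Known limitations

* The Dryad-deposited recordings are not redistributed here and their
  on-disk layout is undocumented; a loader for them would be a thin
  adapter producing the same `PoseTable` / head-trace / `StimulusLog`
  inputs.
* The effective projection radius has no universal default; real rigs
  must calibrate it.
* Pooling across mice currently means pooling trials or averaging
  per-session statistics; no mixed-effects modeling.
* `session_io` relies on pandas for all CSV dialects rather than custom
  parsers; the three-header-row pose dialect is read via a two-level
  `read_csv` header.
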