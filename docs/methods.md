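# Methods

## Scope and data model

`falldet` models a wrist-worn fall detector built from triaxial sensor
recordings sampled nominally at 50 Hz. A *recording* is one trial of one
activity by one participant: accelerometer (m/s², gravity included),
gyroscope (rad/s) and orientation (scalar-first unit quaternion,
body-to-world) traces plus metadata. Activities are eight fall types
(F01–F08: slips, trips and sitting falls) and eleven activities of daily
living (D01–D11: walking, jogging, stairs, postural transitions, hitting a
table, clapping, handling a door). Fall recordings carry a manually
delimited **actual fall** interval `[a, b]` — the span containing the
four fall phases (prefall, impact, adjustment, postfall).

Time is seconds from recording start. The actual-fall interval is closed;
analysis windows are half-open `[t, t+w)`, so a 9 s window at 50 Hz holds
exactly 450 samples (`t·f ≤ i < (t+w)·f`). On disk a recording is one CSV
per sensor (`t,x,y,z`; orientation `t,qw,qx,qy,qz`) plus a flat key-value
sidecar holding cohort, rates and the fall interval; a layout descriptor
can absorb alternative column namings. CSVs are written at 17 significant
digits and read with pandas' `round_trip` float parser so write→read is
the exact identity.

## Acquisition protocol arithmetic

The young-participant (YP) protocol is 14 users × all 19 activities × 3
repetitions, with the lateral sitting fall F08 repeated 4 times:
14×7×3 + 14×4 = 350 fall signals and 14×11×3 = 462 ADL signals. The elder
(EP) protocol stores each elder's ADL subset verbatim; elders' repetition
counts varied with mobility and fatigue in the original campaign, so the
published EP totals are treated as metadata and never recomputed.

## Synthetic generator

The generator exists so every downstream stage is testable; it emulates
the statistical structure the pipeline relies on, not biomechanics. All
output is a pure function of (activity code, parameters, seed).

**Falls.** File duration is uniform on [8, 16.5] s. The actual-fall
duration is drawn from Normal(3.1037, 0.2731) s truncated below at 1.5 s,
and the interval is centred on the impact time, so the greatest
acceleration variation sits at the interval midpoint. Phases: context
movement (walking gait for F01–F04, seated for F05–F08), a free-fall onset
in which the measured gravity reaction fades toward zero, an impact
cluster of 2–4 short spikes peaking near `impact_peak` (default 30 m/s²),
a decaying 11 Hz adjustment oscillation, then lying still. Orientation
tilts from upright to lying (≈90°) across the event; the gyroscope is the
angular rate of that tilt.

**ADLs** fall into four movement classes: *periodic* (walk 1.9 Hz, jog
3.0 Hz, stairs 1.7 Hz — a fundamental plus a weak 2f harmonic),
*transitional* (one smooth posture change with a moderate bump),
*impulsive* (repeated short spike clusters: hit/clap at ~22 m/s² peak,
deliberately between periodic ADLs (~14 m/s²) and fall impacts (~30 m/s²)
so they are fall-confusable), and *quasi-static* (door handling, ~1 m/s²).
The 20 Hz cap on fundamentals reflects the maximum frequency of human body
movement. The spec's acquisition protocol gives no signal amplitudes;
`impact_peak`, class amplitudes and the additive Gaussian noise
(σ = 0.3 m/s² per axis) are the package's calibration choices, fixed
before any evaluation and not revisited.

Sensor consistency: the accelerometer reads the body-frame gravity
reaction `R(q)⁻¹·(0,0,g)` plus movement plus noise, so at rest, rotating
the accelerometer vector by the orientation recovers (0, 0, g). Per-user
jitter (±15 % amplitude, ±8 % frequency) makes users differ more than
repetitions; elder recordings scale amplitudes ×0.6 and frequencies ×0.8
("less vigorous" movement). ADL files share the fall files' 8–16.5 s
duration range — one campaign-wide convention; a consequence is that
roughly one file in five is shorter than the 9 s deployed window and
contributes no windows, which mirrors the real protocol's awkward fit of
8 s files to 9 s windows.

## Preprocessing

*Rate reduction* resamples onto a uniform grid (`round(duration·f)` points
at `k/f`) by per-axis linear interpolation — deterministic, and exact for
the non-integer 50→40 Hz ratio; a block-median mode exists for sensitivity
checks. Upsampling is refused. *Median filtering* is a centre-aligned
rolling median (default width 5) with passthrough edges, preserving length
and hence window arithmetic. *Vertical acceleration* rotates body-frame
acceleration into the world frame through the (interpolated, renormalised)
quaternion and keeps the world z-component — at rest +g. The quaternion
convention (scalar-first, body-to-world) is isolated in one function and
cross-checked in tests against a hand-written rotation-matrix oracle.

## Windowing and labeling

Windows start at 0 and advance by `jump_s` (default 1 s) while
`start + w ≤ duration`; the count has the closed form
`floor((d − w)/jump) + 1`. A window is Fall iff its overlap with the
actual-fall interval is ≥ 50 % of that interval's length; the tie (exactly
50 %) counts as Fall — the safety-first reading, since a missed fall costs
more than a false alarm. Overlap is measured against the fall, not the
window: a 9 s window therefore keeps the Fall label anywhere it retains
≥ ~1.55 s of a ~3.1 s fall, which for a centrally placed fall is every
admissible start; 5 s windows discriminate start positions. Remainder
samples after the last full window are discarded; files shorter than the
window yield no windows (logged).

## Features

FS-1 is {max, min, mean, sample variance} per axis; variance uses the N−1
denominator in both routes. The streaming route updates per reading:
max/min by replace-or-keep, mean by `m += (x − m)/N`, and variance by
`s² ← ((N−2)s² + (x − m_{N−1})(x − m_N))/(N−1)` (0 for N ≤ 1) — the
recursion algebraically identical to accumulating the Welford M2 sum and
dividing once at the end. Streaming equals batch to < 1e-9 over 450-sample
windows; this equivalence is the module's central property test. No
feature scaling is applied anywhere: the on-watch kNN runs on raw
features. A selectable *feature* for the study grid is a
(sensor, statistic) pair applied jointly to x, y, z — the granularity
under which three sensors give a pool of 12 and 4095 non-empty subsets.
Orientation contributes its quaternion vector part (qx, qy, qz) as the
three axes.

## Classification and evaluation

kNN is from scratch: stable argsort over Euclidean distances, majority
vote. Distance ties at the k-th neighbour resolve by training-point
insertion order (reproducibility); vote ties predict Fall (safety).
SVM (RBF/poly) and decision trees (gini/entropy/log-loss) delegate to
scikit-learn behind the same fit/predict surface; they exist only for the
offline grid.

Cross-validation is stratified 5-fold, seeded, by window; a
`group_by_recording` option keeps a trial's windows in one fold for
leakage control (off by default, matching the apparent offline protocol).
Fold metrics aggregate to mean and sample (N−1) standard deviation;
metrics with zero denominators are reported as explicit undefined markers,
never NaN. `run_grid` decodes flat indices into configurations (so
counting is exact without materialising 1.5 M points), caches feature
tables per (rate, window), and accepts a seeded subsample budget — the
full grid at realistic data scale is a cluster job, not a desk one.

## Online simulator

The watch cannot thread: it alternates collecting one window (streaming
updates per reading) with classifying it. Classification occupies a *dead
zone* during which samples are dropped; its duration is modelled as linear
in dataset size, `|dataset| × 2/650 s` — calibrated to the single field
observation of ~2 s at ~650 points, and exposed as a config constant since
no better timing model is available. A ground-truth fall wholly inside a
dropped span is counted as a missed fall (false negative): the detector
provably cannot see it. Stream samples are conserved: collected + dropped
= total.

On a Fall prediction the wearer is queried; the window's features join the
dataset with the confirmed label (no answer ⇒ fall, fail-safe), then the
memory cap (default 400 points = the 200+200 seed dataset) is enforced by
pruning: oldest seed ADL points first, then oldest seed falls, then oldest
feedback points — prioritising the broader user-feedback data — with class
balance kept within 3:1 where possible. Streams for simulation are built
by concatenating recordings with quasi-static idle filler; collection
restarts immediately after classification (an optional feedback pause knob
exists).

The battery chain divides capacity by observed and baseline lifetimes,
rounding draws to 3 decimals (1.02 Wh / 34 h → 0.030 W; /144 h → 0.007 W;
delta 0.023 W, 0.552 Wh per day).

## Problem sizes and what the tests show

The default test and acceptance runs use: the full synthetic YP campaign
(812 recordings, ~3.1 k windows) across 5 seeds for end-to-end recovery;
1000 random windows for streaming-vs-batch; 500 random instances for
kNN-vs-brute-force; and a ~10-minute simulated session for the learning
loop. On this synthetic data the deployed configuration reaches ~0.995
accuracy — higher than one should expect on real recordings, because the
generator's classes are cleaner than real wrist data: no sensor dropouts,
no inter-subject biomechanical idiosyncrasy, simple stationary noise.
Passing tests therefore validate the *pipeline* (labeling, features,
classifier, simulator, arithmetic), the direction of effects (rate
degradation, learning reducing false alarms), and the generator's
documented statistics — not field performance. Reproducing the original
study's tables requires the real public dataset; the pipeline accepts it
through the CSV layout descriptor.

## Known limitations

* The generator is phenomenological; impact shapes and gyroscope coupling
  are stylised.
* The dead-time model is a single-point linear calibration.
* Quaternion interpolation is per-component with renormalisation —
  adequate for slowly varying orientation, not for fast tumbling.
* Elder repetition counts are nominal (3); the real campaign varied them
  per person.
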