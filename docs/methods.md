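# Methods

## Model overview

The package simulates a two-day interference experiment in which two
opposing velocity-dependent curl fields are learned concurrently, each
cued by the direction of a contextual lead-in movement, and the learned
compensation is probed with channel trials whose lead-in kinematics and
modality vary. It is organized as a simulator (kinematics, protocol,
environment, memory), an analysis pipeline (MPE and force-compensation
metrics, generalization surfaces, transfer ratios), and a ground-truth
synthetic-data generator that lets every estimator be validated by
parameter recovery.

Coordinate frame: the central via point is at the origin, angles are
measured counter-clockwise from +x, the 0° target is at (0.18 m, 0), and
the 270° target at (0, −0.18 m). Lead-in start locations sit at the
lead-in distance from the via point at 135°/225° (0° target) and 45°/135°
(270° target). A lead-in arriving at +45° relative to the upcoming reach
cues the CW field by default; participant parity flips this mapping
(counterbalancing). All signals are sampled at 1 kHz (dt = 1 ms).

## Trajectories

All prescribed movements are straight-line minimum-jerk profiles,
`x(τ) = d·(10τ³ − 15τ⁴ + 6τ⁵)`, which start and end at rest and peak at
`1.875·d/T` at the temporal midpoint. The experiment specifies only the
adaptation movement's extent (18 cm) and rewarded duration band
(450–600 ms); the simulator's desired adaptation trajectory is minimum
jerk over 525 ms, the midpoint of that band. The reversed-visual
("lead-away") probe is the training profile with start and end exchanged;
because the minimum-jerk speed profile is time-symmetric this is
implemented as a reversed heading, not a reversed speed profile.

## Trial dynamics

The hand is a planar point mass, m = 1.5 kg, driven by

    m·ẍ = K_p(x_d − x) + K_d(ẋ_d − ẋ) + m·ẍ_d − c·F_curl(k_ctx, ẋ_d) + F_env + η

with tracking gains K_p = 700 N/m, K_d = 40 N·s/m (values in the range
used by published point-mass simulations of this paradigm; the experiment
itself does not model the arm), inverse-dynamics feedforward `m·ẍ_d`, the
learned compensatory feedforward (recalled compensation fraction `c`
times the negated curl force at the desired velocity), and white motor
force noise η (sd 0.2 N per axis per sample, seeded per trial).
Integration is semi-implicit Euler at 1 ms, stable for these gains.

Environments: null; curl `F = k·[[0,−1],[1,0]]·ẋ` with |k| = 16 N·m⁻¹·s
(CW ⇔ k < 0 in this frame); or a channel — spring 6000 N/m and damper
30 N·m⁻¹·s acting purely perpendicular to the straight via-to-target
line. On channel trials the tracking error is projected onto the channel
direction before feedback is computed: the clamp removes perceived
lateral error, so there is no error-induced lateral feedback and the
wall force isolates the predictive feedforward. Without this projection a
700 N/m feedback spring fighting the 6000 N/m wall would systematically
shrink the compensation readout by ~10%.

Dwell time at the via point is drawn uniformly from 0–250 ms. The
simulator never aborts trials; the >500 ms dwell abort rule exists only
as a validation concern for imported logs.

### Accuracy of the channel readout

The force pressed into the wall equals the compensatory feedforward plus
the hand's inertial reaction `m·p̈` to its own sub-millimetre lateral
excursion. Since `p ≈ c·k·v/spring`, the inertial term is proportional to
`v̈` and correlates with the regressor `k·v` at the level
`m·⟨v̈v⟩/(spring·⟨v²⟩) ≈ 1.3%` for these parameters. The simulator's
compensation readout is therefore accurate to ~1–2 percentage points, not
exact; the same coupling is present in any physical implementation of the
paradigm. The synthetic-data generator, by contrast, plants forces on an
ideal clamp, so estimator recovery there is exact up to noise.

## Contextual memory

Each field context holds a compensation weight `w`, updated after every
field trial by the single-rate state-space rule `w ← A·w + B·e` with
retention A = 0.99 and learning rate B = 0.1 — the simplest learner with
the observed saturating exponential time course. The drive `e` is the
simulated sign-corrected lateral error normalized by `error_ref` and
clipped to [−1, 1]. `error_ref = 0.07 m` is the model's one calibration
constant: with a naive (zero-compensation) MPE of ≈13 mm, the fixed point
`w* = B·g/(1 − A + B·g)`, `g = MPE₀/error_ref`, lands the trained-probe
asymptote in the low-to-mid 60% range, matching the published asymptotes
(62.7% passive, 68.8% visual), which serve as calibration, not
validation. Credit is assigned to the cued context only, scaled by the
recall weight of its trained condition at the experienced lead-in; the
opposing context, cued by the other lead-in direction, is untouched —
this is what lets the two memories grow without mutual cancellation.
Between days the weights decay once by `A^200` (configurable); day-2
exposure re-saturates them before generalization is probed.

Recall of a weight at a probe lead-in is a product of factors:

- Gaussian in duration offset, width σ_T (passive 0.45 s, visual 0.70 s);
- Gaussian in peak-speed offset, σ_v (passive 0.25 m/s, visual 0.40 m/s);
- saturating in distance: 1 at and above the trained distance,
  half-Gaussian of width h below it (passive 0.05 m, visual 0.08 m) —
  lengthening the lead-in beyond the trained 10 cm costs nothing,
  shortening it does;
- a cross-modal gain (passive→visual 0.352, visual→passive 0.130) and a
  reversed-visual gain (0.227 when trained passive, 0.293 when trained
  visual).

The functional forms are a modelling choice constrained only by the
qualitative shape of the published generalization surfaces (tuning in
duration and speed, flat in distance above training, narrower for passive
than visual, asymmetric transfer); the widths were chosen once to that
shape, and the gains equal the published transfer ratios by construction.
Duration and peak-speed tuning cannot be fully dissociated by the probe
grid (they covary except along iso-lines), so the product form is one of
several consistent choices. Whether cross-modal transfer acts on recall
or on learning is likewise undetermined; it is implemented as a recall
gain.

## Protocol

Day 1: 2×40 pre-exposure (36 null + 4 channel: training ×2 directions,
transfer ×2), one 102-trial familiarization pass (3 × 17 conditions × 2
directions, scheduled consecutively as its own phase and exempt from the
adjacency constraint — the only reading that reproduces the printed
day-1 total of 1546), 2×40 pre-exposure, 12×40 exposure (36 field + 4
channel), 6×134 generalization (100 field, 25 per type + one of each of
the 34 probes). Day 2: 6×40 exposure + 10×134 generalization. Totals:
1546 + 1580 = 3126 trials, 2248 field, 544 generalization channels, 34
probes × 16 repetitions. The design description elsewhere implies 38
trained-probe channels outside generalization, but the block arithmetic
yields 44; the scheduler follows the block arithmetic and the validator
reports the realized count.

Within-block ordering: channel positions are drawn uniformly over all
position sets with no adjacent channels and none first in a block, via
the standard gap bijection (an exact constructive sampler — equivalent in
distribution to rejection-sampled shuffles, but it cannot fail and is
fast enough to validate hundreds of schedules). Rest breaks are placed
every 195–205 trials (uniform, seeded). The same (seed, participant)
always reproduces the same schedule.

## Analysis

- **MPE**: signed extreme perpendicular deviation of the adaptation path
  from the straight line joining its first and last samples (using the
  path's own endpoints makes the measure isometry-invariant), sign-flipped
  on CW trials before averaging; analysis blocks of 8 trials.
- **Compensation**: over the window from leaving the via point to
  entering the target (first sample beyond / first sample within 0.75 cm
  of the respective centre — target radius 1.25 cm minus cursor radius
  0.5 cm; half-open; ≥50 samples required), the perpendicular channel
  reaction force is regressed on `k`·(forward velocity); percent = 100 ×
  slope. The regression passes through the origin — perfect compensation
  implies zero force at zero velocity — with an intercept available as a
  sensitivity option. Projecting the reaction force on the field's push
  direction makes both field directions read positive with no post-hoc
  flip. Sequential channel pairs (opposite contexts) are averaged.
- **Surfaces**: per-participant condition means first, then across
  participants (SE with n−1); optional normalization to each
  participant's trained-condition value (trained cell = 100 by
  construction). Missing cells are flagged absent, never imputed.
- **Transfer ratio**: 100 × mean probe compensation / trained asymptote
  (mean of the final 4 blocks); ratios with asymptote ≤ 5% are refused as
  unstable.
- **Tuning fit**: nonlinear least squares of the recall model on the
  15-condition normalized surface recovers σ_T, σ_v and h.

## Synthetic data

The generator plants: a single-exponential learning curve per context
(asymptote 0.627, rate constant 60 field trials), kinematic recall from
the tuning defaults, per-sample channel force noise (sd 0.3 N), and — for
field/null logs — a smooth perpendicular path bump `A·sin²(πτ)` with
planted amplitude and Gaussian trial-to-trial jitter (sd 2 mm). A smooth
bump is used instead of white positional noise because the MPE of a
white-noise path is biased upward by max-statistics. Channel logs lie
exactly on the channel line (ideal clamp). The generator emulates the
statistical structure the analysis assumes — it does not emulate hardware
artifacts (transducer noise spectra, the 500 Hz anti-aliasing filter,
display latency), feedback corrections, or trial aborts, so recovery
results bound estimator correctness, not robustness to un-modelled
physiology.

## Problem sizes and runtime

Default problem sizes, chosen to keep the full validation loop
interactive: closed-loop simulation of all 3126 trials of one participant
(~2 s with the jitted integrator); synthetic cohorts of 8 participants ×
3126 trials for recovery studies (~5 s each); Monte-Carlo regression
recovery at 1000 trials per compensation level; schedule validation over
100 seeds.

## Known limitations

- No two-joint arm, muscles, or feedback-delay model; the PD point mass
  understates within-trial feedback corrections in field trials.
- The channel readout carries the ~1% inertial coupling described above.
- The single-rate learner cannot reproduce spontaneous recovery or
  savings phenomena that motivate dual-rate models; it was chosen for the
  saturating learning curve only.
- The `A^200` between-session decay overstates overnight forgetting
  relative to the small dips seen in human data; it is configurable and
  is washed out by day-2 exposure before any generalization measure.
- Tuning widths and transfer gains are calibrated, not fitted: simulated
  surfaces reproducing the published asymmetries validate the pipeline's
  plumbing, not the model against human data.
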