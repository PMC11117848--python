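# Methods

`limbsim` reimplements, at reduced order, a PID-controlled lower-limb
simulator: a mechanism driven by external boundary conditions (a vertical
hip load, lumped quadriceps and hamstring tensions, ankle
flexion–extension and internal–external torques, an ankle medial–lateral
force, and kinematically prescribed hip anterior–posterior position and
pelvic rotation) whose five controlled outputs — knee flexion angle and
the tibiofemoral compressive, AP, IE and VV loads in the tibial frame —
are servoed onto per-patient target profiles by per-axis PID loops.  The
package covers target-profile I/O, a synthetic patient-cohort generator,
the reduced plant, the closed-loop controller, gain calibration by grid
search, the activity-average vs patient-specific motion comparison with
its RMSE reporting arithmetic, and PCA-based modelling and sampling of
the resulting actuator profiles.

## The reduced plant

The plant replaces a deformable finite-element limb with a rigid
femur–tibia chain in the sagittal plane.  The ankle sits at the origin,
fixed in AP/SI translation; the hip is fixed mediolaterally, free
vertically, and its AP position is prescribed.  Given knee flexion phi
and hip AP offset x, the chain closes in closed form: the hip lies on a
circle of radius R(phi) about the ankle, so the segment tilt angles and
the hip height y_h = sqrt(R(phi)^2 - x^2) — and their analytic
derivatives with respect to flexion — come from elementary trigonometry
(`_kernels.geom`).

**Load paths.** The femur is treated as a two-force member: a vertical
hip load W arrives at the knee as an axial femur force `N_f = W /
cos(theta_f)`.  Its component along the tibial axis compresses the joint
(the axial transmission factor `cos(phi)` is floored at 0.15 — a
conforming articulation never converts hip load into distraction at deep
flexion) and a conformity fraction (`hip_shear_frac`, default 0.25) of
its transverse component reaches the tibial tray as AP shear; femoral
rollback and articular conformity carry the rest.  Muscle tensions
compress the joint through lumped fractions (`quad_compression_frac`
0.75 — the patellofemoral mechanism diverts part of the extensor force —
and `ham_compression_frac` 0.8) and act on the flexion DOF through
effective moment arms (quadriceps extend, 0.05 m; hamstrings flex,
0.035 m).  Pelvic rotation psi tilts the muscle lines in the sagittal
plane by `pelvis_tilt_coupling * psi` (0.05 deg/deg — most of a
transverse rotation stays out of the sagittal plane), feeding the AP and
IE channels, and offsets the hip-load line in the frontal plane by
`pelvis_vv_lever_m * sin(psi)` (0.08 m), feeding VV.  The ankle torques
and ML force reach the knee by lever laws (`M_fe / L_tibia` into AP,
`M_ie cos(theta_t)` into IE, `F_ml L_tibia` into VV).

**Degrees of freedom.** Flexion plus three compliant secondary DOFs (AP
translation, IE and VV rotation) with lumped linear springs (30 N/mm,
0.5 N·m/deg, 1.5 N·m/deg) standing in for the implant constraint and
soft tissue.  The secondary loads reported by the plant are the spring
loads `k·deflection` — what the implant constraint carries — and equal
the statically applied loads at equilibrium, which is the package's
Newton–Euler consistency check.  The flexion DOF is driven by virtual
work of the hip load and segment weights against hip height: an
inverted-pendulum-like DOF with no open-loop stable equilibrium.  The
quasi-static mode regularizes it with viscous damping
(`c_flexion_Nms_per_rad`, default 15) and advances all DOFs by implicit
relaxation (fixed-point iteration for flexion, exact backward-Euler for
the springs); a semi-implicit dynamic mode with lumped inertias exists
for settling-equivalence checks.  Flexion stops act at −15 and 160 deg.

Segment masses default to 11 kg (femur, including distributed thigh soft
tissue) and 6 kg (tibia/shank); lengths to 0.42/0.40 m.  All parameters
are package defaults for a generic adult limb, fully configurable, and
none are fitted.

## Control

One PID loop per axis, each mapped to exactly one actuator: flexion to a
signed extensor demand split over quadriceps/hamstrings (negative demand
scaled by the moment-arm ratio so the commanded knee moment is
preserved; both tensions are always non-negative), compression to the
hip load, AP to the ankle FE torque, IE to the ankle IE torque, VV to
the ankle ML force.  Error signs are fixed so positive gains stabilize
every loop.  The integral term uses conditional anti-windup (integration
suspends while the command is saturated in the direction of the error);
the derivative gain exists but defaults to zero and is not tuned,
matching a calibration procedure that varies only P and I.

The control period is fixed in physical time (2 ms) rather than per
cycle percent, so one gain set has identical discrete-loop dynamics
across activities of different durations.  Two plant substeps run per
update.  A 100-update lead-in holds the initial targets so reported RMSE
measures tracking rather than the cold start.  Activity durations map
the 0–100% cycle to 4 s (gait stance), 6 s (step-down) and 8 s (deep
knee bend): the simulator plays activities back slower than real time,
as load-controlled joint rigs do, which keeps actuation rates modest
while leaving the cycle-domain profiles unchanged.  Command bounds are
generous rig-actuator values: muscles 0–8000 N, hip load 0–5000 N,
ankle torques ±500 N·m, ML force ±1000 N.

Gain calibration follows the source procedure — uniformly varied P and I
gains, best fit kept — structured as a coordinate-wise search: axes in
the order compression, flexion, AP, IE, VV (the load path is dominated
by the first two), each axis's 7×7 grid evaluated with the other axes at
their current best, plus one refinement pass.  Candidates are scored by
the fit to the desired loading as a whole (per-axis RMSE normalized by
the axis's target peak-to-peak range, summed over the five axes): the
loops interact — aggressive flexion gains track flexion marginally
better while their quadriceps activity pollutes the compressive load —
so a per-axis objective would reward cross-axis damage.  Ties resolve to
the smallest ki, then the smallest kp.  Default grid ranges follow from
the static input–output gains of the default plant (e.g. the
compression loop sees a gain of roughly `cos(phi)/cos(theta_f) +
(c_q/r_q)·h(phi,x)`, between about 1 and 7 over the motion envelope,
which bounds the stable kp·ki region at the 2 ms loop period).

## The synthetic cohort generator

The measured data the package is designed around (telemetric knee
implant recordings of nine TKA patients over stance-phase gait,
step-down and deep knee bend, with video-derived hip AP motion) is
commercially restricted, so all downstream stages run on synthetic
cohorts.  The generator emulates two things:

* **waveform shape** — smooth per-activity templates built from Gaussian
  bumps and cosine ramps: double-peaked stance-gait compression (peaks
  near 25% and 75% cycle, flexion < 25 deg), a single step-down
  compression peak with flexion to ~60 deg, and a deep-knee-bend flexion
  excursion to ~100 deg at mid-cycle with the compression peak at
  maximum flexion; compression is negative throughout and baselines stay
  near 0.6 body weight, as weight-bearing joints do;
* **cross-patient variability** — per-channel target SDs defaulting to
  the published cycle-averaged joint-load SDs (121 N AP, 3.52 N·m IE,
  12.3 N·m VV, 655 N compression, 15.4 deg flexion) and motion SDs to
  the published actuator SDs (73.2 mm hip AP, 20.3 deg pelvic rotation).
  Those printed values are single numbers per channel covering three
  activities, so the SD budget is distributed across activities in
  proportion to each template waveform's rms (stance-gait flexion varies
  a few degrees across patients, deep-knee-bend flexion tens), with the
  three-activity mean equal to the configured value.

Patient variation is `template × (1 + a_i) + b_i · shape(t)`: one
multiplicative amplitude factor and one smooth low-frequency offset
field per channel, not pointwise noise — measured joint loads are smooth
and patients differ by amplitude and offset.  Amplitude factors share a
latent loading-severity factor across channels (correlation 0.85 for
flexion and compression, 0.7 AP, 0.5 IE/VV): a patient who flexes deeper
and loads harder does so everywhere, which also keeps light compression
targets away from heavy-posture floors.  Amplitude factors are clipped
to [0.2, 2.2] (sign-preserving) and motion offsets to ±2 nominal SDs
(reach-preserving); both draw scales are inflated so the clipped
distributions still carry the configured variance, and any amplitude
variance the clipped factor cannot carry moves to the offset field, so
the realized SD stays linear in the configured SD.  Flexion targets are
clipped to a post-arthroplasty range (−10 to 125 deg) and pelvic
rotation to an anatomical ±30 deg.

Two consistency layers make each patient's loads physical, which is what
gives the patient-specific motion scenario its tracking advantage:

1. **static/trajectory consistency** — the compression target is built on
   the patient's own *floor*: the compression that holding their flexion
   trajectory already produces through (i) gravity on the segments,
   (ii) the ankle-torque cross-moment their AP target demands, and
   (iii) the viscous flexion-rate moment, each balanced by quadriceps or
   hamstring tension whose compression side-effect is the floor.  The AP
   target likewise carries the hip-path shear of the patient's posture
   and hip-load level.  Only the effort above the floor is scaled by the
   amplitude draw.
2. **motion consistency** — the load deviation the patient's own
   hip/pelvis motion produces is measured with the plant itself: the
   provisional targets are run closed-loop under the patient's motion and
   under the template motion with fixed reference gains, and the smoothed
   achieved-load difference (11-point Hann window, which strips the
   reference controller's transient signature) is added to the targets.

Because the consistency layers are nonlinear, two further deterministic
corrections keep the ensemble on its configured statistics: probe draws (fixed
internal seed, antithetic pairs) measure the realized cycle-averaged SD
so the draw scales can be iterated onto the configured SD, and measure
the construction's mean deviation so it can be subtracted (with the
floor re-enforced afterwards), making the cohort mean converge to the
template.  A final reachability pass clamps every compression target to
the floor computed from the final channels and the patient's own motion,
with one muscle-tilt iteration.

**What the generator does not emulate:** the actual measured waveforms
(no digitized curves are fitted); within-patient cycle-to-cycle
variability; channel noise; the cycle-resolved structure of the printed
SDs (matched in cycle-average only); soft-tissue differences between
patients.  Passing tests on synthetic cohorts therefore demonstrate the
architecture — control, calibration, scenario comparison, PCA — not
agreement with any real patient's loads.

## The scenario comparison

Two boundary-condition sets are compared per patient and activity:
patient-specific (the patient's own hip AP and pelvic rotation) and
activity-average (the cohort-mean motion for that activity).  Gains are
tuned independently for every patient × activity × scenario, then the
tuned loop runs once and per-axis RMSE is recorded; per (activity, axis,
scenario) the mean and n−1 SD over patients form the RMSE table, from
which the overall per-axis RMSE (unweighted mean over the three activity
means), per-cell percent reductions, and the 15-cell average reduction
are computed.  A packaged reference table from the published nine-patient
cohort exercises this arithmetic against its printed values.

With integral action, any reachable slowly-varying target is tracked
under either motion input; the structural advantage of patient-specific
motion comes from the one-sided actuator constraints — chiefly that the
hip load cannot pull (W ≥ 0), so a simulator driven with the wrong
motion cannot reproduce compression targets lighter than the floor that
motion imposes — plus the finite-bandwidth rejection of the unmatched
motion-consistent load components.  The packaged scenario study (20
seeded three-patient cohorts, all three activities, compressive-axis
cohort-mean RMSE) measures how often the patient-specific scenario wins
under exactly this mechanism.

## Numerical choices

* angles in degrees at every interface, radians internally; profile
  files carry 9 significant digits, making round-trips stable;
* the quasi-static flexion solve is a 6-iteration fixed point of the
  implicit relaxation step; its contraction factor is bounded by
  `(dt_sub / c_flexion) · dQ/dphi`, well below 1 for the default
  parameters;
* reach feasibility requires `|hip AP| < 0.95 × horizontal reach`,
  keeping postures away from the chain's singular stretch;
* PCA is a column-mean-centered SVD after per-channel standardization by
  the pooled cross-instance SD (pointwise variance across instances,
  pooled over the cycle) — channels mix N, N·m, mm and deg; components
  keep `min(instances − 1, features)` rows, the sign convention makes
  each component's largest-magnitude coefficient positive, and sampling
  draws per-component Gaussian scores truncated at ±2 SD;
* every stage is deterministic given its seed; the closed loop contains
  no randomness at all.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen as
the package's study conditions: a nine-patient cohort (the published
cohort's size) for the tracking gate; 20 three-patient cohorts with a
5×5 gain grid for the scenario study; 200 instances for PCA fraction
recovery; 101-point cycle grids throughout.

## Known limitations

* The plant is a sagittal-dominant rigid-link reduction: no ligament
  laxity, no patellofemoral joint, no contact geometry, no ML load
  distribution between condyles.  Absolute RMSE magnitudes are therefore
  plant-specific and are not comparable with values obtained on a
  deformable finite-element limb driven by measured data.
* The flexion DOF's quasi-static viscosity is a regularization, not a
  measured property; the damping value trades plant bandwidth against
  muscle-rate demands and is documented above.
* The scenario effect is a statistical property of the generator's
  consistency layers and the actuator constraints; cohorts whose drawn
  motion offsets are small yield near-tied scenario comparisons that can
  fall either way.
* The PCA variance fractions of synthetic cohorts depend on the
  generator's two-factor (amplitude/offset) structure plus motion
  couplings and are not expected to reproduce any published fractions.
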