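# Methods

## The model

`scapsim` implements a musculoskeletal model of the human shoulder whose
defining feature is a kinematically *uncoupled* scapula: instead of slaving
scapular rotation to humeral elevation, the scapula glides on a
thorax-fixed ellipsoid through a four-coordinate scapulothoracic joint, and
the large thoracoscapular muscles (trapezius, serratus anterior, rhomboids,
levator scapulae) drive its motion. This makes shrugging and independent
scapular movement representable, and it lets muscle-work accounting
attribute scapular work to the muscles that actually perform it.

### Scapulothoracic joint

The contact point is located on the ellipsoid (semi-axes `rx, ry, rz`,
default 0.09 / 0.21 / 0.145 m, center at the thorax origin, optional
sagittal tilt) by two surface angles through the trigonometric
parameterization

    p = (-rx cos e cos a,  ry sin e,  rz cos e sin a)

with *abduction* `a` a longitude about the vertical axis (measured from the
posterior midline; positive moves the scapula laterally around the thorax)
and *elevation* `e` a latitude. Reference offsets (`a0 = 0.6`, `e0 = 0.35`
rad) place the zero pose posterolaterally, so all four coordinates are zero
in the reference configuration. The scapula frame is the orthonormal
surface basis (lateral tangent, vertical tangent, outward normal) composed
with *winging* about the vertical tangent — the medial-border axis — and
*upward rotation* about the outward normal, in that order (winging
innermost). With winging innermost its axis stays near-vertical at every
upward-rotation angle; with the opposite order the axis tilts with upward
rotation and, at high elevation, is loaded with ~90 N·m of the arm's
gravity moment that in reality the unilateral blade-on-thorax contact
carries — a torque no thoracoscapular muscle can produce. Both orders
satisfy the four-coordinate definition at winging = 0.

The contact point satisfies the implicit ellipsoid equation identically,
by construction, for every pose; the property test checks a residual below
1e-9. An analytic Jacobian of the twelve transform components is generated
symbolically (sympy, cached after first use) and cross-checked against
central differences.

The humeral ball joint is parameterized Rz(flexion) · Ry(axial) ·
Rx(−abduction) about thorax-aligned reference axes (the default scapular
orientation is factored out of the joint). The axial angle sits in the
middle of the sequence because it stays small in the study tasks, which
keeps the parameterization non-singular both at the arm-hanging reference
and through 90° of flexion or abduction. ISB-style reporting angles remain
an I/O-boundary conversion.

### Bodies and anthropometry

Thorax (welded to ground), clavicle (welded; an attachment body), scapula
(0.70 kg), humerus (2.8 % body mass) and a lumped forearm+hand segment
(2.2 % body mass, welded at 20° elbow flexion) scaled to the 52 kg / 1.62 m
reference subject. A hand-held point mass (0 or 2 kg) attaches at the
distal forearm.

### Muscles

The 33 musculotendon actuators carry the published architecture table
(maximum isometric force, optimal fiber length, tendon slack length,
pennation) exactly. Attachment coordinates and wrap geometry are **not**
published; the fixture's geometry is authored so each muscle's line of
action produces the anatomically expected moment signs at the reference
pose (superior trapezius elevates and upward-rotates the scapula, serratus
anterior protracts and upward-rotates, rhomboids retract and
downward-rotate, middle deltoid abducts, and so on). After authoring, each
origin is slid along its default-pose line of action until the default MTU
length equals `l_ts + l_opt·cos(pennation)`; this keeps the published
architecture usable with approximate geometry while preserving
default-pose moment arms (sliding an endpoint along the line of action
leaves the line, hence all moment arms at that pose, unchanged). Slides are
clamped to keep origins clear of wrap surfaces; a few muscles therefore sit
slightly off optimal at reference (all within 0.8–1.35 l_opt).

Muscle paths route over two wrap surfaces: a thoracic ellipsoid (slightly
inset from the joint ellipsoid, top tilted toward the sternum by a
configurable angle, default −0.08 rad, which keeps the serratus anterior
path well-defined across the scapular range of motion) and a humeral-head
sphere (r = 24 mm) for the deltoids and rotator cuff.

### Wrapping

Sphere and cylinder wraps are closed-form (tangent–arc–tangent; the
cylinder is solved in the unrolled plane). A segment that only grazes a
surface is tie-broken to the straight segment, so path length is continuous
in the coordinates. Ellipsoid wraps are solved numerically as the
taut-string equilibrium of a polyline: each interior vertex relaxes toward
the midpoint of its neighbors and is projected back to the surface if it
would penetrate (red-black Gauss–Seidel with over-relaxation). Vertices off
the contact region line up on the straight tangent segments, so partial
contact needs no special casing. A Richardson step (doubling the vertex
count and extrapolating the O(1/k²) chord error) brings the default
`wrap_over_surface` setting to well under 1e-6 m against the sphere closed
form; model-level path evaluation (`solve_path`, `geometry_state`) uses a
faster 12-vertex setting without extrapolation (~1e-4 m bias on a deep
wrap, smooth in the coordinates) with warm-starting across consecutive
solves.

### Moment arms

Tendon excursion, r = −∂L/∂q, by central differences with a 1e-5 rad step
(configurable). A tree-locality test skips coordinates whose joint the
muscle does not span, which also makes the zero-moment-arm cases exact.
Continuity of every muscle's length over every coordinate's full range is
verified at 0.5° resolution (no step exceeding 2 mm).

### Muscle mechanics

Rigid-tendon Hill model: several tendons in the table have zero or
near-zero slack length, making tendon compliance negligible; fiber length
follows algebraically as `(l_mtu − l_ts)/cos(pennation)` with constant
pennation. Force is `[a·f_L·f_V + f_P]·F_max·cos(pennation)` with a
Gaussian active force-length curve (width 0.45), a Hill hyperbola with
eccentric plateau 1.4 (C1-matched at zero velocity, v_max = 10 l_opt/s),
and an exponential passive curve engaging above optimal length and
reaching F_max at 70 % fiber strain. The passive strain constant matters:
with a stiffer curve (F_max at 50 % strain) the antagonists stretched at
high elevation produce >100 N·m of passive torque that agonists must
cancel, roughly doubling the apparent muscle work. All curve constants
live in `MuscleCurves` and are configurable. Activation follows a
first-order lag (τ_act = 10 ms, τ_deact = 40 ms) advanced by the exact
exponential update.

### Operating-range tuning

`check_fiber_operating_range` reports each muscle's normalized fiber-length
range over a trajectory, flagging excursions outside [0.5, 1.5].
`tune_muscle_lengths` applies the published remedy iteratively: grow
optimal fiber length by 2 % and shorten tendon slack length by the same
absolute amount until the muscle is back in range or its tendon slack
reaches zero (then clamp and report). One step maps a ratio r to
(r + 0.02)/1.02, which converges toward 1 from both sides while slack
remains; muscles that hit zero slack while still too short cannot be fixed
by this rule and are reported as unresolved. The tracking pipeline runs
this tuning on a copy of the model for each task trajectory before
simulating — the same model-personalization step the original modelers
describe — while the built-in model itself always carries the published
table values.

## Tracking controller

A per-step static-optimization variant of computed muscle control. At each
control step (default 10 ms):

1. a critically damped PD law (k_p = 100 s⁻², k_v = 20 s⁻¹) converts
   tracking error into desired accelerations q̈*;
2. the torque demand τ = M q̈* + c − G − Rᵀf_P is distributed over muscle
   activations by a bound-constrained least-squares problem minimizing
   Σa² + w_r Σ(r/r_scale)² (w_r = 1000, r_scale = 1 N·m), with one reserve
   actuator per coordinate closing the residual exactly;
3. the bounds on each activation are its one-step reachable set under the
   activation dynamics, and the excitation is recovered by inverting the
   first-order lag. This activation-dynamics inversion is what makes the
   controller stable: without it the lag under-delivers torque for a few
   steps and the light scapular coordinates (inertia ~0.002 kg·m²)
   diverge.

The skeleton integrates semi-implicitly at 1 ms substeps with gravity
re-evaluated every substep; the mass matrix and the velocity bias are held
over the control interval (the tasks are slow, so the kinetic terms change
little in 10 ms; halving the control step to 5 ms roughly halves the
residual tracking error at double the cost). The mass matrix is assembled
from finite-difference body Jacobians of the vectorized forward
kinematics; the velocity bias uses the Christoffel form of a
finite-differenced mass matrix, which preserves the no-work property of
the velocity terms — the work-energy balance of the simulations closes to
well under 2 % of the gross muscle work.

### Known limitation: reserve usage at high elevation

On the shrug the reserves are numerically zero (RMS share < 0.1 % of the
muscle-generated force). In the arm-elevation tasks the winging and axial
rotation coordinates draw visible reserve torques at high elevation: the
fixture's authored geometry gives the muscle set limited authority there
(in reality part of those moments is carried by the unilateral
blade-on-thorax contact pressure, which a bilateral ideal joint cannot
represent, and by broad attachment areas the two-point paths
approximate). The reserve-share property is therefore asserted on the
shrug and reported, not asserted, elsewhere.

## Work accounting

Muscle power is MTU force times shortening velocity (concentric positive);
positive work is the trapezoidal integral of the positive part over the
elevation phase, detected as the span from 5 % of the primary coordinate's
excursion to its peak (shrug: scapular elevation; arm tasks: the humeral
coordinate). External work is the potential-energy change of all segments
plus the hand mass between the phase endpoints — path-independent by
construction. Because lengthening muscles absorb energy, total positive
muscle work exceeds the external work in every elevation condition, which
the acceptance suite asserts for all six study conditions. Work is grouped
into thoracoscapular (trapezius, serratus anterior, rhomboids, levator
scapulae, pectoralis minor) and glenohumeral (deltoids, rotator cuff,
teres major, and the remaining actuators crossing the glenohumeral joint);
contributors below 3 % of the total are flagged as excluded from headline
rankings.

## EMG processing

Zero-phase 4th-order Butterworth high-pass at 100 Hz, full-wave
rectification, zero-phase 4th-order Butterworth low-pass at 4 Hz, then
normalization by the maximum envelope across MVC trials. Filter order and
the forward-backward application follow standard surface-EMG convention and
are configurable. Model-to-EMG comparison uses the mean absolute error
over the task interval; for serratus anterior the mean of the three bundle
activations is compared against the single surface electrode.

## Synthetic study conditions

The generator emulates the experimental battery: three tasks (shrug,
forward flexion, abduction), each without and with a 2 kg hand mass, three
trials each — 18 trials. Profiles are minimum-jerk raise-and-return
(4 s default); flexion/abduction peak at 110° of the humeral coordinate
with scapular upward rotation coupled at 1:2 (scapulohumeral rhythm as a
controller target, not a model constraint); the shrug moves only the
scapular-elevation coordinate, with a 15° latitude amplitude — about
5.5 cm of scapular rise on the default ellipsoid, a physiological shrug
excursion (30° of latitude would be an 11 cm rise, which no muscle set
with the published architecture can produce). Markers are forward
kinematics at 120 Hz plus isotropic Gaussian noise (3 mm default); EMG-like
channels are band-limited (20–450 Hz) unit-RMS noise carriers
amplitude-modulated by per-channel activation profiles at 1000 Hz, with an
additive floor at 1/SNR of the peak. One seed per (task, load, trial),
derived from a base seed, makes the battery bit-reproducible.

What the synthetic data do **not** emulate: soft-tissue marker artifact
(noise is white and isotropic), electromechanical delay and cross-talk in
the EMG channels, inter-trial kinematic variability, and a moving thorax
(the model's thorax is welded to ground). Passing tests therefore
demonstrate internal consistency of the pipeline — generator, solver and
simulator agreeing with each other and with closed forms — not agreement
with recordings of a human subject, which additionally requires the
anatomical attachment geometry of the deposited model.

## Numerical choices

- IK: per-frame trust-region least squares bounded by the coordinate
  ranges, warm-started from the previous frame; frames with fewer than
  three visible markers are flagged and interpolated.
- Ellipsoid calibration: Nelder–Mead over (tilt, rx, ry, rz) with an inner
  warm-started IK on subsampled calibration frames; the post-fit objective
  never exceeds the pre-fit one (the initial point is in the simplex).
- Finite-difference steps: 1e-6 (Jacobians, gravity), 1e-5 rad (moment
  arms, mass-matrix derivatives).
- Tie-breaks: grazing wrap contact resolves to the straight segment;
  activation-dynamics inversion clips excitations to [0, 1].
- Test problem sizes: the test suite runs 2 s versions of the tasks and a
  24–40-frame calibration sweep; the acceptance script uses the full 4 s
  trials at 120 Hz.
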