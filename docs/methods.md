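# Methods

This note documents the models, numerical choices and limitations of
`neurorun`, in the order the simulation composes them.

## Rigid-body dynamics

The skeleton is a tree of rigid segments rooted at a floating pelvis.
Generalized positions hold the base orientation as a unit quaternion, the
base position, then joint angles; generalized velocities hold world-frame
base angular/linear velocity, then joint rates. Spherical joints are
parameterized as intrinsic Z-X-Y Euler triplets — compiled internally into
three stacked single-axis rotations sharing one anchor — which avoids
per-joint quaternion bookkeeping and is far from gimbal lock at gait-range
angles. World-anchored chains (no floating base) are supported for test
rigs such as pendulums.

The equations of motion `M(q) u̇ + c(q,u) = τ + Σ Jᵀf` are assembled densely:
a forward kinematics pass computes each body's frame, velocity and
zero-acceleration (bias) accelerations; the mass matrix is the
Jacobian-weighted sum of segment masses and world-frame inertias, and the
bias vector collects Coriolis, centrifugal, gyroscopic and gravity terms.
At the model sizes this package targets (≤ 31 DOF) dense assembly is
simpler to verify than a propagated articulated-body algorithm and costs
well under the contact/muscle evaluation. The test suite checks the whole
chain (mass matrix, bias forces, forward dynamics) against an independent
symbolic Euler–Lagrange derivation on 1–3 link chains to 1e-8, and checks
energy conservation of passive chains (< 0.5 % drift over 2 s at
dt = 1e-4 s).

Integration is semi-implicit (symplectic) Euler — velocities first,
positions with the new velocities, the quaternion advanced by the exact
exponential map. Defaults: dt = 1e-3 s (desk profile 3e-3 s with 16
substeps per control step, ≈ 20.8 Hz control). Joint limits are soft
one-sided torsional springs (default 50–60 N·m/rad) with extra damping
inside the violation; all joint DOF carry light viscous damping
(0.5–1 N·m·s/rad) representing unmodeled passive structures. A state
whose velocities exceed 500 rad/s (or m/s) is declared blown up; inside an
episode this truncates with zero reward rather than aborting training.

## Contact

The ground is the plane z = 0. Each foot carries one calcaneal and two
toe spheres. Normal force follows Hunt–Crossley,
`F_n = k_n d^{3/2}(1 + c_n ḋ)` clamped at zero (no adhesion), with
k_n = 5e5 N/m^{3/2} (desk 1e5), c_n = 1 s/m. Friction is Coulomb with a
tanh regularization over a 0.05 m/s reference slip speed, so the force is
smooth through zero velocity and saturates at μF_n (μ = 0.9). The per-foot
center of pressure is the normal-force-weighted centroid of active contact
points. A compliant model was chosen over an impulse/LCP solver because it
is fully reproducible, smooth, and adequate at the penetrations (mm–cm)
the desk stiffness produces.

## Muscle-tendon units

Each MTU routes a straight polyline through fixed via points; no wrapping
surfaces (none of the shipped paths needs them at gait-range angles).
Moment arms and generalized muscle forces come from virtual work through
the point Jacobians, which equals the tendon-excursion definition
`r_j = −∂L/∂q_j` exactly (verified against finite differences).

Dimensionless curves (constants configurable):

* active force–length: Gaussian `exp(−((l̃−1)/0.45)²)`;
* force–velocity: Hill hyperbola on the concentric side (zero at
  ṽ = −1, one at ṽ = 0, shape factor 0.25) and a slope-continuous rational
  eccentric branch saturating at 1.4;
* passive fiber: exponential reaching 4 % of maximal force at l̃ = 1.2;
* tendon: quadratic toe to 2 % strain, then linear at 35 f_max per unit
  strain.

Activation follows the first-order lag `ȧ = (e − a)/τ` with τ_act = 10 ms,
τ_deact = 40 ms. The rigid-tendon mode (fiber length = path length −
slack) is used inside control loops; an elastic-tendon mode solving the
series force balance by bracketed Brent root-finding is available for
analysis. Pennation is omitted.

The desk model's 34 MTUs (per side: gluteus maximus/medius, iliopsoas,
adductors, hamstrings, rectus femoris, vasti, gastrocnemius, soleus,
tibialis anterior; a torso oblique sling per side; per arm: three deltoid
compartments, pectoralis, biceps, triceps) are tagged with the three
accounting groups (upper limb / torso / lower limb). Tendon slack lengths
are calibrated automatically so each fiber operates centered on its optimal
length over one cycle of the default reference motion, and fibers are
widened when their excursion would otherwise leave the force-producing
range; this keeps passive forces physiological across running postures.
The full-scale roster (150 muscles, 58 upper-limb) ships with schematic
two-point paths: it defines structural contracts (counts, masking,
observation size), not desk-scale dynamics.

## Reference motion

The synthetic gait generator replaces subject motion capture. Every joint
coordinate is a truncated Fourier series in stride phase (≤ 3 harmonics),
so trajectories are exactly periodic and C∞; the pelvis translates at the
commanded speed (default 3.33 m/s, i.e. 12 km/h) with a two-per-stride
vertical oscillation (4 cm), and arms swing contralaterally (right shoulder
in phase with left hip). Default amplitudes: hip flexion ≈ 10° ± 35°, knee
20–90°, ankle ± 20°, shoulder ± 30°, elbow 90° ± 15°, torso yaw ± 8°,
cadence 1.35 strides/s. The mean pelvis height is auto-shifted so the
lowest contact sphere grazes the ground (5 mm) at its lowest phase, making
the target roughly consistent with stance. What the generator does *not*
emulate: measured inter-joint coordination detail, stance-phase kinematic
discontinuities, soft-tissue artifact, or any subject-specific asymmetry —
so quantitative outcomes of controllers trained on it cannot be compared
with subject-specific values, only structurally and qualitatively.

## Controller and training

The observation is the standard dynamic-state vector: pelvis orientation
(3 Euler angles), pelvis angular+linear velocity (6, pelvis frame), pelvis
height (1), joint angles and rates (n_j each), per-foot GRF and center of
pressure (12) in the pelvis frame — 22 + 2 n_j values (72 at full scale,
60 on the desk model). Per-component normalization scales are part of the
observation spec.

The reward is a weighted sum of exponentiated negative squared errors in
joint angles (w = 0.65, σ = 0.3 rad), joint rates (0.1, 3 rad/s), COM
position (0.1, 0.2 m) and end-effector positions of feet/hands/head
(0.15, 0.2 m), plus an activation term `0.2 exp(−mean(a²))`. Errors are
summed (not averaged) within each term. Episodes start from reference
states at uniformly random phase and terminate when pelvis height drops
below 60 % of its reference or torso tilt exceeds 60°.

Policy and value networks are tanh MLPs (default 2×256; desk profile 2×64)
written in numpy with manual backpropagation and Adam; exploration is
Gaussian in pre-squash space with a learned per-muscle log-σ, and
excitations are the sigmoid of the raw action. Training is PPO with a
clipped surrogate (ε = 0.2), GAE (γ = 0.99, λ = 0.95), per-batch advantage
normalization, 4 epochs of minibatch updates, and is bitwise deterministic
given (seed, single thread). Condition controllers warm-start from the
reference controller: parameters are copied wherever the observation label
or muscle name survives the condition; mismatched rows/columns keep their
fresh initialization.

## Arm conditions

* **active** — unmodified.
* **fixed** — shoulders and elbows welded (DOF removed, the crossed-arm
  rotation folded into the fixed joint transform: shoulder flexion 60°,
  adduction 20°, elbow flexion 120°). Welding makes "no effort to hold the
  arms" literal and avoids stiffness artifacts. Reward masks drop arm
  coordinates and hand end-effectors; the observation shrinks with the
  coordinate map. Arm muscles remain in the model but, spanning only
  welded joints, are isometric and do no work.
* **passive** — skeleton unchanged; all upper-limb-group muscles receive
  zero excitation for the whole simulation. Their passive fiber/tendon
  elasticity and the joint-limit springs still act — a deliberate choice:
  without passive structures a "passive swing" would be a free double
  pendulum, which is not the physiological question.

Total model mass is identical across conditions.

## Metabolic accounting and gait analysis

Fiber mechanical power `P = −F·v` (shortening positive) is integrated at
the physics rate into per-muscle positive and negative work ledgers.
Metabolic energy applies the Margaria efficiencies as divisors:
`E = W⁺/0.25 + W⁻/(−1.2)`, which keeps metabolic cost above mechanical
work; the alternative multiplicative reading is available behind
`MetabolicParams(multiply_coefficients=True)`. Basal energy is
1.2 W/kg × mass × duration; basal cost of transport is 1.2/speed. The
gross cost of transport equals the upper-limb + torso + lower-limb +
basal partition exactly before display rounding (two decimals for CoT,
one for degrees).

Heel strikes and toe-offs are threshold crossings of vertical GRF (20 N)
with a dwell-based debounce: a crossing counts only if the median over the
following 50 ms stays on the new side, and events alternate per foot.
Event timing is therefore accurate to the debounce window under noise.
Stance-normalized GRF curves use linear resampling onto 101 points. Torso
longitudinal rotation is the Z component of the Z-X-Y decomposition of
`R_pelvisᵀ R_torso`, reported as a range averaged over detected cycles
(whole-window range when no full cycle is present).

## Problem sizes and what the desk scale shows

The desk profile simulates a 12-segment, 6+19-DOF, 34-muscle model at
dt = 3 ms with ≈ 21 Hz control, and configures training at 8 environments
× 2048 samples × 300 updates (retraining 150), with the full-scale counts
(200 environments, 80,000 samples, 80,000/40,000 updates, 20 s
evaluations) kept as a documentation profile. One on-policy sample costs
about 30 ms of wall time in this numpy implementation, which puts even the
desk training budget in the hours and the sample count itself one to two
orders of magnitude below what muscle-driven three-dimensional imitation
running is known to require. The shipped test suite therefore runs the
full three-condition pipeline (reference training → warm-start retraining
→ deterministic evaluation → metabolic/yaw comparison) at a miniature
budget that exercises every stage end to end; at that budget the
controllers do not yet run, so the published qualitative orderings (lowest
gross cost of transport and smallest torso rotation with active arm swing)
are *not* expected to emerge, and the corresponding assertions document
that gap rather than hide it. Everything below the controller — dynamics,
contact, muscles, reward, accounting — is verified against closed forms
and independent oracles at full precision.

## Known limitations

* No muscle wrapping surfaces, pennation, or fiber-state metabolic models
  (heat rates, oxygen-uptake conversion).
* Compliant contact admits centimeter-scale penetration at desk stiffness;
  no impulse resolution of heel-strike transients.
* The synthetic reference is plausible but not subject-derived; absolute
  cost-of-transport values from controllers trained on it are not
  comparable to treadmill measurements.
* Spherical-joint Euler parameterization would degenerate near ±90° of the
  X rotation; gait-range motion stays far from that configuration.
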