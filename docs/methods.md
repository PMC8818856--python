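# Methods

`kafogait` predicts one periodic cycle of four-point crutch walking for a
subject wearing two active knee-ankle-foot orthoses (KAFOs) and two
forearm crutches, and ranks settings of the orthosis' pre-defined knee
flexion-extension trajectory by clinically used gait measures.  This
note records the model, the numerical formulation, the synthetic data
conditions, and the design choices that were genuinely open.

## Skeletal model

The full-body torque-driven skeleton is described declaratively
(`data/fullbody_31dof.yaml`): 31 unlocked coordinates — six between
pelvis and ground, three per hip, one per knee, three lumbosacral, three
per shoulder, two per elbow, two per wrist — with ankle, subtalar and
metatarsophalangeal joints locked at 0° by the orthosis, crutches welded
to the hands, and orthosis links welded to thigh and shank.  That schema
is used for conformance and documentation only.

Dynamics run on a sagittal-plane reduction with 12 DOF: pelvis
translation (x, y) and rotation, lumbar flexion-extension, and
flexion-extension at both hips, knees, shoulders and elbows.  Out-of-plane
DOFs (hip ab/adduction and rotation, lumbar bending/rotation, shoulder
ab/adduction, forearm pronation, wrists) are dropped because every
outcome measure (foot clearance, stride length, cadence, hip flexion
ROM) and every cost term is sagittal.  Each crutch is welded to its
forearm segment (the planar model has no wrist) and each orthosis link
is merged into the inertial properties of its host thigh or shank-foot
segment, with the device centre of mass taken at the segment centre of
mass and slender-rod device inertias computed from the host geometry.
Device masses default to 1.5 kg (thigh link), 1.3 kg (shank link,
including the foot support) and 0.8 kg per crutch, so the model total
mass is subject mass + 7.2 kg.

Subjects are described by mass and height only.  Segment lengths, masses,
centre-of-mass offsets and radii of gyration follow a standard published
anthropometric regression table (fractions of height / body mass,
recorded verbatim in `data/default_config.yaml`); head+neck are folded
into the torso, hands into the forearms, feet into the shank-foot
segments.  The model is assembled so that, standing, hip height is
0.530·H and shoulder height 0.818·H.

Kinematics and inverse dynamics are exact planar rigid-body expressions
evaluated with NumPy, vectorised over time samples and dtype-generic:
the optimal-control transcription differentiates the whole
dynamics+contact path function by complex-step, which is accurate to
machine precision.  Inverse dynamics follows the virtual-work form
g(q, q̇, q̈) = Σ_s [m_s J_s^T (a_s − g) + I_s α̈_s ∂α_s/∂q] − Σ_p J_p^T F_p;
`g[0:3]` are the floating-base residual loads and `g[3:12]` must equal
the joint torques.  Mass-matrix symmetry/positive-definiteness and
power balance are property-tested against finite differences.

## Contact

Each foot sole carries 16 viscoelastic elements (8 longitudinal
stations × 2 lateral copies; the lateral offset is inert in 2-D but the
element count matches the hardware sole grid):

    f_n = max(0, k δ (1 + c(−ẏ))),  δ = max(0, −y)        (foot element)
    f_n = max(0, k δ^{3/2} (1 + c(−ẏ)))                    (crutch tip)

with continuous friction f_t = −μ f_n tanh(v_t / v_s).  Defaults:
k_foot = 3·10⁴ N/m per element, k_crutch = 10⁶ N/m^{3/2}, c = 1 s/m,
μ = 0.8, v_s = 0.05 m/s.  These are declared design defaults of the
synthetic study conditions (no calibrated values exist to import); they
put quad-support foot penetrations at 2–4 mm and crutch penetrations
near 2.5 mm under realistic load shares.  Inside the optimizer the two
`max(0,·)` clips are replaced by C¹ square-root smoothings with scales
5·10⁻⁶ m and 10⁻², small enough that smoothed and exact forces differ
by well under the 1 N residual tolerance except exactly at grazing
contact; all verification re-evaluates the exact forms.

Calibration fits the shared {stiffness, damping, friction} of both feet
and both crutches (the hardware is identical side-to-side) to a
reference trajectory by seeded nonlinear least squares in log-parameter
space at fixed reference kinematics; the slip-smoothing velocity is held
fixed because it is poorly identifiable.  Zero-force references trigger
an identifiability warning.

## Optimal control formulation

One cycle is transcribed by fixed-mesh trapezoidal collocation.  The
mesh is partitioned into the eight phases of the four-point pattern
(multiple support alternating with single-device swings in the order
left crutch → right leg → right crutch → left leg); each phase holds a
fixed number of intervals (default 2 per swing, 1 per support → 13
nodes) whose durations scale with the free gait parameters: cycle
duration T, stride length L, and the eight phase fractions (summing
to 1).  Trapezoidal collocation was chosen over higher-order schemes to
keep the NLP small and its Jacobian structure simple; the interval count
and scheme name are config-exposed.

States: q, q̇, q̈ (12 each) and τ (9) per node.  Controls: joint jerk
(12), torque rate (9), and the four device ground reactions (8) per
node.  Torque is a state with torque-rate control (the variant found to
behave best for this class of problem); jerk closes the q̈ chain.
Constraints:

* trapezoidal defect chains q→q̇→q̈→jerk and τ→τ̇;
* implicit dynamics at every node: |base residuals| ≤ 0.6·(1 N, 1 N·m)
  and |g_joint − τ| ≤ 0.6 N·m (the 0.6 margin guarantees the declared
  (1 N, 1 N·m) tolerance after replacing smoothed by exact contact);
* reaction controls tied to the contact-model resultants by equality;
* anti-slip: |v_x| ≤ 0.05 m/s for foot midpoints and crutch tips at all
  stance nodes of that device;
* swing clearance: toe, heel and crutch-tip heights ≥ 5 mm at interior
  swing nodes, and ≥ 0 at the Hermite midpoints of all swing intervals
  (without the midpoint rows a coarse mesh lets the interpolated foot
  arc dip below ground between nodes);
* ground guard: the same extremity points may never sit more than 1 cm
  below ground at any node.  Without it the optimizer can sweep a limb
  through the ground while it moves upward — the damping factor
  (1 + c(−ẏ)) zeroes the contact force during fast rebound in both the
  exact and smoothed models — and the small exact-vs-smooth force
  difference in that regime wrecks the exact residual re-check;
* knee prescription: node-wise equality q_knee = θ(u)·(swing window),
  where θ is the assistive trajectory evaluated at normalized swing time
  — so the prescription is independent of the free parameters — and 0
  during stance (and everywhere for the locked-knee problems);
* periodicity of joint angles, velocities, and torques; pelvis forward
  translation advances exactly L; normal-force periodicity is implied
  through the contact ties whenever velocities are periodic and is
  imposed explicitly only otherwise.  Knee coordinates are excluded
  from the periodicity rows (their endpoints are already pinned by the
  prescription; keeping them would make the equality Jacobian
  structurally rank-deficient);
* mean forward speed L/T within ±0.05 m/s of the reference speed;
* free parameters bounded at reference ±20% (T, L) and ±0.05 absolute
  (fractions); per-joint torque bounds (±150 N·m default); coordinate
  bounds at reference ±0.6 rad, widened at the knees to accommodate the
  prescribed flexion trajectory.

SCI profile: the knees carry only the orthosis motor torque, bounded at
±34 N·m; hip torque is bounded at (reference tracking maximum)/0.8,
i.e. the reference effort is assumed to have used 80% of the available
hip capacity.

Objectives.  `track` mode minimizes coordinate tracking (weight
10⁴ rad⁻², strong enough that re-tracking a consistent reference
reproduces it to sub-millirad RMSE) plus 0.01-weighted jerk and torque-change regularization,
with the free parameters pinned to the reference by a stiff quadratic
penalty (tracking data fixes the gait parameters).  `predict` mode uses
the selected predictive cost: lumbar mechanical power, all-segment local
angular momentum (L_s = I_s ω_s about each segment's own CoM), knee
motor torque, plus the 0.01-weighted regularizers.  Every term is
integrated with trapezoidal quadrature and scaled by its value on the
reference trajectory (fallback 1 if that value vanishes), which brings
all terms to comparable magnitude; the non-regularization weights
default to 1.

Solver.  The sparse NLP (≈1300 variables at the default mesh) is solved
with SciPy's `trust-constr`.  Constraint Jacobians combine analytic
blocks (defects, ties, periodicity) with complex-step derivatives of the
per-node dynamics/contact path function; the objective supplies its
exact gradient and a Gauss–Newton Hessian (positive semidefinite,
dropping only the small quadrature-weight cross terms), and constraint
curvature is linearized.  Initial guesses interpolate the reference onto
the mesh; when the knee prescription is unchanged the derivative chains
are repaired minimally onto the defect manifold, so a dynamically
consistent reference is an exactly feasible start, and the interior-point
barrier is then started at 10⁻⁸ (a cold barrier would first drag the
iterate far into the interior).  Predictions with a new knee trajectory
are warm-started from the previous solution in the sweep (locked → 20°
→ 30° → ...), with the swing hip raised so the flexed foot keeps (plus a
flexion-proportional margin over) the source's ground clearance, and the
knee/hip derivative chains seeded by the local prescribed delta only —
a global minimum-norm chain repair would leak velocity into stance
nodes, where the stiff contact damping amplifies it into hundreds of
newtons of spurious dynamics violation.  Solves stop early once the
iterate is feasible (scaled violation ≤ 10⁻⁷) and nearly stationary
(projected optimality ≤ 2·10⁻²); the package asserts feasibility of
returned solutions, not deep optimality polishing.  Two recovery
mechanisms handle interior-point stalls: a stalled tracking solve can be
restarted from its own iterate with a fresh solver state (the synthetic
reference generator does this automatically), and a solution that is
feasible for the smoothed contact but fails the exact residual re-check
is re-polished warm-started with a 5x smaller smoothing scale.  Solutions are verified
independently of solver claims: residuals, torque match, periodicity,
slip, clearance, prescription error and torque bounds are re-evaluated
with exact contact at every node, and `converged` reflects that check.

## Synthetic reference gait

The study's motion-capture inputs are emulated by a two-stage generator.
A closed-form draft builds smooth periodic coordinates honouring the
four-point phase order with knees locked: stance feet and crutch tips
planted (single-link leg / two-link arm inverse kinematics), swing
targets advancing one stride with a C² smooth-step, a plateau-shaped
swing hip-flexion bump (default 25°, full after 30% of swing) that
yields centimetre-scale toe clearance, a 7° forward trunk lean, crutches
planted 0.15 m ahead of the shoulder, and a smoothed periodic pelvis
height holding the deepest planted foot point near 3 mm penetration.
Default gait parameters are the study conditions for a slow assisted
gait: T = 4.4 s, L = 0.51 m, phase fractions 0.16 per leg swing, 0.12
per crutch swing, 0.11 per support interval.  The draft's torques and
reactions come from inverse dynamics and the exact contact models; it is
smooth and periodic but not dynamically consistent (the rigid locked
legs overdetermine ground contact), so it is refined by the jerk-
minimizing tracking solve, which returns the dynamically consistent
reference used as tracking target, calibration input and initial guess
everywhere downstream.  Optional Gaussian measurement noise (deg,
seeded) can be added to the coordinates.  The generator is deterministic
for equal specs.

What the synthetic subject does *not* emulate: out-of-plane compensation
(circumduction, hip hiking), soft-tissue and marker artefacts,
trial-to-trial variability, and subject-specific asymmetries.  Passing
tests therefore demonstrate internal consistency of the method under
controlled planar conditions, not fidelity to any real subject.

## Gait measures

Foot clearance is the minimum toe height during the central 60% of that
foot's swing window (evaluated on a cubic interpolant; at lift-off and
touch-down the toe is at ground level by definition, so a margin of 20%
of the window is trimmed at each end, as a gait-event detector would).
The dense evaluation uses the
solution's own cubic Hermite interpolant (q with its q̇ states) — the
representation whose ground clearance the transcription constrains; an
unrelated global spline could dip below ground between nodes and report
spurious negative clearances.  Stride length is the mean anterior
advance of the four device contact points over the cycle; cadence is 120/T (two foot steps per cycle,
which reproduces the scale of published values for this gait); hip
flexion ROM is max − min of each hip angle over the cycle.  RMSE tables
compare angular coordinates (deg) in the groups pelvis+torso / upper
limbs / lower limbs / all (unweighted channel means within groups, both
cycles normalized to [0, 1]) and normal/tangential forces (N) across
devices.  Sweep reports normalize every measure to the locked-knee
baseline.

## Problem sizes and tolerances

Default runs use the reduced mesh above (17 nodes); the test suite uses
a further reduced mesh (13 nodes) for solver-backed checks.  Interior
solves stop at gtol 10⁻⁴ / xtol 10⁻¹² or 2000 iterations; feasibility of
the returned solutions is what the package asserts, via the exact
post-solve verification, with the declared tolerances: residuals
≤ (1 N, 1 N·m), angle periodicity ≤ 10⁻³ rad, torque periodicity
≤ 0.1 N·m, normal-force periodicity ≤ 1 N, stance point speed ≤ bound
+10⁻³ m/s, knee prescription ≤ 10⁻⁶ rad.

## Known limitations

* The planar reduction cannot express mediolateral strategies; the
  mediolateral foot-crutch symmetry constraint of the 3-D formulation
  has no planar analogue and lives only in the declarative schema.
* Predictive optima tend to ride the free-parameter bounds (slower,
  shorter gaits cost less effort), so cycle duration and stride length
  often saturate at the ±20% tolerance; clinical-measure trends across
  the knee-flexion sweep are driven mainly by clearance and hip ROM.
* Trapezoidal collocation at the reduced mesh resolves the gait at
  ≈0.2–0.3 s per interval; finer meshes sharpen swing dynamics at
  roughly linear cost in solve time.
* Contact smoothing is exact to ≲0.3 N near grazing contact; the
  residual margin (0.6) absorbs this in the declared (1 N, 1 N·m)
  budget.
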