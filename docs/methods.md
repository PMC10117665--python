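# Methods

`droptrap` models how a zebrafish larva is hydrodynamically trapped inside a
small vibrated droplet and how its body angle in that trap quantifies
mobility. This note records the models, the parameter choices, the numerics,
and what the synthetic benchmarks do and do not demonstrate.

## Flow fields

A sessile droplet on a vibrating substrate develops steady internal
recirculation; depending on drive frequency the pattern has one, two or four
closed cells. The vibration physics itself is *not* modelled — frequency
bands (22–35 / 36–47 / 48–53 Hz for one / two / four cells) are carried as
metadata only. The fields are the lowest-order streamfunction modes in a
disk of radius R that satisfy no-penetration on the rim and have the target
cell topology, with velocities (u, v) = (∂ψ/∂y, −∂ψ/∂x) so incompressibility
is exact:

| pattern | ψ | notes |
|---|---|---|
| `pure_strain` | ε̇xy | (u,v) = (ε̇x, −ε̇y); the analytic trap model |
| `one_cell` | (ε̇/2)(R² − r²) | solid rotation, single-signed vorticity |
| `two_cell` | ε̇Ry(1 − r²/R²) | two counter-rotating cells; through-flow u(0,0)=ε̇R between them |
| `four_cell_bounded` | ε̇xy(1 − r²/R²) | reduces exactly to `pure_strain` as r/R → 0 |

The one-cell mode deserves a remark: any axisymmetric cell whose tangential
velocity vanishes at both the centre and the rim necessarily has
sign-changing vorticity (∫(rψ′)′dr = 0), i.e. a hidden counter-rotating
annulus. A clean single cell therefore requires tangential slip at the rim,
which is physical at a free droplet surface; the solid-rotation profile is
the minimal such mode and gives the classifier an unambiguous single
streamfunction extremum.

Sign convention: ε̇ > 0 puts outflow on the x axis (the "source" axis) and
inflow on the y axis (the "sink-feeding"/upstream axis). Angles are degrees
counterclockwise from +x at all interfaces, radians internally; positions
are metres. The strain-rate magnitude inside a real droplet is not known
from first principles, so ε̇ is a free parameter with default 1 s⁻¹; every
angular result below depends only on ratios (A/ε̇, Dr/ε̇), not on ε̇ itself.

### Pattern classification

`classify_pattern` counts recirculation cells on a sampled grid: the
streamfunction is reconstructed by trapezoidal path integration (−v along
the row through the droplet centre, then u along each column — paths that
start on the first grid row pick up O(h) bias where they cross the rim),
smoothed with a Gaussian of σ = 1 grid cell, and its extremal plateaus are
counted. Only nodes whose full 3×3 neighbourhood lies inside the mask are
candidates (this excludes the spurious rim minima every monotone radial
field otherwise produces), ties are clustered by 8-connectivity so a
plateau counts once, and counts {1, 2, 4} map to the named labels, anything
else to `random`. A field whose maximum speed is below 1e−12 is degenerate:
`("random", 0)`.

## Slender-body torque and equilibria

The larva is a rigid rod (length L, cross-section radius a) in Stokes flow.
Resistive-force theory gives per-unit-length drag coefficients
c∥ = 4πμ/c and c⊥ = 8πμ/c with the correction c = 2 ln(L/a) − 1; geometry
with L/a < e is rejected (c would drop below 1, outside the slender regime
as adopted here). Defaults L = 4 mm, a = 0.25 mm describe a ~72 hpf larva.

With the rod pivoted at the stagnation point and spanning arc length
s ∈ [0, L], the net viscous torque from the circumferential relative flow
u′_θ = u_θ − θ̇s is

    T(θ) = ∫₀ᴸ s · c⊥ · u′_θ(s) ds = −(8πμε̇/c)(L³/3) sin 2θ.

The [0, L] domain is deliberate: it is what produces the L³/3 prefactor (a
centre pivot would give L³/12); the sin 2θ structure, the zero set and the
stabilities are unaffected by that choice. The quadrature
(`torque_numeric`, 64-point Gauss–Legendre, exact for polynomial fields)
doubles as the independent oracle for the closed form and works on any
bounded field the rod fits inside.

Zeros in (0°, 180°], found by sign-change bracketing + Brent refinement:
90° with positive torque slope (a perturbation grows — unstable) and 180°
with negative slope (stable). Angles are reported modulo the rod's
head–tail symmetry; which of 90°/270° a fish actually faces is a question
for the behaviour/statistics layers, not mechanics.

## Swimmer dynamics

Dividing T by the rotational drag ζ = c⊥L³/3 cancels all material constants
and leaves the passive law θ̇ = −ε̇ sin 2θ. Active rheotaxis is the minimal
smooth self-righting drive toward a goal heading g (default 90°):

    θ̇ = −ε̇ sin 2θ + A sin(g − θ),     dθ ← θ̇ dt + √(2 Dr dt) ξ.

- A = 0 recovers the passive (anesthetized) model exactly.
- Linearizing at θ = g gives decay rate A − 2ε̇, so A_crit = 2ε̇.
- For 0 < A < 2ε̇ the stable headings sit at arcsin(A/2ε̇) and its mirror —
  they migrate continuously from the sink axis to the source axis as A
  grows, which is exactly why the angle works as a graded mobility score.

Noise is orientational only (the droplet supplies translational trapping);
Dr defaults to 0.05 rad²/s, chosen so that a type-I fish (A = 5ε̇,
linear relaxation rate 3 s⁻¹) fluctuates with sd √(Dr/(A−2ε̇)) ≈ 7.4°, i.e.
a ≈ ±2σ band of 80–100°, and a passive fish (rate 2ε̇) sits at ~0±10°.
Euler–Maruyama is explicit, so `simulate` rejects dt·(|ε̇| + A) > 0.2 rad;
trajectories are bitwise reproducible for a given seed.

`estimate_activity` regresses the wrapped finite-difference θ̇ on the drift
regressors [−sin 2θ, sin(g − θ)], with the strain coefficient fixed at the
known ε̇ by default (co-estimation is available but ill-conditioned near
fixed points, where the two regressors are first-order collinear). Because
data are generated by the same discrete update, the regression is exactly
consistent at the simulation step. The reported estimate is clipped at zero
(activity is a rate); the raw coefficient is also returned since only it is
unbiased around A = 0. `measure_critical_activity` brackets the bifurcation
by bisection on noiseless runs from θ₀ = 91° (supercritical swimmers relax
back to 90°, subcritical ones slide to the migrated equilibrium).

## Synthetic data as study conditions

`CohortSpec` defaults encode the study design: 5 fish per class, ε̇ = 1 s⁻¹,
Dr = 0.05 rad²/s, 5-minute observations sampled via a 0.01 s integrator
step (finer than the 20 fps video interval so the explicit step resolves
the fastest drift), uniform random initial headings, per-fish seeds spawned
deterministically from the cohort seed.

- type_i (untreated): A = 5ε̇, comfortably supercritical.
- type_ii (anesthetized): A = 0.
- type_iii (recovering): A ramps linearly 0 → 5ε̇ over 20 simulated
  minutes; the ramp shape is a modelling choice (only "gradual recovery" is
  constrained). The fish tracks the migrating equilibrium, so its folded
  angle sweeps 0° → 90° continuously, crossing A_crit 40% into the ramp.
- lipin1 (motor-neuron deficient): parameterized identically to type_ii —
  no recovery — but kept as a distinct label in reports.

`SceneSpec` emulates the imaging: a 12 mm droplet, 20 µm/px, 30 fps tracer
video (20 fps for fish), tracers rendered as Gaussian spots (σ = 1.5 px,
SNR = amplitude/noise-σ = 50 at defaults) advected by RK2 steps along the
analytic field, the fish as an oriented ellipse whose head half is brighter.
An optional minimum initial tracer separation (off by default) exists for
round-trip benchmarks that are defined for well-separated tracks, since
uniform seeding can place two tracers inside one PSF. `generate_pool_walk`
produces the no-flow random-walk reference for MSD work, optionally with a
reflecting circular wall.

What these generators do *not* emulate: burst-and-coast kinematics,
dwell/freeze intermittency, inter-fish variability of A, translational
motion of the trapped fish, occlusions, uneven illumination, or droplet
shape dynamics. Benchmarks passing on this data show the pipeline is
correct and well-calibrated under the model's own assumptions — not that
the behavioural model captures everything real larvae do.

## Tracking

The video pipeline fixes concrete algorithms where the experimental
workflow used interactive tools: relative global threshold (at a fraction
of the frame maximum, hence intensity-scale invariant) → 8-connected
components ≥ min_area → intensity-weighted centroids; orientation from
second central image moments (modulo 180°, with an optional brightness-skew
head resolution using the sign of the third moment along the principal
axis); frame-to-frame linking by optimal bipartite assignment on
displacement with a hard gate max_disp and no gap closing (a missed frame
splits the track); deterministic tie-breaks via within-frame sorting.
Velocimetry is per-track binning of step velocities (PTV) rather than
correlation PIV — adequate at synthetic seeding densities and directly
testable against ground truth. Pixel convention: origin top-left, y down;
conversion to physical units flips y so angles match the flow convention.
Threshold/linking defaults (0.5 relative threshold used for fish, 0.3 for
dim tracers; max_disp 10 px) are tuned on synthetic fixtures only.

## Mobility statistics

Heading summaries use circular statistics (vector-mean direction and
resultant length R ∈ [0, 1]); an antipodally balanced series has an
undefined mean and is flagged rather than guessed. Deviations fold the
head–tail and left–right symmetries: source deviation is the distance to
the nearest of {90°, 270°}, sink deviation to {0°, 180°}; the two sum to
90° for every heading, and the "folded source angle" 90° − source-deviation
is the 0-to-90 mobility scale used for recovery trends.

Classification windows mirror the observed bands and are configurable:
intact if source deviation ≤ 10° with R ≥ 0.9; disrupted if sink deviation
≤ 20° with R ≥ 0.9; recovering if source deviation ≤ 40° with R ≥ 0.5;
otherwise indeterminate (rules applied in that order).

The chance-alignment probability generalizes the printed single instance to
p = (w/360)ⁿ · (360/w): partition the circle into 360/w windows, require
all n fish in one of them, union-bound over windows, cap at 1. For
(n, w) = (5, 30°) this is 12⁻⁴ ≈ 4.82×10⁻⁵. The cohort pipeline reports it
when the per-fish means fit inside a single 30° arc (the "narrow region"
observation); the Monte-Carlo calibration uses the fixed 12-bin partition
that the combinatorial factor presumes. MSD is the standard time-averaged
⟨|r(t+τ) − r(t)|²⟩ over all overlapping pairs on uniformly sampled tracks.

## Problem sizes and numerical tolerances

The shipped benchmarks use: 181-point torque grids; 64-node classification
grids; 20-second noiseless relaxations at dt = 5 ms; bisection to 0.5%
bracket width for A_crit; 20 seeds × 2000 steps per activity level for
estimator recovery; 40-tracer (round-trip) and 300-tracer (PTV) scenes at
40 µm/px; 100-seed random walks for MSD; 10⁶ cohorts for the alignment
calibration; and the default 5+5+5 cohort with 2-minute bins for recovery
trends. These sizes make the whole analysis run in seconds on one core
while leaving every tolerance comfortably met; all are plain parameters.

## Known limitations

- Orientation-only trapping: no translational force balance, settling, or
  wall contact; bending-induced migration in the one-cell flow is outside
  the rigid-rod model.
- The activity term is phenomenological; it is the minimal one-parameter
  drive consistent with passive mechanics at A = 0, not a fitted behaviour
  model, and dwell/intermittency statistics are not simulated.
- `classify_pattern` assumes a mostly filled grid; sparse PTV grids must be
  interpolated to the droplet disk first (`fill_grid_to_disk`).
- The alignment p-value is a union bound tied to a window that divides
  360°; it is not a general-purpose uniformity test.
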