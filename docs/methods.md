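# Methods

`paleogait` couples two pipelines that meet on a common pair of axes —
track phase versus dimensionless speed: (1) a predictive simulation that
finds energetically optimal symmetric gaits of a planar quadruped by
trajectory optimization, and (2) an ichnometric pipeline that reduces
digitized fossil trackways to the same gait parameters.  This note records
the model, its assumptions, the numerical scheme, and the choices made
where the design was genuinely open.

## The planar locomotor model

The trunk is a single rigid body of mass `M` and pitch moment of inertia
`I` about its centre of mass (COM).  The COM lies on the glenoacetabular
axis; the hip (acetabulum) sits a distance `MF'·LB` caudal of the COM and
the shoulder (glenoid) `(1−MF')·LB` cranial of it, where `LB` is the
glenoacetabular distance and `MF'` the "COM forelimb bias" (the static
fraction of weight borne by the forelimbs).  Four massless, axial legs
connect fixed ground points (the footfalls, decision parameters) to their
girdle joints; leg force acts along the foot-to-joint axis and appears
instantaneously as ground reaction force (point feet, infinite friction,
no leg inertia, no elastic elements).  Legs can only push (`F ≥ 0`), and a
leg may transmit force only while its length does not exceed its
anatomical standing length (`LH` hind, `LF` fore), imposed as relaxed
complementarity `F·(L − L_max) ≤ ε`.

States are the six trunk kinematic states plus the four limb forces;
controls are the four force *rates*, so force and velocity are continuous
and impulsive collisions are excluded by construction.  The objective over
a stride of period `T` is

    J = Σ_i ∫₀ᵀ |F_i · L̇_i| + c · Ḟ_i² dt ,

axial limb work plus a force-rate penalty.  Minimizing signed work would
be degenerate (negative work would subsidize positive work), so positive
and negative work are charged equally; inside the solver the absolute
value is smoothed as `sqrt(P² + δ²) − δ` with `δ = 10⁻³` in body-weight ×
hip-height units, while all reported work/cost-of-transport values use the
exact positive/negative split on the returned trajectory.  The penalty
coefficient is quoted as the dimensionless `c' = c·M·g/(LB·T)` at the
reference speed `U_H' = 0.4` and the underlying dimensional `c` is held
fixed across speeds, so faster tasks see an effectively smaller penalty in
proportion to their shorter period.

Tasks are posed nondimensionally: speeds as `U_H' = U/√(g·H)` and strides
as `D_H' = D/H`, with the hip height convention `H := LH` (the standing
pes-to-acetabulum length, the only hip-to-ground length available for both
bodies).  By default stride length is paired to speed through the dynamic
similarity relation `U_H' = 0.25·D_H'^1.67` (inverted for `D_H'`), the
same relation used to estimate trackway speeds.  Internally the solver
works in units of hip height, body mass and `√(H/g)`; `g = 9.81 m/s²` is a
configurable constant.

## Transcription and solution

One *half* stride is transcribed (symmetric gaits repeat with left/right
roles swapped every `T/2`) with compressed Hermite–Simpson collocation on
a fixed mesh.  Constraints: collocation defects; COM `x(0) = 0`,
`x(T/2) = D/2`; periodicity of `z, θ, ẋ, ż, θ̇`; left-limb forces and
force rates at `t = 0` equal to right-limb values at `t = T/2`; pitch
`θ ∈ [−π/2, π/2]`; hip and glenoid heights ≥ 0; `F ∈ [0, 20·Mg]`;
complementarity `F·(L − L_max) ≤ ε` with `ε = 10⁻³ Mg·H`.

Unfolding the half cycle to a full stride relocates each limb's foothold
between half cycles.  A limb loaded across a half-cycle boundary is
kinematically consistent only if the limb pair's footfalls obey the
symmetric-gait print relation `p_left − p_right = ±D/2`; without this
condition the optimizer discovers unphysical duty-factor-1 "gaits" whose
feet teleport under load (one leg effectively pressing at a cranial and a
caudal point in the same stride — the degeneracy the leg-impulse state in
the model lineage exists to prevent).  The relation is imposed as a hard
linear equality whose sign (which boundary a limb's contact may span) is a
per-start branch chosen from the initial guess, together with zero force
at the opposite boundary.  Per-limb impulse time series are retained in
solutions and multiple disjoint contacts per stride are flagged in the
gait summary.

The NLP is solved with SLSQP using analytic gradients and hand-assembled
Jacobians (verified against central finite differences in the test suite);
an interior-point alternative (`trust-constr`, sparse Jacobians) is kept
as an option but was consistently slower.  A start counts as converged
when the solver reports success and the worst constraint violation is
below `10⁻⁶` in solver units.  Multistart covers the gait space with three
gait-structured guesses (trot `φ_L = 0.5`, lateral sequence `0.25`,
diagonal sequence `0.75`: sin²-bump force profiles scaled so fore/hind
limbs statically carry the `MF'`-split body weight, footfalls under the
girdles at mid-stance) plus random-bump starts with footfalls uniform on
`[−D/2, D]`, one RNG stream per start index.  Speed sweeps additionally
warm-start each task from the previous speed's best solution.  The best
feasible local optimum is kept; per-start logs are part of every result.

Defaults: 24 mesh intervals per half cycle and 12 starts.  The heavy
replication tests run a reduced profile — 16 intervals, 4 starts, coarser
speed grids — sized for a single CPU; mesh adequacy is property-tested
(halving the mesh spacing on a converged task moves `J` by < 1%, measured
0.45% on the dog at `U_H' = 0.5`).  Published-scale runs (40+ intervals,
50 starts, 0.05 speed grids) use the same code through `GaitTask`.

## Gait descriptors

Half-cycle solutions are unfolded to a full stride (limb `i`'s second half
equals its mirror limb's first).  Contact is `F` above a threshold of
`max(10⁻³·Mg, 0.05·peak force of that limb)`; the relative floor is
needed because the complementarity relaxation leaves residual swing forces
that scale with `ε`, not with body weight.  Duty factor is the contact
fraction of the stride; limb phase `φ_L` is the hind-to-fore contact onset
lag over `T`.  A planar model cannot distinguish lateral- from
diagonal-sequence gaits, so `φ_L` is determined modulo 0.5 and reported
inside a configured modulation window ((0, 0.6) for the dog, (0.4, 1) for
*Batrachotomus*), ties resolved toward the window centre.  The predicted
track phase is `mod((p_fore − p_hind)/D, 1)` from the footfalls, sharing
the same ambiguity; the candidate consistent with the chosen `φ_L` under
the analytic relation `Φ_T = mod(φ_L + LBx/D, 1)` is reported, and
agreement of footfall-based and analytic values (within ~0.02) is used as
a steadiness check rather than being imposed.

Ground-reaction-force profiles within a contact are classified by interior
local maxima (prominence ≥ 5% of peak): two or more humps = vaulting
("double-humped"); one hump = bouncing ("single-humped") unless the peak
sits more than 10% of the contact duration from midstance ("skewed",
asymmetric generative/absorptive bouncing).  Cost of transport is
`J/(M·g·D)`, reported both with and without the penalty term.  Transitions
along a speed sweep are declared when adjacent grid speeds differ in limb
phase by > 0.05 (modulo the 0.5 ambiguity) or change GRF class, and are
located as the bracketing interval's midpoint.

The track-phase-constrained variant fixes `p_fore − p_hind` to a target
(wrap branch per start).  The default target function interpolates the
published trackway (speed, track phase) points piecewise-linearly; any
callable can be substituted.  Because constrained and unconstrained solves
are local optimizations, cost comparisons between them additionally seed
the unconstrained problem with the constrained optimum, so ratios compare
equal search effort.

## Trackway geometry

Footprints are digitized as two landmarks — reference-digit tip and
caudal-most point; the midpoint stands in for the centre of pressure.
Stride vectors join midpoints of successive same-side pes prints (manus
prints substitute when no pes pair survives, flagged in the summary);
manus–pes distance `d` is the projection of the pes-to-manus midpoint
vector on the trackway's mean stride direction, signed (positive = manus
cranial), with an unprojected-norm fallback for trackways lacking an
orthogonal view.  Track phase is `mod(d/D, 1)`, applied at the report
stage only so signed distances survive intermediate arithmetic.  Published
inter-print distances convert to midpoint distances as
`(pes + manus)/2 + IPD`.  Special cases are explicit operations, never
silent corrections: trailing-manus distances (stride minus distance to the
next same-side pes), caudal-point extension for cropped prints (recorded
in the print's notes), and inclusive print-id exclusion ranges that remove
turning segments from stride/phase statistics while keeping them in size
statistics.  Manus–pes pairing picks the nearest caudal same-side pes
within one stride (tolerating ~D/4 of caudal overshoot for noisy prints);
unresolvable manus prints are reported in the summary notes.  Distances
that differ by a whole stride describe the same print geometry (a manus
nearly overstepping the next pes can pair to either pes under noise), so
before averaging, per-pair distances are shifted onto the wrap branch
nearest their circular mean; otherwise mixed branches corrupt the mean at
track phases close to 0/1.

Speed is estimated by scaling the reference body to the trackmaker
(`H = mean pes length · LH/LP`), then applying the dynamic-similarity
relation to `D/H`.  Glenoacetabular distance from slow (quadruple-stance)
trackways uses the trot relation `LBx = d + D/2`; its mutual consistency
with the analytic track-phase relation at `φ_L = 0.5` is enforced as a
property test to machine precision.

## Synthetic trackways

The generator lays down the print pattern of a steady symmetric gait: pes
midpoints every `D` per side, right side offset `D/2` along travel, each
manus `mod(φ_L + LBx/D, 1)·D` cranial to its pes — i.e. the analytic
relation used generatively.  Prints are straight two-landmark segments
aligned with travel (sufficient, since the analysis uses only
tip/caudal/midpoint geometry; an optional in-plane manus rotation mimics
rotated manus prints and is verified not to move midpoints).  Isotropic
Gaussian landmark noise (default SD 1 cm, a typical digitization
uncertainty for decimetre-scale prints) and random print dropout emulate
preservation quality.  Defaults describe a moderate chirotheriid walking
trackway (D = 1.2 m, pes 0.26 m, manus 0.10 m, width 0.3 m, 8 strides).
What the generator does *not* emulate — substrate deformation, print
morphology, overstepping erasure, systematic digitizer bias, trackway
curvature — bounds what recovery tests show: they validate the geometry
pipeline, not robustness to taphonomy.

## Known limitations

- The gait model is planar: no lateral dynamics, yaw, or distinct left/
  right behaviour; asymmetrical gaits (gallop, bound) are out of scope, as
  are leg inertia, elastic tendons, and a compliant torso.
- Local optimization with finitely many starts can misrank close gait
  basins; per-start logs and the warm-chaining options are the mitigation,
  and reported transitions carry their grid brackets rather than point
  estimates.
- The reduced test profile resolves GRF shape classes and phase jumps but
  not fine structure (e.g. brief hindlimb unloading episodes within
  stance) that finer meshes reveal.
- The analytic track-phase relation assumes steady travel at constant
  heading; the rigid-motion invariance of the trackway pipeline does not
  extend to curved trackways, which should be segmented via exclusion
  ranges instead.
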