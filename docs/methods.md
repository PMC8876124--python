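# Methods

## Scope and data model

The package analyses uniaxial compression tests on cylindrical specimens of
mycelium-bound particle composites.  Machine records are displacement u
(mm, monotone non-decreasing) against compressive force F (N) with specimen
geometry (diameter D₀, height L₀, optional top-face slant and post-test
height).  Engineering measures are used throughout the measurement layer:
σ = F/A₀ with A₀ = πD₀²/4 (MPa, stored as magnitudes) and ε = ΔL/L₀,
positive in compression.  The stretch convention λ = 1 − ε is applied in
exactly one place, at the boundary between measured curves and the
constitutive model, which is fully signed (λ < 1, S₃₃ < 0 in compression).

## Curve reduction

* Samples before the force first crosses the 1 N machine pre-load are
  trimmed (`preload=0` disables this).
* Elastic modulus m: ordinary least-squares slope of σ over ε in a window
  whose default is [0.10, 0.10 + elastic recovery].  The 10 % floor skips
  the regime where slanted specimens load unevenly.  The elastic recovery
  is ε_max − (L₀ − h_post)/L₀ from the post-test height h_post; it can be
  interpreted either as a strain *span* placed on top of the floor (the
  default) or as an absolute upper bound (`recovery_is_span=False`).  Both
  are legitimate readings of recovery-based window selection; the span form
  is the default because it always produces a non-empty window whenever
  recovery is positive.  With no post-test measurement, the fallback window
  is [0.10, min(0.30, 0.95 ε_max)].
* Compressive strength σ_st is σ linearly interpolated at ε = 0.20; the
  stress carried at 50 % strain is the same operation at ε = 0.50.  A curve
  ending before the target strain yields an explicit absent value, never 0.
* Negative elastic recovery (post-test height below the minimum height
  reached during the test — physically impossible, occasionally produced by
  measurement error) is clipped to zero with a warning.
* Mean curves: replicates are linearly interpolated (no smoothing — linear
  interpolation is reproducible and order-preserving) onto a uniform strain
  grid capped at the shortest replicate, then averaged pointwise with a
  two-sided Student-t 95 % half-width t₀.₉₇₅(n−1)·s/√n.

## Constitutive model

Compressible Neo-Hookean energy in principal stretches:

    w = c (λ₁² + λ₂² + λ₃² − 3 − 2 ln J) + d (J − 1)²,   J = λ₁λ₂λ₃,

c, d > 0 in MPa.  Uniaxial loading along e₃ with stress-free lateral faces:
setting ∂w/∂λ₁ = 0 at λ₁ = λ₂ gives the quadratic d J² + (c/λ − d) J − c = 0
whose unique positive root defines J(λ), and with ψ = 2λJ the axial second
Piola–Kirchhoff stress has the closed form

    S₃₃(λ) = 2c (1 − 1/λ²) + d (ψ/λ³)(ψ/(2λ) − 1),
    ψ(λ) = λ − c/d + √(4 (c/d) λ² + (λ − c/d)²).

**The sign under the root.**  A widely circulated variant of ψ carries
(λ + c/d)² under the root.  That form violates ψ(1) = 2 and therefore
S₃₃(1) ≠ 0 — a non-zero stress in the undeformed reference state, which is
inconsistent with the S₃₃ expression it accompanies.  Re-deriving ψ from
the lateral stress-free condition produces the minus-sign form above, which
satisfies both identities to machine precision.  The package defaults to
the consistent form; the plus-sign variant is available via
`as_published=True`, and a test demonstrates its identity violation.

Linearization about the identity: shear modulus μ = 2c and first Lamé
parameter 2d, hence E = 2c(2c + 3d)/(c + d) and ν = d/(2(c + d)), strictly
inside (0, ½) for any positive pair.  These are used for fit initialization
and the FEM small-strain check.

**Verification oracle.**  `brute_force_stress` minimizes w(q, q, λ) over
the lateral stretch q by bounded scalar minimization, polishes the
stationary point by bisecting the central-difference energy gradient, and
evaluates S₃₃ = (1/λ) ∂w/∂λ₃ by central differences — a path that never
touches the closed form.  Agreement is better than 10⁻⁸ relative over
λ ∈ [0.5, 0.99] and c/d ∈ [0.01, 100].

**Fitting.**  Bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on log-parameters, which enforces positivity
without constrained-solver edge cases; the start point inverts the measured
secant modulus at ν₀ = ¼ (giving c₀ = d₀ = m/5).  Deterministic — no random
restarts.  Two stress interpretations are offered and recorded in the fit
report: `second_piola` compares |S₃₃| directly with σ = F/A₀ (the
convention in common use for this model even though F/A₀ is nominal
stress), and `nominal` compares |λS₃₃| = |P₃₃|, the mechanically exact
match for force per undeformed area.  Ground-truth recovery tests use
`nominal` because the synthetic generator produces physical forces;
`second_piola` remains the default for conventional fits.  Uniaxial data
identifies d only weakly (the classic ν-from-one-test problem): with 2 %
force noise and 6 replicates, recovered parameters typically land within
2–5 % of truth, with d fluctuating about twice as much as c.

## Synthetic studies

The generator emulates the lab protocol so that every downstream stage has
a testable ground truth:

* Geometry: D₀ ~ U(69, 71) mm, L₀ ~ U(60, 70) mm, top-face slant
  U(0°, 3°) — cylinders moulded in 7 cm tubes at 6–7 cm height.
* Forward model: nominal force F(u) = A₀ |λ S₃₃(λ)| with λ = 1 − ε_eff.
  A soft surface-mycelium layer absorbs displacement before the bulk
  engages: u_toe(u) = t·(1 − e^{−s·u/t}) with depth t = 2 mm and sharpness
  s = 3 by default — the simplest smooth monotone engagement with a
  saturating depth.  ε_eff = max(0, (u − u_toe)/L₀).
* Sampling: uniform 0.1 mm displacement grid (far finer than any analysed
  feature); the test stops at the first sample reaching 1.8 kN or a
  condition-specific displacement limit (RS 32, RM 42, RL 44, HS 30,
  HM 35, HL 40 mm), that sample included.
* Noise: multiplicative mean-one lognormal with cv = 0.02 pointwise;
  between-specimen scatter multiplies (c, d) by independent mean-one
  lognormals with cv = 0.10.  Lognormal everywhere because forces and
  moduli are positive.
* Conditions: six substrate × particle-size groups with foam-scale
  parameters (c = d, between 0.038 and 0.090 MPa), ordered so smaller
  particles stiffen the composite and large hemp beats large rapeseed —
  the qualitative structure such studies report.  These are plausibility
  values, not fits to any dataset (none is public).
* Post-test height: 50–70 % of the peak strain recovers elastically
  (uniform draw), fixing the recovery-based modulus window.
* EPS benchmark group: a three-segment linear/plateau/densification curve
  (E = 2.37 MPa, plateau from 0.08 MPa, quadratic densification beyond
  45 % strain — magnitudes of commercial EPS board) with 2 % specimen
  scatter.  Report plumbing for comparative rankings only; it has no
  Neo-Hookean ground truth and is excluded from fitting.

What the generator does **not** emulate: damage and substrate debonding
(real curves can soften), unloading hysteresis, specimen-shape
imperfections beyond a planar slant, and load-rate effects.  Passing
recovery tests therefore demonstrates correctness of the analysis chain,
not validity of the constitutive model for real composites.

## Finite elements

Total-Lagrangian formulation, tri-linear hexahedra with full 2×2×2 Gauss
quadrature.  Stresses from S = 2∂w/∂C = 2c(I − C⁻¹) + 2d(J−1)J C⁻¹; exact
consistent tangent ℂ = 2∂S/∂C assembled per element; internal forces use
P = FS.  No locking treatment: ν < ½ strictly and fitted foams sit near
ν ≈ ¼, where tri-linear elements behave well — documented limitation for
d ≫ c.

* **Mesh**: butterfly-pattern structured cylinder (square core + four
  blended blocks), extruded axially.  The azimuthal core resolution must be
  even so that nodes exist on the x/y axes (the rigid-mode pins use them).
  A slant shears node heights z → z(1 + tan α·x/L₀), keeping the bottom
  flat and the volume unchanged.  The polygonal cross-section underestimates
  πD₀²/4 by ~(Δθ)²/6 (0.6 % at 32 azimuthal segments, quartering per
  refinement); closed-form comparisons therefore use the mesh's own
  cross-section area — the discrete specimen is the domain being solved.
* **Boundary conditions**: bottom face fixed vertically, laterally free
  (frictionless platen), plus three pins (axis node: u_x = u_y = 0; one
  +x-axis node: u_y = 0) removing the remaining rigid-body modes without
  constraining radial expansion.  This set admits the exact homogeneous
  uniaxial state, which is the key solver oracle: on any mesh the reaction
  must equal A·|λS₃₃(λ)|.  A clamped-bottom option exists for qualitative
  barreling.
* **Contact**: frictionless node-wise penalty against the plane z = h.
  Per-node stiffness κ_a = f·E·A_a/L₀ with A_a the consistent (row-sum)
  nodal area of the top face; the area weighting makes uniform penetration
  statically equivalent to uniform pressure, preserving the homogeneous
  oracle.  The default factor f = 1000 keeps the penetration error in the
  reaction below ~0.15 % while remaining well-conditioned for the direct
  solver; f = 100 would admit ~1 % reaction shifts that a 10× stiffness
  increase exposes.
* **Solver**: stamp lowered in uniform increments (default L₀/100), each
  step solved by Newton iteration on the semismooth residual (contact set
  re-detected every iteration), relative tolerance 10⁻⁹ against the contact
  force scale, automatic step halving on non-convergence or element
  inversion with gradual re-growth.  Linear systems use SuperLU in
  symmetric mode with one iterative-refinement pass (≈7× faster than the
  default ordering on these SPD-like tangents at identical accuracy).
* **Outputs**: stamp travel vs reaction, final displacement field, and the
  per-element von Mises norm of the Cauchy stress σ = J⁻¹PFᵀ (the
  equivalent-stress measure is a reporting choice).  Export is legacy
  ASCII VTK (text-only, readable by ParaView and by the bundled parser).

Verification chain: zero residual at zero displacement, tangent symmetry
and agreement with directional finite differences (<10⁻⁵), exact zero
internal force under rigid rotation, homogeneous-state reaction within
0.2 % of the closed form to 30 % compression, small-strain stiffness
within 1 % of EA/L₀, reaction shifts <0.2 % under 10× penalty and <1 %
under uniform mesh refinement in the slanted case.

## Particle statistics

Max Feret diameter: largest pairwise distance between convex-hull vertices.
Min Feret: smallest projection width over hull-edge normal directions
(rotating calipers — the minimum width is attained flush against a hull
edge).  Ratio histograms default to 20 uniform bins on (0, 1], the modal
ratio being the midpoint of the highest-count bin (ties → lower bin).
Sieving: a particle passes a mesh iff its min Feret is strictly below the
mesh size — the standard proxy for square-mesh sieving of elongated
particles — and lands in the interval between the largest mesh it does not
pass and the smallest it passes; undersize/oversize buckets keep the mass
balance exact.  Synthetic particles are rotated rectangles with small
vertex jitter; the hemp-like preset is longer and thinner (modal
width/length ratio ≈ 0.2–0.25) than the rapeseed-like preset (≈ 0.4–0.5),
with masses proxied by area × unit thickness.

## Pipeline

One seed drives everything: `numpy.random.SeedSequence(seed)` spawns
independent child streams per condition (and for the EPS group), so stages
re-run independently yet reproducibly, and rerunning with the same config
yields a byte-identical `report.json` (the only timestamp lives in
`run.log`).  Configs are validated strictly — unknown keys anywhere are
rejected — and embedded verbatim in the report for provenance.  Condition
ranking orders by mean σ_st with Welch-t overlap flags on adjacent pairs
(flags omitted when a condition has fewer than two usable replicates).
Stage failures are recorded in the report and dependent stages skipped.

Default problem sizes keep a full demo (6 conditions × 6 replicates + EPS,
FEM at 4/2/4 resolution ≈ 190 elements) in the low seconds on one CPU;
the FEM verification meshes used by the test suite range from 24 to ~2000
elements, chosen as the coarsest meshes on which each property is
informative.

## Known limitations

* Hyperelastic only: no damage, debonding, viscoelasticity or unloading —
  fitted (c, d) are effective loading-branch parameters.
* The toe model is a stand-in for surface-mycelium engagement, not an
  inferred mechanism; fits on toe-bearing curves yield effective parameters
  unless the toe region is excluded via the fit window.
* Frictionless contact and bottom support; no friction models.
* Tri-linear hexahedra without locking treatment degrade for d/c ≫ 1.
* Min-Feret sieving is a geometric idealization of real sieve passage.
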