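# Methods

## Scope and model chain

`bcdirect` analyses the directional sensitivity of bone-conduction (BC)
stimulation applied to the otic capsule, using two mechanical criteria
evaluated at the round window (RW): the averaged displacement of the bony
rim along the window normal, and the fluid volume displacement (VD) of the
membrane relative to that rim.  The chain is

    harmonic fields → rim rigid-motion fit → membrane VD →
    per-frequency normalization and weights → weighted-sum criteria →
    coarse grid extremes → biquadratic refinement.

Displacements are complex phasors (one frequency at a time); all angle
arithmetic is in degrees; lengths are mm and volumes mm³ at the analysis
level, SI internally in the FE solver.

## Direction parametrization

A stimulation frame (origin + right-handed orthonormal versors x̂₀₀, ŷ₀₀,
ẑ₀₀) is anchored at the implant site.  The force direction for angles
(α, β) is obtained by two sequential Rodrigues rotations: α about x̂₀₀,
then β about the rotated ŷ axis.  In the frame basis this is equivalently
ẑ_αβ = sin β·x̂₀₀ − cos β sin α·ŷ₀₀ + cos β cos α·ẑ₀₀; the equivalence is
asserted in tests rather than assumed.  Versors printed at 3 decimals
violate orthonormality at the 1e−3 level and are re-orthonormalized on load
by one Gram–Schmidt pass anchored on x̂₀₀ (each versor moves < 2e−3).

Two exact identities follow from the algebra and are test-asserted on a
lattice: ẑ(α+180°, β+180°) = +ẑ(α, −β) and ẑ(α+180°, β) = −ẑ(α, −β).
`symmetry_image` therefore reports a phase sign derived from the actual
vectors at run time (+1 for the (α+180°, β+180°) pair, i.e. the two
parameter pairs name the *same* direction).  Under a linear model,
antiparallel forces give equal amplitudes with reversed phase, so amplitude
maps extend across the ±90° boundary either way; this completion is what
makes refinement stencils at the grid edge well defined.

Inverting a direction vector is ambiguous up to sign; `canonical_angles`
prefers the representative with α ∈ [−90°, 90°], then cos β cos α ≥ 0.  At
gimbal lock (|β| = 90°, force along x̂₀₀) α is undefined and reported as 0
with an explicit flag.

## Rim kinematics and volume displacement

The rim fit inverts w_s = w + γ·y_s − φ·x_s for node triples using the
explicit adjugate of the 3×3 system, so a planted rigid field is recovered
to machine precision; the rim motion is the complex arithmetic mean over
triangles (identical to separate real/imaginary bookkeeping).  The
small-rotation form is inherited as-is; no finite-rotation correction.

Triangle grouping is injectable.  The default groups angularly consecutive
disjoint triples — matching how the rim triangles are drawn in the source
model — but consecutive triples on a near-circular rim are thin and
ill-conditioned: nodal noise of std σ is amplified ~36× into each
triangle's w because the fit extrapolates to the window center.  The
alternative "spread" grouping (i, i+n/3, i+2n/3) is near-equilateral; with
it the averaged w̄ error obeys the σ/√n averaging law, and the analysis
command uses it by default (the toy model's square 12-node rim makes some
consecutive triples exactly collinear).  For noiseless rigid fields the two
groupings agree exactly; the choice matters only for non-rigid or noisy
fields.

VD uses signed shoelace areas of the xy-projections of membrane triangles
(node z-coordinates are ignored).  The canonical winding is
counterclockwise seen from +z (toward the cochlea), so outward deflection
gives positive V; clockwise meshes are re-wound on load with a logged
notice, and quads whose two split triangles have opposite-sign areas are
flagged as self-intersecting.  Quads split along the (ABC, ACD) diagonal;
the alternative diagonal is a config switch (it changes V only for
non-planar fields over a quad).  Exactness properties: any rigid field
applied to rim and membrane gives V = 0 to round-off; a piston of complex
amplitude d gives V = A_total·d; V is complex-linear in the field and
invariant under in-plane rotation of the window axes.

## Criteria and refinement

Per frequency, amplitudes are normalized by their grid maximum and weighted
by μ = 1 − min/max ∈ [0, 1]; the weighted sums over the frequency set give
dimensionless criteria in [0, 1], equal to 1 exactly at a grid point that
attains every per-frequency maximum with μ > 0.  A fully
direction-independent surface (Σμ = 0) raises an explicit degenerate-case
error rather than silently returning a flat map.  Grid argmax/argmin ties
are broken deterministically by smallest (|α|, |β|, α, β) and logged;
continuous data has no ties, so this only affects synthetic edge cases.

Refinement interpolates the 3×3 neighbor stencil with tensor-product
quadratic Lagrange shape functions (the 9-node Lagrangian surface element)
and locates the interpolant's extremum over the biunit square by a dense
lattice scan (step 0.005 in local coordinates ≈ 0.075° at 15° spacing)
followed by one Newton polish, accepted only when it stays in the square
and improves the objective.  Dense-scan-first avoids the biquadratic's
saddle; results are clamped to the square (no extrapolation) and an
extremum on the stencil boundary is flagged as a misidentified coarse
extremum.  The refined value never falls below the best nodal value.

The B81 helper converts transducer output force level (dB re 1 μN) to
newtons, F = (2.5/2.83)·10⁻⁶·10^(OFL/20), for force-calibrated comparisons.

## Toy finite-element model

The solver is a minimal frequency-domain elastodynamics code: trilinear
hex8 elements with 2×2×2 Gauss quadrature, consistent mass, hysteretic
damping as a complex modulus E(1 + iη) per material (rate-independent, the
standard harmonic-analysis convention; η defaults to 0.05), lumped
soft-tissue surface mass (2.5·10⁻³ g/mm² on the free outer faces), and the
implant as a 0.16 g point mass split equally over the attachment node
circle (radius 1.5 mm) that also receives the harmonic force (0.1 N
default) split equally along +ẑ_αβ.  One sparse complex LU factorization
per frequency is reused across all force directions; there is no modal
superposition (damping is non-proportional in general).  Verified physics:
a static uniaxial patch test is exact, a fixed-free rod's quarter-wave
resonance is matched within 2%, and undamped reciprocity holds to 1e−8.

The toy geometry is a 12 mm bone cube (E = 14.1 GPa, ν = 0.3,
ρ = 1900 kg/m³) with a 5×5×5 mm fluid cavity under the top face, a 3×3 mm
membrane window (E = 1 MPa, ν = 0.45, ρ = 1200 kg/m³, η = 0.1) forming part
of the cavity's outer wall, the rest of that wall a 1-element bone layer (a
wall-compression pathway), a fixed bottom face, and the stimulation patch
on the +x face.  The cochlear fluid is a nearly incompressible, very-low-
shear elastic solid (ν = 0.499, E = 13 MPa, bulk modulus ≈ water) rather
than an acoustic formulation — one element type for everything, at the cost
of shear artifacts that a real fluid would not have.  Cavity volume
(125 mm³) is deliberately proportionate to the window area the way inner-
ear fluid volume relates to the round window; a much smaller sealed cavity
makes VD fluid-compression-limited and hides the membrane compliance
entirely.  With these defaults, stiffening the membrane to bone drops |V|
by ≈ 22 dB at 1 kHz — the rigid-window limit is visible, which is the
property the fixture exists to exercise.

The toy model is explicitly non-anatomical.  It shares the reference boundary
conditions (fixed outer boundary, immobilized-stapes topology: the cavity
has no second compliant window), force amplitude, frequency set, implant
mass, and surface mass density, but none of its geometry; the specific
extreme directions it produces are properties of the toy cube, not of any
temporal bone.  What transfers to real data is the analysis chain and its
guarantees, plus the angle relationships among the published characteristic
directions, which depend only on the printed frame and the parametrization.

## Synthetic generators

All fixtures are pure functions of (config, seed).  The window fixture is a
48-node circular rim (radius 1 mm, optional angular jitter) and an all-quad
O-grid disc (rectangular core + concentric layers) whose layout is searched
to hit the requested quad count exactly — the default 218 resolves to a 4×5
core with 11 layers of 18 quads; unreachable counts fall back to the
nearest achievable with a warning.  Planted fields put an exact rigid
motion on the rim and rigid + profile·d (+ complex Gaussian noise,
independent re/im parts, no spatial correlation) on the membrane; the
piston profile has the closed form V = A_total·d.  Planted response
surfaces follow amp(α, β, f) = c(f)·(ε + max(0, ẑ_αβ·d*)^p), whose
continuum argmax is the planted unit direction d* for any sharpness p > 0;
with p = 4 and the 15° grid, coarse search + refinement recovers an
off-grid d* to about 0.2°, comfortably inside the 1.5° budget used in
tests.

## Problem sizes and numerical choices

Tests run the toy model at 12³ elements (≈ 6.6k DOF) and reduced sweeps
(5×5 directions × 5 frequencies), sizes chosen so the full suite exercises
every pipeline branch in well under a minute of FE time; the solver itself
is size-agnostic.  Tolerances: frame orthonormality 1e−9 after
construction; rigid-fit and VD exactness asserted at 1e−10 relative or
better; triangle degeneracy threshold 1e−12 mm²; refinement lattice step
0.005.  Degenerate inputs (collinear triangles, zero per-frequency maxima,
Σμ = 0, |β| = 90° gimbal lock, singular FE systems) raise typed errors
naming the offending entity rather than propagating NaNs.

## Known limitations

Only the z-component of rim motion enters the criteria (no in-plane rim
kinematics); the membrane is a mid-surface (no through-thickness
distinction); the fluid is an elastic pseudo-solid; hex8 elements lock for
ν → 0.5 and thin bending, so toy-model amplitudes are stiffness-biased;
there is no basilar membrane, middle/outer ear, or cadaver-data comparison.
The package reproduces the *method* and the frame-geometry results, not the
anatomy-specific response surfaces.
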