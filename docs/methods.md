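# Methods

`nucleomech` simulates the mechanical link between substrate stiffness and
nuclear deformation in adherent cells. This note records the model, its
parameters, the synthetic-data generators, the numerical choices, and the
limits of what the simulations show.

## Units

One consistent unit system is used throughout: lengths in µm, moduli and
stresses in Pa, forces in pN, spring stiffnesses in pN/µm. These are
mutually consistent without conversion factors: 1 Pa·µm² = 1 pN and
1 Pa·µm = 1 pN/µm, so a substrate modulus in Pa times a focal-adhesion
diameter in µm is directly a spring stiffness.

## Cell model

The cell body is a semi-ellipsoid resting on the rigid basal plane z = 0.
Its basal footprint is an ellipse of prescribed spread area A and aspect
ratio r = a_y/a_x ≥ 1 (π·a_x·a_y = A, major axis along y); the apex height
h is the third semi-axis. The nucleus is a sphere of radius R centred on
the z-axis at z = R + g, where g is a small basal gap.

Defaults: A = 1200 µm², r = 1.5, h = 13 µm, R = 5.5 µm, g = 0.5 µm. The
spread area and aspect ratio are placeholders at realistic epithelial-cell
magnitudes and should be overridden with measured values per condition; the
nucleus radius of 5.5 µm is used as the geometric parameter even though it
is sometimes quoted together with a nuclear volume of 660 µm³, which a
5.5 µm sphere does not exactly match ((4/3)π·5.5³ ≈ 697 µm³) — the radius,
not the volume, is authoritative here. The height default is the smallest
round value that encloses the undeformed nucleus with margin; it is not a
sensitive parameter because the load path runs through the fibers, not the
apical surface.

Four materials (linear isotropic elasticity):

| part      | E        | ν    | extra                               |
|-----------|----------|------|-------------------------------------|
| membrane  | 7 kPa    | 0.3  | shell thickness 0.2 µm, in-plane only |
| cytoplasm | 0.25 kPa | 0.3  |                                     |
| nucleus   | 1 kPa    | 0.45 | nearly incompressible               |
| filament  | 250 kPa  | 0.3  | truss, section radius 0.25 µm, ε₀ = 0.2 |

## Filament network

Actin filaments are idealised as three classes of pre-strained axial
trusses (no shear or bending):

* **nucleus–membrane** fibers: straight segments from the nucleus
  equatorial band (|z − z_c| < R/3, sampled uniformly) to focal-adhesion
  anchors in the outer 20 % annulus of the basal footprint. Their tension
  pulls the nuclear equator outward and down.
* **over-nucleus** fibers (the actin cap): anchor-to-anchor polylines whose
  3–7 interior vertices lie exactly on the apical nucleus sphere along a
  great-circle arc (polar angle 30°–150°, lateral offset up to R/2). A
  straight truss could not push on the nucleus; the wrapping vertices
  convert fiber tension into a distributed normal force that flattens it.
* **ventral network**: Poisson-sampled nodes in the basal disk beneath the
  nucleus joined by Delaunay-neighbour edges; node density is set by a
  length-scale knob (default 3 µm); nodes on the convex hull of the sample
  are substrate-anchored. Exactly `count` edges are kept, drawn without
  replacement with probability proportional to the doubled-angle von Mises
  density at the edge azimuth, which biases the realised orientations
  toward the class target while keeping the network topology.

In-plane fiber azimuths follow a nematic (doubled-angle) von Mises
distribution about the cell's major axis. The orientation distribution is
characterised only by the nematic order parameter S = |⟨e^{2iθ}⟩|; the
doubled-angle von Mises is the maximum-entropy circular distribution
consistent with a prescribed S, and its concentration κ is calibrated by
solving I₁(κ)/I₀(κ) = S (Brent's method on the Bessel ratio). S = 1 has no
finite κ and is treated as the deterministic all-parallel limit.

Per-class fiber counts are met exactly; a replicate's network is fully
determined by (geometry, specs, seed), with the per-replicate seed defined
as base_seed + replicate index.

## Substrate coupling

Each anchored fiber endpoint is grounded through the series combination of
a focal-adhesion spring k_a and an equivalent substrate spring
E_s·d/(1 − ν_s²):

    k_eff = ( 1/k_a + (1 − ν_s²)/(E_s·d) )⁻¹

applied as an isotropic (x, y, z) grounded triad at the anchor node.
Defaults k_a = 10⁵ pN/µm (0.1 N/m) and d = 2 µm are order-of-magnitude
focal-adhesion values and are configurable; ν_s = 0.3. Over the default
grid 0.1–40 kPa, k_eff spans 219 → 46 800 pN/µm, bracketing the fiber axial
stiffness E_f·A/L (≈ 2.5 × 10³ pN/µm at L = 20 µm) — which is why substrate
stiffness modulates transmitted tension so strongly in this range.

## Discretisation

Meshing is fully deterministic. The nucleus surface is a subdivided
icosahedron whose vertices are shared verbatim by both the nucleus and the
cytoplasm tetrahedralisations: each sub-domain is Delaunay-tetrahedralised
separately (the cytoplasm point set sees the nucleus as an empty hole tiled
only by all-icosphere tets, which are discarded), so the interface is
conforming by construction — the interface node set is exactly the
icosphere. Interior and basal grid points carry a tiny (3 % of edge
length) deterministic jiggle that breaks the co-planar degeneracies a
regular lattice induces in Delaunay triangulation; exact surface points
(icosphere, rim, ellipsoid shell) are never jiggled. Degenerate sliver
tets spanned purely by exterior-surface points are dropped (their volume is
negligible; removing them only shifts the shell to the neighbouring faces).
Membrane triangles are the non-basal boundary faces.

A single resolution knob sets the target edge length (default 2.2 µm for
sweeps, ~2 300 nodes; 1.5 µm for verification meshes). The nucleus
interface — the readout surface — is resolved at half the bulk edge length.
At the sweep default, part volumes are within 1 % (nucleus) and 0.5 %
(cytoplasm) of the analytic values, and the projected area of the
undeformed nucleus is within 0.6 % of πR²; both errors shrink under
refinement.

Element library: 4-node constant-strain tetrahedra; 3-node plane-stress
membrane triangles (local-frame CST embedded in 3D, no bending); 2-node
axial trusses; grounded spring triads. Fiber vertices are rigidly tied to
their nearest mesh node (tie tolerance = mesh resolution; a farther vertex
is an error, not a silent drop).

## Loading, constraints, solve

The only load is filament pre-strain, applied as equivalent axial end-force
pairs of magnitude E_f·A·ε₀ ≈ 9 817 pN per segment. The formulation is
geometrically linear throughout: ε₀ = 0.2 is large, and treating it as an
initial axial stress in small-strain theory is a deliberate, testable
simplification — outputs scale exactly linearly in ε₀ (verified to 10⁻⁶),
so results are best read as trends and ratios rather than absolute strains.

Boundary conditions: basal-surface nodes are fixed in z (rigid,
frictionless dish); all in-plane restraint comes from the anchor springs,
so substrate stiffness genuinely matters. Weak in-plane regularization
springs (10⁻³ × k_eff, configurable) on every basal-rim node suppress the
residual in-plane rigid modes; they are applied to the whole rim rather
than a minimal three points because that conditions the operator well even
for a fiber-free model, and at 10⁻³ × k_eff their forces are negligible
against the fiber loads.

The symmetric sparse system is solved by a direct sparse LU factorisation
after eliminating prescribed displacements. A solve is rejected
(explicitly, as a singular-system error) if the relative equilibrium
residual exceeds 10⁻⁶; in practice residuals are at machine precision
(~10⁻¹⁵). Fibers whose total axial strain would make tension negative are
flagged and counted but keep their linear element (slack is not modelled;
preserving linearity is the point).

Verification cases with closed forms:

* pre-strained truss against a grounded spring — u = E·A·ε₀/(k + E·A/L),
  exact to 10⁻⁸;
* patch test — a linear displacement field imposed on the boundary of a
  jiggled cube mesh reproduces uniform strain to ~10⁻¹⁴;
* hydrostatic sphere — uniform pressure p on the nucleus material gives
  mean normal strain −p(1 − 2ν)/E. The pressure is applied along the true
  spherical normals sampled at surface nodes, so the load carries the
  geometric faceting discrepancy: the error (1.6 % at 1.5 µm resolution,
  0.4 % at 0.75 µm) is a genuine discretisation error that vanishes under
  refinement. (With facet-consistent loads the uniform-strain state is
  exactly representable by linear tetrahedra and the test would be exact at
  every resolution, verifying nothing about convergence.) The 3-2-1 point
  constraints are compatible with the uniform field because the icosphere
  contains vertices exactly on the coordinate axes.

## Nuclear readouts

* **Total force**: at every fiber vertex tied to a nucleus-surface node,
  the transmitted force is the vector sum of adjacent segment tensions
  along their axes; the reported total is the sum of per-attachment
  magnitudes. A near-symmetric filament arrangement makes the plain vector
  sum cancel toward zero, which would hide the loading; the vector-sum
  convention remains available as a configuration switch.
* **Strain/stress**: volume-weighted means of the diagonal (normal) strain
  and stress components over nucleus tetrahedra, using constant-strain
  element values with no nodal smoothing — the simplest scheme with an
  exact hydrostatic check.
* **Projected area**: area of the convex hull of the displaced
  nucleus-surface nodes projected on the basal plane. Concave silhouettes
  are out of scope at this deformation scale.

With zero pre-strain or zero fibers every readout is zero to 10⁻⁹ —
the null model is exact, not approximate.

A model property worth knowing: the x-direction normal stress is the small
difference between lateral confinement and Poisson expansion and crosses
zero across the stiffness grid, so its *magnitude* is not monotone in
stiffness even though strain_x is consistently positive. The z (and y)
components trend monotonically as expected.

## Monte-Carlo sweep

The default experiment solves 20 random network realisations at each of
0.1, 0.7, 5, 14 and 40 kPa (the replicate count is a package default; the
coarse default mesh keeps the full sweep under a minute on one CPU). The
default per-stiffness filament statistics are synthetic placeholders
encoding the qualitative experimental behaviour — counts per class rise
linearly from (10, 5, 15) at 0.1 kPa to (40, 20, 60) at 40 kPa and the
orientation target S from 0.2 to 0.8 — and are fully overridable from the
configuration file; conclusions from the defaults are directional
(signs, orderings, monotone trends), never magnitudes. Per-fiber anchor
tension is monotone in k_eff for an isolated fiber; in a coupled network,
neighbouring fibers deforming the shared cytoplasm can unload an individual
anchor, so monotonicity is asserted for the aggregate transmitted force,
not per fiber. Results are returned as a tidy per-replicate table
(summaries are recomputed from it, never stored separately); identical
configuration and base seed reproduce the table bit for bit, and solver
failures mark their row as failed rather than aborting the sweep or
fabricating values.

## Synthetic micrographs and the alignment parameter

The imaging module generates filament micrographs with known ground truth:
segments with von Mises-distributed orientations are rendered as
Gaussian-profile ridges (default: 640×640 px frame at 0.1 µm/px, ridge
width 2 px, 5 % additive Gaussian noise) and the per-segment orientations
and lengths are carried on the image.

The measurement is the gradient structure tensor: the image is smoothed at
the gradient scale σ_g (default 1 px), outer products of its gradients are
windowed with a Gaussian of scale σ_w (default 4 px), and the tensor is
eigen-decomposed into per-pixel orientation θ (minor eigenvector — the
ridge direction), coherency (λ₁−λ₂)/(λ₁+λ₂) and energy λ₁+λ₂. The scalar
alignment parameter is the energy × coherency-weighted nematic resultant

    S = |Σ w·e^{2iθ}| / Σ w,   w = energy · coherency,

deliberately the same statistic as the fiber-space order parameter, so
image-space and fiber-space S are directly comparable. Angles live in the
image frame (x = columns, y = rows increasing downward), which flips the
sign of visual rotations; equivariance holds with that sign convention.

Estimator properties, measured on the synthetic generator: S is invariant
under intensity scaling, equivariant under rotation to within 2°, and
recovers the rendered ground-truth order to better than 0.1 across
ground-truth S ∈ {0, 0.3, 0.6, 0.9} at 200 segments. Two biases are worth
noting: (i) where filaments cross, the window mixes orientations and the
coherency weight discounts those pixels, slightly inflating S at
intermediate order and high filament density — the default frame keeps
density low enough that the bias stays within the 0.1 envelope; (ii) with
finitely many segments the realised order of a sample differs from the
distribution target by O(1/√n) (≈0.07 SD at n = 200), so recovery is
defined against the image's realised ground truth, which the generator
records, not against the sampling target.

What the synthetic images do *not* emulate: filament curvature, branching,
variable width and brightness, out-of-focus light, and camera noise
statistics — so passing recovery tests demonstrates correctness of the
estimator pipeline, not performance on real micrographs.

## Hertz fit and correlation

Hydrogel calibration uses the spherical-indenter Hertz relation
F = (4/3)·E/(1−ν²)·√R·δ^{3/2}. The model is linear in E, so the
least-squares fit is the closed-form projection E = ΣF·g/Σg² with
g = (4/3)√R·δ^{3/2}/(1−ν²): it recovers noise-free forward curves exactly
(to 10⁻¹⁶) and cannot return a negative modulus for non-negative forces.
Trend analysis uses ordinary least squares with Pearson's r and a
two-sided p-value from the t distribution with n − 2 degrees of freedom;
no multiple-testing correction is applied.

## Known limitations

* Small-strain linear elasticity with 20 % pre-strain: absolute strains of
  0.1–0.45 are outside the formal validity of linear theory; signs,
  orderings and ratios are the meaningful outputs.
* No contact mechanics: fibers are tied to mesh nodes, the nucleus cannot
  separate from or slide along the cytoskeleton, and slack fibers retain
  linear stiffness (flagged, not removed).
* No membrane bending, no viscoelasticity, no filament turnover or
  force-dependent remodeling; the nucleus is a homogeneous elastomer with
  no distinct envelope.
* Default spread area, aspect ratio, per-stiffness filament statistics,
  k_a and d are literature-scale placeholders, not fitted values; every one
  is a configuration field.
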