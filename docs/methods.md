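# Methods

This note documents the model, the numerics, and the design decisions
behind `plaquestretch`, in the spirit of a model-description appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Problem statement

We solve quasistatic finite-strain equilibrium of a tissue-labeled vessel
wall cross-section under luminal blood pressure, and post-process the
principal tissue stretch field with respect to the distance from
macro-calcifications. Two load cases are standard: diastole (80 mmHg) and
systole (140 mmHg); 1 mmHg = 133.322 Pa.

## 2. Synthetic labeled geometry

Real inputs to this kind of analysis are CTA segmentations produced by
proprietary clinical software; the generator replaces them with a
parametric, exactly reproducible stand-in. A cross-section is an annulus
between a circular lumen (radius `Ri`) and a circular outer wall (radius
`Ro`) whose center may be offset along +x by
`e · (Ro − Ri − 0.5 mm)`, `e ∈ [0,1]`, producing an eccentric
(stenotic-looking) wall while preserving a 0.5 mm minimum thickness.
CALC arcs and LRNC pools are annular sectors expressed in wall coordinates
`(θ, f)`: angle about the lumen center and fractional depth through the
wall (0 = lumen boundary, 1 = outer boundary). Inclusions must lie strictly
inside the wall and may not overlap each other; overlaps are rejected with
the colliding regions named. An optional seeded jitter perturbs arc
boundaries; with jitter off (the default) generation is fully
deterministic and the seed is inert.

The default **reference stenotic plaque** (`reference_stenotic_spec`) is
`Ri = 2.5 mm`, `Ro = 5.5 mm`, eccentricity 0.4 (wall 2–4 mm), one
120°-span CALC arc at `f ∈ [0.35, 0.65]` on the thick side (≈ 1.2 mm thick
at the arc center) and a 60° LRNC pool opposite at mid-depth. These values
are package choices, selected once so that MATX exists both within and
beyond 1 mm of CALC; they emulate a heavily calcified carotid lesion, not
any specific patient.

What the generator deliberately does **not** emulate: irregular
(non-circular) lumina, spiculated or speckled micro-calcification, fibrous
cap thinning, multi-layer wall structure, imaging noise and partial-volume
effects. Passing tests therefore demonstrate the mechanism on idealized
topologies, not segmentation-grade anatomies; externally supplied labeled
meshes can be analyzed through the same pipeline (`mesh_path` in the
config).

### Meshing

Because every region is a rectangle in `(θ, f)` space, the mesher is
structured and boundary-conforming: breakpoints in `θ` and `f` are snapped
to all region edges (deduplicated at 1e-9 to avoid zero-width strips), each
parameter cell is refined to the target edge length `h` and split
criss-cross into four triangles about a center node, and mid-edge nodes are
placed by the smooth `(θ, f) → (x, y)` map. This yields curved
isoparametric 6-node triangles whose boundary nodes lie exactly on the
lumen/outer circles, guarantees that every element lies wholly inside one
region (element label = region of its parameter-space center, with
CALC > LRNC > MATX precedence on exact ties), and — because the criss-cross
split has no diagonal bias — maps mirror-symmetric geometries to
mirror-symmetric meshes, which the solver's symmetry test exploits.
The `(θ, f)` parametrization is orientation-reversing, so corner loops are
walked f-first to keep all Jacobians positive.

Distance-to-CALC is the distance from each element centroid to the union
of CALC element triangles (an STRtree nearest query), zero on CALC and +∞
when no CALC exists; it is exact to within one element diameter.

## 3. Constitutive model

Three-parameter Yeoh energy on the isochoric invariant with a quadratic
volumetric penalty:

`W = c1(Ī₁−3) + c2(Ī₁−3)² + c3(Ī₁−3)³ + κ/2 (J−1)²`, `Ī₁ = J^(−2/3) tr C`.

* The isochoric split is a convention choice: the original material fits
  may have used the full invariant. At `J → 1` the two coincide, and the
  penalty keeps `|J−1| ≲ 1e-3`, so the difference is below the other
  modeling errors; it is nevertheless a documented possible divergence from
  the fits' native convention.
* `κ = 1000·μ₀` per material by default (`μ₀ = 2c1`); configurable upward.
  A mixed u–p ("Lagrange-multiplier") treatment of incompressibility would
  be the saddle-point alternative; the penalty was chosen to keep the
  linear algebra definite and simple at desk scale.
* The negative `c2` of the CALC and LRNC presets does not produce
  softening in the working range: `dW/dĪ₁` has negative discriminant for
  all three presets, and the test suite asserts energy non-negativity along
  uniaxial and equibiaxial incompressible paths for λ ∈ [0.8, 1.5].
* Stress (Cauchy, via first Piola–Kirchhoff) and the first-elasticity
  tensor `∂²W/∂F²` are analytic and verified against central finite
  differences of the energy to ~1e-10 relative in tests.

## 4. Finite-element solver

Plane strain (`F₃₃ = 1`): appropriate for axially tethered vessels and
consistent with a cross-sectional readout. Displacement formulation on
6-node triangles with the 3-point (degree-2) triangle rule — the standard
rule for quadratic triangles, whose mild under-integration also relieves
volumetric locking under the penalty; a 6-point degree-4 rule is available
(`SolverSettings.n_quad = 6`) and changes results negligibly.

* **Reference configuration.** The generated geometry is treated as
  stress-free at zero pressure; no residual stress or prestretch recovery
  is attempted. This mirrors the upstream procedure this pipeline emulates
  and is a shared limitation: in vivo, the diastolic configuration is the
  imaged one and arteries carry residual stress.
* **Pressure** is a follower load on the lumen loop. In 2D its exact
  linearization (`p ∫ N_a R N'_b`, R a 90° rotation) is
  displacement-independent but unsymmetric; the full unsymmetric tangent is
  kept and factorized by sparse LU (SuperLU), which is deterministic on one
  thread. The external force is variationally consistent with the pressure
  potential `−p·A_lumen(u)` (finite-difference verified during
  development).
* **Rigid-body constraints.** A closed pressure loop is self-equilibrated,
  so only the three 2D rigid modes need fixing: the outer-boundary node
  nearest 0° is fixed in x and y, the node nearest 180° in y. Both lie on
  the x-axis for mirror-symmetric geometries, so the constraint set
  preserves mirror symmetry; the reactions vanish to roundoff (asserted ≤
  0.5% of the total pressure force). The converged field consequently
  contains an irrelevant rigid translation; every reported quantity
  (gradient-based stretch, perimeter-based inner-wall stretch) is
  translation-invariant.
* **Continuation.** Uniform load stepping (default 10 steps) with adaptive
  step halving (≤ 5) on Newton failure. The Newton line search only guards
  against element inversion and non-finite residuals — the residual norm is
  legitimately non-monotone along healthy Newton paths for follower
  loads — plus a damping of wild early steps. Convergence is declared at
  relative residual ≤ 1e-8 of the applied-force norm, or when the increment
  stagnates at machine level while the residual sits at the roundoff floor
  of the large penalty (accepted only below 1e-5 relative); zero pressure
  converges immediately with an exactly zero field.

### Verification

`cylinder_inflation_oracle` solves the plane-strain, exactly
incompressible thick-walled-cylinder inflation by reducing it to a 1D
integral in the circumferential stretch,
`P(λᵢ) = ∫ 2 W'(I₁) (λ²+1)/λ³ dλ` between the outer and inner stretch
(adaptive quadrature at 1e-10, Brent root find at 1e-12, root bracketed in
(1, 3)). The FE inner-wall stretch (deformed/reference lumen perimeter)
matches it to ~0.02% at `h = 0.1 mm` on the Ri=3/Ro=4 mm MATX annulus at
80 mmHg.

The convergence study runs a raised penalty (`κ = 1e5·μ₀`) so the
`O(μ/κ)` incompressibility modeling error sits below the discretization
error of the family, and uses meshes `h = {1.6, 0.8, 0.4} mm`: the curved
quadratic elements superconverge on this smooth problem (observed order
3.5–4.5), so on finer meshes the oracle comparison saturates at the
penalty floor (~1e-4 of the stretch increment) rather than measuring
discretization error. The acceptance check therefore demonstrates monotone
error decay and order ≥ 2 on the coarse family and the ≤ 1% oracle match on
the fine mesh — the accuracy statement the study is for, with the order
measured where it is observable.

## 5. Stretch analysis

"Principal tissue stretch" is defined here as the **maximum in-plane
principal stretch** `λ₁ = √(max eig FᵀF)` of the quadrature-point-averaged
element deformation gradient, reported as `(λ₁−1)·100` %. The out-of-plane
stretch is identically 1 under plane strain and is excluded so in-plane
compression (λ₁ < 1) remains visible. Quadrature-point averaging avoids
superconvergent-point artifacts of nodal extrapolation on quadratic
triangles.

* **Profiles**: diametral lines through the lumen center (defaults 0°,
  60°, 120° — a 2D stand-in for multiple 3D cross-sections), sampled at
  `h/2`, with lumen samples labeled LUMEN (NaN stretch) and out-of-vessel
  samples dropped.
* **Zone summary**: MATX elements split at 1 mm (configurable) distance to
  CALC; per-zone mean/median/5th/95th percentiles of stretch %, fraction of
  elements above the 12.5% reference line, and the far/near mean ratio —
  the stretch-shielding readout. Element means are unweighted (element
  areas are near-uniform on the structured mesh); percentages in report
  JSON are rounded to 0.1.
* One measured caveat: strict *elementwise* monotonicity of λ₁ in pressure
  holds for homogeneous inflation but not universally on heterogeneous
  geometry — in the stretch-shielded zone (λ₁ ≈ 1.001) the in-plane
  principal direction can rotate as load grows, producing deficits ≲ 1e-3
  in ~1% of elements. Tissue-mean monotonicity is strict. The tests assert
  exactly this structure.

## 6. Reproducibility and I/O

Everything is deterministic: geometry and meshing are seed-stable
bit-exact, assembly and the direct solver are single-threaded and
order-stable, and `run_pipeline` on an identical config reproduces
`report.json` byte for byte (asserted in tests). Meshes and fields are
written as ASCII XML `.vtu` (quadratic-triangle cells, `tissue_label` /
`principal_stretch_pct` / `dist_to_calc_mm` cell data, `displacement`
point data) with 17-significant-digit floats so write→read round-trips are
exact; boundary loops can be exported as an ASCII STL ribbon for
STL-based toolchains. Configs are YAML with strict validation
(unknown keys rejected with nearest-key suggestions; invalid values
rejected naming the field).

Problem sizes used by the default tests and the acceptance script —
`h = 0.3 mm` (≈ 8k elements) for the stenotic plaque, `h = 0.1 mm`
(≈ 10k elements) for the verification annulus — were chosen as the
desk-scale sizes at which all reported quantities are mesh-stable to well
within their acceptance tolerances.

## 7. Known limitations

* 2D plane strain; no 3D bifurcation geometry, no axial variation (the
  mesher's extrusion of boundary ribbons is an export convenience, not a
  3D solve).
* No residual stress / prestretch; pressures are applied from a stress-free
  segmented configuration.
* Isotropic Yeoh only — no collagen-fiber anisotropy, viscoelasticity, or
  damage; tissue properties are generalized literature values, not
  patient-specific.
* Penalty incompressibility: `|J−1|` is small (99th percentile ≤ 1e-3) but
  not zero; exact-incompressibility comparisons carry an `O(μ/κ)` floor.
* Stretch, not stress, is the readout; force-based quantities are exposed
  only as solver diagnostics.
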