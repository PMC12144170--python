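# Methods

## Scope and model

The package compares fracture-fixation treatment variants on idealized,
fully synthetic bone–implant constructs. The physical model is static,
small-strain, isotropic linear elasticity on a monolithic tetrahedral
mesh: all interfaces (bone–implant, callus–bone, plate–bone) are
perfectly bonded through shared nodes. There is no contact, friction,
geometric or material nonlinearity, no fatigue and no time evolution of
the callus. One load step represents the peak of a representative
activity (e.g. mid-stance of gait).

These assumptions have a visible consequence worth stating up front: a
*bonded* construct already transmits torsion through the nail–bone
interface, so adding a transverse "strain-reduction" screw barely changes
either the implant stress or the fracture-gap strain state (the shipped
torsion case shows <0.1% change in peak nail stress). Capturing the
clinically reported benefit of such screws would require torsional play
(contact) at the nail interface, which is out of scope.

## Synthetic anatomy

A construct is an analytic solid evaluated at voxel centers (no
anti-aliasing), so the label map is exact ground truth:

* bone: a circular cylinder of length `bone_length` (axis +z, distal end
  at z = 0) with cortical shell thickness `cortical_thickness` and
  trabecular interior (which also fills the medullary canal);
* fracture: a transverse slab of width `gap_width` centered at
  `gap_position`, filled with soft callus out to the periosteal radius;
* implants: an intramedullary nail (cylinder, radius ≤ canal radius), an
  optional plate (partial cylindrical shell flush with the periosteum)
  and optional transverse screws (cylinders). Label precedence is
  implant > callus > cortical > trabecular > background.

Greyvalues are HU-like per-region constants (background −1000, callus
50, trabecular 300, cortical 1500, metal 3000) plus i.i.d. Gaussian noise
with an explicit seed; identical spec + seed is bit-identical. The
defaults are well separated so the threshold segmentation can recover the
ground truth exactly in the noise-free case, which is what makes the
end-to-end recovery tests meaningful. What the generator deliberately does
*not* emulate: anatomical bone curvature and cross-section variation,
fracture comminution, imaging physics (beam hardening, metal artifacts,
partial-volume averaging), scanner metadata. Passing tests therefore
validate the pipeline's mechanics and bookkeeping, not robustness to
clinical image artifacts.

The wrist scene is a concave spherical articular cup (radius 15 mm) on
the distal radius analogue and a rigid proximal carpal unit modeled as a
single sphere (radius 6 mm) whose center sits 8 mm from the rotation
center, leaving 1 mm radial clearance at neutral. A malunion prominence
is an inward quadratic bump on the cup (default: 25° toward radial
deviation, 5° half-width, 2 mm high — taller than the clearance, so it
must impinge). Deviation is a rigid rotation about an axis through the
cup center; with no prominence the clearance is rotation-invariant by
construction, giving a guaranteed contact-free reference scene.

## Segmentation

Half-open intervals `[lower, upper)` over the greyvalue axis, validated
to be non-overlapping and gap-free with ±inf catch-alls. The default
table places boundaries at midpoints between the tissue levels. Regions
sharing a greyvalue (several metallic components) are merged by
thresholding — as in clinical CT, where implant components are separated
manually; the end-to-end cases therefore mesh from the construct's label
map (the external label-map entry point) and record the threshold
segmentation's agreement with the merged ground truth in provenance.
Under Gaussian noise the expected misclassified fraction is computable
exactly from normal tails per region; the tests assert the observed
fraction against that bound plus four binomial standard errors.

## Meshing

Each foreground voxel splits into 6 tetrahedra sharing the voxel's main
diagonal (Kuhn subdivision, one tet per axis permutation, odd
permutations reordered for positive volume). Using the same local
orientation in every voxel makes face diagonals agree across voxel faces,
so the mesh is conforming by construction, and node deduplication is done
on integer grid indices — conformity is bit-exact, never
tolerance-dependent. Mesh volume equals foreground voxel count × h³
exactly. Order 2 inserts one unique mid-edge node per edge (C3D10-style
10-node tetrahedra). Order 1 is the default at pipeline scale because its
constant-strain fields make closed-form verification exact; order 2 is
available and is strictly more accurate in the bending benchmarks.

## Materials

Bone: `rho = max(a + b·HU, rho_min)` g/cm³, `E = c·rho^d` MPa with
defaults a = 1.0, b = 0.001 per HU, c = 6850, d = 1.49, rho_min = 0.05 —
a published apparent-density power-law family; the calibration is
configurable and recorded in every report. Fixed regions: soft callus
E = 3 MPa, ν = 0.4 (early-callus convention of the tissue-differentiation
literature); titanium alloy E = 110 GPa, ν = 0.3 (steel 200 GPa
available); bone ν = 0.3. Each element inherits the greyvalue of its
parent voxel, so all 6 tets of a voxel share properties and no
interpolation ambiguity exists.

## Finite elements

Standard TET4/TET10 displacement elements; TET10 uses the 4-point Gauss
rule. Dirichlet constraints are eliminated from the system; reactions are
recovered from the residual on constrained dofs, so the global
equilibrium check `sum(reactions) = −sum(applied)` is an actual test of
the solve, not an identity.

Load application: a total force on a cuboid node set is split *equally*
per node by default — appropriate for the load-reference regions at the
bone ends, where Saint-Venant's principle makes the fracture region
insensitive to the exact distribution. For verification against
closed-form uniform-stress states an *area-consistent* distribution is
provided (tributary boundary-face areas; for quadratic faces the standard
zero-corner / third-per-midside weights), which reproduces the axial-bar
solution to machine precision. Equal splitting is not the consistent load
of a uniform traction and leaves an O(1%) end effect in the bar's mean
tip displacement; the verification suite therefore uses the consistent
distribution, the pipeline the equal one.

Solvers, chosen by problem size:

* ≤ 80k free dofs: SuperLU direct factorization (deterministic);
* larger voxel meshes: an exact block-tridiagonal direct solver that
  exploits the extruded structure — grouping dofs by z-plane makes the
  stiffness block-tridiagonal (6-tet voxel elements couple only adjacent
  planes); forward elimination forms per-layer Schur complements, each
  factored by dense Cholesky and stored packed. Memory scales with
  (cross-section dofs)² × layers (~2 GB at the desk scale) instead of
  with 3-D fill-in, and the result is exact to factorization accuracy
  (verified against SuperLU at 4e-13 relative);
* unstructured large systems fall back to ILU-preconditioned CG
  (relative residual 1e-10).

Rigid-body sufficiency of the constraints is checked before solving by
ranking the 6 rigid modes restricted to the constrained dofs; the error
message names the number of unconstrained modes.

Strain/stress recovery is per element at the centroid: the constant
element state for order 1, the average of the 4 Gauss points (equal to
the centroid value of the affine strain field) for order 2. Reported
stress maxima are raw per-element centroid values — no nodal averaging or
smoothing — with ties broken toward the lowest element id.

## Healing-window evaluation

Per callus element the principal strains give
`gamma_oct = (2/3)·sqrt((e1−e2)² + (e2−e3)² + (e3−e1)²)` and
`eps_vol = e1+e2+e3`. Zone rules (dimensionless strain, defaults
configurable and embedded in every report):

| zone | rule |
|---|---|
| understimulated | `gamma < 0.0025` and `abs(eps_vol) < 0.0025` |
| intramembranous | `gamma ≤ 0.05` and `abs(eps_vol) ≤ 0.05` |
| endochondral | `gamma ≤ 0.15` and `−0.15 ≤ eps_vol ≤ 0.05` |
| excessive | otherwise |

Upper bounds are inclusive — a state exactly on a boundary belongs to the
lower-strain zone — and the rules are evaluated in the order listed, so
they partition the plane. The ±5%/±15% structure follows the classical
tissue-differentiation thresholds; the exact values in the source
literature vary, which is why they are configuration, not constants.
Fractions are reported both volume-weighted and by element count (they
coincide exactly on the uniform voxel mesh); the healing window is the
union of the intramembranous and endochondral zones.

## Range-of-motion sweep

The carpal unit rotates rigidly about the cup center in steps (default
0.5° over ±40°, covering the clinical radial/ulnar deviation targets of
20–30°/30–40°). Contact is exact triangle–triangle intersection
(interval test on the plane-intersection line, with coplanar and
degenerate cases handled), behind an axis-aligned bounding-box broadphase;
an optional clearance epsilon turns it into a proximity query. Motion
limits are the last contact-free sampled angles scanning outward from
neutral; contact at neutral is a reported state, not an error. The test
oracle is an independent separating-axis implementation densely sampled at
step/100 on the same meshes.

## Shipped experiments and problem sizes

Desk scale (defaults): bone 200 mm, outer radius 12 mm, cortex 4 mm,
canal 6 mm, 4 mm gap at mid-shaft, 1 mm voxels → ~90k foreground voxels,
~540k tetrahedra, ~290k free dofs, a few minutes per variant on one CPU.
Loads: 1500 N axial compression plus 150 N transverse at the proximal
reference region (a walking-peak stand-in; patient-specific
musculoskeletal loads are not available, so these are explicit,
provenance-recorded configuration). The torsion case uses an equilibrated
force couple (±2000 N desk scale, ±400 N miniature, applied over the
x > 0 / x < 0 halves of the proximal set) sized so the callus strain
state sits inside the healing window rather than below the
understimulated floor. The miniature variants (bone 60 mm, same diameter
ratios, 400 N axial / 150 N transverse) are geometrically similar
seconds-scale versions used by the test suite.

For the nail-exchange experiment the slender-beam section-modulus oracle
predicts a peak-stress reduction of `100·(1 − (8/11)³) ≈ 61.5%`; the
voxel-FE result is lower (50–56% depending on scale) because the larger
nail's jagged voxelized surface concentrates stress and because the
construct is not a pure beam (load sharing with bone away from the gap).

## Numerical choices and edge cases

* Half-open conventions everywhere an interval decision is made
  (thresholds, gap slab, nail extent) so every point has a unique owner.
* Node sets use closed boxes; grid-aligned coordinates make membership
  unambiguous.
* The generator rejects geometrically infeasible specs naming the
  violated invariant (e.g. nail radius exceeding canal radius).
* Asymmetric tensors are rejected beyond a relative tolerance rather than
  silently symmetrized (the solver's own tensors are symmetric by
  construction; the tolerance matters for user-supplied input).
* JSON reports are written with sorted keys; two runs of the same case
  and seed are byte-identical.

## Known limitations

Idealized straight-cylinder geometry; no contact mechanics (see the
screw discussion above); linear kinematics only, so large-gap instability
is out of reach; threshold segmentation cannot separate metals of equal
greyvalue; the density–modulus calibration and zone thresholds are
literature-style defaults, not patient-calibrated values — conclusions
should be read as variant *comparisons* under identical assumptions, not
absolute stress or healing predictions.
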