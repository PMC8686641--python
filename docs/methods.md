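# Methods

## The model

The package simulates a resin plate ("pseudopalatal plate") bonded to the
denture-supporting palatal mucosa, which in turn adheres to rigid bone.
Both materials are homogeneous, isotropic, linear elastic; the analysis is
static, small-strain, with no contact or material nonlinearity. Units are
a consistent mm–N–MPa system.

Coordinates: `x` left–right (midline at 0), `y` anterior→posterior, `z`
from the bone surface (top) toward the oral cavity. The bite load acts in
−z, pressing the plate onto the mucosa.

**Boundary conditions.** The mucosa top ("bone") surface is clamped in
all components. The bite force (default 111 N — the subject-protocol
pain-onset force) is distributed over plate oral-surface nodes within a
patch radius (default 3 mm) of the plate centre, weighted by nodal
tributary area. A finite patch replaces the nominal centre point load
because a point load on tet4 elements has a mesh-dependent singular
stress, which would make the thresholded volumes resolution artefacts.
The patch radius is configurable and recorded in every report.

**Materials.** Plate: E = 2650 MPa, ν = 0.3 (acrylic resin in a humid
environment). Mucosa: the subject-specific modulus in the original
protocol is not public, so it is an explicit free parameter; the default
E = 3.0 MPa, ν = 0.45 is a representative oral-mucosa literature range
(soft, nearly incompressible). Both are configurable per study and echoed
in the provenance block.

## Synthetic palate geometry

The generator emulates the modelled region — the palate from mesial of
the first molars to distal of the second molars — as a rectangular
footprint (default 25 mm arch length × 30 mm width) with a cosine-arch
vault of configurable rise (default 8 mm; 0 gives a flat slab with
closed-form volumes and stress states, used by the verification
fixtures). Plate thickness defaults to 1.5 mm.

Mucosal thickness is sampled per segment from a 7-row × left/right grid
of 14 segments (the count matches the clinical measurement sites; their
true positions are unpublished, so the grid layout is a stand-in and
stays configurable). Default per-segment bounds rise from ~1–2.5 mm
anteriorly to ~3–5.5 mm posteriorly, inside the 1–6 mm range reported for
palatal mucosa. Sampling is uniform within bounds from a seeded
generator; segment-centre values are blended over the footprint by
clamped bilinear interpolation, so the sampled value is recovered exactly
at each centre and the surface is C0 between segments.

What the generator does **not** emulate: real vault asymmetry and
rugae/tori, the true spatial correlation of thickness, nonlinear and
time-dependent mucosa response, and any particular subject's geometry.
Consequently the study's *percentages are geometry-dependent*: passing
tests demonstrate the pipeline's mechanics and the qualitative
redistribution behaviour, not subject-specific numbers.

## Meshing

A structured grid is laid over the footprint (midline kept as a grid
line), node columns are extruded through the mucosa and plate, and every
hexahedral cell is split into six tetrahedra by the Kuhn rule, which is
translation-invariant and therefore conforming — in particular the
plate–mucosa interface is a shared triangulated surface, realising the
bonded (adhesion) condition by shared nodes. Through-thickness layers are
`ceil(t/h)` with a minimum of two for the mucosa (the relief decision
depends on the through-thickness stress gradient) and one for the plate.
Element order is linear (tet4); quadratic elements are out of scope.

The reference in-plane resolution is 0.5 mm (`PalateConfig.mesh_edge`);
the shipped study default is 1.5 mm (`StudyConfig.mesh_edge`), giving
~10⁴ elements and second-scale runtimes for the seven-scenario study while
leaving the qualitative findings unchanged. At 1.5 mm the baseline peak
mucosal von Mises is ≈ 0.15 MPa and rises toward the 0.20 MPa range end
under refinement; ratio-table entries at thresholds with zero baseline
volume are reported as not-applicable rather than silently zero.

Mesh I/O: ASCII VTU (preferred; part labels, segment ids, node-set masks
and result fields round-trip exactly) and Gmsh MSH 2.2 (part labels as
physical tags; node sets and segment ids do not survive, documented in
the reader). Both readers validate part labels and raise a format error
naming the missing field.

## Solver

Constant-strain tetrahedra, vectorised assembly into a sparse symmetric
stiffness, Dirichlet constraints by exact row/column elimination (clean
reaction recovery), and a sparse direct factorisation (SuperLU). The
relative residual of the reduced system is checked against 1e-8 and the
solve fails loudly otherwise — this also catches mechanically singular
configurations (e.g. a plate attached through a single hinge node) that
pass the graph-connectivity pre-check, which itself rejects fully
floating parts with a message naming them. Stress is recovered per
element (piecewise constant), and von Mises is √(3/2 s:s).

## Relief

Relief is realised by *decoupling* the bonded interface instead of
re-meshing a trimmed plate: in a linear bonded model with an open
0.25 mm gap no force can cross a relieved area, so removing the bond is
mechanically equivalent while every scenario keeps the same element set
(volumes stay directly comparable). Two conventions close the design:

* **Facet selection** projects element stress to the interface by the
  maximum von Mises over mucosa elements touching each facet (sharing at
  least one node) — conservative, relieving anything in contact with
  super-threshold stress.
* **Decoupling closure**: every interface node incident to a selected
  facet is duplicated and *all* plate elements touching it reconnect to
  the duplicate. Tractions on the selected region are then exactly zero;
  the decoupled zone extends one facet ring beyond the selection, again
  erring toward more relief.

Selection is single-pass: all regions derive from the no-relief stress
field, never from post-relief fields. Iterated ("repeated") relief is
deliberately not implemented.

A post-solve check compares the relative normal approach of each
duplicated pair with the physical gap depth and warns when the mucosal
bulge would close the 0.25 mm gap — there the no-force-transfer
equivalence breaks and a contact model would be needed; results in such
scenarios (typically the aggressive 0.04 MPa borderline) are upper
bounds on the redistribution effect.

Whether the original protocol trimmed only the plate or also re-meshed
the mucosa is not documented; the decoupling equivalence is this
package's reading of it. The borderline values are stress thresholds in
MPa (0.04–0.14), strictly inside the 0.02–0.20 MPa baseline range.

## Metrics

The stress-distribution volume V(θ) accumulates mucosa element volumes
with von Mises ≥ θ from the piecewise-constant element stresses (no nodal
interpolation — it would be inconsistent with the tet4 stress
representation). Both the cumulative "≥ θ" curve and disjoint per-bin
volumes are computed and written, since binned distribution plots admit
either reading. Ratios are percentages of the no-relief baseline; a zero
baseline volume makes a ratio undefined and it is reported as `n/a`,
never 0. The default reporting grid is 0.02–0.20 MPa in 0.02 steps.

## Reproducibility and problem sizes

All randomness is the thickness sampling, driven by one integer seed;
`run_study` is bit-reproducible (identical CSV bytes) for a fixed config.
Shipped problem sizes: the default study at 1.5 mm (~10,200 elements,
seven solves); verification fixtures (patch tests, uniaxial cube,
convergence slabs) are 10²–10⁴ elements. The refinement-convergence check
uses a slab whose dimensions make halving the edge length a true uniform
refinement in all three directions, and probes a fixed 3 mm ball with a
volume-weighted average, which is well-defined for element-constant
stress.

## Known limitations

* No contact: gap closure is detected and warned, not resolved.
* Linear kinematics and elasticity; mucosa viscoelasticity, nonlinearity
  and pain thresholds are out of scope.
* Structured meshing only; no unstructured/adaptive refinement, no
  curved-boundary fitting beyond the vertical vault profile.
* Single synthetic subject per study; no statistics across geometries.
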