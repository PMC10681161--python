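# Methods

## Model

The package simulates the soft-tissue response of the mid-face to a
LeFort I maxillary repositioning as a small-strain, isotropic
linear-elasticity boundary-value problem on a labeled tetrahedral mesh.
Each mesh region carries a constant (E, ν) pair; the load is purely
kinematic — a rigid displacement u = (0, Δy, Δz) prescribed on every
node of the LF1 segment (Δy = 5.4 mm advancement along +Y, Δz = 3.8 mm
impaction along +Z by default), with the top of the head, the back of
the head, the neck and the whole mandible fixed. There are no forces,
no contact and no material or geometric nonlinearity: a single linear
solve per configuration. Consistent units are mm / MPa / N.

Default materials: bulk soft tissue E = 0.1 MPa, ν = 0.45; bone
E = 5000 MPa, ν = 0.2. Bone is modeled as a very stiff elastic solid
rather than a rigid body; the prescribed LF1 values are still exact by
construction. In the homogeneous (H) model every muscle also carries
the bulk soft-tissue properties. The sensitivity study varies the four
muscle stiffnesses over literature ranges (buccinator, masseter,
zygomaticus major: 6.7–14.1 kPa; orbicularis oris: 14.6–22.0 kPa),
left/right members of a pair sharing one parameter, ν held at 0.45.

### Element and solver

The element is the 4-node constant-strain tetrahedron (K_e = V·BᵀDB,
D from the Lamé constants). TET4 at ν = 0.45 is mildly stiff near
incompressibility; the package's claims are about exactly representable
(affine) fields, symmetry, linearity and signed sensitivities, all of
which are insensitive to this, and refinement (smaller `element_size`)
is the documented mitigation for absolute accuracy. Elements with
volume ≤ 1e-12·(longest edge)³ are rejected as degenerate.

The global matrix is assembled region by region (vectorized over
elements). Because K depends linearly on each region's Young's modulus
at fixed ν, a per-region unit-modulus cache (`RegionStiffnessCache`)
turns a material sweep into a re-scaled sum plus a sparse LU
factorization (SuperLU) of the free-DoF block; solutions are accepted
at relative residual ≤ 1e-8 and Dirichlet values are re-inserted
exactly. Meshes at the default resolution have ~8k free DoF, so one
solve takes well under a second.

## The synthetic face phantom

Patient CBCT/MRI geometry is private, so the study runs on a
parametric phantom that reproduces the *mechanisms* of the clinical
model rather than its shape: an 84 × 60 × 90 mm block (X left/right,
Y posterior→anterior, Z inferior→superior) with

* an 18 mm posterior bone slab split into mandible (z < 18), LF1
  segment (24 ≤ z < 42, detached from the rest of the skeleton by 6 mm
  soft "osteotomy gap" layers below, above and behind it) and skull
  base (z ≥ 48);
* a 42 mm soft-tissue shell with the free skin at y = 60;
* seven muscle boxes: the orbicularis oris spans from the LF1 anterior
  face to just behind the upper-lip skin (series coupling), masseter
  and buccinator rise from the fixed mandible face into the lateral
  tissue (tether coupling), and zygomaticus major hangs from the fixed
  upper-lateral bone. Minor mimic muscles are not resolved — they are
  part of the bulk soft tissue, as in the imaging protocol the model
  emulates;
* four landmark targets snapped to the nearest skin node (ties broken
  by lowest node index): N (0, 60, 48), UL (0, 60, 34),
  LC/RC (±28, 60, 30).

The osteotomy gaps are a modeling necessity the source geometry gets
from the actual bone cuts: without them the mobile segment would share
nodes with fixed bone and the Dirichlet sets would clash.

### Meshing and symmetry

The block is meshed on a structured grid (cells no larger than
`element_size`, default 6 mm) and every hexahedral cell is split into
five tetrahedra with checkerboard parity. The two parity splits are
mirror images of each other, so with an even cell count across the
width — enforced — the mesh is *exactly* mirror-symmetric about the
midsagittal plane, which is what makes the LC/RC symmetry check hold to
1e-6 mm (observed ~1e-14) rather than only to discretization error.
Cells are labeled whole, by their center, with priority
bone > muscle > soft tissue. Every default region boundary is a
multiple of 6 mm, so at h = 6, 3, 1.5 … the meshed regions coincide
exactly with the configured boxes (region volumes are invariant under
refinement, not merely convergent).

### Population

The eight-subject cohort is generated by seeded ±10% uniform
perturbations of the muscle box dimensions and shell thickness
(attachments to the bone face preserved; invalid draws are retried on
the next seed substream). Two honest caveats: (i) perturbations are
quantized to cell granularity, so at the default resolution the
realized anatomies often remain left/right symmetric and some subjects
share individual muscle volumes (the eight 7-muscle volume tuples are
pairwise distinct); (ii) the variation explores mesh-topology-level
anatomy only — it does not emulate real inter-patient shape variation,
facial asymmetry, or imaging/segmentation error. Passing tests
therefore demonstrate correctness of the machinery and robustness of
the *sign* of the muscle effects to moderate anatomical variation, not
clinical accuracy on real faces.

## Design of experiments and statistics

The "optimal space-filling" design is a seeded maximin Latin
hypercube: 200 candidate designs, each column one point per stratum
midpoint with independent permutations, keeping the candidate whose
minimum pairwise distance in unit coordinates is largest (first on
ties). Defaults: 25 points over the 4 muscle parameters.

Local sensitivity of landmark L to muscle i is
S_i(L) = 100·[Y_L(x_i = max, rest mid) − Y_L(x_i = min, rest mid)] /
Y_L(all mid) — a full-range signed percentage with an all-mid
normalization (2·n+1 solves per subject). This denominator convention
is a package definition; absolute magnitudes depend on it, signs do
not. Left and right cheek sensitivities are averaged into C before
aggregation. A muscle capturing zero elements leaves the stiffness
matrix bitwise unchanged, so its sensitivity is exactly 0.

The Wilcoxon signed-rank test drops zero differences, assigns average
ranks to ties and enumerates all 2ⁿ sign assignments for n ≤ 12
(normal approximation with tie and continuity corrections beyond);
tests are two-sided by default with one-sided alternatives available.
With eight same-sign subjects the exact two-sided p is 2/2⁸ =
0.0078125 — the package reports this value, not any software-specific
variant. Paired comparisons of the homogeneous model against the
per-subject DoE extremes (max/min per landmark) use the same test; a
degenerate sample (H coinciding with the extreme for every subject)
reports p = NaN rather than an arbitrary number.

## Validation stage

The predicted skin surface is aligned to the reference surface by
point-to-point ICP (nearest-neighbor correspondences on a KD-tree,
closed-form Kabsch update restricted to proper rotations, centroid
initialization, tolerance 1e-6 mm on the RMS improvement; the RMS
trace is non-increasing). Vertices displaced less than the crop
threshold (default 0.1 mm — a package choice, exposed as a flag) are
sliced away together with their triangles. Distances are signed
point-to-*triangle*: nearest point on the reference triangulation
(in-plane projection when the barycentric coordinates admit it,
otherwise the nearest edge point; zero-area reference triangles are
skipped), signed by the reference facet normal — positive outside. A
vertex-to-vertex variant exists for comparison with tools that report
point-to-point distances. Summaries are the mean and sample SD;
colormaps are exported as PLY (per-vertex `quality` scalar plus
diverging colors on a symmetric scale about zero), legacy VTK and CSV.

Reference postoperative surfaces are not public either, so the
end-to-end validation test fabricates one: the FEM-displaced skin plus
seeded Gaussian vertex noise and a known rigid misalignment. With zero
noise the loop must close (ICP recovers the offset to 1e-6, mean
|signed distance| < 1e-5 mm); with noise the mean signed distance
stays near zero while the SD tracks the noise level. This checks the
validation *machinery*, not prediction accuracy against real scans.

## Orchestration and reproducibility

`run_full_study` executes, per subject, the H model, the 25-point DoE
and the sensitivity sweep — 8 × 25 = 200 design-point solves plus
8 × (1 + 1 + 9) auxiliary solves at defaults — and writes per-subject
CSV/VTK artifacts, population tables, the comparison box plot, the
validation bundle and a manifest (versions, seeds, per-stage solve
counts, SHA-256 of every output file). One master seed spawns the
anatomy, design and validation substreams, so reruns are byte-identical
on all CSV outputs and any stage is reproducible in isolation. Solves
run sequentially; nothing in the pipeline is order-dependent.

Problem sizes used throughout (default 6 mm elements, ~10.5k
tetrahedra, 25 design points, 8 subjects) were chosen so a full study
completes in minutes on one CPU; all scientific claims made by the
test suite are resolution-independent properties (exact representability,
symmetry, linearity, signs, enumeration exactness).

## Known limitations

* TET4 + ν = 0.45 is dispersion-stiff near incompressibility; no mixed
  or higher-order formulation is provided.
* Dirichlet-only loading: no lip sliding interface, no muscle
  activation, no mandibular (BSSO) movement, no nasal cartilage.
* The phantom's muscle attachments encode qualitative anatomy only;
  an axis-aligned box cannot represent the oblique zygomaticus course,
  so its attachment is approximated by a box touching the fixed
  upper-lateral bone.
* Sensitivity magnitudes are phantom- and definition-specific and are
  not comparable to patient-derived values; only directions and the
  statistical machinery carry over.
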