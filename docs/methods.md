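# Methods

`cranioload` models the mechanical loading the masticatory system places
on the infant cranium over the first 48 months of life: how large the
jaw-closing muscle forces are at each age, what temporal-fascia force is
needed to stabilize the zygomatic arch, what bite forces and
temporomandibular-joint (TMJ) reactions result under three bite modes,
and how von Mises strain and stress distribute over the skull.  Because
the clinical CT geometries such analyses are normally built on are not
redistributable, every input is synthesized by the package itself; this
note records the model, its assumptions, and the choices made where the
problem was genuinely open.

## 1. The skull surrogate

`anatomy.build_skull_mesh` voxelizes a stylized skull from signed-distance
primitives on a uniform grid and splits each occupied cube into five
tetrahedra (alternating parity, so neighbouring cubes share face
diagonals).  The solid has six parts:

* an ellipsoidal **calvarial shell** (default semi-axes 55 x 70 x 50 mm at
  48 months, 7 mm thick), split by position into frontal, parietal,
  occipital and skull-base regions;
* a **skull-base plate** closing the shell inferiorly, with a footprint
  shrunk to 80% of the calvarial outline so the zygomatic arches can pass
  it freely;
* a vertical **facial plate** (10 mm thick) with an **alveolar/palatal
  ridge** at its base carrying the bite points;
* a solid **zygomatic body** buttressing each anterior arch root — without
  it the arch root rotates under masseter pull and the fascia-balance
  problem degenerates;
* two tubular **zygomatic arches** (radius 3 mm) bowed 10 mm laterally so
  the free span stands clear of the braincase wall, running at the level
  ~9 mm above the occlusal plane from the zygomatic body to the lateral
  skull base.

One half (x >= 0) is voxelized and reflected about the mid-sagittal
plane, so the mesh is *exactly* bilaterally symmetric and every left/right
node set maps onto its twin under x-negation; left-side landmark nodes are
found by nearest-point search and right-side ones are defined as their
mirror images.  Disconnected stray voxel clusters are discarded before
tetrahedralization and the final mesh is verified to be a single connected
component of positively oriented elements.

**Age scaling.**  All reference lengths are 48-month values.  A head-scale
factor `s(a) = 0.78 + 0.22*sqrt((a-3)/45)` (fast early growth, slowing
later) multiplies every dimension; facial *heights* are additionally
raised to the `facial_growth_exponent` (default 1.25) power of `s` so the
face grows faster in height than in breadth.  The voxel pitch (default
3 mm at 48 months) scales with `s` too, keeping resolution relative to
feature size constant across ages; the builder refuses configurations
whose shell would be thinner than two voxels.

**Sutures.**  Compliant bands (metopic, coronal, sagittal, lambdoid,
anterior fontanelle, a facial suture system, and a skull-base joint) are
carved out of the bone regions as geometric strips.  The configured width
(2 mm at 3 months, scaled with age) is clamped from below to 1.2 voxel
pitches so bands remain contiguous at desk resolution.  A patency
schedule maps age to the set of open joints — all joint classes at 3
months, calvarial sutures and fontanelle at 6, the anterior fontanelle
only at 12, none from 24 — and closed bands are relabelled as the bone
they run through.  The schedule is validated to be monotone (joints only
ever close).

**Calibration.**  Absolute bite forces depend on anatomy that a stylized
surrogate cannot reproduce, so the default geometry was calibrated once —
using the rigid-body lever oracle and full finite-element runs at 48
months — to place the published force *ratios* in their reported ranges
(incisor/molar bite-force ratio, fascia/masseter balance, fascia-induced
bite-force reduction), and then frozen.  The decisive quantities are the
bite-point and TMJ lever arms, the positions of the masseter origins along
the arch (anterior third: mostly on the zygomatic body, partly on the free
span), and the positions of the fascia insertions (around arch mid-span,
where a newton of fascia force is most effective).  After calibration the
surrogate's emergent absolute bite forces (~80 N at 3 months to ~215 N at
48 months, bilateral molar biting) happen to bracket the published
90.5-184.2 N, but only the ratios are treated as reproducible.

## 2. Synthetic CSA cohort and growth regression

`generate_csa_cohort` emulates a 51-individual cohort, one or two
individuals per month of age over 0-48 months.  Per muscle, the expected
maximum anatomical cross-sectional area (CSA_max, cm^2) follows a
monotone PCHIP curve through control ages {0, 3, 18, 36, 48} whose 3- and
48-month anchors are the published mean per-side forces divided by the
37 N cm^-2 muscle stress factor (temporalis 30.9→87.0 N, masseter
25.6→69.6 N, medial pterygoid 23.1→58.9 N).  The temporalis trajectory is
given its characteristic fast-slow-fast shape (62% of the rise by month
18, 75% by month 36); the other muscles are closer to linear.  Noise is
multiplicative, mean-preserving lognormal with configurable coefficient
of variation (default 10%), seeded.  The generator reproduces its inputs
bit-identically for a given (parameters, seed).

What the cohort does **not** emulate: real inter-individual covariance
between muscles, sex or ethnicity structure, measurement error from plane
misalignment, and the true (unpublished) distribution of the clinical
sample.  A green recovery test therefore establishes that the regression
machinery is unbiased on data of the stated noise class — not that the
published curves were re-derived.

`fit_growth` converts CSAs to forces and fits, per muscle, the same
monotone family (values at the fixed control ages, parameterized as a
positive base plus non-negative increments) by least squares, with an
optional second-difference curvature penalty whose weight is chosen by
deterministic 5-fold cross-validation.  On noise-free data the
unpenalized fit has zero cross-validation error, is selected, and
recovers the generating curve to optimizer precision (<1e-6 relative).
95% confidence bands come from a seeded residual bootstrap (500 resamples
by default).  Known limitation: the value at 48 months is an edge
estimate driven by the last ~dozen records; a correlated noise excursion
there moves the estimate by the size of the excursion, which no
data-driven smoother can undo (the default cohort seed exhibits exactly
this for the temporalis: a +9% late-window draw).

## 3. The CSA_max protocol

`csa_max` measures a muscle mask with two parallel planes, P2 exactly
2 mm above P1 along the (unit) plane normal, and returns the mean of the
two in-plane areas.  Each plane's area is voxel-counted over a
one-voxel-thick slab with triangular (linear-interpolation) weights, so a
plane falling between voxel layers averages the adjacent layers rather
than double-counting them; the estimate is exact for axis-aligned normals
up to boundary discretization.  Planes that miss the mask raise an
explicit empty-section error.  `peak_force` multiplies CSA_max by the
muscle stress factor and is exactly linear.

## 4. Muscle and fascia force vectors

42 landmarks mark origins and insertions: temporalis 1-12, masseter
13-24, medial pterygoid 25-36, temporal fascia 37-42, each muscle with
three origin/insertion pairs per side.  Insertion landmarks lie on the
mandible, which is deliberately not modelled, so they are stored as
coordinates only.  Each vector points from an origin landmark toward its
insertion landmark; the per-side muscle force is divided evenly over the
side's vectors (default 3 per side; the fascia defaults to 6 total with 8
selectable, mirroring an internal inconsistency in the published vector
counts).  A vector's force is spread uniformly over its attachment patch:
all mesh nodes within 4 mm graph-geodesic distance (Dijkstra over mesh
edges) of the origin node.  Fascia vectors originate on the superior
border of the zygomatic arch and point toward the fascia landmarks over
the temporalis; **no counter-force is applied at the temporal lines**,
reproducing the source simplification — which is exactly why adding the
fascia reduces predicted bite force.

## 5. Finite-element core

Standard small-strain linear elasticity on 4-node constant-strain
tetrahedra, isotropic Hooke materials, in a consistent mm / N / MPa
system.  Bone: E = 421 MPa at 3 months + 125 MPa/month to 48 months,
nu = 0.22.  Cranial joints: E = 30 MPa at 3 months + 100 MPa/month up to
month 12 (frozen after), nu = 0.30.  Ages below 3 months are outside the
material domain.  Constraints fix all three translations of the bite
nodes and two TMJ nodes per side; the reduced system is solved by sparse
LU (SuperLU), the contract being the residual bound ||Ku-f|| <= 1e-8||f||
rather than the method.  Reactions are recovered from the unmodified
operator, so global force balance holds to solver precision.  Well-
posedness requires at least three non-collinear fully-fixed nodes (three
suffice when all translations are fixed).

Element strain is B u_e; stress C eps.  Von Mises stress is computed from
principal stresses; the von Mises *equivalent strain* (reported in
microstrain) divides the principal-strain form by (1 + nu') with nu' the
element material's Poisson ratio, the common commercial-solver
convention; nu' = 0.5 is available as an override.  Nodal probe values
are volume-weighted averages of adjoining element values.

Numerical notes: constant-strain tets are stiff in bending — the
cantilever validation (8 elements through the depth) reaches
Euler-Bernoulli within 15%, and the voxelized arch is likewise stiffer
than an ideal beam of its nominal radius; the calibration absorbs this.
All solutions are exactly linear in the loads, which the fascia solve and
several tests exploit.

## 6. Fascia balance and the bite pipeline

The temporal-fascia force (TFF) is defined as the minimum force applied
along the arch's superior border that removes the *inferior deflection of
the arch mid-span node* under the muscle loads — the balance criterion is
operationalized as zero vertical displacement at that control node
(configurable), since the source describes only "resisting inferior
deflection".  By linearity the balancing scale is s* = -u0/du from one
baseline and one unit-fascia solve; both arches must balance and the
larger scale is taken, a verification re-solve checks the residual
against the 1e-6 mm tolerance, and an un-deflected arch yields TFF = 0
with a warning.  A bisection search over the scale serves as the
independent oracle in the tests.  An arch-length transfer
(TFF_target = TFF_ref x L_target/L_ref) mirrors the published
force-per-millimetre scaling procedure and agrees with per-age direct
balancing to ~5% on the default surrogate (20% tolerance frozen in the
test).

`run_bite` assembles per-age muscle forces from the growth model,
constrains the mode's bite nodes (alveolar-margin nodes before 12 months,
cusp nodes after) plus both TMJs, optionally adds the balanced fascia
load, solves, and reports: bite force as the sum of reaction-vector
magnitudes over bite nodes (the occlusal z-component is reported
alongside, since the published scalar is not defined), per-side TMJ
reactions (magnitude of the summed per-side reaction vector), and von
Mises strain/stress at nine facial probe locations with their mirror
values for asymmetry analysis.  `run_series` sweeps (age, mode, fascia)
factorially, records failed cells without aborting, and derives the
mode2/mode1 ratio, fascia reduction percentages and TFF ratios per age.

The rigid-body oracle solves the 6-equation force/moment balance with
point supports at the bite and TMJ centroids, assuming the bite reaction
is purely occlusal; bilateral symmetric cases are thereby determinate
(the classic jaw-lever balance) and mode 3 is solved by min-norm least
squares.  FEM reactions satisfy the same balance identically (Newton);
the oracle's *split* between bite and TMJ differs from the elastic one,
which is statically indeterminate — the oracle is a cross-check and
calibration device, not a substitute solver.

## 7. Reproducibility

A single global seed fans out to per-stage seeds by CRC-32 hashing of the
stage name (all below 2^31).  Identical (configuration, seed) reproduce
bit-identical cohort tables, meshes and result tables.  The YAML/JSON
configuration is schema-validated with unknown keys rejected; a JSON
manifest records the configuration hash, seed, package version and
per-stage status.

## 8. Known limitations

* The surrogate reproduces topology and lever geometry, not anatomy;
  absolute forces, reactions and strain magnitudes are not comparable to
  clinical values — only ratios, orderings and trends are.
* Linear elasticity, linear tets, no suture contact or nonlinearity, no
  mandible, no organs, biting only (no chewing dynamics), by design.
* The TFF balance reconstruction is faithful to the described intent but
  the original sensitivity-analysis protocol (supplementary material) is
  not reproducible from the main text.
* Blocky voxel beams make the arch's effective stiffness resolution-
  dependent; the calibrated ratios hold at the frozen default resolution.
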