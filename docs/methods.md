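# Methods

This note documents the geometric model behind `legalign`, the numerical
choices, the phantom generator used for validation, and the package's known
limitations.

## Inputs and assumptions

The unit of analysis is one leg: a femur mesh and a tibia+fibula mesh
(triangle surfaces, millimetres, any common rigid frame) with named articular
regions given as face-index sets. The tibia and fibula may arrive as one
combined mesh; only labeled articular facets enter any computation, so shaft
geometry is inert. Units are never guessed — `units.scale` only rescales
explicitly. Region boundaries (the sulcus terminalis separating condyles from
trochlea, the trochlear groove separating the condyles, the medial gutter
separating plafond from medial malleolus) are the labeler's responsibility;
the package validates disjointness and presence but does not detect the
boundaries on the mesh. A coarse orientation hint — approximate patient
right, anterior and cranial directions of the input frame, nine numbers —
resolves global sign ambiguities (which way is cranial, which way is patient
right); everything metric is derived from the surfaces themselves.

## Surface data and shape fits

"All available surface data" of a region is materialized as per-face
centroids weighted by triangle area. Area weighting makes every downstream
quantity invariant to retriangulation of the same surface, which vertex sets
are not; the regression suite checks that doubling mesh density moves every
joint centre by less than 0.05 mm.

Planes are weighted total-least-squares fits (smallest eigenvector of the
weighted scatter). Spheres and cylinders are *geometric* fits minimising the
weighted sum of squared orthogonal distances, refined by
Levenberg–Marquardt with analytic Jacobians from an algebraic initialisation
(linear least squares for the sphere; for the cylinder, each principal
direction of the point set is tried as an axis seed, scored by an algebraic
circle fit in its orthogonal plane, and the best seed refined). Geometric
fits are the contract because articular patches cover only part of the
primitive, and partial coverage biases algebraic fits. Convergence tolerance
is 1e-10 (`fit.tolerance`) with at most 200 iterations (`fit.max_iter`).

Cylinder identifiability: if a second refined axis, clearly different in
direction, explains the data within 10 % of the best residual, the axis is
declared unidentifiable (sphere-like data) and a degeneracy error raised.
On genuine two-condyle arc bands a wrong axis is worse by orders of
magnitude, so the check never fires on valid anatomy.

The cylinder model is infinite: only the axis and its intersections with the
bone are consumed, so patch extent along the axis is irrelevant.

## Centres, frames, angles

Joint centres and frames follow the constructions summarised in the README.
Two conventions deserve explicit statement:

* **Extremal points.** The condylar tangent takes, per condyle, the vertex
  most distal in the leg frame; the supracondylar plane takes the most
  proximal vertex of trochlea and both condyles in the femoral frame.
  Ties within 1e-9 mm are averaged into one point, which makes flat-bottomed
  surfaces deterministic and symmetric. A `sfj.mode = border_band` variant
  fits a least-squares plane to the top 2 % of each region's height range
  instead of using single extremal points; the three-point construction is
  the default.
* **Sign algebra.** Clinical angles are side-aware: the medial direction of a
  frame is `-side_sign * x` (x always points to the patient's right). HKAA is
  the angle between the projected proximal mFA and distal mTA rays, taken on
  the medial side (the side their bisector points to). mLDFA is measured
  against the lateral-pointing condylar tangent with the proximal mFA ray;
  mMPTA and the two sagittal slope angles are measured against the
  *distal*-pointing mTA ray, which is what makes varus give mMPTA < 90 and a
  posterior slope give 90 − s, matching the standard clinical convention.
  FVA/TTA are acute angles of projections in the axial plane; the direction
  label comes from the side-adjusted signed angle (anteversion when the neck
  rotates anteriorly; external torsion when the intermalleolar axis rotates
  externally). mMPTA uses the *combined* plateau plane; the per-compartment
  planes are reserved for the sagittal slope angles.

The distal femoral joint centre intersects the cylinder axis with the whole
femur by default (`center.femoral_intersection_scope = bone`); restricting to
the condylar regions is available for cortices distorted by osteophytes, but
arc-band patches that do not cross the axis then raise a construction error
rather than guessing.

## Extension prerequisite and virtual extension

Coronal angles are defined with the knee extended: the residual is the angle
between mFA and mTA projected onto the leg sagittal plane. Policy
(`extension.policy`): `auto` (default) virtually extends when the residual
exceeds 0.5°; `strict` raises; `ignore` computes anyway and records a
warning, for fixed flexion deformities where the per-bone frames remain
meaningful. Virtual extension rigidly rotates the tibia+fibula about the
condylar cylinder axis — the only consensus-derived medial-lateral knee axis;
a functional flexion axis would be an alternative but is not implemented —
and iterates (rotate → recompute tibial landmarks → rebuild leg frame),
because the ankle centre moves with the tibia and the residual is implicit.
Tolerance 0.01°, at most 50 iterations; in practice one iteration suffices
for pure flexion because the built rotation is the exact inverse. The femur
is never moved, and no joint-gap or soft-tissue modelling is attempted.

## Phantom generator

The phantom emulates segmented bone models with labeled articular surfaces;
all validation traces to it. Construction (emission frame: x patient-right,
y anterior, z cranial):

* condylar surfaces: two arc bands (110° posterior to 30° anterior of the
  distal pole) of one cylinder, radius 22 mm, embedded in a closed capped
  cylinder "knee shell" so axis–bone intersections behave as on a real bone;
  the trochlea is a disjoint anterior band;
* femoral head: labeled 85°-cap of a closed 24 mm sphere at the hip point;
  neck: a full cylindrical ring whose centroid is exactly on the neck axis,
  built at the requested version angle *about the mechanical femoral axis*
  and descending at a fixed 40° pitch;
* plateaus: planar rectangles rotated per compartment by their posterior
  slopes; plafond and malleolar facets: rectangles arranged symmetrically
  about the true ankle centre and rotated by the torsion angle *about the
  mechanical tibial axis*;
* coronal deformities tilt the mechanical axes (hip and ankle deviate
  medially for varus) while the joint-line structures stay at the knee, so a
  varus build shows up consistently in HKAA, mLDFA and mMPTA;
* knee flexion is a rigid rotation of the tibia+fibula about the condylar
  axis; Gaussian noise (seeded) is applied along vertex normals, mimicking
  segmentation surface error while keeping labeled regions on-surface.

Because version and torsion are built about the mechanical axes, the true
FVA/TTA equal the built values exactly and are decoupled from coronal
deformities. Ground truth (angles plus every construction point and axis) is
derived from the construction vectors before tessellation and noise, so it is
independent of mesh density and noise; the truth code uses its own local
vector algebra, separate from the measurement modules.

Default dimensions (femur 420 mm, tibia 380 mm, head radius 24 mm, condylar
radius 22 mm, 15° anteversion, 25° external torsion) sit at adult anatomical
norms. Validation presets: NEUTRAL; VARUS5 (2.5° femoral + 2.5° tibial, with
7° slopes); VALGUS8 (−4°/−4°); FLEXED10; TORSION_SWEEP (−20…30°); NOISY
(σ = 0.2 mm, ten seeds). Noise-free presets at 1.5 mm density recover every
angle within 0.2°; noisy replicates within 1.0°. Those tolerances were fixed
from the construction's error budget (extremal-vertex selection under noise
dominates) and the suite asserts them.

**What the phantom does not emulate:** real articular surfaces are not exact
geometric primitives (condyles are neither circular nor coaxial; plateaus are
not planar), segmentation error is spatially correlated rather than i.i.d.,
and region boundaries on real bones are drawn by a human. Passing phantom
tests therefore demonstrates that the measurement chain is correct *given
the consensus constructions and correct labels*, not that results on
clinical segmentations reach phantom-level accuracy.

## Numerical choices and degenerate inputs

Duplicate mesh vertices are merged within 1e-6 mm at load (grid snap; face
order, and hence label indices, are stable). STL stores float32, so a 400 mm
coordinate survives an STL round trip only to ~1e-5 mm; the double-precision
ASCII PLY writer preserves 1e-6 mm. Frames are re-orthogonalised after
construction and validated to 1e-9 (orthonormality and right-handedness).
Sanity guards fail loudly instead of proceeding on pathological
segmentations: mechanical axes shorter than 10 mm, hip–ankle distance under
100 mm, a medial-lateral axis within 0.1° of the longitudinal axis, plateau
or malleolar centroids closer than 1 mm, and a combined plateau plane within
0.1° of the coronal plane all raise distinct errors. Angle computations clip
cosines to [−1, 1]; FVA/TTA fold signed axial angles into [−90°, 90°] so the
reported value is always the acute line angle.

Determinism: the analysis path contains no randomness; the only random
element in the package is the phantom's seeded surface noise. Two runs on
identical inputs produce byte-identical reports except for the timestamp.

## Known limitations

* No segmentation, DICOM/NIfTI reading, or mesh repair beyond vertex merging.
* No automatic detection of the sulcus terminalis / medial gutter splits.
* Sphere and cylinder are the only articular primitives (no ellipsoids, no
  robust M-estimators); they are the package defaults behind a fitting
  interface, not a claim that anatomy is cylindrical.
* The posterior condylar axis, joint-line convergence angle, anatomical
  (shaft) axes, contralateral mirroring workflows and normative-range
  interpretation are out of scope.
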