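# legalign

Standardized 3D leg alignment analysis from labeled bone-surface meshes.

Preoperative planning of osteotomies around the knee increasingly works on 3D
bone models segmented from CT, but the literature derives axes and joint
orientations from those models in wildly inconsistent ways. `legalign`
implements a single, fully specified measurement chain for surgeons and
biomechanical engineers: from a femur mesh and a tibia+fibula mesh whose
articular surfaces are labeled, it derives the joint centres, the anatomical
coordinate systems and the eight clinical alignment angles, using *all
available articular surface data* rather than single landmark points.

## The measurement chain

**Joint centres.** The hip centre is the centre of a geometric
(orthogonal-distance) sphere fit to the femoral-head surface. The distal
femoral joint centre comes from a cylinder fit to the pooled medial and
lateral condylar surfaces: the cylinder axis is intersected with the femur
and the midpoint of the two extreme intersections taken. The proximal tibial
centre is the midpoint of the two plateau area-weighted centroids; the ankle
centre is the single pooled centroid of the plafond and both malleolar
facets. These centres define the mechanical axes

```
mFA = knee_femoral -> hip        (mechanical femoral axis)
mTA = ankle -> knee_tibial       (mechanical tibial axis)
mLA = ankle -> hip               (mechanical leg axis, Mikulicz line)
```

**Coordinate systems.** Each frame has x medial-lateral (pointing to the
patient's right), y posterior-anterior (pointing anteriorly) and z
distal-proximal (pointing cranially). The femoral (tibial) frame has its
origin at the distal femoral (proximal tibial) joint centre, z along mFA
(mTA), and x from the condylar cylinder axis (plateau-centroid axis)
projected along z onto the axial plane; y completes the right-handed triad.
The leg frame shares the femoral origin with z along mLA and x again from
the condylar axis, so it never depends on tibial geometry.

**Joint orientations and angles.** With the knee extended (mFA ∥ mTA in the
leg sagittal plane — enforced, or realised by virtually rotating the tibia
about the condylar axis):

| angle  | plane            | construction                                              |
|--------|------------------|-----------------------------------------------------------|
| HKAA   | leg coronal      | medial angle between projected mFA and mTA                 |
| mLDFA  | leg coronal      | lateral angle between mFA and the condylar tangent (DFJ)   |
| mMPTA  | leg coronal      | medial angle between mTA and the combined plateau plane    |
| mPDFA  | femoral sagittal | posterior angle between mFA and the supracondylar plane    |
| mMPPTA | tibial sagittal  | posterior angle between mTA and the medial plateau plane   |
| mLPPTA | tibial sagittal  | posterior angle between mTA and the lateral plateau plane  |
| FVA    | femoral axial    | acute angle, neck–femur axis vs condylar ML axis           |
| TTA    | tibial axial     | acute angle, intermalleolar vs plateau ML axis             |

Neutral values are HKAA = 180° and 90° elsewhere; varus gives HKAA < 180,
mLDFA > 90, mMPTA < 90; a posterior tibial slope of s° gives 90 − s.
FVA/TTA carry ANTEVERSION/RETROVERSION and EXTERNAL/INTERNAL labels.

Because no public dataset ships the required labeled meshes, the package
includes a **phantom generator**: parametric synthetic legs (deformity
angles, version/torsion, slopes, flexion, mesh density, surface noise) whose
true angles are known in closed form, so the entire pipeline is validated
against analytic ground truth.

## Worked example

```python
import dataclasses
import legalign as la

spec = dataclasses.replace(
    la.PhantomSpec(),
    femoral_varus_deg=2.0, tibial_varus_deg=1.5,
    posterior_slope_medial_deg=7.0, posterior_slope_lateral_deg=5.0,
)
femur, tibfib, truth = la.generate_phantom(spec)
report = la.analyze_leg(femur, tibfib)
for name, value in report.angles().items():
    print(f"{name:12s} {value:8.2f}   (truth {truth.angles()[name]:7.2f})")
```

prints

```
HKAA_deg       176.50   (truth  176.50)
mLDFA_deg       92.00   (truth   92.00)
mMPTA_deg       88.50   (truth   88.50)
mPDFA_deg       90.00   (truth   90.00)
mMPPTA_deg      83.00   (truth   83.00)
mLPPTA_deg      85.00   (truth   85.00)
FVA_deg         15.00   (truth   15.00)
TTA_deg         25.00   (truth   25.00)
```

The built 2° femoral + 1.5° tibial varus shows up as HKAA = 176.5°
(= 180 − 3.5), mLDFA = 92°, mMPTA = 88.5°; the 7°/5° posterior slopes give
mMPPTA = 83° and mLPPTA = 85°; the default 15° anteversion and 25° external
torsion are recovered exactly.

The same pipeline runs from the shell on mesh files:

```bash
legalign phantom --preset NEUTRAL --out-dir demo/
legalign analyze --femur demo/femur.stl --femur-labels demo/femur_labels.json \
    --tibfib demo/tibfib.stl --tibfib-labels demo/tibfib_labels.json \
    --side right --out demo/report.json
legalign validate --mesh demo/tibfib.stl --labels demo/tibfib_labels.json \
    --bone tibia_fibula --side right
```

Input meshes are STL or PLY in millimetres; labels are a JSON sidecar mapping
region names to 0-based face indices (a PLY `region_id` face property with a
small mapping table is accepted as an alternate dialect).

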