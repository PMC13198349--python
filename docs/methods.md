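# Methods

## The collision model

A leadless pacemaker is modeled as a rigid right circular cylinder with flat
caps — no fixation helix, no hemispherical nose — characterized by length
`L` (mm) and diameter `d` (mm). At every node of the septal endocardial
surface a cylinder is seated with its base on the surface and its axis along
the inward surface normal (area-weighted average of incident face normals,
sign-fixed toward the cavity centroid). The device is fully intracavitary:
no septal embedding depth is modeled, since the implant target is the
surface itself. Every structure is advected by the same mesh motion, and the
device rides its attachment node; by default its axis is re-evaluated from
the deformed surface each frame (`per_frame_normals`), with an option to
carry the end-diastolic axis rigidly for sensitivity comparisons.

Collision is **solid–solid overlap with no minimum-penetration threshold**:
tissues are rigid, and any contact in any of the cardiac phases makes a site
positive for that structure. This deliberately overestimates clinical risk —
real tissue yields — but gives a conservative, parameter-free criterion.
Per-frame tests are discrete; swept volumes between frames are not checked,
so a structure passing entirely through the device between two phases would
be missed (negligible at 10 phases per cycle given cardiac velocities).

### Overlap predicate

`cylinder_mesh_overlap` decides overlap between the cylinder solid and a
closed triangle-mesh solid as the union of three tests:

1. **Surface test** — some face comes within `radius` of the axis segment
   with the closest triangle point lying between the two cap planes, or the
   face crosses a cap plane with its intersection segment passing within
   `radius` of the cap center. For a point between the cap planes, distance
   to the axis segment equals its radial distance, so the first clause is an
   exact membership test there; the cap clause covers the end-cap corners.
2. **Containment test** — the axis midpoint lies inside the mesh
   (ray-parity with degenerate-ray re-casting), catching a cylinder wholly
   swallowed by a structure.
3. **Piercing test** — some mesh vertex lies inside the cylinder, catching
   thin structures that pass between surface contacts.

All distance comparisons use an absolute tolerance of 1e-6 mm. Spatial
pruning bounds each face by its circumradius around the centroid and
discards face/cylinder pairs farther apart than `L/2 + radius + circumradius`;
all kernels (point–triangle, segment–segment, segment–triangle,
Möller–Trumbore ray casting) are batched numpy over candidate pairs.

An independent **Monte-Carlo oracle** (`overlap_oracle`) samples points
uniformly in the cylinder solid and, by rejection in the bounding box, in
the mesh solid, reporting overlap if any sample lands in the other solid.
It shares no logic with the analytic predicate beyond point-in-mesh ray
casting and is used only for verification. Because an n-sample oracle cannot
resolve sliver contacts, oracle-equivalence runs only admit scenes passing a
margin certificate (`certify_scene`): either every face clears the axis
segment by more than `radius + 0.5 mm` with no containment either way
(certified gap), or some point sits at least 1 mm interior to both solids
(certified overlap, resolvable volume ≥ a 1-mm ball). The gap certificate
reuses the segment–triangle kernel; that kernel is itself tested against
dense dual sampling, keeping the oracle check non-circular.

### Attachment-site exclusion

Faces of the RV wall whose centroid lies within `exclusion_radius`
(default 10 mm, Euclidean; a geodesic variant is available but slow) of the
frame's attachment point are excluded from the wall's surface and piercing
tests, and the septum itself is never a collision target. This kills the
self-intersection artifact at the wall–septum junction, where the wall rim
abuts the implant surface. The containment test is never excluded, so a
device cannot silently tunnel through a distant wall. Whether the original
exclusion was Euclidean or geodesic is unknowable from the outside; the
Euclidean reading is the default as the simplest interpretation of
"within 10 mm of the attachment site".

## Synthetic anatomy

The generator produces the statistical situation the analysis needs —
chamber size and motion, wall offset, structure placement, annulus
geometry — rather than an image-derived shape. Coordinates: long axis `z`,
apex at the origin, basal (annulus) plane at `z = long_axis_length`
(default 95 mm); the septum is the planar sector `x = 0` and the free wall
bulges into `x > 0`.

- **Cavity**: cross-sections are half-ellipses of depth `a·f(z)` and
  half-width `b·f(z)` against the flat septal chord, with taper
  `f(z) = (z/L)^0.85` — narrow at the apex, widest at the base, the conical
  long-axis silhouette of a dilated RV. Depth/width ratio `a/b = 1.25`
  (the dilated RV bulges anteriorly away from the septum). The transverse
  semi-axes are solved analytically so the closed cavity mesh volume equals
  `edv_target` exactly (volume is linear in transverse cross-section area).
- **Septum**: the planar sector extruded 3.5 mm (`wall_thickness`) away from
  the cavity into a closed slab; implant sites are the endocardial-face
  vertices (273 at the default 32×16 resolution).
- **RV free wall**: the remaining endocardium offset outward 3.5 mm along
  vertex normals and stitched into a closed shell — the uniform-dilation
  wall estimate used when the thin free wall cannot be resolved directly.
- **TV structures**: a ring of radius `annulus_radius` (default 30% of the
  basal half-width, centered inside the basal D) carries a 2-mm-thick
  annulus plane slab, plus the convex cone hull from the papillary chordae
  points to the annulus ring enclosing annulus, leaflets, and chordae. With
  no papillary muscles configured the cone degenerates to the slab alone.
- **Papillary muscles + moderator band**: anterior and inferior PMs on the
  free wall and a septal PM, each a convex tapered cone from a base circle
  on the wall to a tip pointing toward the annulus center — the tip, the
  basal-most point, is the chordae attachment point. The moderator band is a
  capsule strut from the low septum to the anterior free wall. All PM/band
  solids form one collision category.
- **Conduction paths**: polylines of ≥ 12 points on the septal plane: the
  proximal left bundle (LBB) descends from the membranous high septum over
  roughly a quarter of the apicobasal length; the anterior (LAF), posterior
  (LPF), and septal (LSF) fascicles fan anterior-apically,
  inferior-apically, and mid-septally from its distal end. These seed the
  LBBAP target regions without reimplementing a fractal conduction tree.

Every structure mesh is closed (zero boundary edges), which the containment
tests require.

**Motion** is an affine contraction about the apex and long axis: transverse
scale `1 − A·w(t)` and longitudinal scale `1 − c·A·w(t)` with weight
`w(t) = (1 − cos 2πt)/2` over phase fraction `t ∈ {0, 0.1, …, 0.9}` and
longitudinal ratio `c = 0.5`. Cavity volume is then exactly
`EDV·(1−Aw)²·(1−cAw)`, so the amplitude `A` solving
`(1−A)²(1−cA) = 1 − EF/100` (Brent root finding, machine precision) makes
the measured ejection fraction hit `ef_target` at end systole (`t = 0.5`,
frame 5 of 10). The field is a rigid-free idealization: no regional wall
motion abnormality, no twist, no dyssynchrony — so passing tests show the
pipeline's behavior under clean volumetric motion, not under the
patient-specific deformation patterns of real image-tracked meshes.

**Cohorts** draw per-patient parameters around the defaults: log-normal
multiplicative jitter on EDV (CV 38/283) and long-axis length (CV 5%),
normal additive jitter on EF (SD 7 absolute %, clipped to 2–70%), one seeded
generator for everything.

What the generator does *not* emulate: trabeculation, regionally varying
wall thickness, atrial/left-ventricular anatomy, leaflet motion relative to
the annulus, and the crescent wrap of the RV around the LV. Regional
percentages from this geometry are therefore internally consistent study
outputs, not predictions for any real cohort; the directional findings
(risk grows with length, apex is worst, TV risk lives in the 20-mm band)
are the quantities expected to transfer.

## Regional mapping

Septal nodes get chart coordinates from four landmarks (apex, annulus
center, anterior/posterior attachment points): `rho` is 1 minus the node's
distance to the basal plane (spanned by the annulus center and the two
attachment points) normalized by the apex's distance — 0 at the apex, 1 on
the plane; `phi` is the angle about the apex→annulus-center axis measured
from the anterior attachment direction, normalized by the anterior→posterior
angle and clamped to [0, 1]. Both are rigid-invariant. AHA septal segments:
basal third (rho ≥ 2/3) splits at phi = 0.5 into 2 (anteroseptal) and
3 (inferoseptal), the mid third into 8 and 9, and the apical third is 14.
The TV band is the set of nodes within 20 mm of the annulus plane at end
diastole. LBBAP regions are the 2D convex hulls of each fascicle polyline on
the (rho, phi) chart — convexity is only well defined on the flattened
map — dilated by 5 mm (converted to chart units via apicobasal depth and
septal width); a collinear path degenerates to a buffered corridor, and
nodes inside several hulls go to the branch with the nearest path centroid.
Grid resampling bins nodes into a 50×50 (rho, phi) grid (cell mean, empty
cells masked); the grid resolution is a configurable default, as is the
nearest-node binning rule.

## Statistics

Regional prevalence is computed per patient (100 × positive/total sites in
the region) and summarized as mean ± population SD across patients —
population (n) rather than sample (n−1) SD, which is what reproduces the
calibration table's own summary row. Collision-free fractions pool sites
across patients instead ("fraction of the regional area"), the complement
of pooled prevalence. Length trends are ordinary least squares of mean
regional risk on device length (slope reported per 5 mm, with Pearson r;
constant risk reports slope 0 and undefined r). Device contrasts are paired
t tests on per-patient regional risks with Bonferroni correction (p × number
of comparisons, capped at 1); a zero-variance nonzero shift is reported as
degenerate rather than given a fabricated p-value. Mixed-effects models and
ANOVA are intentionally not implemented — the flat CSV outputs
(patient, node, device, per-structure flags) are structured so any external
statistics environment can fit them.

## Problem sizes and determinism

Default meshes use 32 circumferential × 16 long-axis samples (≈ 270 septal
sites, ≈ 1 000–2 500 faces per structure, 10 phases); the default study runs
ten patients over the three catalogue devices plus 25–45 mm sweeps at each
catalogue volume, a few minutes on one CPU. Doubling the resolution moves
all-septum prevalences by ≈ 1 % absolute. All randomness flows from
explicit seeds (cohort draws, oracle sampling, orientation perturbation);
reruns with the same seed are byte-identical.

## Known limitations

Rigid tissue and binary contact (no compliance, no tolerable-overlap
threshold); discrete per-frame collision; analytic motion rather than
image-derived deformation; idealized geometry as listed above; the
exclusion-radius metric and the per-frame-normal convention are defaults
for choices the underlying framework leaves open — both alternatives are
implemented and configurable.
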