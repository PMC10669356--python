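# Methods

`periofem` simulates the mechanical load on the periodontal ligament
(PDL) of single- and multi-rooted teeth under occlusal forces, and how
that load escalates as horizontal periodontal attachment loss removes
the supporting bone and ligament in millimetre steps. This note
documents the model, its assumptions, the numerical choices, and the
limits of what the synthetic geometry can show.

## Model overview

A simulation run consists of five stages:

1. **Geometry** — a parametric layered tooth (enamel, dentin, pulp,
   cementum, PDL) embedded in an alveolar bone block (cortical shell,
   cancellous core), described by star-shaped cross-section radius
   functions `r(θ, z)` around the root axis. The axis convention is +z
   pointing apically with the origin at the cemento-enamel junction
   (CEJ) centroid.
2. **Meshing** — a conforming, region-tagged quadratic tetrahedral mesh
   built by extruding a fixed 2D polar triangulation through a set of
   axial levels. Bonded tissue contact is realized exactly by shared
   nodes; no contact algorithm or penalty parameter exists.
3. **Solve** — static linear elasticity with isotropic Hooke's law per
   tissue, fixed outer bone boundary, and a uniform occlusal traction.
   The 70-step load ramp of the protocol is reproduced as exact linear
   scalings of a single factorized solve; linearity is verified against
   an independent second solve on every run (tolerance 1e-9 relative).
4. **Readout** — the contact pressure on the PDL–bone interface
   (normal traction, compression-positive), regional summaries over
   anatomical zones, von Mises/principal stresses, VTU/CSV/PNG export.
5. **Sweep** — attachment loss applied in 1 mm increments with re-mesh
   and re-solve per step, a failure criterion on the peak pressure, and
   a stop rule (first failure, one confirmation step, then stop).

## Tissue materials

Isotropic linear-elastic constants (E in MPa, ν):
enamel 84 000/0.33, dentin 18 600/0.31, pulp 2.07/0.45, PDL 68.9/0.45,
gingiva 3.0/0.45, cortical bone 13 700/0.30, cancellous bone
1 370/0.30. Cementum is not mechanically distinguished in the source
table; it is assigned dentin-like constants (the layer is 50–150 µm
thin and bonded to dentin, so its compliance contribution is
negligible). The PDL is in reality visco-elastic and non-linear; the
linear-elastic simplification makes the response proportional to load,
which is why the ramp can be collapsed into one solve. All units are
mm–N–MPa.

Near-incompressible tissues (ν = 0.45) are handled with standard
displacement elements; quadratic tetrahedra are the default partly to
mitigate volumetric locking in the thin PDL shell. ν = 0.45 is far
enough from the incompressible limit that no mixed formulation is
needed.

## Parametric anatomy

Key defaults (all configurable via `ToothParams`):

| parameter | single-rooted | multi-rooted | note |
|---|---|---|---|
| root length | 13 mm | 12 mm | standard anatomy ranges |
| cervical / apical root radius | 3.4 / 1.2 mm | 4.5 / 1.4 mm | linear taper |
| crown height | 8 mm | 8 mm | enamel cap 1 mm |
| furcation depth below CEJ | — | 3 mm | groove ramp 3 mm |
| PDL thickness | 0.1 mm | 0.1 mm | uniform shell |
| cementum | 50/100/150 µm | same | abrupt steps by thirds of root height |
| crest offset (biologic width) | 1.5 mm | 1.5 mm | healthy crest below CEJ |
| bone block | ⌀14 × 17 mm | ⌀16 × 16 mm | cortical shell 1.5 mm |

Choices worth explaining:

* **Crest offset.** The healthy alveolar crest sits ~1.5–2 mm apical
  to the CEJ (supracrestal attachment). Placing the crest at the CEJ
  would press the enamel flare directly onto the PDL edge and the bone
  crest, creating an artificial stiff pinch with a strong stress
  singularity. With the biologic-width offset the support spans
  `[crest_offset + reduction, root_length]`.
* **Cementum steps.** The gradation from 50 µm at the CEJ to 150 µm at
  the apex is modelled as three abrupt steps over equal thirds of root
  height; the boundaries and the abruptness are not specified
  anatomically, and thirds is the simplest consistent reading.
* **Multi-rooted form.** The two-rooted molar is modelled as a
  partially fused root: the cross-section below the furcation depth is
  a two-lobed curve `r = R(z)(1 − a sin⁴θ)` whose waist depth `a`
  derives from the fusion of two circular lobes with centres
  `±inter_root_spread/2`. The grooves (the interradicular region,
  filled by PDL and bone) develop over a 3 mm ramp, mimicking the
  dome-shaped fornix of a real furcation. The lobes never leave the
  root-trunk taper envelope, so the cross-section area decreases
  monotonically with depth — fully separated, diverging roots cannot be
  represented by a star-shaped polar section (see Limitations).
* **Layer offsets.** Cementum and PDL surfaces are true 2D
  normal offsets of the root cross-section, enlarged by the axial
  surface slope factor √(1+(∂r/∂z)²) so the 3D normal thickness stays
  at its nominal value on tapered walls and in the furcation ramp.
  Offsets that would self-intersect (curvature radius below the offset)
  raise an error with the location; the default geometries are checked
  at build time.
* **Gingiva** is excluded from the mechanical model by default
  (E = 3 MPa is negligible against bone); a flag adds a gingival collar
  with the library constants.

Attachment loss removes PDL and supporting bone coronal to a plane
perpendicular to the root axis; the root surface above the plane
becomes exposed and traction-free, and the crest re-forms (with its
cortical plate) at the new level, as in chronic horizontal bone loss.

## Meshing

The cross-section has 9 radial interfaces (pulp, two dentin rings,
cementum, two PDL rings, cancellous rings, cortical shell); the thin
layers are always resolved radially (one cementum and two PDL element
layers) regardless of the element-size parameter, which controls the
circumferential and axial resolution. Prisms are split into tetrahedra
with the minimal-global-index diagonal rule, which makes the splitting
agree across shared faces — the mesh is conforming by construction.
An area-preserving radius correction (inscribed polygon → equal area)
keeps mesh volumes within ~0.3% of the parametric solid.

Axial levels pin the structural planes (CEJ, support rim, furcation
ramp, apex and its 150 µm cementum + 100 µm PDL caps, block bottom).
The supported span is filled *relative to the rim* with an extra
refinement band around it, so the mesh pattern at the
pressure-critical rim is identical for every attachment reduction —
without this, rim-resolution differences between reductions would put
a few percent of noise on the escalation curve. Secondary boundaries
(pulp end, cementum steps, crest plate) are tagged per element-slab
centroid and may smear by half a slab.

Because the geometry and the load protocol are mirror-symmetric about
the tooth's mid-sagittal plane, the default mesh covers the y ≥ 0 half
with the exact symmetry condition u_y = 0 on the cut; this halves the
factorization cost. Full meshes are available (`symmetric=False`) and
are used for surface extraction and general load directions.

## Load protocol and calibration

The reference masticatory load is 700 N axial + 350 N transverse
(resultant 782.6 N) applied over a full arch by the closing
musculature. A single-tooth submodel receives an occlusal traction on
a tagged patch (70% of the crown radius); the default per-tooth
terminal force is (70, 35) N — one tenth of the arch load — but
absolute per-tooth forces are not physiologically identifiable, so
cross-class comparisons use the *calibration mode*: the load is scaled
so the full-support peak PDL pressure matches an anchor (0.48 MPa for
the single-rooted tooth, 0.40 MPa for the molar). Since the model is
linear this is an exact scaling. The opposing tooth is not modelled as
a contact body; a traction patch is deterministic and equivalent for
monotone loading of the PDL readouts.

## Contact pressure and zones

The pressure on the tied PDL–bone interface is the normal traction
σₙ = n·σ·n with compression positive. Stresses are evaluated *at each
facet centroid* from the quadratic elements on both sides of the
interface and averaged; one-sided element-centroid sampling produces a
visible odd/even facet pattern in the thin PDL layer, which the
facet-centroid average removes. The free-body balance (transmitted
axial force vs. applied axial load) is monitored per solve; it closes
to ~4% at full support on the single-rooted default mesh (degrading to
~8% as the remaining interface shrinks over a sweep) and ~6–13% on the
multi-rooted mesh, whose grooved interface converges more slowly.

The headline `peak` is the maximum over the interface of the
area-weighted mean pressure within a 1.0 mm radius patch. The rim of
the remaining attachment is a free edge of a thin bonded soft layer,
where the pointwise traction is weakly singular: the raw facet maximum
(`peak_raw`, also reported, with the 99th percentile) grows under
refinement and is remesh-noisy, while the fixed-physical-scale patch
average is stable enough to support trend statements across a sweep.
Even so, the patch peak of the *full-support baseline* still changes
by ~4–10% between the default refinement levels — see Limitations.

Zones partition the remaining interface and are recomputed after every
reduction: `cervical` is the coronal 25% of the remaining interface
height, `apical` the apical 2 mm cap, `furcation_roof` (molar only) the
interradicular groove sector (azimuth within 35° of the groove axes)
over the fornix depth range, and `mid_root` the remainder. `load_share`
is a zone's fraction of the compressive load transmitted across the
interface.

## Failure criterion and sweep

A tooth is declared failed when the peak PDL pressure exceeds a
configurable threshold (default 0.90 MPa, the largest pre-failure value
on the reported clinical scale) or when the model becomes unsupported /
the solve fails. After the first failure the sweep evaluates one more
step to confirm, then stops; later rows are marked not evaluated.
Every result table embeds full provenance: tooth parameters, protocol,
calibration scale, mesh hashes, material table, seed and version.

## Default study sizes

The default sweep meshes use 0.95 mm (single-rooted) and 1.15 mm
(multi-rooted) elements, giving both classes a comparable budget of
roughly 40k full-model-equivalent quadratic tetrahedra (~60–110k
degrees of freedom after symmetry reduction) and a per-solve direct
factorization of ~30–60 s on one CPU. The default refinement study runs
the full-support single-rooted model at 1.6/1.2/0.95 mm. These sizes
were chosen as the package's standard desk-scale configuration;
coarser meshes (≥1.2 mm) reproduce all qualitative orderings but add a
few percent of noise to the escalation curve's second differences.

## What the synthetic geometry does and does not show

The generator emulates the layered periodontal anatomy, the thin
uniform PDL, the graded cementum, the furcation fornix with its
interradicular septum, and horizontal attachment loss. It does not
emulate: patient-specific root form factors (curvature, ovality,
accessory roots), fully separated diverging roots (a star-shaped polar
section cannot represent them, so the sub-furcation interface area of
the fused form is ~10–15% below that of two separated roots — the
molar's post-furcation reserve is correspondingly understated), the
full dental arch with load sharing between teeth, occlusal contact
mechanics, visco-elastic or fibrous PDL behaviour, and bone
remodelling. Passing trend checks on these models therefore supports
the qualitative mechanics of attachment loss — stress concentration
zones, apical load shift, monotone escalation, class ordering of
failure thresholds — not patient-level absolute pressures, which the
calibration mode deliberately pins to reported anchors.

## Known numerical limitations

* The peak pressure sits at the attachment rim's free edge; its patch
  average converges slowly under refinement (changes of ~4–10% between
  the default study levels, against a 2% convergence target). The
  area-weighted mean pressure and the transmitted load converge at ~1%.
* The transmitted-load balance closes to ~4% (single) / ~6% (multi) at
  full support and degrades to ~8% / ~13% at deep reductions, driven by
  the sharpening rim field and, for the molar, the faceted groove
  walls; it tightens under refinement.
* The escalation curve of the molar has a genuine jump when the
  reduction front passes the furcation ramp (support loss is
  concentrated into one step by the fused-root form), which caps the
  fraction of non-negative second differences at ~50% around that
  event; the single-rooted curve is convex at every interior step at
  the default mesh.
* Sliver elements (radius ratio < 0.01) can appear where polar rays
  graze the steep furcation grooves; they are counted in the quality
  report, stay positive-volume, and are handled by the direct sparse
  factorization (MMD-ordered SuperLU).
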