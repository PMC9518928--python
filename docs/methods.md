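# Methods

## Problem and pipeline

`cephaloseed` detects 90 named cephalometric landmarks (46 cranial, 44
mandibular) in head CT volumes.  The approach is semi-supervised: accurate
landmark *labels without images* are far easier to obtain than paired
CT + label data, so the pipeline is built to learn most of its knowledge —
the statistical structure of skull shape — from landmark-only cohorts, and to
use the few paired volumes only where image evidence is indispensable.

Detection proceeds in three steps.

1. **Reference landmarks and normalization.**  The CT volume `x` is
   binarized at ρ = 500 HU into a bone mask `x_b`.  A small multi-view CNN
   reads illuminated orthographic renderings of `x_b` and regresses the 10
   easy-to-find reference landmarks R♯ (Bregma, CFM, Na, ANS, Or L/R, Po
   L/R on the cranium; the mental foramina MF L/R on the mandible).  Five of
   them define the head frame: origin at CFM, v1 = unit(Po(R) − Po(L)) (the
   midsagittal-plane normal), v3 = Bregma − CFM orthogonalized against v1,
   v2 = v3 × v1.  Landmarks are then scaled uniformly about the origin so
   the *cranial volume* — |v1(PoL) − v1(PoR)| · |v2(PoL) − v2(Na)| ·
   |v3(CFM) − v3(Bregma)| — equals the training-cohort mean.  After this
   normalization only shape variation remains.
2. **Coarse local-to-global estimation.**  A variational autoencoder over
   the normalized 270-dimensional landmark vector R learns a latent code
   z ∈ R⁹; a fully-connected map Φ : R♯ ∈ R³⁰ → z is fitted so that
   R◇ = D(Φ(R♯)) estimates all 90 landmarks from the 10 references.  Both
   are trained on the pooled cohort (unpaired landmark sets + paired
   labels); for paired subjects Φ's inputs are the *detected* references,
   so Φ sees the same input distribution at train and test time.
3. **Coarse-to-fine refinement**, split by region:
   * *Mandible* — the bone mask is split by 26-connected component labeling
     (largest component = cranium, second = mandible).  Nine small 3D CNNs
     each read an η-voxel cube of the mandible mask centered at a landmark
     group's coarse position and regress the member offsets jointly.  The
     six condyle landmarks per side (COR, MCP, LCP, Cp, Ct-in, Ct-out) form
     one group per side; bilateral groups share data through horizontal-flip
     augmentation (patch mirrored along v1, L/R labels swapped, v1 offsets
     negated).
   * *Midsagittal cranial landmarks* (MxDML, Od, PNS) — refined in 2D on the
     partially integrated image x^mid = Σ_v1 x_b over a ±7.5 mm slab around
     the midsagittal plane; the v1 coordinate is fixed to the plane itself.
   * *Remaining cranial landmarks* — a second VAE/Φ stage over the
     138-dimensional cranial vector (latent dimension 15), driven by the 8
     cranial references plus the 3 finely detected midsagittal landmarks.
   The final output always prefers CNN-detected positions (10 references,
   3 midsagittal) over decoded ones.

## Training objectives

The VAE minimizes Σᵢ ‖D(E(Rᵢ)) − Rᵢ‖² + KL(N(μᵢ, σᵢ²) ‖ N(0, I)) with
full-batch Adam.  The encoder is three hidden ReLU layers with linear μ and
log-variance heads (σ = exp(logvar/2) keeps σ > 0 by construction);
sampling uses z = μ + σ ⊙ h, h ~ N(0, I).  Two KL forms are exposed:
`standard` = ½Σ(μ² + σ² − log σ² − 1), and `as_printed` = ½Σ(μ² + σ² −
log σ − 1), a variant sometimes printed for this objective (kept selectable
so results under either convention can be reproduced); `standard` is the
default since it is the Gaussian KL the VAE objective derives from.  Φ minimizes Σᵢ ‖Φ(R♯ᵢ) − zᵢ‖² with the
VAE frozen; its latent targets use the deterministic encoder (z = μ) so the
regression target is stable.  Patch CNNs minimize squared coordinate error
of the member offsets in patch-frame mm.

Unpaired subjects enter Φ training as (Sub(R), E(R)) pairs, where Sub keeps
the 10 reference entries of a full vector — this is the semi-supervised
mechanism that lets 229 landmark-only subjects train the local-to-global
map alongside 15 paired ones.

## Parameters

| parameter | default | notes |
|---|---|---|
| ρ (bone threshold) | 500 HU | inclusive (x ≥ ρ) |
| η (patch edge) | 80 voxels / 80 px | ≈ 4 cm at 0.5 mm spacing |
| midsagittal slab | ±7.5 mm | along v1 |
| latent dim | 9 (coarse) / 15 (cranial) | below dim(R♯) = 30 |
| epochs | 45000 / 80000 / 5400 / 23000 / 20000 / 5000 | coarse VAE / cranial VAE / Φ / Φcr / 3D CNN / 2D CNN |
| learning rates | 1e-3 / 1e-3 / 1e-4 / 1e-4 / 5e-4 / 1e-4 | same order; all full batch, Adam |
| split | 15 paired / 229 unpaired / 9 test | |
| patch jitter | 2 × max coarse training error, capped at η·spacing/2 | see below |

These constitute the `paper` preset (`cephaloseed config dump --preset
paper`).  The `desk` preset keeps every architectural choice and shrinks the
workload to minutes on one CPU: 2 mm voxels, 32-voxel patches, 0.3× epochs
for the coarse VAE, 0.1× for the cranial VAE and both Φ maps, and ~1/100 for
the CNNs.  At 1/100 length the published CNN step sizes barely move the
weights, so the desk CNN schedules use larger learning rates (2e-3 for 3D,
1e-3 for 2D), chosen for training-loss convergence.  The `tiny` preset
further shrinks to 16-voxel patches and a 5/30/3 split; it is the
configuration used by the end-to-end tests and `scripts/acceptance.py`.

**Jitter cap.**  Patch-center jitter during CNN training covers twice the
maximum coarse error so the regressors see the test-time error
distribution.  When that radius exceeds half the patch extent, training
targets fall outside the patch's field of view and the regressors learn
noise; the pipeline therefore caps the jitter at η·spacing/2.  At the
published operating point the cap (20 mm) is above any plausible coarse
error, so it only binds at aggressively scaled-down patch sizes.

**Hidden widths** (repo-defined, configurable):
encoder 270→128→64→32, decoder mirrored; cranial stage 138→96→48→24; Φ
30→64→32→d.  The patch CNNs are small conv stacks ([Conv3–ReLU–AvgPool2]×B
followed by two dense layers) rather than any fixed published architecture;
with 5–15 paired subjects, capacity is not the binding constraint.  The
reference detector renders three cardinal illuminated views (shaded +
depth channels), crops them around the foreground centroid, and regresses
all 30 reference coordinates as offsets from that centroid — which makes it
equivariant to whole-voxel translations by construction (up to
silhouette-edge shading effects, below half a voxel in practice).  Its
training schedule (3000 epochs, lr 1e-3, crop jitter augmentation) is
repo-defined.

## Numerical and implementation choices

* All networks are implemented directly on numpy with hand-derived
  gradients and Adam; training is single-threaded and bit-reproducible for
  a fixed seed, which the test suite asserts.  Dense stages run in float64;
  convolutional stacks in float32 (their runtime is memory-bound and
  single precision is ample for mm-scale regression).
* VAE inputs are standardized internally (mean subtracted, one global scale
  factor) for conditioning; the reconstruction loss is computed on the mm
  scale so the objective itself is unchanged.  The standardization is part
  of the stored model.
* Connected-component labeling uses 26-connectivity; equal component sizes
  break ties toward the lower minimum linear voxel index.  Fewer than two
  components is an explicit error (e.g. an occluded bite fusing mandible to
  maxilla), never a silent fallback.
* Patches snap their center to the nearest voxel and zero-fill outside the
  grid; patch-frame ↔ world round trips are exact to half a voxel.
* The midsagittal slab sums voxels whose centers fall in the closed ±7.5 mm
  interval; a slab inside the grid but thinner than one voxel spacing
  yields an all-zero image rather than an error.
* The illuminated renderer is deliberately orthographic and axis-aligned
  (six cardinal view directions), with Lambertian shading from
  depth-gradient normals plus a small ambient floor so the silhouette is
  light-independent.
* Degenerate geometry (coincident porions, Bregma–CFM collinear with the
  porion axis, zero cranial extent) raises typed errors at frame or volume
  construction.

## The synthetic cohort

The generator (`cephaloseed.synth`) emulates the *statistical* structure
the method relies on, not anatomy:

* a bilaterally symmetric 90-landmark template on a stylized skull;
* low-rank correlated shape variation: k = 3 orthonormal deformation modes
  (mandibular anterior-posterior shift; global vertical stretch; an
  asymmetric lateral mandibular deviation emulating dentofacial deformity)
  with standard deviations (40, 30, 20) in unit-mode coordinates, i.e.
  roughly 2–6 mm RMS per landmark per mode;
* isotropic landmark noise of 0.5 mm per coordinate;
* a random similarity pose per subject: rotations up to ±0.05 rad,
  translations up to ±5 mm, scale 0.95–1.05 (head pose in a scanner varies
  mildly; the midsagittal integration assumes near-axis-aligned scans);
  latent draws are truncated at ±3σ so every subject stays on the default
  grid (a ~3% variance shrink, within the covariance test's tolerance);
* rasterized volumes: cranium = ellipsoidal shell (cut off below the skull
  base, which is carried by per-landmark struts toward the shell center)
  plus struts; mandible = tubes along a mirror-symmetrized minimum spanning
  tree of the mandibular landmarks; bone 1200 HU on −1000 HU background so
  ρ = 500 separates cleanly.  By construction the binarized volume has
  exactly two 26-connected components with the cranium strictly larger and
  every landmark on its region's surface — the contracts the segmentation
  and patch stages require.

What passing tests on this cohort show: that the implementation of every
stage is correct, that the semi-supervised local-to-global mechanism
recovers a known low-rank shape family through the latent space, and that
patch refinement improves a realistic coarse error distribution.  What they
do not show: performance on real CT (no soft tissue, metal artifacts, HU
calibration drift, anatomical detail, or occluded bites), nor that the
stylized deformation modes span real craniofacial variability.

## Reference experiments and problem sizes

`scripts/acceptance.py` (and the heavier tests) run two studies:

* **Parameter recovery** — 229 unpaired training subjects, 24 held-out, no
  volumes; VAE latent-dimension sweep d ∈ {1, 3, 5, 7, 9} at the desk
  schedule; Φ from the 10-landmark subvector at d = 9.  Reported:
  reconstruction MDE per d (expected: large at d = 1, plateau from d = k =
  3), the local-to-global MDE, and the constant mean-shape baseline it must
  beat.  Typical: baseline ≈ 4.4 mm, local-to-global ≈ 2.1 mm (≈ 50 %
  better), cranial below mandibular — the generator gives the cranium less
  variance, and the estimator translates that into lower error.
* **Coarse-to-fine** — the tiny benchmark (5 paired / 30 unpaired / 3
  test).  Reported: coarse vs final MDE overall and per region, the
  reference-detector error, and midsagittal in-plane error before/after 2D
  refinement.  Typical: coarse ≈ 5 mm → final ≈ 3.5 mm, with every region
  improving.  The desk-scale detector (≈ 4–7 mm over 10 landmarks from 5
  training subjects) is the main error source; both coarse and final
  estimates inherit it, so the coarse-to-fine comparison remains meaningful.

These sizes keep the full test suite and the acceptance script each within
tens of minutes on one CPU while leaving every stage's behavior measurable.

## Mandibular group design

The 44 mandibular landmarks partition into 9 jointly regressed groups: the
two condyle-6 groups, a self-mirrored symphysis group (6 midline chin/
incisor landmarks + the bilateral mental tubercles), and bilateral ramus
(5), body (3) and dental-arch (4) groups per side.  Groups were chosen so
every member lies within the patch's field of view at the group's center —
a group wider than the patch cannot be refined no matter the training
schedule.  The partition lives in the registry CSV, not in code.

## Known limitations

* The reference detector is the weakest stage at desk scale; with 15 paired
  subjects (the published split) it improves but is still a simplification
  of multi-view illuminated-image landmarking (single multi-view regressor,
  no per-view triangulation).
* The midsagittal integration slab is taken along the grid's v1 axis, not
  the subject's exact midsagittal normal; for strongly rotated heads the
  integrated image blurs (poses in the generator are mild by design).
* Index ranges of landmark blocks are registry-driven; the shipped registry
  holds the names required by the method plus repo-defined picks from
  standard cephalometric nomenclature, and can be edited, but models refuse
  to load against a registry other than the one they were trained with.
* No DICOM ingestion, no HU calibration, no metal-artifact handling, no
  cone-beam CT geometry.
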