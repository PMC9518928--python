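# cephaloseed

Semi-supervised 3D cephalometric landmark detection for head CT.

Cephalometric analysis — the morphometric workhorse of orthodontics and
maxillofacial surgery — rests on named skull landmarks (Nasion, Porion,
Menton, …).  Locating all 90 standard landmarks in a 3D CT volume by hand is
slow even for experts, and supervised learning is starved: paired CT + label
data is scarce for legal and ethical reasons, while *landmark-only* tables
from past treatment planning are comparatively plentiful.  `cephaloseed`
implements a pipeline built around that asymmetry:

1. **Reference detection** — binarize the CT at ρ = 500 HU, render
   illuminated views of the bone mask, and detect the 10 easy-to-find
   reference landmarks R♯ with a small CNN; build the head frame from them
   (v1 = midsagittal normal through the porions, origin at CFM) and
   normalize scale by the cranial volume.
2. **Local-to-global estimation** — a variational autoencoder learns a
   9-dimensional latent code z of the normalized 270-dim landmark vector R
   from the pooled cohort (mostly unpaired); a regressor Φ maps R♯ ∈ R³⁰ to
   z, so R◇ = D(Φ(R♯)) roughly places all 90 landmarks from 10.
3. **Coarse-to-fine refinement** — connected-component labeling splits the
   bone mask into cranium and mandible; nine 3D patch CNNs refine the 44
   mandibular landmarks in groups (the six condyle landmarks per side
   jointly); three cranial landmarks near the midsagittal plane are refined
   in 2D on the partially integrated image Σ_v1 x_b (±7.5 mm slab); the
   remaining cranial landmarks come from a second VAE/Φ stage (latent
   dimension 15) driven by the 8 cranial references plus those 3 landmarks.

Accuracy is reported as the mean detection error
MDE = mean over subjects of the per-subject mean Euclidean distance (mm)
between estimated and ground-truth landmarks.

A synthetic skull generator (`cephaloseed.synth`) — a symmetric 90-landmark
template with low-rank deformation modes, landmark noise, similarity poses,
and rasterized two-component binary skulls — makes every stage trainable and
testable end to end with no patient data.  See `docs/methods.md` for the
model details, parameter tables, and what the synthetic cohort does and does
not demonstrate.

## Worked example

Train everything on a small synthetic benchmark and detect landmarks in a
held-out volume:

```sh
cephaloseed synth --n-paired 5 --n-unpaired 30 --n-test 3 --seed 7 --out bench/
cephaloseed train --benchmark bench/ --preset tiny --seed 1 --out models/
cephaloseed detect --volume bench/test/test_synth*_0000.nii.gz \
    --models models/ --out est.csv \
    --labels bench/test/test_synth*_0000_landmarks.csv
```

The detect step prints, for example:

```
landmarks written to est.csv
MDE 3.74 mm (cranial 3.05, mandibular 4.47); report in est.report.json
```

meaning the 90 estimated landmarks land on average 3.74 mm from the ground
truth for this subject, with the cranial and mandibular subsets at 3.05 and
4.47 mm.  `est.csv` holds one row per landmark
(`name,index,region,v1_mm,v2_mm,v3_mm`).  The same flows are available as
library calls (`cephaloseed.pipeline.run_train_all` / `run_detect`), and
`cephaloseed config dump --preset paper` prints the full published
operating point (80-voxel patches, 45000/80000/5400/23000/20000/5000
epochs, …).

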