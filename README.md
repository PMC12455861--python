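# cordlesion

3D tract-specific quantification of traumatic spinal cord lesions, plus the
longitudinal and prediction models those measures feed.

After acute spinal cord injury (SCI), the post-traumatic lesion seen on
T2-weighted MRI overlaps the cord's white-matter pathways to different
degrees on the left and right, and that asymmetric tract damage carries
prognostic information that conventional 2D lesion measures (midsagittal
tissue bridges, lesion volume) cannot express. `cordlesion` takes
co-registered, template-space segmentation volumes — a *soft* lesion mask
(voxel values in [0, 1] giving the fraction of each voxel occupied by
lesion), a cord mask, and a probabilistic white-matter tract atlas — and
computes, per patient and timepoint:

- **glass-spine projection maps**: for each anatomical plane (axial,
  coronal, sagittal), a 2D map whose pixel values encode the lesion's
  through-plane extent in mm, so every map integrates to the same lesion
  volume;
- **lateralized tract damage**: for the motor and sensory tract groups and
  each hemicord, `100 · Σ(lesion · tract) / Σ(tract)`, with both masks kept
  fuzzy and the sums restricted to the lesion's superior–inferior span;
- **midsagittal tissue bridges**: the narrowest spared ventral and dorsal
  tissue corridors (mm) on the sagittal slice through the cord centroid,
  and the resulting lesion type (central / ventral / dorsal / complete);
- **lesion volume** in mm³ from the soft voxel mass.

A statistics layer fits the three model families these measures are used
in: a linear mixed-effects model of change over months post-injury (random
intercept per patient; age, sex and center as covariates of no interest,
reporting standardized coefficients and Nakagawa marginal/conditional R²),
a lateralized mixed model predicting per-side score recovery from per-side
early tract damage, and cross-sectional linear models at a single
timepoint. ISNCSCI clinical scores are normalized by the maximum attainable
score below the neurological level of injury.

Because clinical MRI and exam data of this kind are not openly deposited,
the package ships a phantom generator (`cordlesion.phantoms`): cylindrical
cords with sectorized tract atlases, soft ellipsoidal lesions whose exact
per-tract overlap, volume, bridge widths and lesion type are enumerated at
generation time, and synthetic longitudinal cohorts with known recovery
dynamics. All tests validate the pipeline against these analytic truths.

## Worked example

```bash
# 1. generate a 4-patient synthetic study with image volumes
cordlesion phantom --seed 7 --n-patients 4 --with-volumes --out study/

# 2. quantify one scan
cordlesion quantify \
    --lesion study/patients/P001/lesion_month1.nii.gz \
    --cord study/cord.nii.gz \
    --atlas-dir study/atlas --manifest study/atlas/manifest.csv \
    --patient P001 --timepoint month1 --out P001_month1.json

# 3. fit the longitudinal lesion-volume model on the cohort table
cordlesion fit --cohort study/cohort.csv --model longitudinal \
    --outcome lesion_volume_mm3 --out fit.json
```

The profile JSON from step 2 contains, for this phantom (a ventral-type
lesion):

```json
{
  "damage_pct_motor_left": 18.75,
  "damage_pct_motor_right": 18.75,
  "damage_pct_sensory_left": 0.0,
  "damage_pct_sensory_right": 0.0,
  "lesion_volume_mm3": 114.0,
  "lesion_type": "ventral",
  "bridges": {"ventral_mm": 0.0, "dorsal_mm": 3.5, "total_mm": 3.5}
}
```

reading: the lesion sits anteriorly, abutting the ventral cord surface
(ventral bridge 0 mm, hence type *ventral*), damages 18.75% of the motor
tract volume within its rostro-caudal span on each side, and spares the
sensory tracts entirely. The fit JSON from step 3 reports the raw volume
slope (here −14.66 mm³/month), its standardized coefficient with 95% CI
(−0.29, CI −0.45 to −0.12), p-value, and marginal/conditional R²
(0.87 / 0.93 — the random patient intercepts absorb the large
between-patient volume differences).

The same operations are available as a library:

```python
from cordlesion import read_mask, load_atlas, damage_profile

lesion = read_mask("study/patients/P001/lesion_month1.nii.gz")
cord = read_mask("study/cord.nii.gz")
atlas = load_atlas("study/atlas", "study/atlas/manifest.csv")
profile = damage_profile(lesion, cord, atlas, "P001", "month1")
print(profile.damage_pct["sensory_right"], profile.lesion_type)
```

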