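# muscleidp

Fully automatic **imaging-derived phenotypes (IDPs) of abdominal muscle** from
CT: a 12-class residual U-Net segments the left and right psoas, quadratus
lumborum, erector spinae, gluteus medius, rectus abdominis and lateral
abdominals on axial slices; labels are restricted to the abdominal cavity slab
(most inferior lung slice to the inferior aspect of L5, inclusive); per-muscle
volume is voxel counting, and mass applies a fixed muscle density of
1.06 g/mL. Cohort statistics then characterize muscle mass by age and sex —
the quantitative basis of sarcopenia phenotyping at biobank scale.

The package is aimed at researchers who want a tested, end-to-end reference
implementation of this pipeline. Real labeled abdominal CT is controlled
access, so a first-class **phantom module** generates synthetic HU-valued
volumes with voxel-exact 12-class ground truth and simulated cohorts with
known mass–age structure; every stage is validated against those.

## The model

The segmenter family maps a windowed axial slice (window 400 HU, level 40 HU,
values in [0, 1]) to a 13-channel per-pixel probability map (12 muscles +
background) through 4 encoding and 3 decoding blocks. Encoding blocks are
conv → batch norm → PReLU stacks; with *n* ∈ {1..4} residual units each unit
adds an identity connection from its input to its final addition (*n* = 0 is
the simple U-Net). Decoding blocks upsample, concatenate the encoder skip,
and apply norm → activation → conv → addition. Training uses Adam, a compound
soft-Dice + cross-entropy loss, random zoom [−0.2, 0.2] / rotation [−20°, 20°] augmentation
(p = 0.8), strictly study-level train/validation splits, and repeated
five-fold cross-validation aggregated across fold means. Predicted maps are
decoded by per-pixel argmax (ties to the lowest channel), hole-filled per
class, and intersected with the skeletal-muscle attenuation range
[−29, 150] HU.

The network and its backpropagation are implemented directly in NumPy
(`muscleidp._nn`), with analytic gradients verified against finite
differences in the test suite.

Cohort analyses: descriptive mass tables by sex and age decile, Pearson
correlations of mass with age, height²- and BMI-adjusted skeletal muscle mass
(SMM), the interaction model
`SMM/h² = β₀ + β₁·BMI + β₂·sex + β₃·sex·BMI`, OLS decline rates in g/year
with 95% CIs, and the density-error analysis of the fixed 1.06 g/mL
assumption under fatty replacement.

## Worked example

```bash
python examples/03_extract_idps.py
```

prints, for one phantom (40×64×64 voxels at 5×2×2 mm):

```
cavity slab: slices 8..34 inclusive
voxel volume: 20 mm³

  psoas                      39.2 g
  quadratus_lumborum         22.3 g
  erector_spinae             54.1 g
  gluteus_medius             14.5 g
  rectus_abdominis           45.6 g
  lateral_abdominals         85.9 g
  total                     261.4 g (246.6 mL x 1.06 g/mL)
```

Each group mass is the left+right voxel count inside the cavity slab times
the 0.02 mL voxel volume times 1.06 g/mL; the phantom is ~10× smaller than an
adult abdomen, so masses are correspondingly small. The other examples cover
phantom generation (`01`), training a residual U-Net to ≥0.9 held-out Dice
(`02`), cohort statistics recovering the simulated −0.96/−1.73 g/year decline
slopes (`04`), and Dice/ICC agreement metrics (`05`).

A CLI mirrors the library: `muscleidp phantom | train | segment | extract |
evaluate | stats | run-all` (see `muscleidp --help`).

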