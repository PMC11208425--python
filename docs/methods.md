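# Methods

## Problem and pipeline

Abdominal skeletal muscle mass, measured opportunistically from clinical CT,
is a quantitative trait ("imaging-derived phenotype", IDP) relevant to
sarcopenia. The pipeline implemented here takes an abdominal CT volume plus
two axial landmarks (most inferior lung slice; inferior aspect of the L5
vertebra), segments 12 muscle classes slice-wise with a residual U-Net,
cleans the labels, restricts them to the cavity slab between the landmarks,
converts voxel counts to volume (mL) and mass (g), and runs population
statistics on the resulting per-subject table.

## Synthetic phantoms

Labeled clinical CT is controlled access, so correctness is established on
phantoms (`muscleidp.phantom`). A phantom is a (z, y, x) grid — default
40×64×64 voxels at 5×2×2 mm — containing an elliptical fat body, a two-lobed
lung region superior to the lung landmark, a posterior bone column, and 12
muscle structures (elliptic tubes for the paraspinal/wall groups, ellipsoids
for gluteus medius) that must be pairwise disjoint; overlap is a hard error
naming the colliding classes. Tissue HU means are air −1000, lung −800, fat
−100, muscle +50, bone +700 with additive Gaussian noise (SD 10 HU): plausible
CT values chosen so the muscle attenuation window [−29, 150] HU separates
muscle from fat and bone. `make_phantom_set` jitters structure centres
(±2 voxels) and radii (±12%) per phantom to emulate anatomical variation, so
held-out phantoms genuinely differ from training phantoms. Left/right
geometry is symmetric by default.

What the phantoms do **not** emulate: partial-volume fractions at tissue
boundaries, contrast-phase texture, organs, pathology, scanner kernels, beam
hardening, or realistic muscle shapes. Passing the learnability benchmark
therefore shows the architecture/training machinery works end-to-end at desk
scale, not that clinical Dice levels are attainable; clinical performance
claims require real data.

## Cohort simulator

`generate_cohort` draws sex ~ Bernoulli (default P(male) = 0.45), age ~
Uniform(18, 95), and total mass = intercept + slope·age + N(0, 450 g), with
resampling to keep masses positive. Default slopes are −0.96 (female) and
−1.73 (male) g/year, and intercepts are calibrated so the age-60 means equal
the published cohort means of 2041 g (female) and 3086 g (male); per-class
masses split the total by fixed per-sex proportions derived from the same
descriptive table, L/R symmetric. Height ~ N(1.62, 0.07) / N(1.76, 0.08) m
and BMI ~ N(27.5, 5.5) / N(28, 5) by sex, truncated to plausible ranges. An
optional `height_coupling_exp` multiplies mass by (height/1.7 m)^exp to induce
a mass–height correlation; it exists to validate the height² adjustment and is
off by default. Age is continuous; decile binning happens only in the
analysis stage.

## Segmentation architecture and training

The family is fixed at 4 encoding blocks (strides 1, 2, 2, 2; widths w, 2w,
4w, 8w) and 3 decoding blocks, head = 1×1 conv to 13 channels + softmax, so
input slices must be multiples of 8. Each encoding block opens with a
(strided) conv → batch norm → PReLU; a residual unit is conv → BN → PReLU →
conv → BN with an identity connection into the final addition, then PReLU.
`residual_units = 0` (the simple U-Net) uses the same stack without the
identity path — hence 0 and 1 units have equal parameter counts and differ
only in the skip. Decoding blocks use nearest ×2 upsampling, skip
concatenation, BN → PReLU → 3×3 conv, plus a 1×1-projected shortcut forming
the block's addition. Downsampling is by stride-2 convolution (pooling type
was an open choice; strided conv keeps every operation learnable).

The loss is a compound of mean soft-Dice over the 13 channels and
cross-entropy, equally weighted (either alone by config). Dice is the
selection metric, so optimizing it directly is natural — but pure soft-Dice
has a known failure mode at small widths: if a channel's predicted mass
collapses early, its Dice gradient is near zero and the class never
re-enters the argmax (observed here as one muscle class stuck at Dice 0
while all others exceeded 0.94). The cross-entropy term keeps a per-pixel
gradient on every channel and removes that failure across seeds.

Optimizer is Adam. The *protocol* defaults mirror a model-selection
stage of 100 epochs at lr 1e-4 followed by fine-tuning of the selected model
for 100 epochs at 1e-5 and 100 at 1e-6 (`FINALIZE_SCHEDULE`); "128 validation
steps per epoch" is interpreted as up to 128 validation batches per epoch
(batch size default 8, capped at one pass over the validation set). The
end-of-schedule model is returned (last-epoch, not best-epoch, weights).
Augmentation draws zoom 1+U(−0.2, 0.2) and rotation U(−20°, 20°) with
probability 0.8, applied identically to image (bilinear) and labels (nearest,
preserving the palette). Splits are study-level everywhere; a study appearing
in both train and validation is a hard data-leakage error. Cross-validation
partitions studies into k folds per repeat and aggregates the mean and SD
across fold-average Dice values.

The entire network, including backpropagation, batch-norm statistics, and
Adam, is written in NumPy (`muscleidp._nn`), channels-last so the im2col
gather is contiguous; analytic gradients are checked against central finite
differences in `tests/test_nn.py`. All randomness (init, shuffling,
augmentation, folds) flows from named integer seeds; two equal-seed runs
produce identical histories.

### Desk-scale benchmark sizes

The shipped benchmark trains on 64×64 slices, base width 8, 8 training
phantoms (216 slices) and 4 held-out phantoms, 30 epochs at lr 1e-3 without
augmentation for the 2-residual-unit model, reaching ≥0.90 held-out Dice on
the large-structure classes (psoas, erector spinae, rectus abdominis, lateral
abdominals). The capacity comparison (simple U-Net vs 4 residual units) runs
15 epochs under identical conditions: deeper variants converge more slowly
per epoch at this scale, and 15 epochs is where both have plateaued enough
for a fair last-epoch comparison. These sizes are the package's benchmark
definition; the full-scale protocol remains available through `TrainConfig`.

## Postprocessing

Argmax decoding breaks ties toward the lowest channel index (deterministic;
uniform maps decode to background). Hole filling operates per class,
slice-wise in 2D by default (matching the 2D pipeline; a 3D mode exists):
background pixels unreachable from the image border through the class's
complement — 4-connectivity in 2D, 6 in 3D, the referenced filter's default —
are reassigned to the class. Existing nonzero labels are never overwritten;
competing claims go to the lowest class id; the operation is idempotent.
Predicted labels are finally intersected with the raw-HU attenuation mask
(configurable off): windowed intensities feed the model, but HU-based masking
always uses raw HU. Attenuation bounds are treated as inclusive at −29 and
150 HU (inclusivity is conventionally unstated; fixed here for determinism).

## IDP extraction

The cavity slab is inclusive at both boundary slices, at whole-slice
granularity (no interpolation between landmark planes). Volume is pure voxel
counting (partial-volume effects ignored, matching the method being
implemented); units are mm/mL/g with 1 mL = 1000 mm³ and mass = 1.06 g/mL ×
volume, the standard skeletal-muscle density. Totals are exactly additive
over classes and over slices.

## Statistics

* **Dice**: 2|A∩B|/(|A|+|B|); a slice where both masks are empty is N/A and
  excluded from aggregation (not scored 1); one-empty scores 0. Aggregation
  is across 2D slices (test-set convention) or across fold means (CV
  convention); per-side and pooled summaries are both available.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — computed from the ANOVA mean squares; this is the
  conventional variant for method agreement, and the variant choice matters
  when comparing against published coefficients. Cross-checked against
  pingouin's ICC(A,1) in the tests.
* **Regression**: OLS of automatic on manual areas (slope/intercept/r²,
  two-sided slope p-value), via statsmodels.
* **Age bins**: "<40", "41–50" … "81–100" with closed-right edges, so age
  exactly 40 falls in the youngest bin (the labels leave 40 ambiguous; this
  convention is fixed and tested).
* **Adjustments**: mass/height² (g/m²), mass/BMI, and BMI-standardized
  z-scores of height-adjusted mass (OLS residuals standardized to mean 0,
  SD 1).
* **Interaction model**: OLS of height-adjusted SMM on BMI, sex (0 = female
  reference, 1 = male) and their product; unidentifiable on single-sex
  cohorts, which are rejected.
* **Decline rate**: the OLS slope of total mass on age over the stratum's
  full adult age range (not a peak-to-oldest-bin difference), with 95% CI.
* All p-values are two-sided; no multiple-testing correction is applied.
* **Density error**: muscle/fat densities 1.06/0.9 g/cm³ give a density
  excess of 100·(1.06−0.9)/0.9 = 17.8%; replacing a fraction f of muscle by
  fat makes the effective density (1−f)·1.06 + f·0.9, and assuming pure
  muscle overestimates mass by 100·(1.06−ρ_eff)/ρ_eff ≈ 8.2% at f = 0.5.

## Pipeline robustness

`run_pipeline` treats per-study failures (unreadable volumes, inverted
landmarks, implausible segmentations) as logged exclusions, not fatal errors.
The manual-review step of a clinical deployment is replaced by an automated
sanity rule — zero foreground in the slab, or any single class exceeding the
slab volume, excludes the study — which is logged and configurable. Outputs
are never silently overwritten, and every run writes a manifest (package
version, seed, inputs, outputs, exclusions) sufficient to reproduce its
artifacts.

## Numerical choices

Float32 throughout the network; batch-norm eps 1e-5, momentum 0.1; soft-Dice
eps 1e-6; He-uniform init; PReLU slopes init 0.25. Windowed intensities stay
floating point in [0, 1] (no 8-bit quantization). Argmax ties and hole-fill
conflicts resolve to the lowest id. Degenerate statistical inputs (constant
series, single-sex cohorts, n below the minimum) raise errors rather than
returning conventional values.

## Known limitations

The landmark classifier that would localize the lung/L5 planes on real data
is out of scope: landmarks arrive from phantom ground truth or user
annotation. DICOM handling, contrast-phase classification, muscle attenuation
statistics, vertebral-level single-slice indices, and any claim about
clinical Dice levels are likewise out of scope. The NumPy backend is
single-core and desk-scale by design; the full-scale profile (512² slices,
wide channels) is expressible in the configs but not practical on one CPU.
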