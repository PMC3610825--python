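# Methods

`hypoperf` implements a paired-design regional cerebral blood flow (rCBF)
analysis for a two-condition (euglycemia vs. hypoglycemia) within-subject
study measured with two modalities — pulsed arterial spin labeling MRI
(PASL, PICORE QUIPSS II) and [15O]water-PET-like relative perfusion imaging
— together with a phantom simulator that provides ground truth for every
stage.

## ASL quantification

A PASL acquisition alternates *tag* frames (arterial water magnetically
inverted proximal to the imaging slab) and *control* frames. Pairwise
subtraction dM = control − tag isolates the perfusion-weighted signal, and
with QUIPSS II timing the single-compartment closed form applies:

    f = λ · dM / (2 · α · M0 · TI1 · exp(−TI2 / T1a))

with f in mL/g/s, converted once to mL/100 g/min by the declared constant
6000. Parameter defaults (units, rationale):

| parameter | default | meaning |
|---|---|---|
| TI1 | 0.7 s | tag-bolus duration (time to deliver the tag) |
| TI2 | 1.8 s | inversion-to-imaging time |
| α | 0.98 | inversion (tag) efficiency |
| λ | 0.9 mL/g | blood/tissue water partition coefficient |
| T1a | 1.6 s | longitudinal relaxation time of arterial blood |

M0 (equilibrium magnetization) defaults to the mean control image — the
standard proxy when no separate M0 scan exists — with a pass-through
override for a measured map. Voxels with M0 below 10% of its robust (99th
percentile) maximum are zeroed and flagged invalid (the formula divides by
M0; air is meaningless). The method cannot map rCBF below 10 or above
150 mL/100 g/min reliably; `valid_mask` encodes that range and ROI means
use valid voxels only. The frame order convention (`tag_first` default) is
explicit in the acquisition config and in the aslcontext TSV sidecar
(`volume_type` ∈ {label, control}); no pair-level outlier rejection is
applied.

## PET-like processing

PET perfusion maps carry an arbitrary global scale, so the four repeats of
a condition are averaged (noise efficiency) and the mean image is rescaled
to a whole-brain mean of 50 mL/100 g/min. Normalization is scale-invariant
and idempotent; averaging-then-normalizing is the fixed pipeline order and
assumes repeats within a condition share a global scale (the simulator
draws one scale per subject × condition accordingly). Normalized PET maps
have no per-voxel validity flags; all in-mask voxels count.

## Rigid registration and motion correction

Transforms are 6-parameter rigid mappings in world (mm) coordinates
(Euler x-y-z angles about the volume center, then translation).
Registration minimizes the mean squared intensity difference with cyclic
bounded golden-section line searches over the 6 parameters on a two-level
schedule (isotropic 6 mm smoothing, translations only; then 3 mm, all six
parameters). Three numerical choices matter on a coarse 4×4×8 mm grid:

- Pyramid smoothing is isotropic in millimetres, not voxels: an
  anisotropic kernel does not commute with rotation and biases recovered
  angles toward zero.
- The metric is *symmetric* — each side is resampled by half the candidate
  transform, with cubic B-spline interpolation of precomputed
  coefficients. An asymmetric metric pays an interpolation-blur penalty
  that grows with the transform magnitude, which visibly pulls the optimum
  toward the identity on sharp-edged volumes.
- If the search cannot improve on the identity, the identity is returned
  with a warning rather than a spurious transform.

Motion correction registers every frame to either the first frame or the
temporal mean; with the mean reference the target is rebuilt once from the
corrected frames and the estimation repeated, because the first-pass mean
is smeared by the very motion being estimated. Estimated *motion* is
reported as the inverse of the applied correction, directly comparable to
transforms injected by the simulator.

**Known limitation.** At 4×4×8 mm voxels, fractional-voxel motion is not
fully recoverable by any resampling-based correction: a single trilinear
resampling at acquisition already smears the contrast of a 2-voxel-radius
structure by ~10–20% of its ROI mean (verified against an FFT-exact
unwind). Recovery tests therefore inject integer-voxel in-plane
translations — where resampling is lossless and corrected quantification
matches motion-free quantification to well under 1% — while transform
*estimation* accuracy (≤0.5 voxel, ≤1°) is verified for fractional
translations and rotations separately. Real PASL studies face the same
partial-volume physics.

## ROI statistics

Per-subject, per-condition ROI means feed a two-sided paired t-test per
ROI and modality: t = mean(d)/(sd(d)/√n), d = hypo − eu, sample SD, df =
n − 1, significance at p < 0.05 (strict). Zero-variance differences with
nonzero mean report the 0-limit (t = ±∞, p = 0). The cross-modality
agreement flag marks ROIs significant in both PET and ASL.

Reliability is summarized by the coefficient of variation (COV): the mean
across subjects of the within-subject SD of repeat-level ROI means,
divided by the grand mean of those means, within one condition. The repeat
unit is modality-specific: one of the 4 injections for PET (each repeat
normalized individually, so repeat means are comparable across subjects),
and one tag/control pair for ASL (70 repeats per condition). The per-pair
reading is the one consistent with both reliability calibration and the
observed detectability of ~10% effects at n = 9: if the ASL repeat were an
entire 35-pair scan, a 12% COV would imply a per-ROI paired-test power of
only ~0.55 for a +10% effect, incompatible with both methods detecting all
three responsive ROIs.

## Voxel-wise statistics

The same paired t-test is applied per voxel over the intersection of all
subjects' valid masks, giving t, p and mean-difference maps. Family-wise
error over voxels is controlled by Holm (default), Bonferroni, or sign-flip
max-T permutation — exact for a paired design since each subject's
difference map is sign-symmetric under the null. All 2^n sign patterns are
enumerated when they fit within the permutation budget (always at n ≤ 9
with the default 1000); otherwise random sign vectors are drawn with the
identity always included. Bonferroni ⊆ Holm ⊆ uncorrected holds by
construction. No smoothing is applied by default.

## The phantom

The simulator emulates the study's measurement structure: 9 subjects × 2
conditions; per subject and condition one 140-frame ASL series (70 pairs)
and 4 PET repeats. Anatomy is parametric on a 24×24×12 grid of 4×4×8 mm
voxels: a triaxial ellipsoidal brain (40/32/36 mm semiaxes — deliberately
asymmetric so all three rotation angles are observable by intensity-based
registration), an inner white-matter ellipsoid, spherical named ROIs
(thalamus, medial prefrontal cortex, globus pallidum, right
orbitoprefrontal cortex; 19–33 voxels each), and background gray matter.
Baselines are 60 mL/100 g/min for gray structures and 20 for white matter.

Hypoglycemia multiplies CBF by 1.10 in thalamus, medial prefrontal cortex
and globus pallidum (0 elsewhere). The study reported significance rather
than effect magnitudes, so +10% is a simulation parameter chosen as
plausible for the reported p-values at n = 9; it is configurable. Each
subject carries a single multiplicative factor drawn once from
N(1, 0.10) and shared by both conditions, so the paired design holds by
construction and between-subject variance cancels from the paired
differences.

Forward models: the ASL control frame is the M0 image (binary brain/air,
1000 scanner units; proportionality 1 by convention) and the tag frame is
control minus the dM predicted by inverting the quantification formula —
so the noiseless chain simulate → split → subtract → quantify is exact to
floating point. Frame noise is additive Gaussian (thermal regime), scaled
as a fraction of in-brain M0. PET images are truth × an arbitrary
unrecoverable global scale × (1 + multiplicative Gaussian voxel noise).

Noise scales are not free-floating: `calibrate_noise` bisects the noise SD
until the *pipeline-measured* repeat-level ROI COV (averaged over the four
named ROIs, euglycemia cohort, fixed random substream so the objective is
deterministic and monotone) hits the target. The defaults
`asl_noise_sd = 0.0037` and `pet_noise_sd = 0.33` are the calibration
outputs for the study figures of 12% (ASL) and 6% (PET). All randomness
derives from one root seed through named substreams (per subject,
condition, modality, stage); identical seeds give bit-identical cohorts.

What the phantom does *not* model: realistic anatomy, arterial transit
time maps, k-space/MRI physics, PET sinograms/attenuation, scanner drift,
physiological noise. Passing tests therefore demonstrate correctness of
the analysis contract (formulas, pairing, normalization, statistics,
registration recovery) under the stated noise models — not robustness to
every artifact of real acquisitions.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks run at sizes chosen to keep sampling error well inside
the asserted bands: effect-detection uses 100 simulated cohorts (the null
calibration 200 cohorts, pooled over 4 ROIs × 2 modalities ≈ 1600
independent null tests, SE ≈ 0.006); COV calibration is verified on 10
replicate cohorts per modality; the acceptance script uses 40 effect
cohorts and 100 null cohorts and reports the cohort count alongside every
value. Motion tests use 8–10-frame series, which exercise the same
per-frame estimation path as full-length series.
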