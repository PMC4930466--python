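# pancmorph

Quantitative morphometry of the pancreas from MRI segmentations: organ
**volume** by slice summation, border **irregularity** as a box-counting
fractal dimension (FD) of the projected silhouette, **fat content** by
three-point Dixon water–fat separation, and the two-group / three-timepoint
**cohort statistics** used in diabetes-reversal studies. Because no imaging
data is distributable, the package ships a synthetic-data layer — serrated
organ phantoms, analytic fractal fixtures, Dixon phantoms with known truth
and simulated cohorts — so every stage is testable end to end.

## Who this is for

Imaging scientists who have segmentation masks (manual or automated) of an
abdominal organ and want reproducible, scriptable versions of three common
manual workflows: planimetric volumetry, FracLac-style border fractal
analysis, and ROI-based proton-density fat-fraction readings, plus the group
summary tables and tests that accompany them.

## The measurements

**Volume.** For per-slice polygon ROIs or a 3D binary mask with voxel
spacing (s₀, s₁, s₂) mm, volume is the slice-summation estimate
V = Σ_slices A_slice · s₀, which for a voxel mask is exactly
(count) · s₀s₁s₂. The *pancreas volume index* V / BMI (cm³ m² kg⁻¹)
normalises organ size for body habitus and is computed per individual.

**Border fractal dimension.** The mask is orthographically projected along
an anatomical axis, the outer 8-connected border of the (hole-filled)
silhouette is extracted, and boxes of side s = 2, 4, …, ⌊min dim/4⌋ px are
counted over an ensemble of grid origins (the zero origin plus seeded random
shifts). FD is the OLS slope of log N_min(s) against log(1/s), where
N_min(s) is the smallest count over origins — the minimal-cover estimate of
the covering number. A smooth outline gives FD ≈ 1, a space-filling border
FD → 2; serrated organ borders fall in between. Replicate precision is
quantified as the coefficient of variation (CV, %) of FD over re-randomised
origin ensembles.

**Fat fraction.** From three echoes S₁ = W+F, S₂ = (W−F)e^{iφ},
S₃ = (W+F)e^{2iφ}, the phase error φ is recovered as half the phase of
S₃·conj(S₁), the opposed-phase echo is demodulated, and
FF = 100·F/(W+F) is computed per pixel. Tissue fat percentage follows the
conventional reading scheme: three 100 mm² circular ROIs per slice, two
slices, all averaged. Visceral fat percent at L2–L3 is fat inside the inner
subcutaneous boundary over all fat within the outer boundary.

**Cohort statistics.** Participants are classified as responders when
post-diet fasting plasma glucose is strictly below 7 mmol/l. Summaries are
mean ± SEM per variable × group × timepoint; within-group change uses
Student's paired t, between-group contrasts use the unpaired t
(Mann–Whitney U for fasting insulin), with no multiple-testing correction.

## Worked example

```python
import numpy as np
from pancmorph import (PhantomSpec, generate_organ_phantom, compute_volume,
                       pancreas_volume_index, fd_of_mask)

smooth   = generate_organ_phantom(PhantomSpec(serration_amplitude=0.0, seed=1))
serrated = generate_organ_phantom(PhantomSpec(serration_amplitude=0.3, seed=1))

for name, mask in [("smooth", smooth), ("serrated", serrated)]:
    vol = compute_volume(mask)
    fd, prec = fd_of_mask(mask, axis="anterior_posterior",
                          n_offsets=10, n_replicates=2, seed=1)
    print(f"{name:8s} volume {vol.volume_cm3:6.2f} cm^3   "
          f"index {pancreas_volume_index(vol.volume_cm3, 34.0):.3f} cm^3 m^2 kg^-1   "
          f"FD {fd.fd:.3f}  (replicate CV {prec.cv_percent:.2f}%)")
```

prints

```
smooth   volume  37.70 cm^3   index 1.109 cm^3 m^2 kg^-1   FD 1.003  (replicate CV 0.00%)
serrated volume  39.23 cm^3   index 1.154 cm^3 m^2 kg^-1   FD 1.141  (replicate CV 0.85%)
```

The smooth ellipsoid phantom (semi-axes 30 × 20 × 15 mm) digitises to its
analytic volume 37.70 cm³ and measures FD ≈ 1.0, a smooth curve. Dialling
the serration amplitude to 0.3 roughens the border and FD rises to 1.14 —
the regime reported for diabetic pancreas borders — while the replicate CV
of under 1% shows the estimator, not the organ, contributes little noise.

## Command line

```bash
pancmorph simulate --outdir demo --seed 5          # synthetic demo dataset
pancmorph run --manifest demo/manifest.json --seed 7 --outdir out
pancmorph volume --mask m.nii.gz --bmi 34.0 --out vol.csv
pancmorph fd --mask m.nii.gz --axis ap --offsets 10 --replicates 2 --seed 7 --out fd.csv
pancmorph fat --in-phase ip.nii.gz --opposed op.nii.gz --echo3 e3.nii.gz \
              --rois rois.json --out fat.csv
pancmorph report --cohort cohort.csv --out table1.csv
pancmorph blind --cohort cohort.csv --seed 3 --out blinded.csv --key key.csv
```

`run` executes volume → FD → fat → report for every participant-timepoint in
a manifest, isolates per-participant failures, and writes provenance; given
the same seed and inputs its outputs are byte-identical across reruns.
`blind` supports the blinded-analysis discipline by recoding identities and
stripping group labels.

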