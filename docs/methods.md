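# Methods

This note records the models implemented by pancmorph, the parameters that
matter, the synthetic data the tests run on, and the numerical decisions
taken where the design was genuinely open.

## Conventions

Masks are `(slice, row, col)` arrays, axis 0 inferior → superior, axis 1
anterior → posterior, axis 2 left → right; `voxel_spacing[i]` is mm per
voxel along axis `i`. Polygons live in continuous pixel coordinates in
`(row, col)` order; pixel `(r, c)` occupies `[r, r+1) × [c, c+1)` with its
center at `(r+0.5, c+0.5)`. A pixel belongs to a polygon or disc ROI iff its
center lies inside (strict interior for polygons). These rules make every
rasterisation bit-reproducible; ties of a center lying exactly on a polygon
edge are resolved by the strict-interior rule (excluded).

## Volumetry

Slice-summation volumetry is exact for the voxel representation: volume =
foreground count × voxel volume, reported in cm³ with per-slice areas in
mm². The empty mask is an error (`EmptySegmentationError`), not a zero:
an absent organ is a segmentation failure, and silently reporting 0 cm³
would corrupt group means downstream. The volume index divides by BMI per
individual; aggregation happens in the statistics layer, because the mean
of per-individual ratios is not the ratio of means.

Digitisation error of the center-counting rule is O(h²)-ish for smooth
convex bodies but oscillates: for the (30, 20, 15) mm ellipsoid it is
already below 0.03 % at 1 mm and fluctuates non-monotonically thereafter.
Convergence tests therefore assert strict error decrease on a centred
sphere across 2 → 1 → 0.5 mm and an order-of-magnitude reduction for the
ellipsoid, rather than strict monotonicity of an error already at its
floor.

## Border fractal dimension

Chain: orthographic projection along a stated axis (foreground iff any
voxel along the ray) → nearest-neighbour resampling to isotropic pixels at
the finer in-plane spacing → hole filling → outer border = foreground minus
its 3 × 3 erosion → box counting → log–log fit.

Box sizes form a dyadic ladder from 2 px to ⌊min dimension / 4⌋; fewer than
five sizes is a configuration error because a two-decade-short ladder
cannot support a stable slope. Grid origins are an ensemble: the canonical
zero origin plus `n_offsets − 1` seeded uniform shifts in `[0, s)²` per box
size.

**Estimator.** FD is the OLS slope of log N_min(s) vs log(1/s) with
N_min(s) the minimum count over the origin ensemble. The box-counting
dimension is defined through the minimal covering number, and the minimum
over candidate origins is its direct estimate. The alternative — averaging
per-origin slopes — carries a systematic downward bias on bounded sets
(measured −0.05 to −0.09 on the calibration fixtures) because a shifted
grid splits boxes at the set's edges, inflating counts at large s by a
random +O(s/L) term. Minimal cover measures 1.000 / 1.028 / 2.000 / 1.269
on the line / circle / filled square / iteration-5 Koch curve, against
analytic dimensions 1 / 1 / 2 / 1.2619. Per-origin slopes and R² are still
reported as a grid-placement sensitivity diagnostic.

**Replicates.** A "replicate" re-randomises the origin ensemble on the same
projection; the reported FD is the mean of replicate FDs (two by default,
matching the convention of averaging two measurements per image), and the
replicate CV (100 · SD/mean, sample SD) isolates estimator noise from
anatomy. What distinguished replicate images in the original manual
workflow is not recoverable, so this choice deliberately measures the
estimator-noise floor.

**Projection axis.** Default anterior–posterior, configurable and recorded;
the rendering view used in manual workflows is unstated, and the default is
the view in which the organ outline is conventionally presented.

**Binarisation.** Inputs are binary masks; if a grayscale render is
supplied, Otsu's threshold is the parameter-free default.

## Serrated organ phantom

An ellipsoid (default semi-axes 30, 20, 15 mm — pancreas-like scale) with
radial perturbation r(θ, φ) = r₀(θ, φ)(1 + a·s(θ, φ)). The serration field
s is a seeded random spherical-harmonic sum over degrees ℓ … 3ℓ (default
ℓ = 12, capped at degree 48) with 1/degree amplitude weighting, giving a
dominant lobe frequency with structure across a range of scales; a single
degree produces scallops at one wavelength only, which the silhouette
projection — an envelope over the collapsed ray — largely averages away.
The field is standardised to zero mean and clipped at 2.5 × RMS before
scaling to max |s| = 1, so the containment bound r ≤ r₀(1 + a) is exact
while typical serration depth remains an O(1) fraction of the amplitude
knob `a` (clipping at fewer σ flattens deep serrations and saturates the FD
response at high a; normalising by the un-clipped maximum dilutes typical
depth to near sub-voxel at small a).

Default resolution is 0.25 mm isotropic on a (344, 232, 176) grid: the
smallest amplitude step studied (a = 0.1) produces serrations of roughly
1 mm depth, which 0.5 mm voxels do not resolve. A voxel is foreground iff
its center lies inside the surface; only the shell 1 − a < ρ < 1 + a needs
the angular field, which keeps generation at a few seconds. `a = 0`
short-circuits to the exact digitised ellipsoid.

**Dose–response protocol.** FD is measured over amplitudes
{0, 0.1, 0.2, 0.3, 0.4} with the same seed (hence the same field shape and
origin ensembles) per sweep, averaging 32 replicate ensembles: a single
ensemble's grid-placement noise (~0.02 in FD) is comparable to the
0 → 0.1 amplitude step, and averaging brings the estimator noise an order
of magnitude below the signal. Under these conditions FD increases
strictly with amplitude in ≥ 9 of 10 seeds (roughly 1.02 → 1.15 across the
sweep).

## Dixon phantom and separation

Forward model per pixel, with real non-negative water W and fat F and B0
phase error φ per echo interval: S₁ = W+F, S₂ = (W−F)e^{iφ},
S₃ = (W+F)e^{2iφ}, plus independent Gaussian noise of sd `noise_sd` on the
real and imaginary channel of each echo. `signal_intensity` is the total
W+F per pixel, partitioned by the fat-fraction map, so image SNR is uniform
across the fat range.

Separation: φ̂ = ½·arg(S₃·conj(S₁)) (valid for |φ| < π/2 without
unwrapping), demodulate S₂, average the two in-phase echoes symmetrically
(Ŝ = (S₁ + S₃e^{−2iφ̂})/2 — using both halves the in-phase noise variance),
then W, F from real parts with negatives clamped to zero and counted.
FF = 100·F/(W+F), clamped to [0, 100] with clamp accounting. The estimator
is exact on noiseless data (max error ~1e-14 pp on a 0–50 % ramp) and
invariant to a global intensity rescaling. φ̂ errors enter FF only at second
order, so no phase smoothing is applied by default — it would trade
noiseless exactness for a negligible noise gain.

**SNR convention.** SNR = total signal magnitude / RMS of the complex noise
(per-channel sd × √2). At SNR 50 the measured RMSE over truth FF ∈ [0, 50] %
is ≈ 0.76 pp. Under the per-channel convention (SNR = signal / σ_channel)
the same data measures ≈ 1.07 pp, which is this estimator's information
bound — Var(F̂) = 3σ²/8 already uses all three echoes optimally — so that
number is reported alongside for comparability with either convention.

Magnitude-only input (real arrays) assumes φ = 0 with a warning; ROI
placement on real data is observer-driven and therefore an *input* — the
lowest-variance-disc search is provided only as a labelled convenience for
tests and demos.

## Cohort generator and statistics

The generator emulates the published two-group (12 responders / 17
non-responders) × three-timepoint structure. Cell parameters are the
published group means with per-participant SDs recovered from the printed
SEMs (SD = SEM·√n at n = 12/17). Two drawing modes:

* **`exact_moments=True` (default):** normal draws standardised so each
  cell's sample mean and (n−1) SD equal the targets exactly, in the style
  of `MASS::mvrnorm(empirical = TRUE)`. The week-8 fasting glucose, which
  carries the responder rule, is instead drawn from a gamma distribution on
  the distance to the 7 mmol/l threshold, moment-matched to the target mean
  and SD and sampled by shuffled stratified quantiles — the constraint
  holds by construction and the sample mean tracks the target to O(1/n).
  (A normal truncated at 7 would shift the non-responder mean by ~20 %, and
  iid draws could not reproduce printed means for high-variance variables
  like fasting insulin, whose SD/mean is ~0.6.)
* **`exact_moments=False`:** plain iid normal draws; the constrained
  glucose resamples each participant up to 1000 times before raising a
  constraint error (an infeasible specification fails loudly).

The generator draws cells independently: repeated measures on one synthetic
participant are uncorrelated, which real longitudinal data is not, so
paired-test p-values on synthetic cohorts are conservative and exercise
code paths rather than emulate effect sizes. Values are not clipped to
physiological ranges (a large-SD insulin draw can go negative); normality
itself is an assumption of the generator, not a claim about the source
data, which is summarised only as mean ± SEM. Group moments are matched
per cell; responder/non-responder records otherwise share no structure.

Responder classification is strict: FPG < 7.0 → responder, 7.0 itself →
non-responder. Summaries report mean ± SEM with per-cell n; missing values
are excluded pairwise. Within-group contrasts are paired t on participants
present at both timepoints; between-group contrasts are unpaired (the named
exceptions: Mann–Whitney U for fasting insulin, unpaired t for age and
duration — the table convention of "paired t for everything else" cannot
apply between independent groups, so unpaired t covers those columns). The
Mann–Whitney p is exact by enumeration for tie-free samples with n ≤ 8 and
otherwise uses the tie- and continuity-corrected normal approximation
(within ~0.01 of exact at n = 8). Zero-variance inputs yield an explicit
not-computable result rather than a fabricated p. No multiple-testing
correction is applied anywhere, matching the single-table reporting
convention; interpret families of p-values accordingly.

## Pipeline determinism and provenance

All randomness descends from one root seed, split per (stage, participant,
timepoint) through SHA-256, so adding or removing a participant does not
perturb the others' streams. Provenance records input digests, the config
snapshot (minus the output directory), package version and seed — but no
wall-clock timestamp by default, because rerun byte-identity is the
stronger reproducibility contract; `timestamps=True` restores them.

## What passing tests do and do not show

The synthetic layer validates geometry, estimators and plumbing against
known truth. It does not emulate MRI acquisition physics (coil profiles,
partial volume, motion), realistic pancreas anatomy (head/body/tail
lobulation), inter-observer segmentation variability, or correlated
longitudinal physiology. Published study values (group FDs of 1.13–1.18,
volumes of ~40–52 cm³) arise from 29 participants' scans that are not
distributable; the package reproduces the *methods* and their measurable
properties, not those numbers. Known limitations: FD is measured on one
projected border, not the 3D surface; the Dixon model is single-peak
without T2* correction; phase errors beyond |φ| ≥ π/2 per echo interval
would require unwrapping that is out of scope.
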