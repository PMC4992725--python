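# Methods

## The measurement model

Neuromelanin (NM) chelates paramagnetic metals; with magnetization-transfer
preparation, NM-rich nuclei — the substantia nigra (SN) in the midbrain and
the locus coeruleus (LC) by the floor of the fourth ventricle — appear
hyperintense on T1-weighted images. The package treats an NM image as a
3-D scalar grid indexed (row, column, slice) with anisotropic voxels
(default 0.5 × 0.5 × 3.0 mm), and defines every quantity relative to
reference regions on the same slice:

* **Background statistics.** A reference ROI (4-mm circle in the cerebral
  crus for the SN; 6-mm circle in the pontine tegmentum for the LC) yields
  a mean and a *population* standard deviation. The population SD is used
  because the threshold is a statement about the voxel population, not an
  inference about a sampled mean; repeat averaging across measurement runs
  uses the *sample* SD, because there the repeats are the sample.
* **Segmentation.** A voxel enters the binary map iff its intensity is
  strictly greater than MN_CC + 3 SD_CC (the rule says "greater than", so
  the boundary value is excluded), within a declared mesencephalic search
  region and on the requested side of the mid-sagittal plane (the midline
  is the half-way row of the grid). Per slice and side the largest
  8-connected in-plane component is kept; components are stacked over the
  4 consecutive slices maximizing total suprathreshold area — "slices in
  which the SN is visible" is not otherwise well defined, and this window
  rule is the deterministic operationalization. Fewer than 4 signal
  slices are used as-is with a warning; a side with no suprathreshold
  cluster is returned flagged, not raised.
* **CNR.** CNR_SN per slice is (MN_SN − MN_CC)/SD_CC; the side value is
  the unweighted mean across analyzed slices (no area weighting — the
  source describes a plain average across slices). Both CNRs are invariant
  under positive affine intensity rescalings, which the suite checks to
  1e-9 relative.
* **LC.** LC_MAX is the arg-max intensity voxel within a band of voxels
  within 2 in-plane voxels (Chebyshev) of the fourth-ventricle mask,
  excluding the mask, per side; the radius is a package choice — the
  source says only "adjacent". Ties break to the smallest (row, column).
  LC intensity is the mean of LC_MAX and its 4 in-plane neighbours
  (neighbours off the grid are dropped with a warning).
* **Asymmetry.** AI = |(ipsi − contra)/(ipsi + contra)| × 200 ∈ [0, 200],
  with contra the hemisphere opposite the clinically worse hemibody and
  the right side taken as ipsilateral in controls.

**Iron chain.** For two echoes the log-linear least-squares fit has the
closed form R2* = ln(S1/S2)/(TE2 − TE1); it is exact on noiseless
mono-exponential data (checked to 1e-9 s⁻¹) and invariant to a common
scaling of both echoes. TEs enter in ms and are converted to seconds, so
maps are in s⁻¹. Noise can produce S2 ≥ S1; those voxels are clamped to 0
and flagged invalid (configurable to keep the negative estimate, still
flagged), and nonpositive signals invalidate a voxel rather than raising.
ROI sampling excludes invalid voxels and reports their fraction. Dipole
inversion for susceptibility mapping is deliberately out of scope: the
pipeline consumes susceptibility maps (ppm) as input.

**Statistics.** Group comparisons use the two-sided Mann-Whitney U
(scipy): exact enumeration when both groups have n ≤ 8 without ties,
tie-corrected normal approximation otherwise; an all-tied sample has zero
tie-corrected variance and is short-circuited to p = 1. Spearman
correlations use mid-rank ties and BH-FDR across a *declared* battery
(which tests form one family is a user declaration, not an inference).
ROC candidate cut-offs are midpoints between adjacent distinct pooled
values; the trapezoid AUC equals U/(n₁n₂) (property-tested on random
tables with ties). The three named operating points are: the lowest
cut-off with sensitivity 1 (all patients below it, maximizing
specificity), the highest with specificity 1 (all controls above it,
maximizing sensitivity), and the accuracy maximizer with ties broken by
larger Youden J then smaller cut-off — "best trade-off" is named but not
defined in the source, so the package defines it. Sensitivity and
specificity carry exact Clopper-Pearson 95% CIs (beta inversion, checked
against direct binomial tail inversion for all k ≤ n ≤ 30). Reliability
is ICC(2,1) — two-way random effects, absolute agreement, single
measurement — the conservative choice for one rater repeating single
measurements; it matches pingouin's ICC(A,1) to 1e-9. DAT prediction is
OLS with R², RMSE = √(SSE/(n−p)), leave-one-out PRESS from hat-matrix
leverages (equal to explicit refits to 1e-9), the overall F-test, and
per-predictor partial p-values.

## The phantom generator

The phantoms are minimal digital objects, not anatomy: two SN disk-stacks
spanning the 4 SN slices (per-slice voxel counts follow elliptical
cross-sections and sum exactly to round(volume/voxel volume), so the
ground-truth volume is within half a voxel of the request), crus and
tegmentum cylinders hosting the reference ROIs, a rectangular
fourth-ventricle block, and 5-voxel LC crosses 2 voxels lateral to the
ventricle. Structure intensity is bg_mean + CNR × bg_SD. The LC cross
centre is tipped up by 4ε and each arm down by ε (ε = 0.04 bg_SD): the
5-voxel mean stays exactly at the target while the arg-max localization
becomes deterministic (a perfectly flat cross would tie and the tie-break
would land on an arm, whose neighbourhood includes background).

Noise is additive Gaussian (not Rician): at the contrasts of interest
(CNR ≈ 3.5–5 in SD units) the Gaussian approximation is adequate and
keeps the oracles analytic. For exact oracles the background can instead
carry a deterministic ±bg_SD checkerboard: any region with equal counts
of the two voxel parities then returns the nominal (mean, SD) *exactly*,
so the full ROI → threshold → CNR chain has closed-form values. The
"exact" analysis layout therefore uses rectangular explicit-mask reference
ROIs with an even column count (parity-balanced by construction); the
realistic layout uses the study's circular ROIs, whose odd lattice counts
carry an O(SD/N) parity bias that vanishes under noise anyway.

The cohort generator draws each measure per group from a zero-truncated
normal at the printed group mean/SD (volumes, CNRs, binding ratios and
rates are physically nonnegative; at these means the truncation is
numerically negligible). Within the patient group, contralateral SN
volume and putaminal DAT binding are coupled by a Gaussian copula at a
target *rank* correlation (default 0.75 — the study's correlation claims
are Spearman and it reports SN volume as "highly correlated" with DAT
binding without printing the coefficient), using the sin transform
r = 2 sin(πρ/6) and mapping through the truncated-normal quantile
function, which preserves ranks. Sides are drawn independently (no side
correlation is reported), so the derived asymmetry-index columns are
computed from the drawn sides and are wider than the printed AI
distributions; they are internally consistent rather than
distribution-matched. Clinical covariates (age, disease duration, UPDRS
scores) are rough truncated-normal emulations of the reported medians and
ranges, present so that correlation batteries against clinical variables
can be exercised.

**What the phantoms do not model** — and hence what passing tests do not
show about real data: Rician noise at low SNR, B1/magnetization-transfer
inhomogeneity across slices, partial-volume blurring beyond voxelization,
anatomical variation in structure shape and position (placement is
conventional, not anatomical), and any systematic rater behaviour beyond
±1-voxel ROI re-placement jitter.

## Repeats and reliability emulation

NM measurements are repeated (default 4) with every circular reference
ROI re-placed under ±1-voxel uniform jitter, emulating intra-rater
variability in background placement; means and sample SDs across repeats
are reported and the per-repeat values feed the ICC. Iron measurements
are repeated twice; the second delineation is emulated as a conservative
inner trace (the mask eroded by one in-plane voxel, falling back to the
original where erosion would empty it) — a re-drawn ROI varies at the
boundary but stays on the structure, whereas a rigid shift would sample
neighbouring tissue and bias the mean.

## Numerical choices and degenerate inputs

* Circle rasterization: voxel-centre convention, 0-based indices; a
  circle must lie fully inside the grid.
* Strict ">" at the segmentation threshold; thresholding a constant
  (noiseless, texture-free) background is degenerate — SD_CC = 0 raises,
  which is why the exact oracles use the checkerboard texture.
* Volume is monotone non-increasing in the threshold multiplier
  (property-tested at 3 → 4 → 5).
* R2* clamp-vs-exclude for negative apparent rates: clamp to 0 by
  default, flagged either way.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; identical spec + seed is
  bit-reproducible, and the run manifest hashes every input and output.

## Known limitations

Under full noise (noise SD = background SD) the threshold chain is
*biased by design*: at a constructed CNR of 4.28, about 10% of true SN
voxels fall below the MN + 3 SD cut, so the recovered volume
underestimates truth by several percent while the kept-voxel mean — and
hence CNR_SN — overestimates the constructed contrast; this is a property
of threshold segmentation itself, not of the implementation, and any
cut-off calibrated on such measurements inherits it. The 5-voxel LC cross
is fragile under heavy noise: the located maximum can land on an arm,
pulling background voxels into the LC mean and underestimating CNR_LC;
the noiseless and low-noise regimes recover the constructed value
exactly. LC volumetry and nigral pars compacta/reticulata subdivision are
intentionally unsupported, and the statistics layer omits demographic
chi-squared tests and stepwise-regression analyses peripheral to the
measurement pipeline.

## Problem sizes

The test suite and the acceptance script run on small grids (64 × 64 × 12
NM phantoms, 64 × 64 × 16 iron phantoms), 18-per-group cohorts for the
integration checks, and 5000-per-group cohorts for the ROC operating
characteristics, where the empirical AUC has a standard error of ≈0.003
— comfortably inside the ±0.01 window used to compare against the
binormal closed form Φ((344−236)/√(50²+51²)) = 0.935.
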