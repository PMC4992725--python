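# nigrascan

Quantification of the substantia nigra (SN) and locus coeruleus (LC) from
neuromelanin-sensitive and iron-sensitive MRI, for researchers studying
Parkinson's disease (PD): the loss of neuromelanin-containing dopaminergic
neurons makes the SN smaller and fainter on magnetization-transfer-prepared
T1-weighted images, and the package measures exactly that — together with
the iron-sensitive maps (R2*, magnetic susceptibility) of the same region
and the cohort statistics used to relate the imaging measures to striatal
dopamine-transporter (DAT) binding from FP-CIT SPECT.

Because no patient data are distributable, the package ships a synthetic
phantom and cohort generator with exact ground truth; every measurement
rule is validated against closed-form expectations on those phantoms.

## What it computes

**NM-MRI chain** (`nigrascan.nm`). Circular 4-mm background ROIs in the
cerebral crus give per-slice, per-side statistics (MN_CC, SD_CC, population
SD). The binary map keeps voxels with intensity strictly greater than

    MN_CC + 3 × SD_CC

restricted to a mesencephalic search region; per slice the largest
8-connected component on each side of the midline is the SN, stacked over
the four consecutive slices with the most suprathreshold area. Then

    SN volume = voxel count × voxel volume (mm³)
    CNR_SN    = (MN_SN − MN_CC) / SD_CC          (averaged across slices)

The LC is located per slice as the brightest voxel adjacent to the fourth
ventricle (LC_MAX); its intensity is the mean of LC_MAX and its four
in-plane neighbours, referenced to a 6-mm pontine-tegmentum ROI:

    CNR_LC = (MN_LC − MN_TG) / SD_TG             (averaged over 3 slices)

CNRs can be normalized to the healthy-control median (%CNR), and left–right
imbalance is scored by the asymmetry index

    AI = |(ipsi − contra) / (ipsi + contra)| × 200

(contra = hemisphere opposite the clinically worse body side). All
measurements are repeated with re-placed ROIs and averaged.

**Iron chain** (`nigrascan.iron`). From a dual-echo gradient-echo magnitude
pair, the two-point log fit

    R2* = ln(S(TE1) / S(TE2)) / (TE2 − TE1)      (s⁻¹, TE in seconds)

with clamping/validity rules for non-decaying voxels; SN ROI masks sample
the R2* and susceptibility maps (unweighted means, two-repeat averaging).

**Cohort statistics** (`nigrascan.stats`). Mann-Whitney U group
comparisons, Spearman correlation batteries with Benjamini-Hochberg FDR,
ROC analysis (trapezoid AUC = U/(n₁n₂), three named cut-offs, exact
Clopper-Pearson CIs), ICC(2,1) intra-rater reliability, and OLS prediction
of DAT binding with R², RMSE and leave-one-out PRESS.

**Phantoms and cohorts** (`nigrascan.phantom`). NM slabs at 0.5×0.5×3.0 mm
with SN/LC targets of controlled true volume and contrast, mono-exponential
dual-echo pairs, susceptibility maps, and subject tables drawn from the
printed PD/HC group distributions with a Gaussian-copula rank coupling
between SN volume and putaminal DAT binding.

## Worked example

```python
from nigrascan import default_nm_spec, make_nm_phantom, nm_layout
from nigrascan.nm import measure_sn, measure_lc
from nigrascan.phantom import LABEL_CODES, CohortSpec, make_cohort
from nigrascan.stats import group_compare, roc_analysis

# a noiseless phantom built at the PD group means: 236 mm³, CNR 4.28 / 3.54
spec = default_nm_spec(sn_volume_mm3=236.0, sn_cnr=4.28, lc_cnr=3.54,
                       noise_sd=0.0, texture="checkerboard")
ph = make_nm_phantom(spec)
layout = nm_layout(spec, exact=True)
sn = measure_sn(ph.vol, layout.bg_rois, layout.search_mask)
lc = measure_lc(ph.vol, ph.labels == LABEL_CODES["fourth_ventricle"],
                list(layout.lc_slices), layout.teg_rois)
print(f"SN volume (left):  {sn['left'].volume_mm3:.2f} mm^3")
print(f"CNR_SN   (left):  {sn['left'].cnr:.4f}")
print(f"CNR_LC   (left):  {lc['left'].cnr:.4f}")

# a simulated 18 + 18 cohort, compared and classified
cohort = make_cohort(CohortSpec(seed=0))
cmp = group_compare(cohort, "sn_volume_contra")
roc = roc_analysis(cohort, "sn_volume_contra", direction="lower")
best = roc.cutoff_best_accuracy
print(f"Mann-Whitney U = {cmp.u_statistic:.1f}, p = {cmp.p_value:.2e}")
print(f"AUC = {roc.auc:.3f}")
print(f"best cut-off {best.cutoff:.0f} mm^3: sens {best.sensitivity:.0%} "
      f"(CI {best.ci_sensitivity[0]:.2%}-{best.ci_sensitivity[1]:.2%}), "
      f"spec {best.specificity:.0%}, acc {best.accuracy:.0%}")
```

prints

```
SN volume (left):  236.25 mm^3
CNR_SN   (left):  4.2800
CNR_LC   (left):  3.5400
Mann-Whitney U = 14.0, p = 3.06e-06
AUC = 0.957
best cut-off 271 mm^3: sens 89% (CI 65.29%-98.62%), spec 94%, acc 92%
```

The recovered volume is the requested 236 mm³ rounded to whole voxels
(315 × 0.75 mm³), both CNRs are exact because the phantom background is
deterministic, and on an 18-per-group cohort drawn from the study's group
distributions the SN volume separates PD from HC with an AUC near 0.95 and
an accuracy-maximizing cut-off in the high 200s of mm³.

There is also a CLI mirroring the library (`nigrascan phantom | nm | iron |
stats | run | accept`); `nigrascan run` executes the whole synthetic
pipeline and writes CSV/JSON reports plus a manifest with input/output
hashes — reruns with the same seed are byte-identical.

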