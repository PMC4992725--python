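"""Headline end-to-end checks, recomputed from scratch.

Each entry generates its own synthetic input at the study's parameter
values, runs the full measurement chain on it, and reports the measured
quantity:

* ``t1``/``t2`` — SN volume (mm^3) recovered by the threshold-segmentation
  chain on noiseless phantoms built at the PD / HC contralateral group
  means (236 / 344 mm^3) with 0.5 x 0.5 x 3.0 mm voxels.
* ``t3`` — CNR_SN measured on a phantom constructed at 4.28 background-SD
  units of SN contrast.
* ``t4`` — CNR_LC measured on a phantom with the LC cross at 3.54
  tegmentum-SD units.
* ``t5`` — SN-ROI mean of the two-point R2* fit on a noiseless dual-echo
  pair (TE 9.2 / 23 ms) generated at 41.17 s^-1.
* ``t7``-``t10`` — ROC operating characteristics of contralateral SN
  volume on large simulated cohorts (5000 per group) drawn from the two
  printed group distributions: trapezoid AUC, and sensitivity /
  specificity / accuracy (%) at the 292 mm^3 cut-off.

The noiseless phantoms use the deterministic checkerboard background with
parity-balanced reference ROIs, so every exact target has a closed-form
expected value (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .iron import DualEchoPair, fit_r2star, sample_sn_rois
from .nm import measure_lc, measure_sn
from .phantom import (
    CohortSpec,
    default_iron_spec,
    default_nm_spec,
    LABEL_CODES,
    make_cohort,
    make_dual_echo_phantom,
    make_nm_phantom,
    nm_layout,
)
from .stats import confusion_at_cutoff, roc_analysis

__all__ = [
    "run_acceptance",
    "recover_sn_volume",
    "recover_cnr_sn",
    "recover_cnr_lc",
    "recover_r2star",
    "roc_on_cohort",
]

#: the accuracy-maximizing SN-volume cut-off (mm^3) evaluated in t8-t10
SN_VOLUME_CUTOFF = 292.0


def _exact_phantom(sn_volume: float = 344.0, sn_cnr: float = 4.91, lc_cnr: float = 4.89):
    spec = default_nm_spec(sn_volume_mm3=sn_volume, sn_cnr=sn_cnr, lc_cnr=lc_cnr,
                           noise_sd=0.0, texture="checkerboard")
    return make_nm_phantom(spec), nm_layout(spec, exact=True)


def recover_sn_volume(sn_volume_mm3: float, sn_cnr: float = 5.0) -> tuple[float, int]:
    """Segmented SN volume (mm^3) on a noiseless phantom; returns (value, n voxels)."""
    ph, layout = _exact_phantom(sn_volume=sn_volume_mm3, sn_cnr=sn_cnr)
    sn = measure_sn(ph.vol, layout.bg_rois, layout.search_mask, layout.sn_window)
    n = int(sn["left"].mask.sum())
    return float(sn["left"].volume_mm3), n


def recover_cnr_sn(sn_cnr: float) -> tuple[float, int]:
    """Side-average CNR_SN measured on a noiseless phantom built at ``sn_cnr``."""
    ph, layout = _exact_phantom(sn_cnr=sn_cnr)
    sn = measure_sn(ph.vol, layout.bg_rois, layout.search_mask, layout.sn_window)
    return float(sn["left"].cnr), int(sn["left"].mask.sum())


def recover_cnr_lc(lc_cnr: float) -> tuple[float, int]:
    """Three-slice CNR_LC measured on a noiseless phantom built at ``lc_cnr``."""
    ph, layout = _exact_phantom(lc_cnr=lc_cnr)
    ventricle = ph.labels == LABEL_CODES["fourth_ventricle"]
    lc = measure_lc(ph.vol, ventricle, list(layout.lc_slices), layout.teg_rois)
    return float(lc["left"].cnr), len(lc["left"].cnr_per_slice)


def recover_r2star(r2star: float) -> tuple[float, int]:
    """SN-ROI mean of the two-point R2* fit on a noiseless dual-echo pair."""
    spec = default_iron_spec(r2star=r2star, noise_sd=0.0)
    de = make_dual_echo_phantom(spec)
    qmap = fit_r2star(DualEchoPair(de.te1, de.te2, spec.te1_ms, spec.te2_ms))
    sample = sample_sn_rois(qmap, {"left": de.mask("SN_left")})
    return float(sample["left"].mean), sample["left"].n


def roc_on_cohort(seed: int, n_per_group: int = 5000) -> dict[str, float]:
    """AUC and 292 mm^3 operating point on a large simulated cohort."""
    cohort = make_cohort(CohortSpec(n_pd=n_per_group, n_hc=n_per_group, seed=seed))
    roc = roc_analysis(cohort, "sn_volume_contra", direction="lower")
    pd_vals = cohort.loc[cohort.group == "PD", "sn_volume_contra"].to_numpy()
    hc_vals = cohort.loc[cohort.group == "HC", "sn_volume_contra"].to_numpy()
    sens, spec, acc = confusion_at_cutoff(pd_vals, hc_vals, SN_VOLUME_CUTOFF, "lower")
    return {"auc": roc.auc, "sensitivity_pct": sens * 100.0,
            "specificity_pct": spec * 100.0, "accuracy_pct": acc * 100.0,
            "n": 2 * n_per_group}


def run_acceptance(seed: int = 1) -> dict[str, dict[str, float]]:
    """Recompute every headline quantity; see the module docstring."""
    ss = np.random.SeedSequence(seed)
    cohort_seed = int(ss.generate_state(1)[0] % (2**31))

    v1, n1 = recover_sn_volume(236.0)
    v2, n2 = recover_sn_volume(344.0)
    c3, n3 = recover_cnr_sn(4.28)
    c4, n4 = recover_cnr_lc(3.54)
    r5, n5 = recover_r2star(41.17)
    roc = roc_on_cohort(cohort_seed)

    return {
        "t1": {"value": round(v1, 4), "n": n1},
        "t2": {"value": round(v2, 4), "n": n2},
        "t3": {"value": round(c3, 6), "n": n3},
        "t4": {"value": round(c4, 6), "n": n4},
        "t5": {"value": round(r5, 6), "n": n5},
        "t7": {"value": round(roc["auc"], 4), "n": roc["n"]},
        "t8": {"value": round(roc["sensitivity_pct"], 2), "n": roc["n"]},
        "t9": {"value": round(roc["specificity_pct"], 2), "n": roc["n"]},
        "t10": {"value": round(roc["accuracy_pct"], 2), "n": roc["n"]},
    }
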